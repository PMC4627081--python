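"""Readers and writers for the external formats the pipeline touches.

Three input dialects are supported, each strict and documented:

* Canal-style ``.ser`` helical-parameter series: optional ``#`` comment
  lines, then whitespace-separated rows with a leading time (ps) or frame
  column followed by one value per base-pair/step level.
* GROMACS-style ``.xvg`` scalar series: ``#``/``@`` metadata lines, then
  exactly two numeric columns (time, value).
* An IARC-like mutation TSV with header
  ``record_id  codon  site_key  context5  ref  context3  alt  stratum``.

The 11-sequence TP53 duplex panel (11-mers with a central 5-MeC.G CpG,
the guanine at position 6 being the BPDE adduct site) ships as packaged
data and is loaded with :func:`load_fixture_panel`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETER_NAMES",
    "INTRA_BP_PARAMETERS",
    "STEP_PARAMETERS",
    "AXIS_PARAMETERS",
    "ROTATION_PARAMETERS",
    "HelicalSeries",
    "ScalarSeries",
    "MutationRecord",
    "DuplexFixture",
    "BondGeometrySeries",
    "FormatError",
    "SchemaError",
    "read_ser",
    "write_ser",
    "read_xvg",
    "write_xvg",
    "read_mutation_table",
    "write_mutation_table",
    "read_geometry",
    "write_geometry",
    "load_fixture_panel",
]

#: The six intra-base-pair parameters (one value per base pair, 11 levels
#: for an 11-mer duplex).
INTRA_BP_PARAMETERS = ("shear", "buckle", "stretch", "propeller", "stagger", "opening")
#: The six base-pair-step parameters (one value per step, 10 levels).
STEP_PARAMETERS = ("shift", "tilt", "slide", "roll", "rise", "twist")
#: The five helical-axis parameters (per base pair, 11 levels).
AXIS_PARAMETERS = ("xdisp", "ydisp", "axis_bend", "inclination", "tip")

PARAMETER_NAMES = frozenset(INTRA_BP_PARAMETERS + STEP_PARAMETERS + AXIS_PARAMETERS)

#: Parameters measured in degrees; the rest are translations in Angstrom.
ROTATION_PARAMETERS = frozenset(
    {"buckle", "propeller", "opening", "tilt", "roll", "twist",
     "axis_bend", "inclination", "tip"}
)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class SchemaError(ValueError):
    """A tabular file is missing required columns."""


def _level_kind_for(parameter_name: str) -> str:
    return "per-step" if parameter_name in STEP_PARAMETERS else "per-base-pair"


@dataclass
class HelicalSeries:
    """A frames x levels matrix for one named helical parameter.

    ``values[i, j]`` is the parameter at time ``times[i]`` (ps) and level
    ``levels[j]``.  Levels are 1-based; for per-step parameters step ``i``
    spans base pairs ``i`` and ``i + 1``.  Rotations are in degrees,
    translations in Angstrom.
    """

    parameter_name: str
    times: np.ndarray
    values: np.ndarray
    level_kind: str = ""
    levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.parameter_name not in PARAMETER_NAMES:
            raise ValueError(
                f"unknown helical parameter {self.parameter_name!r}; "
                f"expected one of {sorted(PARAMETER_NAMES)}"
            )
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError(
                f"row count {self.values.shape[0]} != number of times "
                f"{self.times.shape[0]}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.level_kind:
            self.level_kind = _level_kind_for(self.parameter_name)
        if not self.levels:
            self.levels = tuple(range(1, self.values.shape[1] + 1))
        elif len(self.levels) != self.values.shape[1]:
            raise ValueError("levels must match the number of value columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]


@dataclass
class ScalarSeries:
    """A single time series, e.g. RMSD (nm) or total energy (kJ/mol)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class MutationRecord:
    """One curated base substitution with trinucleotide context and stratum."""

    record_id: str
    codon: int
    site_key: str
    context5: str
    ref: str
    context3: str
    alt: str
    stratum: str = "unknown"

    def __post_init__(self) -> None:
        for base in (self.context5, self.ref, self.context3, self.alt):
            if base not in _VALID_BASES:
                raise ValueError(f"invalid base {base!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.stratum not in ("smoker", "nonsmoker", "unknown"):
            object.__setattr__(self, "stratum", "unknown")

    def opposite_strand(self) -> "MutationRecord":
        """The same substitution written on the complementary strand."""
        return MutationRecord(
            record_id=self.record_id,
            codon=self.codon,
            site_key=self.site_key,
            context5=_COMPLEMENT[self.context3],
            ref=_COMPLEMENT[self.ref],
            context3=_COMPLEMENT[self.context5],
            alt=_COMPLEMENT[self.alt],
            stratum=self.stratum,
        )


@dataclass(frozen=True)
class DuplexFixture:
    """One 11-mer duplex of the TP53 panel.

    The methylated cytosine sits at position 5 and the adducted guanine at
    position 6 (1-based top strand).  ``observed_gt`` is the number of
    G:C>T:A substitutions recorded at the guanine in lung tumours and
    ``printed_p`` the binomial point probability reported for it.
    """

    codon: int
    sequence: str
    hotspot_status: str
    observed_gt: int
    printed_p: float
    adduct_level: int = 6
    methyl_level: int = 5

    def __post_init__(self) -> None:
        if len(self.sequence) != 11:
            raise ValueError("panel sequences are 11-mers")
        if self.sequence[self.methyl_level - 1] != "C":
            raise ValueError("position 5 must be the methylated cytosine")
        if self.sequence[self.adduct_level - 1] != "G":
            raise ValueError("position 6 must be the adducted guanine")

    @property
    def adduct_context(self) -> tuple[str, str, str]:
        """(5' base, G, 3' base) around the adducted guanine."""
        i = self.adduct_level - 1
        return self.sequence[i - 1], self.sequence[i], self.sequence[i + 1]


@dataclass
class BondGeometrySeries:
    """Per-frame Watson-Crick H-bond geometry at one base pair.

    ``distances[i]`` holds the three donor-acceptor distances (Angstrom)
    and ``angles[i]`` the three D-H...A angles (degrees) at ``times[i]``.
    """

    times: np.ndarray
    distances: np.ndarray
    angles: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.atleast_2d(np.asarray(self.distances, dtype=float))
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        n = self.times.shape[0]
        if self.distances.shape != (n, 3) or self.angles.shape != (n, 3):
            raise ValueError("distances and angles must be n_frames x 3")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise ValueError("angles must lie in [0, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]


# ---------------------------------------------------------------------------
# Canal-style .ser


def read_ser(
    path: str | Path,
    parameter_name: str | None = None,
    *,
    frame_index: bool = False,
    dt: float = 2.0,
) -> HelicalSeries:
    """Read a Canal-style ``.ser`` file into a :class:`HelicalSeries`.

    The first column is the time in ps, or a frame index converted via
    ``dt`` when ``frame_index`` is true.  The parameter name is taken, in
    order of precedence, from the ``parameter_name`` argument, a leading
    ``# <name>`` comment whose token is a known parameter, or the file
    stem.  Ragged rows and malformed numeric tokens are rejected with the
    offending line number.
    """
    path = Path(path)
    header_name: str | None = None
    times: list[float] = []
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                token = line.lstrip("#").strip().split()
                if token and token[0].lower() in PARAMETER_NAMES:
                    header_name = token[0].lower()
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            try:
                numbers = [float(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric token ({exc})")
            if width is None:
                width = len(numbers)
            elif len(numbers) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(numbers)} columns, "
                    f"expected {width})"
                )
            times.append(numbers[0])
            rows.append(numbers[1:])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    name = parameter_name or header_name or path.stem.lower()
    if name not in PARAMETER_NAMES:
        raise FormatError(
            f"{path}: cannot infer a helical parameter name from {name!r}; "
            "pass parameter_name explicitly"
        )
    t = np.asarray(times, dtype=float)
    if frame_index:
        t = t * dt
    return HelicalSeries(parameter_name=name, times=t, values=np.asarray(rows))


def write_ser(series: HelicalSeries, path: str | Path) -> None:
    """Write a ``.ser`` file that :func:`read_ser` reproduces exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {series.parameter_name}\n")
        for t, row in zip(series.times, series.values):
            fh.write(" ".join([repr(float(t))] + [repr(float(v)) for v in row]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# XVG


def read_xvg(path: str | Path, label: str = "") -> ScalarSeries:
    """Read a two-column GROMACS-style ``.xvg`` series.

    Lines starting with ``#`` or ``@`` are metadata.  A ``@ title``
    directive supplies the label when none is given.  Data rows must have
    exactly two columns.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    title = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("@"):
                if line[1:].strip().startswith("title"):
                    title = line.split("title", 1)[1].strip().strip('"')
                continue
            if line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(tokens)}"
                )
            try:
                t, v = float(tokens[0]), float(tokens[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric token ({exc})")
            times.append(t)
            values.append(v)
    if not times:
        raise FormatError(f"{path}: no data rows")
    return ScalarSeries(times=np.asarray(times), values=np.asarray(values),
                        label=label or title)


def write_xvg(series: ScalarSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if series.label:
            fh.write(f'@ title "{series.label}"\n')
        for t, v in zip(series.times, series.values):
            fh.write(f"{float(t)!r} {float(v)!r}\n")


# ---------------------------------------------------------------------------
# Mutation table

_MUTATION_COLUMNS = (
    "record_id", "codon", "site_key", "context5", "ref", "context3", "alt", "stratum",
)


def read_mutation_table(
    path: str | Path | io.TextIOBase,
    *,
    sep: str = "\t",
) -> tuple[list[MutationRecord], int]:
    """Read an IARC-like mutation table.

    Returns ``(records, n_rejected)`` where ``n_rejected`` counts rows
    dropped because ``ref == alt``.  Stratum values outside
    ``{smoker, nonsmoker}`` (e.g. ``ex-smoker``) map to ``unknown``;
    pooling of smokers/ex-smokers is the caller's choice upstream of this
    reader.  ``sep=","`` tolerates comma-separated exports.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing column(s): {', '.join(missing)}")
    records: list[MutationRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        if row.ref == row.alt:
            n_rejected += 1
            continue
        stratum = row.stratum if row.stratum in ("smoker", "nonsmoker") else "unknown"
        records.append(
            MutationRecord(
                record_id=str(row.record_id),
                codon=int(row.codon),
                site_key=str(row.site_key),
                context5=str(row.context5),
                ref=str(row.ref),
                context3=str(row.context3),
                alt=str(row.alt),
                stratum=stratum,
            )
        )
    return records, n_rejected


def write_mutation_table(
    records: Iterable[MutationRecord],
    path: str | Path,
    *,
    sep: str = "\t",
) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_MUTATION_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Bond geometry TSV

_GEOMETRY_COLUMNS = ("time_ps", "d1", "d2", "d3", "g1", "g2", "g3")


def read_geometry(path: str | Path, label: str = "") -> BondGeometrySeries:
    """Read a per-frame H-bond geometry table (time_ps, d1..d3, g1..g3)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"geometry table missing column(s): {', '.join(missing)}")
    return BondGeometrySeries(
        times=df["time_ps"].to_numpy(float),
        distances=df[["d1", "d2", "d3"]].to_numpy(float),
        angles=df[["g1", "g2", "g3"]].to_numpy(float),
        label=label,
    )


def write_geometry(series: BondGeometrySeries, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.times, series.distances, series.angles]),
        columns=_GEOMETRY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged TP53 duplex panel


def load_fixture_panel() -> list[DuplexFixture]:
    """The 11 TP53 duplex sequences with their lung-cancer G:C>T:A counts.

    Every sequence carries the central 5-MeC.G CpG: cytosine at position 5,
    the (adducted) guanine at position 6.
    """
    with resources.files("dnadistort.data").joinpath("tp53_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        DuplexFixture(
            codon=int(row.codon),
            sequence=str(row.sequence),
            hotspot_status=str(row.hotspot_status),
            observed_gt=int(row.observed_gt),
            printed_p=float(row.printed_p),
        )
        for row in df.itertuples(index=False)
    ]
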