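"""Synthetic stand-ins for every input the pipeline consumes.

Real inputs come from upstream tools (GROMACS for RMSD/energy, Curves+
and Canal for helical parameters, a curated mutation database for
substitution records).  None of those runs can ship with the package, so
each input is emulated with planted, recoverable structure:

* mutation tables: M substitutions multinomially allocated over S guanine
  sites, with chosen sites enriched by a configurable factor and
  smoker/non-smoker strata assigned per site;
* helical-parameter trajectories: AR(1) series per level around target
  medians, with an adduct effect (median shift at the CpG levels 5/6 and
  a buckle/opening sign flip at the methylated cytosine, the
  codon-157-like pattern) switched on for adducted runs;
* H-bond geometry: Gaussian perturbations around ideal Watson-Crick
  values at the adducted pair;
* RMSD series: piecewise-stationary Gaussian plateaus (a low
  equilibration plateau followed by a higher production plateau).

Every generator is a pure function of its configuration and seed:
identical seeds give identical output, and written files round-trip
through :mod:`dnadistort.io_formats` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .hbond_quality import IdealBondParams, IDEAL_GC
from .io_formats import (
    INTRA_BP_PARAMETERS,
    STEP_PARAMETERS,
    PARAMETER_NAMES,
    ROTATION_PARAMETERS,
    BondGeometrySeries,
    HelicalSeries,
    MutationRecord,
    ScalarSeries,
    load_fixture_panel,
)
from .mfa import VariableGroup
from .signature_builder import CHANNELS, Channel96

__all__ = [
    "MutationSimConfig",
    "TrajectorySimConfig",
    "gen_mutation_table",
    "gen_helical_trajectory",
    "gen_bond_geometry",
    "gen_rmsd_series",
    "gen_mfa_panel",
    "gen_signature_records",
    "BASELINE_MEDIANS",
    "BASELINE_IQRS",
]

#: Gaussian IQR-to-sigma conversion: IQR = 2 * Phi^-1(0.75) * sigma.
_IQR_TO_SD = 1.0 / 1.3489795003921634

#: Near-canonical B-DNA per-level medians (degrees for rotations, Angstrom
#: for translations).  Buckle and opening carry non-zero baselines so the
#: adduct sign flip is observable.
BASELINE_MEDIANS: dict[str, float] = {
    "shear": 0.0, "buckle": 6.0, "stretch": -0.1, "propeller": -11.0,
    "stagger": 0.1, "opening": 2.0,
    "shift": 0.0, "tilt": 0.0, "slide": 0.2, "roll": 1.5, "rise": 3.32,
    "twist": 34.3,
    "xdisp": -0.5, "ydisp": 0.0, "axis_bend": 2.0, "inclination": 2.0,
    "tip": 0.0,
}

#: Typical per-level MD fluctuation scales (25th-75th percentile span).
BASELINE_IQRS: dict[str, float] = {
    name: (8.0 if name in ROTATION_PARAMETERS else 0.6)
    for name in PARAMETER_NAMES
}


# ---------------------------------------------------------------------------
# Mutation tables


@dataclass
class MutationSimConfig:
    """Configuration for an IARC-like synthetic mutation table.

    ``m_total`` substitutions fall on ``n_sites`` guanine sites; sites in
    ``enriched`` receive ``factor``-fold the baseline weight.  Strata are
    smoker/nonsmoker with ``smoker_fraction`` overall; enriched sites use
    ``enriched_smoker_fraction`` (hotspot sites in lung-cancer data are
    smoker-dominated).  Defaults mirror the curated panel scale: 421
    substitutions over 353 candidate guanines.
    """

    n_sites: int = 353
    m_total: int = 421
    enriched: Mapping[str, float] = field(default_factory=dict)
    smoker_fraction: float = 0.75
    enriched_smoker_fraction: float = 0.95
    seed: int = 0

    def site_keys(self) -> list[str]:
        width = len(str(self.n_sites))
        return [f"s{i + 1:0{width}d}" for i in range(self.n_sites)]

    def validate(self) -> None:
        if self.n_sites < 1 or self.m_total < 0:
            raise ValueError("need n_sites >= 1 and m_total >= 0")
        known = set(self.site_keys())
        for key, factor in self.enriched.items():
            if key not in known:
                raise ValueError(f"enrichment on unknown site {key!r}")
            if factor < 1:
                raise ValueError(f"enrichment factor must be >= 1, got {factor}")
        for frac in (self.smoker_fraction, self.enriched_smoker_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def gen_mutation_table(config: MutationSimConfig) -> list[MutationRecord]:
    """Draw a reproducible mutation table (all G:C>T:A, i.e. G>T records).

    Counts are multinomial with enriched sites upweighted.  Enriched
    sites take their trinucleotide context (and codon number) from the
    TP53 duplex panel, cycling through it in key order; other sites draw
    uniform flanking bases.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    keys = config.site_keys()
    weights = np.ones(config.n_sites)
    for i, key in enumerate(keys):
        if key in config.enriched:
            weights[i] = config.enriched[key]
    probs = weights / weights.sum()
    counts = rng.multinomial(config.m_total, probs)

    panel = load_fixture_panel()
    enriched_keys = sorted(config.enriched)
    fixture_for = {
        key: panel[i % len(panel)] for i, key in enumerate(enriched_keys)
    }
    bases = np.array(list("ACGT"))
    records: list[MutationRecord] = []
    rid = 0
    for i, (key, n_here) in enumerate(zip(keys, counts)):
        if n_here == 0:
            continue
        if key in fixture_for:
            fx = fixture_for[key]
            c5, _, c3 = fx.adduct_context
            codon = fx.codon
            p_smoker = config.enriched_smoker_fraction
            flanks = [(c5, c3)] * n_here
        else:
            codon = i + 1
            p_smoker = config.smoker_fraction
            flanks = list(zip(rng.choice(bases, n_here), rng.choice(bases, n_here)))
        smoker = rng.random(n_here) < p_smoker
        for j in range(n_here):
            rid += 1
            records.append(
                MutationRecord(
                    record_id=f"r{rid:05d}",
                    codon=codon,
                    site_key=key,
                    context5=str(flanks[j][0]),
                    ref="G",
                    context3=str(flanks[j][1]),
                    alt="T",
                    stratum="smoker" if smoker[j] else "nonsmoker",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Helical-parameter trajectories


@dataclass
class TrajectorySimConfig:
    """Configuration for a synthetic 17-parameter helical trajectory.

    Defaults follow the production protocol emulated by the pipeline:
    11 levels, 2-ps sampling over 10 ns (5001 frames; 4851 survive the
    300-ps equilibration discard).  Temporal correlation is AR(1) with
    coefficient ``ar1``; the marginal noise scale is set from the target
    IQR via IQR = 1.349 sigma, applied after correcting for the AR(1)
    stationary variance, so the planted IQR is the stationary IQR.

    The adduct effect adds ``rotation_shift`` (deg) / ``translation_shift``
    (Angstrom) to the target median at ``adduct_levels`` and flips the
    sign of the target median of ``sign_flip_params`` at the methylated
    cytosine level (level 5), the codon-157-like pattern.
    """

    n_levels: int = 11
    dt: float = 2.0
    t_total: float = 10000.0
    ar1: float = 0.8
    seed: int = 0
    medians: Mapping[str, float] = field(default_factory=lambda: dict(BASELINE_MEDIANS))
    iqrs: Mapping[str, float] = field(default_factory=lambda: dict(BASELINE_IQRS))
    adduct_levels: tuple[int, ...] = (5, 6)
    rotation_shift: float = 15.0
    translation_shift: float = 0.8
    sign_flip_params: tuple[str, ...] = ("buckle", "opening")
    sign_flip_level: int = 5

    def validate(self) -> None:
        if self.dt <= 0 or self.t_total <= 0:
            raise ValueError("dt and t_total must be positive")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1 for a stationary series")
        if self.n_levels < 3:
            raise ValueError("need at least 3 levels")
        unknown = set(self.medians) - PARAMETER_NAMES
        if unknown:
            raise ValueError(f"unknown parameter(s) in medians: {sorted(unknown)}")

    def n_frames(self) -> int:
        return int(round(self.t_total / self.dt)) + 1

    def target_median(self, parameter: str, level: int, adducted: bool) -> float:
        """The planted stationary median for one parameter at one level."""
        m = float(self.medians.get(parameter, 0.0))
        if not adducted:
            return m
        if parameter in self.sign_flip_params and level == self.sign_flip_level:
            m = -m
        if level in self.adduct_levels:
            shift = (
                self.rotation_shift
                if parameter in ROTATION_PARAMETERS
                else self.translation_shift
            )
            m = m + shift
        return m


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) columns with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(shape) * innov_sd
    eps[0] = rng.standard_normal(shape[1]) * sd  # stationary start
    return lfilter([1.0], [1.0, -phi], eps, axis=0)


def gen_helical_trajectory(
    config: TrajectorySimConfig, adducted: bool
) -> dict[str, HelicalSeries]:
    """Generate all 17 helical-parameter series for one run.

    Intra-base-pair and axis parameters have ``n_levels`` columns; step
    parameters ``n_levels - 1``.  Zero-IQR configurations give exactly
    constant series at the target medians.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_frames()
    times = np.arange(n) * config.dt
    out: dict[str, HelicalSeries] = {}
    for name in sorted(PARAMETER_NAMES):
        width = config.n_levels - 1 if name in STEP_PARAMETERS else config.n_levels
        sd = float(config.iqrs.get(name, 0.0)) * _IQR_TO_SD
        noise = _ar1_noise(rng, (n, width), config.ar1, sd)
        medians = np.array(
            [config.target_median(name, lvl, adducted) for lvl in range(1, width + 1)]
        )
        out[name] = HelicalSeries(
            parameter_name=name, times=times, values=medians + noise
        )
    return out


# ---------------------------------------------------------------------------
# Bond geometry


def gen_bond_geometry(
    ideal: IdealBondParams = IDEAL_GC,
    *,
    distance_shift: float | Sequence[float] = 0.0,
    angle_shift: float | Sequence[float] = 0.0,
    distance_sd: float = 0.0,
    angle_sd: float = 0.0,
    n_frames: int = 1000,
    dt: float = 2.0,
    seed: int = 0,
    label: str = "",
) -> BondGeometrySeries:
    """Gaussian H-bond geometry around ``ideal`` plus a planted shift.

    Distances are in Angstrom, angles in degrees (clipped to [0, 180]).
    Zero shift and zero sd reproduce the ideal geometry in every frame,
    so the quality index is exactly 0.
    """
    if distance_sd < 0 or angle_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    d0 = np.asarray(ideal.d0) + np.broadcast_to(np.asarray(distance_shift, float), (3,))
    g0 = ideal.gamma0 + np.broadcast_to(np.asarray(angle_shift, float), (3,))
    distances = d0 + rng.standard_normal((n_frames, 3)) * distance_sd
    angles = g0 + rng.standard_normal((n_frames, 3)) * angle_sd
    return BondGeometrySeries(
        times=np.arange(n_frames) * dt,
        distances=np.clip(distances, 0.5, None),
        angles=np.clip(angles, 0.0, 180.0),
        label=label,
    )


# ---------------------------------------------------------------------------
# RMSD plateaus


def gen_rmsd_series(
    levels: Sequence[tuple[float, float, float, float]],
    dt: float = 2.0,
    seed: int = 0,
    label: str = "RMSD",
) -> ScalarSeries:
    """Piecewise-stationary Gaussian series from (t0, t1, mean, sd) windows.

    Windows must tile [0, T] contiguously (each window's start equals the
    previous window's end); overlaps and gaps are rejected.  A frame at
    time t belongs to the window with t0 <= t < t1; the final frame at
    t = T belongs to the last window.
    """
    if not levels:
        raise ValueError("need at least one window")
    ordered = sorted(levels, key=lambda w: w[0])
    for (a0, a1, *_), (b0, b1, *_) in zip(ordered, ordered[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping windows: ({a0}, {a1}) and ({b0}, {b1})")
        if b0 > a1:
            raise ValueError(f"gap between windows at t={a1}")
    t_end = ordered[-1][1]
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + dt / 2, dt)
    values = np.empty_like(times)
    for t0, t1, mean, sd in ordered:
        if sd < 0:
            raise ValueError("sd must be non-negative")
        mask = (times >= t0) & ((times < t1) | (t1 == t_end) & (times == t1))
        values[mask] = mean + rng.standard_normal(int(mask.sum())) * sd
    return ScalarSeries(times=times, values=values, label=label)


# ---------------------------------------------------------------------------
# Summary-level MFA panel


def gen_mfa_panel(
    seed: int = 0,
    n_sequences: int = 11,
    effect_size: float = 1.5,
    noise_sd: float = 1.0,
    n_levels: int = 11,
) -> tuple[list[VariableGroup], np.ndarray]:
    """A 17-group panel of per-level medians with planted adduct separation.

    Observations are ``n_sequences`` adducted plus the same number of
    control sequences.  Within each parameter group, adducted rows get an
    ``effect_size``-sigma offset on the CpG-adjacent columns (levels 4-6)
    on top of i.i.d. Gaussian noise, mimicking localized adduct
    distortion of the level medians.  Returns ``(groups, labels)`` with
    ``labels[i] = 1`` for adducted observations.

    This generates the summary tables directly (what MFA actually
    consumes) rather than frame-level trajectories, which keeps large
    replicate studies cheap.
    """
    rng = np.random.default_rng(seed)
    n_obs = 2 * n_sequences
    labels = np.concatenate([np.ones(n_sequences), np.zeros(n_sequences)])
    obs_names = tuple(
        [f"seq{i + 1}S" for i in range(n_sequences)]
        + [f"seq{i + 1}C" for i in range(n_sequences)]
    )
    groups = []
    for name in sorted(PARAMETER_NAMES):
        width = (n_levels - 1 if name in STEP_PARAMETERS else n_levels) - 2  # trimmed
        X = rng.standard_normal((n_obs, width)) * noise_sd
        affected = [j for j, lvl in enumerate(range(2, width + 2)) if lvl in (4, 5, 6)]
        X[:n_sequences, affected] += effect_size * noise_sd
        groups.append(VariableGroup(name=name, matrix=X, obs_names=obs_names))
    return groups, labels


# ---------------------------------------------------------------------------
# Channel-weighted signature records


def gen_signature_records(
    n: int,
    weights: Mapping[tuple[str, str], float] | None = None,
    stratum: str = "smoker",
    seed: int = 0,
    site_key: str = "sig",
    mixed_strands: bool = True,
) -> list[MutationRecord]:
    """Records drawn over the 96 channels with given relative weights.

    ``weights`` maps (pyrimidine context, substitution) to a relative
    weight; missing channels get weight 1, so an empty mapping is the flat
    table.  With ``mixed_strands`` each record is emitted on a random
    strand representation, exercising the pyrimidine-strand folding.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    w = np.ones(len(CHANNELS))
    if weights:
        index = {ch: i for i, ch in enumerate(CHANNELS)}
        for key, value in weights.items():
            ch = Channel96(*key)
            if ch not in index:
                raise ValueError(f"unknown channel {key!r}")
            if value < 0:
                raise ValueError("weights must be non-negative")
            w[index[ch]] = value
    probs = w / w.sum()
    draws = rng.choice(len(CHANNELS), size=n, p=probs)
    flip = rng.random(n) < 0.5 if mixed_strands else np.zeros(n, dtype=bool)
    records = []
    for i, (k, flipped) in enumerate(zip(draws, flip)):
        ctx, sub = CHANNELS[k]
        rec = MutationRecord(
            record_id=f"g{i + 1:05d}",
            codon=0,
            site_key=site_key,
            context5=ctx[0],
            ref=ctx[1],
            context3=ctx[2],
            alt=sub[2],
            stratum=stratum,
        )
        records.append(rec.opposite_strand() if flipped else rec)
    return records
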