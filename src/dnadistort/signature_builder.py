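"""96-channel trinucleotide mutation signatures (Alexandrov format).

Every base substitution is referred to the pyrimidine of the mutated
Watson-Crick pair: a G>T on the purine strand at context 5'-C G T-3' is
the same event as C>A at 5'-A C G-3' on the opposite strand, and both
count toward the (ACG, C>A) channel.  Six substitution classes by 16
flanking contexts give 96 channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io_formats import MutationRecord

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CHANNELS",
    "Channel96",
    "Signature96",
    "SiteSummary",
    "to_pyrimidine_channel",
    "build_signature",
    "signature_difference",
    "probability_vs_difference_correlation",
    "site_substitution_summary",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = ("C", "T")
_BASES = ("A", "C", "G", "T")

#: Substitution classes on the pyrimidine strand; C>A is G:C>T:A.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class Channel96(NamedTuple):
    """One of the 96 (pyrimidine-strand trinucleotide, substitution) pairs."""

    pyr_context: str
    substitution: str


def _make_channels() -> tuple[Channel96, ...]:
    channels = []
    for sub in SUBSTITUTION_CLASSES:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                channels.append(Channel96(f"{five}{ref}{three}", sub))
    return tuple(channels)


#: Canonical channel ordering: substitution class major, then 5' and 3'
#: flanks each in A,C,G,T order.
CHANNELS: tuple[Channel96, ...] = _make_channels()
_CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


def to_pyrimidine_channel(context5: str, ref: str, context3: str, alt: str) -> Channel96:
    """Map a stranded substitution to its pyrimidine-strand channel.

    Purine references are reverse-complemented (trinucleotide reversed and
    complemented, alt complemented) before lookup, so both strand
    representations of a substitution land on the same channel.
    """
    for base in (context5, ref, context3, alt):
        if base not in _BASES:
            raise ValueError(f"ambiguous or invalid base {base!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in _PYRIMIDINES:
        context, sub = f"{context5}{ref}{context3}", f"{ref}>{alt}"
    else:
        context = f"{_COMPLEMENT[context3]}{_COMPLEMENT[ref]}{_COMPLEMENT[context5]}"
        sub = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    return Channel96(context, sub)


@dataclass
class Signature96:
    """Counts and percent probabilities over the 96 channels for one stratum."""

    stratum: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError("counts must be a 96-vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Percent of all substitutions per channel; sums to 100."""
        total = self.total
        if total == 0:
            return np.zeros(96)
        return 100.0 * self.counts / total

    def class_probabilities(self, substitution: str) -> np.ndarray:
        """Percent renormalized within one substitution class (16 contexts)."""
        idx = _class_slice(substitution)
        sub_counts = self.counts[idx]
        total = sub_counts.sum()
        if total == 0:
            return np.zeros(16)
        return 100.0 * sub_counts / total

    def class_channels(self, substitution: str) -> list[Channel96]:
        return list(CHANNELS[_class_slice(substitution)])


def _class_slice(substitution: str) -> slice:
    if substitution not in SUBSTITUTION_CLASSES:
        raise ValueError(
            f"unknown substitution class {substitution!r}; "
            f"expected one of {SUBSTITUTION_CLASSES}"
        )
    k = SUBSTITUTION_CLASSES.index(substitution)
    return slice(16 * k, 16 * (k + 1))


def build_signature(records: Iterable[MutationRecord], stratum: str) -> Signature96:
    """Count the stratum's substitutions into the 96 channels.

    ``stratum="all"`` pools every record.  An empty stratum is an error:
    a signature of nothing is meaningless.
    """
    counts = np.zeros(96, dtype=int)
    n = 0
    for rec in records:
        if stratum != "all" and rec.stratum != stratum:
            continue
        ch = to_pyrimidine_channel(rec.context5, rec.ref, rec.context3, rec.alt)
        counts[_CHANNEL_INDEX[ch]] += 1
        n += 1
    if n == 0:
        raise ValueError(f"no records in stratum {stratum!r}")
    return Signature96(stratum=stratum, counts=counts)


def signature_difference(a: Signature96, b: Signature96) -> np.ndarray:
    """Per-channel probability difference a - b, in percentage points.

    Because both probability vectors sum to 100, the difference sums to 0.
    """
    return a.probabilities - b.probabilities


def probability_vs_difference_correlation(
    smoker: Signature96,
    nonsmoker: Signature96,
    substitution: str = "C>A",
) -> tuple[float, float]:
    """Correlate per-context probability with the smoker excess.

    Over the 16 contexts of one substitution class (C>A, i.e. G:C>T:A, by
    default), Pearson r between the smoker probabilities and the
    smoker-minus-nonsmoker differences; two-sided p from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    idx = _class_slice(substitution)
    x = smoker.probabilities[idx]
    y = x - nonsmoker.probabilities[idx]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "correlation undefined: zero variance in probabilities or differences"
        )
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


@dataclass(frozen=True)
class SiteSummary:
    """Substitution breakdown at one site.

    Percentages: G:C>T:A among all substitutions at the site; smokers among
    the site's G:C>T:A events; smoker G:C>T:A among all substitutions.
    """

    site_key: str
    n_total: int
    n_gt: int
    n_gt_smoker: int
    pct_gt: float
    pct_gt_smoker_of_gt: float
    pct_gt_smoker_of_total: float
    empty: bool


def _is_gc_to_ta(rec: MutationRecord) -> bool:
    ch = to_pyrimidine_channel(rec.context5, rec.ref, rec.context3, rec.alt)
    return ch.substitution == "C>A"


def site_substitution_summary(
    records: Iterable[MutationRecord], site_key: str
) -> SiteSummary:
    """Summarize the G:C>T:A share (and its smoker share) at one site."""
    site = [r for r in records if r.site_key == site_key]
    if not site:
        return SiteSummary(site_key, 0, 0, 0, float("nan"), float("nan"),
                           float("nan"), empty=True)
    n_total = len(site)
    gt = [r for r in site if _is_gc_to_ta(r)]
    n_gt = len(gt)
    n_gt_smoker = sum(1 for r in gt if r.stratum == "smoker")
    return SiteSummary(
        site_key=site_key,
        n_total=n_total,
        n_gt=n_gt,
        n_gt_smoker=n_gt_smoker,
        pct_gt=100.0 * n_gt / n_total,
        pct_gt_smoker_of_gt=100.0 * n_gt_smoker / n_gt if n_gt else float("nan"),
        pct_gt_smoker_of_total=100.0 * n_gt_smoker / n_total,
        empty=False,
    )
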