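"""Binomial hotspot calling for G:C>T:A counts at guanine sites.

Under the null that each of the M recorded substitutions falls on any of
the S candidate guanines with equal probability 1/S, the count N at one
site is Binomial(M, 1/S).  A site is called a hotspot when its p-value
falls below the Bonferroni threshold alpha/S.

Two p-value modes are exposed.  ``point`` is Pr[X = N], the mode that
reproduces the published non-hotspot values (Pr[X=0]=0.303, Pr[X=1]=0.362,
Pr[X=2]=0.216 at M=421, S=353); ``tail`` is the upper tail Pr[X >= N] of
a conventional one-sided exact binomial test.  Both are evaluated in log
space via log-gamma so that magnitudes down to 1e-40 survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "SiteMutationCount",
    "HotspotCall",
    "log_binomial_point_prob",
    "binomial_point_prob",
    "binomial_upper_tail",
    "classify_hotspots",
]


@dataclass(frozen=True)
class SiteMutationCount:
    """Observed substitution count at one site plus panel totals.

    N: substitutions observed at the site; M: total substitutions across
    the panel; S: number of candidate sites (null probability 1/S each).
    """

    site_key: str
    N: int
    M: int
    S: int

    def __post_init__(self) -> None:
        _check_domain(self.N, self.M, self.S)


@dataclass(frozen=True)
class HotspotCall:
    site_key: str
    N: int
    p_value: float
    log10_p: float
    alpha: float
    threshold: float
    is_hotspot: bool


def _check_domain(N: int, M: int, S: int) -> None:
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    if not 0 <= N <= M:
        raise ValueError(f"N must satisfy 0 <= N <= M, got N={N}, M={M}")


def log_binomial_point_prob(N: int, M: int, S: int) -> float:
    """log Pr[X = N] for X ~ Binomial(M, 1/S), via log-gamma."""
    _check_domain(N, M, S)
    if S == 1:
        return 0.0 if N == M else -math.inf
    log_p = -math.log(S)
    log_q = math.log1p(-1.0 / S)
    return (
        gammaln(M + 1) - gammaln(N + 1) - gammaln(M - N + 1)
        + N * log_p + (M - N) * log_q
    )


def binomial_point_prob(N: int, M: int, S: int) -> float:
    """Pr[X = N] for X ~ Binomial(M, 1/S)."""
    return float(math.exp(log_binomial_point_prob(N, M, S)))


def binomial_upper_tail(N: int, M: int, S: int) -> float:
    """Pr[X >= N] for X ~ Binomial(M, 1/S), accumulated in log space."""
    _check_domain(N, M, S)
    if N == 0:
        return 1.0
    ks = np.arange(N, M + 1)
    log_terms = (
        gammaln(M + 1) - gammaln(ks + 1) - gammaln(M - ks + 1)
        - ks * math.log(S) + (M - ks) * math.log1p(-1.0 / S)
        if S > 1
        else np.where(ks == M, 0.0, -np.inf)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def classify_hotspots(
    counts: Sequence[SiteMutationCount],
    alpha: float = 0.05,
    mode: str = "point",
) -> list[HotspotCall]:
    """Call hotspots at family-wise level ``alpha`` with Bonferroni over S.

    All sites must share the same panel totals M and S.  The per-site
    p-value (point mass by default, upper tail with ``mode="tail"``) is
    compared against ``alpha / S``.
    """
    if mode not in ("point", "tail"):
        raise ValueError(f"mode must be 'point' or 'tail', got {mode!r}")
    if not counts:
        return []
    M, S = counts[0].M, counts[0].S
    for c in counts:
        if (c.M, c.S) != (M, S):
            raise ValueError(
                f"inconsistent panel totals: site {c.site_key} has "
                f"(M={c.M}, S={c.S}), expected (M={M}, S={S})"
            )
    threshold = alpha / S
    calls = []
    for c in counts:
        if mode == "point":
            log_p = log_binomial_point_prob(c.N, c.M, c.S)
            p = float(math.exp(log_p))
        else:
            p = binomial_upper_tail(c.N, c.M, c.S)
            log_p = math.log(p) if p > 0 else -math.inf
        calls.append(
            HotspotCall(
                site_key=c.site_key,
                N=c.N,
                p_value=p,
                log10_p=log_p / math.log(10),
                alpha=alpha,
                threshold=threshold,
                is_hotspot=p < threshold,
            )
        )
    return calls
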