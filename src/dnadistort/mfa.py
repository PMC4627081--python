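"""Multiple factor analysis (MFA) over helical-parameter variable sets.

MFA is a two-step PCA for multi-table data sharing the same observations
(here: sequences, adducted and control; one table per helical parameter,
its columns the per-level medians).  Step one standardizes each table and
performs a PCA on it; the table is then divided by the square root of its
first eigenvalue, so that every table's first singular value becomes 1 and
no single parameter can dominate the joint solution.  Step two
concatenates the weighted tables and runs a global PCA; observation
scores, per-component variance shares, variable-component correlations
and per-group contributions are read off the global decomposition.

All eigenvalues use the n-1 divisor.  Any consistent divisor rescales
every group identically, so the MFA solution does not depend on the
choice; n-1 keeps single-table results aligned with the usual sample
covariance PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "VariableGroup",
    "MFAModel",
    "VariableCorrelations",
    "pca",
    "mfa_fit",
    "variable_correlations",
    "percent_variance",
    "groups_from_summaries",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    scores: np.ndarray       # observations x components (U @ diag(s))
    loadings: np.ndarray     # variables x components (columns of V)
    singular_values: np.ndarray
    kept_columns: np.ndarray  # indices into the input after dropping degenerate ones


def _standardize(X: np.ndarray, center: bool, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns (Z, kept column indices).

    Zero-variance columns cannot be scaled and are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0) if center else X.copy()
    kept = np.arange(X.shape[1])
    if scale:
        sd = X.std(axis=0, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn(
                f"dropping {int(degenerate.sum())} zero-variance column(s)",
                stacklevel=3,
            )
            Z = Z[:, ~degenerate]
            kept = kept[~degenerate]
            sd = sd[~degenerate]
        Z = Z / sd
    return Z, kept


def _fix_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-magnitude loading is positive."""
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u, vt


def pca(X: np.ndarray, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA via singular values of the (optionally) standardized matrix.

    Eigenvalues are squared singular values divided by n-1; scores are
    the observation coordinates U @ diag(s).  With ``scale=True`` and no
    degenerate columns the eigenvalues sum to the number of variables
    (the trace of the correlation matrix).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 variable")
    Z, kept = _standardize(X, center, scale)
    if Z.shape[1] == 0:
        raise ValueError("all columns are degenerate")
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    u, vt = _fix_signs(u, vt)
    n = X.shape[0]
    return PCAResult(
        eigenvalues=s**2 / (n - 1),
        scores=u * s,
        loadings=vt.T,
        singular_values=s,
        kept_columns=kept,
    )


@dataclass
class VariableGroup:
    """One parameter's table: observations (sequences) x per-level variables."""

    name: str
    matrix: np.ndarray
    obs_names: tuple[str, ...] = ()
    var_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] < 2:
            raise ValueError(f"group {self.name!r}: need at least 2 observations")
        if not self.obs_names:
            self.obs_names = tuple(f"obs{i + 1}" for i in range(self.matrix.shape[0]))
        if not self.var_names:
            self.var_names = tuple(
                f"{self.name}_{j + 1}" for j in range(self.matrix.shape[1])
            )
        if len(self.obs_names) != self.matrix.shape[0]:
            raise ValueError("obs_names must match the number of rows")
        if len(self.var_names) != self.matrix.shape[1]:
            raise ValueError("var_names must match the number of columns")


@dataclass
class MFAModel:
    group_names: tuple[str, ...]
    obs_names: tuple[str, ...]
    first_eigenvalues: np.ndarray        # per-group lambda1 from the partial PCA
    eigenvalues: np.ndarray              # global, descending
    scores: np.ndarray                   # observations x components
    loadings: np.ndarray                 # weighted variables x components
    standardized: np.ndarray             # pre-weighting standardized columns
    weighted: np.ndarray                 # post-weighting matrix fed to the global PCA
    column_groups: np.ndarray            # group index per retained column
    column_names: tuple[str, ...]
    group_contributions: np.ndarray      # groups x components, columns sum to 1

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def mfa_fit(
    groups: Sequence[VariableGroup],
    center: bool = True,
    scale: bool = True,
) -> MFAModel:
    """Fit the two-step MFA.

    Raises on mismatched observation orderings and on groups whose first
    partial eigenvalue is 0 (a constant table carries no structure and
    cannot be weighted).
    """
    if not groups:
        raise ValueError("need at least one variable group")
    obs_names = groups[0].obs_names
    n = groups[0].matrix.shape[0]
    for g in groups:
        if g.matrix.shape[0] != n or g.obs_names != obs_names:
            raise ValueError(
                f"group {g.name!r} does not share the observation ordering"
            )
    blocks, lambdas, col_groups, col_names = [], [], [], []
    for gi, g in enumerate(groups):
        Z, kept = _standardize(g.matrix, center, scale)
        if Z.shape[1] == 0:
            raise ValueError(f"group {g.name!r}: all columns degenerate")
        s1 = np.linalg.svd(Z, compute_uv=False)[0]
        lam1 = s1**2 / (n - 1)
        if lam1 <= 0:
            raise ValueError(f"group {g.name!r}: first eigenvalue is zero")
        blocks.append(Z / np.sqrt(lam1))
        lambdas.append(lam1)
        col_groups.extend([gi] * Z.shape[1])
        col_names.extend(g.var_names[j] for j in kept)
    standardized = np.hstack([b * np.sqrt(l) for b, l in zip(blocks, lambdas)])
    weighted = np.hstack(blocks)
    u, s, vt = np.linalg.svd(weighted, full_matrices=False)
    u, vt = _fix_signs(u, vt)
    nonnull = s > s[0] * 1e-12 if s.size else np.array([], dtype=bool)
    u, s, vt = u[:, nonnull], s[nonnull], vt[nonnull]
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    col_groups = np.asarray(col_groups)
    contrib = np.zeros((len(groups), s.size))
    sq = loadings**2
    for gi in range(len(groups)):
        contrib[gi] = sq[col_groups == gi].sum(axis=0)
    return MFAModel(
        group_names=tuple(g.name for g in groups),
        obs_names=obs_names,
        first_eigenvalues=np.asarray(lambdas),
        eigenvalues=eigenvalues,
        scores=u * s,
        loadings=loadings,
        standardized=standardized,
        weighted=weighted,
        column_groups=col_groups,
        column_names=tuple(col_names),
        group_contributions=contrib,
    )


@dataclass
class VariableCorrelations:
    """Variable-component correlations plus per-group summaries."""

    per_variable: pd.DataFrame  # group, variable, correlation
    per_group: pd.DataFrame     # group, best_variable, best_correlation, mean_correlation


def variable_correlations(model: MFAModel, component: int) -> VariableCorrelations:
    """Pearson correlation of each original variable with one component.

    Correlations are computed from the standardized, pre-weighting
    columns against the observation scores, so the group weighting does
    not distort them.  ``component`` is 0-based.
    """
    if not 0 <= component < model.n_components:
        raise IndexError(
            f"component {component} out of range (model rank {model.n_components})"
        )
    scores = model.scores[:, component]
    cols = model.standardized
    sc = scores - scores.mean()
    denom_s = np.sqrt((sc**2).sum())
    cc = cols - cols.mean(axis=0)
    denom_c = np.sqrt((cc**2).sum(axis=0))
    corr = (cc.T @ sc) / (denom_c * denom_s)
    per_var = pd.DataFrame(
        {
            "group": [model.group_names[g] for g in model.column_groups],
            "variable": list(model.column_names),
            "correlation": corr,
        }
    )
    rows = []
    for gi, gname in enumerate(model.group_names):
        sub = per_var[per_var["group"] == gname]
        best = sub.loc[sub["correlation"].abs().idxmax()]
        rows.append(
            {
                "group": gname,
                "best_variable": best["variable"],
                "best_correlation": best["correlation"],
                "mean_correlation": sub["correlation"].mean(),
            }
        )
    return VariableCorrelations(per_variable=per_var, per_group=pd.DataFrame(rows))


def percent_variance(model: MFAModel) -> np.ndarray:
    """Percent of total variance per global component; sums to 100."""
    return 100.0 * model.eigenvalues / model.eigenvalues.sum()


def groups_from_summaries(summaries: pd.DataFrame) -> list[VariableGroup]:
    """Build variable groups from a long table (sequence, parameter, level, median).

    Observations are sequences (sorted by first appearance), one group per
    parameter, one column per level.  Missing (sequence, level) cells are
    an error: MFA needs a complete table.
    """
    required = {"sequence", "parameter", "level", "median"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing column(s): {sorted(missing)}")
    seq_order = list(dict.fromkeys(summaries["sequence"]))
    groups = []
    for param, sub in summaries.groupby("parameter", sort=True):
        wide = sub.pivot(index="sequence", columns="level", values="median")
        wide = wide.reindex(seq_order)
        if wide.isna().any().any():
            raise ValueError(f"parameter {param!r}: incomplete sequence x level table")
        groups.append(
            VariableGroup(
                name=str(param),
                matrix=wide.to_numpy(float),
                obs_names=tuple(str(s) for s in seq_order),
                var_names=tuple(f"{param}_L{int(c)}" for c in wide.columns),
            )
        )
    return groups
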