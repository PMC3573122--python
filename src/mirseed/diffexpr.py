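"""Normalization, moderated differential statistics, FDR and categorization.

The two-colour dye-swap pipeline of the original arrays (within-array loess,
empirical-Bayes B statistic) is deliberately replaced by a single-channel
model: quantile normalization across columns followed by a moderated
two-sample t with a configurable variance prior.  Downstream stages only
consume AveExpr / logFC / adjusted p, which this model provides.

Threshold comparisons in :func:`categorize` are strict on |logFC| and on the
adjusted p ("above" / "below") and inclusive on AveExpr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import SampleSheet


@dataclass(frozen=True)
class Thresholds:
    """Expression/effect/significance cutoffs for transcript categorization."""

    min_aveexpr: float
    min_abs_logfc: float
    max_adjp: float

    def __post_init__(self) -> None:
        if not 0 < self.max_adjp <= 1:
            raise ValueError("max_adjp must be in (0, 1]")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")


#: broad alteration screen (AveExpr 7.0, |logFC| > 0.7, adjP < 0.05)
THRESHOLDS_ALTERED = Thresholds(7.0, 0.7, 0.05)
#: stringent candidate screen (AveExpr 7.0, |logFC| > 1.5, adjP < 0.01)
THRESHOLDS_STRINGENT = Thresholds(7.0, 1.5, 0.01)


@dataclass(frozen=True)
class CategorySets:
    up: frozenset
    down: frozenset
    background: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down categories overlap")
        if not (self.up | self.down) <= self.background:
            raise ValueError("categories must be subsets of the background")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-means of the
    column-sorted matrix.  Idempotent; labels preserved.

    Ties within a column keep their (stable) input order rather than being
    averaged; this keeps the post-condition exact: after normalization every
    column has an identical sorted value vector.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    arr = matrix.to_numpy(dtype=float)
    means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        out[order, j] = means
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def differential(
    matrix: pd.DataFrame,
    samplesheet: SampleSheet,
    contrast: tuple[str, str] | str,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated two-sample t for ``treatment - control``.

    Parameters
    ----------
    contrast
        ``(treatment, control)`` condition labels, or a ``"treat:ctrl"``
        string.
    prior_df, prior_var
        Variance shrinkage: ``s2_tilde = (prior_df*prior_var + df*s2) /
        (prior_df + df)``; p-values use ``df + prior_df`` degrees of freedom.
        ``prior_var=None`` uses the median per-feature pooled variance.
        ``prior_df=0`` recovers the ordinary equal-variance two-sample t.

    Returns
    -------
    DataFrame indexed by feature with columns AveExpr, logFC, t_mod, p, adjP.
    """
    if isinstance(contrast, str):
        parts = contrast.split(":")
        if len(parts) != 2:
            raise ValueError("contrast string must be 'treatment:control'")
        contrast = (parts[0], parts[1])
    treatment, control = contrast
    conditions = samplesheet.conditions()
    for cond in contrast:
        if cond not in conditions:
            raise ValueError(f"contrast names unknown condition {cond!r}")
    t_cols = [s for s in samplesheet.samples(treatment) if s in matrix.columns]
    c_cols = [s for s in samplesheet.samples(control) if s in matrix.columns]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")

    t_arr = matrix[t_cols].to_numpy(dtype=float)
    c_arr = matrix[c_cols].to_numpy(dtype=float)
    n1, n2 = t_arr.shape[1], c_arr.shape[1]
    df = n1 + n2 - 2

    ave_expr = np.concatenate([t_arr, c_arr], axis=1).mean(axis=1)
    logfc = t_arr.mean(axis=1) - c_arr.mean(axis=1)
    s2 = ((n1 - 1) * t_arr.var(axis=1, ddof=1) + (n2 - 1) * c_arr.var(axis=1, ddof=1)) / df

    if prior_df > 0:
        if prior_var is None:
            prior_var = float(np.median(s2))
        s2_tilde = (prior_df * prior_var + df * s2) / (prior_df + df)
    else:
        s2_tilde = s2
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))

    t_mod = np.zeros_like(logfc)
    p = np.ones_like(logfc)
    ok = se > 0
    t_mod[ok] = logfc[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t_mod[ok]), df + prior_df)
    degenerate = ~ok & (logfc != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero residual variance and "
            "nonzero logFC; t set to +/-inf, p to 0",
            RuntimeWarning,
        )
        t_mod[degenerate] = np.sign(logfc[degenerate]) * np.inf
        p[degenerate] = 0.0

    return pd.DataFrame(
        {
            "AveExpr": ave_expr,
            "logFC": logfc,
            "t_mod": t_mod,
            "p": p,
            "adjP": bh_adjust(p),
        },
        index=matrix.index,
    )


def bh_adjust(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    adj(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p-values.
    """
    is_series = isinstance(p_values, pd.Series)
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p_values.copy() if is_series else p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    if is_series:
        return pd.Series(adj, index=p_values.index)
    return adj


def categorize(detable: pd.DataFrame, thresholds: Thresholds) -> CategorySets:
    """Split features into up/down/background per the threshold triple.

    background: AveExpr >= min_aveexpr (inclusive);
    down: background and logFC < -min_abs_logfc and adjP < max_adjp (strict);
    up symmetric.
    """
    if len(detable) == 0:
        raise ValueError("empty DE table")
    bg_mask = detable["AveExpr"] >= thresholds.min_aveexpr
    sig = bg_mask & (detable["adjP"] < thresholds.max_adjp)
    down = sig & (detable["logFC"] < -thresholds.min_abs_logfc)
    up = sig & (detable["logFC"] > thresholds.min_abs_logfc)
    return CategorySets(
        up=frozenset(detable.index[up]),
        down=frozenset(detable.index[down]),
        background=frozenset(detable.index[bg_mask]),
    )


def relative_expression_ddct(ct_target, ct_reference):
    """qPCR relative expression by the comparative CT method: 2^-(dCT)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("CT values must be finite")
    out = 2.0 ** -(ct_target - ct_reference)
    if out.ndim == 0:
        return float(out)
    return out


def collapse_probes(
    detable: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse multi-probe genes to the probe with maximal AveExpr."""
    mapped = detable.loc[[p for p in detable.index if p in probe_to_gene]].copy()
    mapped["gene"] = [probe_to_gene[p] for p in mapped.index]
    best = mapped.sort_values("AveExpr", ascending=False).drop_duplicates("gene")
    return best.set_index("gene").sort_index().rename_axis(index=None)
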