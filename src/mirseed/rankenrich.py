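"""Weighted running-sum (GSEA-style) enrichment of a set in a ranked list.

The ranking metric defaults to the moderated t from the differential stage
(a fold change scaled by its standard deviation).  Significance uses
gene-tag permutation: with only two arrays per condition in the designs
this emulates, phenotype permutation is not possible, so size-matched
random gene sets form the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import GeneSets


@dataclass(frozen=True)
class RankedList:
    """Feature ids ordered by descending metric; ties broken by id."""

    ids: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        metric = np.asarray(self.metric, dtype=float)
        if len(self.ids) != metric.size:
            raise ValueError("ids and metric lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")
        if not np.all(np.isfinite(metric)):
            raise ValueError("metric values must be finite")
        ids_arr = np.asarray(self.ids, dtype=object)
        order = np.lexsort((ids_arr, -metric))
        object.__setattr__(self, "ids", tuple(ids_arr[order]))
        object.__setattr__(self, "metric", metric[order])

    @classmethod
    def from_detable(cls, detable: pd.DataFrame, metric_column: str = "t_mod") -> "RankedList":
        return cls(tuple(detable.index), detable[metric_column].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ESProfile:
    es: float
    running_sum: np.ndarray
    peak_rank: int
    leading_edge: tuple[str, ...]


@dataclass(frozen=True)
class SignificanceResult:
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_perm: int
    seed: int


def derive_signature(detable: pd.DataFrame, alpha: float) -> GeneSets:
    """Split p < alpha features by logFC sign into an up and a down set."""
    if len(detable) == 0:
        raise ValueError("empty DE table")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig = detable["p"] < alpha
    up = detable.index[sig & (detable["logFC"] > 0)].tolist()
    down = detable.index[sig & (detable["logFC"] < 0)].tolist()
    if not up and not down:
        raise ValueError(f"no features pass p < {alpha}; use a larger alpha")
    sets = GeneSets()
    if up:
        sets.add("up", f"{len(up)} genes up at p<{alpha}", up)
    if down:
        sets.add("down", f"{len(down)} genes down at p<{alpha}", down)
    return sets


def _running_sum(hit: np.ndarray, abs_weight: np.ndarray) -> np.ndarray:
    """Increment member ranks by normalized |metric|^exponent weights,
    decrement the rest by 1/(M - n_hit)."""
    n_hit = int(hit.sum())
    w = np.where(hit, abs_weight, 0.0)
    denom = w.sum()
    if denom == 0:  # all member metrics zero: fall back to equal weights
        w = hit.astype(float)
        denom = float(n_hit)
    steps = w / denom - (~hit) / (hit.size - n_hit)
    return np.cumsum(steps)


def enrichment_score(
    ranked_list: RankedList,
    gene_set: Iterable[str],
    exponent: float = 1.0,
) -> ESProfile:
    """Signed maximal deviation of the weighted running sum.

    The leading edge contains the member genes between the start of the list
    and the peak (for a positive score) or between the peak and the end (for
    a negative score).
    """
    members = set(gene_set)
    ids = ranked_list.ids
    hit = np.fromiter((g in members for g in ids), dtype=bool, count=len(ids))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == len(ids):
        raise ValueError("gene set covers the whole ranked list")
    abs_weight = np.abs(ranked_list.metric) ** exponent
    running = _running_sum(hit, abs_weight)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = tuple(ids[i] for i in range(peak + 1) if hit[i])
    else:
        leading = tuple(ids[i] for i in range(peak, len(ids)) if hit[i])
    return ESProfile(es=es, running_sum=running, peak_rank=peak, leading_edge=leading)


def significance(
    ranked_list: RankedList,
    gene_set: Iterable[str],
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> SignificanceResult:
    """Gene-tag permutation null: ES of size-matched random gene sets.

    ``nes`` rescales the observed ES by the mean |null ES| of the same sign;
    ``p_nominal`` is the add-one-corrected fraction of same-sign null scores
    at least as extreme.  With a single observed set, the sign-stratified
    FDR estimate coincides with the nominal p and is reported as ``fdr_q``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    profile = enrichment_score(ranked_list, gene_set, exponent)
    ids = ranked_list.ids
    members = set(gene_set) & set(ids)
    size = len(members)
    M = len(ids)
    abs_weight = np.abs(ranked_list.metric) ** exponent
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    hit = np.zeros(M, dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(M, size=size, replace=False)
        hit[:] = False
        hit[idx] = True
        running = _running_sum(hit, abs_weight)
        null[b] = running[np.argmax(np.abs(running))]
    same_sign = null > 0 if profile.es >= 0 else null < 0
    pool = null[same_sign] if same_sign.any() else null
    nes = profile.es / float(np.mean(np.abs(pool)))
    p_nominal = (1.0 + np.sum(np.abs(pool) >= abs(profile.es))) / (1.0 + pool.size)
    return SignificanceResult(
        es=profile.es,
        nes=float(nes),
        p_nominal=float(p_nominal),
        fdr_q=float(p_nominal),
        n_perm=n_perm,
        seed=seed,
    )
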