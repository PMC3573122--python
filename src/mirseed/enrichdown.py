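"""Hypergeometric over-representation of predicted miRNA targets.

For each (miRNA, prediction source, category) the quadruple (N, K, n, k) is
formed against the expressed background: N expressed features, K of them
predicted targets, n in the category, k predicted targets in the category.
The upper tail P(X >= k) includes the observed k; BH adjustment is applied
across miRNAs within each (source, category) family.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import CategorySets, bh_adjust
from .seedtargets import TargetPredictions

ENRICH_COLUMNS = [
    "mirna_id", "source", "category",
    "N", "K", "n", "k",
    "fold_enrichment", "fold_defined", "p", "adjP",
]


def hypergeom_upper(N, K, n, k):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts marked items among n draws without replacement from N items of
    which K are marked.  Accepts scalars or broadcastable integer arrays for
    ``k``; returns a float for scalar input.
    """
    N_a, K_a, n_a, k_a = (np.asarray(x) for x in (N, K, n, k))
    for name, arr in (("N", N_a), ("K", K_a), ("n", n_a), ("k", k_a)):
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} must be integer")
    if np.any(K_a > N_a) or np.any(n_a > N_a) or np.any(K_a < 0) or np.any(n_a < 0):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if np.any(k_a < 0) or np.any(k_a > np.minimum(K_a, n_a)):
        raise ValueError("need 0 <= k <= min(K, n)")
    p = hypergeom.sf(k_a - 1, N_a, K_a, n_a)
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(k) or (isinstance(k, np.ndarray) and k.ndim == 0):
        return float(p)
    return p


def enrich(
    category_sets: CategorySets,
    predictions_list: Sequence[TargetPredictions],
) -> pd.DataFrame:
    """One enrichment record per (miRNA, source, category).

    Records are sorted by (source, category, adjP ascending, fold
    descending).  A miRNA with no predicted targets inside the background
    (K = 0) yields p = 1 with the fold flagged undefined.
    """
    background = set(category_sets.background)
    if not background:
        raise ValueError("empty background universe")
    if not predictions_list:
        raise ValueError("no prediction sources given")
    N = len(background)
    rows = []
    for pred in predictions_list:
        for category, members in (("up", category_sets.up), ("down", category_sets.down)):
            cat = set(members)
            n = len(cat)
            for mirna_id in pred.targets:
                targets_bg = pred.target_set(mirna_id) & background
                K = len(targets_bg)
                k = len(targets_bg & cat)
                if K == 0:
                    p = 1.0
                    fold, defined = np.nan, False
                else:
                    p = hypergeom_upper(N, K, n, k)
                    if n > 0:
                        fold, defined = (k / n) / (K / N), True
                    else:
                        fold, defined = np.nan, False
                rows.append(
                    {
                        "mirna_id": mirna_id, "source": pred.source,
                        "category": category, "N": N, "K": K, "n": n, "k": k,
                        "fold_enrichment": fold, "fold_defined": defined, "p": p,
                    }
                )
    table = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "adjP"])
    table["adjP"] = np.nan
    for (_, _), idx in table.groupby(["source", "category"]).groups.items():
        table.loc[idx, "adjP"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table = table.sort_values(
        by=["source", "category", "adjP", "fold_enrichment"],
        ascending=[True, True, True, False],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    return table[ENRICH_COLUMNS]


def enrichment_plot_table(records: pd.DataFrame, adjp_cap: float = 1e-300) -> pd.DataFrame:
    """Plot-ready (fold_enrichment, -log10 adjP) pairs per record."""
    if len(records) == 0:
        raise ValueError("no enrichment records")
    out = records[["mirna_id", "source", "category", "fold_enrichment"]].copy()
    out["neg_log10_adjp"] = -np.log10(np.clip(records["adjP"].to_numpy(), adjp_cap, None))
    return out
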