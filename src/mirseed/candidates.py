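"""Candidate target assembly, cross-species support, cross-model overlap.

The candidate filter intersects multi-source target predictions with the
down-regulated category under a threshold triple and ranks by logFC
(strongest inhibition first).  The cross-model screen applies a per-model
Welch two-sample t on log2 values at a raw (unadjusted) p cutoff, strict
"less than", and requires sign consistency across models for a miRNA to be
called commonly dysregulated; sign-discordant miRNAs are surfaced
separately rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import Thresholds, categorize
from .formats import FormatError, OrthologMap
from .seedtargets import TargetPredictions, intersect_sources


@dataclass(frozen=True)
class CandidateRecord:
    """One Table-style candidate row (Symbol, Accession, Description,
    AveExpr, logFC plus filter provenance)."""

    symbol: str
    ave_expr: float
    logfc: float
    n_sources: int
    accession: str = ""
    description: str = ""
    in_vivo_support: bool = False


def candidate_filter(
    detable: pd.DataFrame,
    predictions_list: Sequence[TargetPredictions],
    mirna_id: str,
    thresholds: Thresholds,
    min_sources: int,
    annotations: Mapping[str, tuple[str, str]] | None = None,
) -> list[CandidateRecord]:
    """Genes predicted by >= min_sources sources AND down-regulated under
    the thresholds, sorted by logFC ascending (largest inhibition first)."""
    consensus, _ = intersect_sources(predictions_list, mirna_id, min_sources)
    if not consensus:
        warnings.warn(
            f"no consensus targets for {mirna_id} at min_sources={min_sources}",
            RuntimeWarning,
        )
        return []
    cats = categorize(detable, thresholds)
    retained = sorted(consensus & cats.down, key=lambda g: detable.at[g, "logFC"])
    n_sources = {
        g: sum(1 for p in predictions_list if g in p.target_set(mirna_id))
        for g in retained
    }
    annotations = annotations or {}
    return [
        CandidateRecord(
            symbol=g,
            ave_expr=float(detable.at[g, "AveExpr"]),
            logfc=float(detable.at[g, "logFC"]),
            n_sources=n_sources[g],
            accession=annotations.get(g, ("", ""))[0],
            description=annotations.get(g, ("", ""))[1],
        )
        for g in retained
    ]


def cross_species_support(
    candidates: Sequence[CandidateRecord],
    in_vivo_detable: pd.DataFrame,
    ortholog_map: OrthologMap,
    alpha: float,
) -> list[CandidateRecord]:
    """Flag candidates whose mapped ortholog is significantly down in vivo
    (adjP < alpha and logFC < 0).  Unmapped symbols are flagged False with
    a warning."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    out = []
    for cand in candidates:
        orthologs = ortholog_map.forward(cand.symbol)
        if not orthologs:
            warnings.warn(f"no ortholog mapping for {cand.symbol}", RuntimeWarning)
            out.append(replace(cand, in_vivo_support=False))
            continue
        supported = False
        for ortho in orthologs:
            if ortho not in in_vivo_detable.index:
                continue
            row = in_vivo_detable.loc[ortho]
            if row["adjP"] < alpha and row["logFC"] < 0:
                supported = True
                break
        out.append(replace(cand, in_vivo_support=supported))
    return out


def candidates_to_table(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Printed-table column order: Symbol, Accession, Description, AveExpr,
    logFC, then provenance columns."""
    return pd.DataFrame(
        [
            {
                "Symbol": c.symbol,
                "Accession": c.accession,
                "Description": c.description,
                "AveExpr": c.ave_expr,
                "logFC": c.logfc,
                "n_sources": c.n_sources,
                "in_vivo_support": c.in_vivo_support,
            }
            for c in candidates
        ],
        columns=[
            "Symbol", "Accession", "Description", "AveExpr", "logFC",
            "n_sources", "in_vivo_support",
        ],
    )


# ---------------------------------------------------------------------------
# Cross-model miRNA overlap
# ---------------------------------------------------------------------------

class MirnaModelTable:
    """Per-miRNA replicate log2 values for the two groups of one model."""

    def __init__(
        self,
        model: str,
        values: pd.DataFrame,
        condition: Mapping[str, str],
        treatment: str = "treatment",
        control: str = "control",
    ) -> None:
        if not model:
            raise ValueError("empty model name")
        condition = dict(condition)
        missing = [c for c in values.columns if c not in condition]
        if missing:
            raise FormatError(f"model {model}: unannotated samples {missing}")
        t_cols = [c for c in values.columns if condition[c] == treatment]
        c_cols = [c for c in values.columns if condition[c] == control]
        if len(t_cols) < 2 or len(c_cols) < 2:
            raise ValueError(f"model {model}: each group needs >= 2 replicates")
        if values.index.has_duplicates:
            raise FormatError(f"model {model}: duplicate miRNA ids")
        self.model = model
        self.values = values.astype(float)
        self.condition = condition
        self.treatment = treatment
        self.control = control
        self._t_cols = t_cols
        self._c_cols = c_cols

    def stats(self, welch: bool = True) -> pd.DataFrame:
        """Two-sample t per miRNA: columns delta, direction, p."""
        t_arr = self.values[self._t_cols].to_numpy()
        c_arr = self.values[self._c_cols].to_numpy()
        res = stats.ttest_ind(t_arr, c_arr, axis=1, equal_var=not welch)
        delta = t_arr.mean(axis=1) - c_arr.mean(axis=1)
        return pd.DataFrame(
            {
                "delta": delta,
                "direction": np.sign(delta).astype(int),
                "p": res.pvalue,
            },
            index=self.values.index,
        )


@dataclass(frozen=True)
class OverlapResult:
    per_model: dict[str, dict[str, int]]  # model -> {mirna: sign} at p < alpha
    venn: dict[frozenset, int]            # exact-region counts
    common: dict[str, int]                # consistent-sign intersection
    discordant: tuple[str, ...]           # significant everywhere, signs differ
    alpha: float


def _significant_sets(
    stats_tables: Mapping[str, pd.DataFrame], alpha: float
) -> dict[str, dict[str, int]]:
    """Strict raw-p screen: p < alpha, direction = sign of group difference."""
    out: dict[str, dict[str, int]] = {}
    for model, table in stats_tables.items():
        mask = table["p"] < alpha
        out[model] = {
            m: int(s)
            for m, s in table.loc[mask, "direction"].items()
        }
    return out


def model_overlap(
    model_tables: Sequence[MirnaModelTable],
    alpha: float = 0.01,
    welch: bool = True,
) -> OverlapResult:
    """Cross-model screen for commonly dysregulated miRNAs.

    Per-model significance uses a raw (not BH-adjusted) p with a strict
    "less than" comparison.  Venn counts cover every exact membership
    region; the common list is the all-model intersection restricted to
    identical signs, and is invariant under permutation of model order.
    """
    if len(model_tables) < 2:
        raise ValueError("need at least 2 model tables")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    names = [t.model for t in model_tables]
    if len(set(names)) != len(names):
        raise ValueError("model names must be distinct")
    stats_tables = {t.model: t.stats(welch=welch) for t in model_tables}
    per_model = _significant_sets(stats_tables, alpha)

    venn: dict[frozenset, int] = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(sorted(names), r)
    }
    all_mirnas = set().union(*(set(s) for s in per_model.values()))
    for mirna in all_mirnas:
        region = frozenset(m for m in names if mirna in per_model[m])
        venn[region] += 1

    everywhere = sorted(
        m for m in all_mirnas if all(m in per_model[name] for name in names)
    )
    common, discordant = {}, []
    for mirna in everywhere:
        signs = {per_model[name][mirna] for name in names}
        if len(signs) == 1 and 0 not in signs:
            common[mirna] = signs.pop()
        else:
            discordant.append(mirna)
    return OverlapResult(
        per_model=per_model,
        venn=venn,
        common=common,
        discordant=tuple(discordant),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Model table I/O (long TSV: mirna_id, condition, replicate, value)
# ---------------------------------------------------------------------------

def read_model_table(
    path: str | Path,
    model: str,
    treatment: str = "treatment",
    control: str = "control",
) -> MirnaModelTable:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "condition": str})
    required = {"mirna_id", "condition", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["value"].isna().any():
        raise FormatError(f"{path}: missing values not supported")
    df["sample"] = df["condition"] + "_" + df["replicate"].astype(str)
    wide = df.pivot(index="mirna_id", columns="sample", values="value")
    if wide.isna().any().any():
        raise FormatError(f"{path}: unbalanced replicate structure")
    condition = dict(df.drop_duplicates("sample")[["sample", "condition"]].values)
    return MirnaModelTable(model, wide, condition, treatment=treatment, control=control)


def write_model_table(table: MirnaModelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tcondition\treplicate\tvalue\n")
        rep_counter: dict[str, int] = {}
        col_rep = {}
        for col in table.values.columns:
            cond = table.condition[col]
            rep_counter[cond] = rep_counter.get(cond, 0) + 1
            col_rep[col] = (cond, rep_counter[cond])
        for mirna, row in table.values.iterrows():
            for col in table.values.columns:
                cond, rep = col_rep[col]
                fh.write(f"{mirna}\t{cond}\t{rep}\t{row[col]:.10g}\n")
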