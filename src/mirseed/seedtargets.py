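"""Exact seed extraction and seed-complementary site scanning in 3'UTRs.

Only perfect Watson-Crick complementarity is implemented: the seed is the
first 2-7 (hexamer) or 1-8 (octamer) nucleotides of the mature miRNA, and a
site is any exact occurrence of the reverse complement of that seed in a UTR
scanned 5'->3' on the given strand.  No G:U wobble, context scoring or
conservation filtering; external tools' predictions enter as flat tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .formats import FormatError, MatureMirna, SequenceSet, normalize_rna

#: seed variant -> 0-based half-open slice of the mature sequence
SEED_VARIANTS: dict[str, tuple[int, int]] = {
    "seed2_7": (1, 7),
    "seed1_8": (0, 8),
}


def seed_sequence(mirna: MatureMirna | str, variant: str = "seed2_7") -> tuple[str, str]:
    """Return ``(seed, target_motif)`` for a mature miRNA.

    ``seed`` is the RNA subsequence of the mature miRNA (nucleotides 2-7 or
    1-8, 1-based inclusive); ``target_motif`` is its reverse complement
    written as DNA, i.e. the exact string searched for in UTRs.
    """
    if variant not in SEED_VARIANTS:
        raise ValueError(f"unknown seed variant {variant!r}")
    seq = mirna.sequence if isinstance(mirna, MatureMirna) else normalize_rna(mirna)
    if len(seq) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt ({len(seq)})")
    start, end = SEED_VARIANTS[variant]
    seed = seq[start:end]
    motif = str(Seq(seed.replace("U", "T")).reverse_complement())
    return seed, motif


@dataclass(frozen=True, order=True)
class SeedSite:
    """One exact seed-complementary occurrence on a UTR (0-based half-open)."""

    utr_id: str
    start: int
    end: int
    variant: str
    matched_motif: str


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    """Yield every (possibly overlapping) occurrence start."""
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def scan_sites(
    sequence_set: SequenceSet, mirna: MatureMirna | str, variant: str = "seed2_7"
) -> list[SeedSite]:
    """Report every exact occurrence of the seed-complement motif.

    Overlapping occurrences are all counted; results are sorted by
    ``(utr_id, start)``.
    """
    _, motif = seed_sequence(mirna, variant)
    sites = [
        SeedSite(utr_id, start, start + len(motif), variant, motif)
        for utr_id, entry in sequence_set.items()
        for start in _find_all(entry.sequence, motif)
    ]
    sites.sort(key=lambda s: (s.utr_id, s.start))
    return sites


@dataclass(frozen=True)
class TargetPredictions:
    """Per-source map miRNA id -> set of predicted target ids."""

    source: str
    targets: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if not self.source:
            raise FormatError("empty prediction source label")
        object.__setattr__(
            self,
            "targets",
            {m: frozenset(genes) for m, genes in dict(self.targets).items()},
        )

    def target_set(self, mirna_id: str) -> frozenset:
        return self.targets.get(mirna_id, frozenset())


def predict_targets(
    sequence_set: SequenceSet,
    mirnas: Iterable[MatureMirna],
    variant: str = "seed2_7",
    min_sites: int = 1,
) -> TargetPredictions:
    """UTR ids carrying at least ``min_sites`` seed-complementary sites."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    targets: dict[str, frozenset] = {}
    for mirna in mirnas:
        counts: dict[str, int] = {}
        for site in scan_sites(sequence_set, mirna, variant):
            counts[site.utr_id] = counts.get(site.utr_id, 0) + 1
        targets[mirna.mirna_id] = frozenset(
            utr for utr, n in counts.items() if n >= min_sites
        )
    return TargetPredictions(source=f"seed-scan:{variant}", targets=targets)


def intersect_sources(
    predictions_list: Sequence[TargetPredictions],
    mirna_id: str,
    min_sources: int,
) -> tuple[frozenset, dict[frozenset, int]]:
    """Consensus targets predicted by >= ``min_sources`` sources, plus Venn counts.

    The Venn dictionary maps each non-empty subset of source labels to the
    number of genes predicted by exactly that subset.
    """
    if not predictions_list:
        raise ValueError("at least one prediction source required")
    labels = [p.source for p in predictions_list]
    if len(set(labels)) != len(labels):
        raise ValueError("prediction sources must carry distinct labels")
    if not 1 <= min_sources <= len(predictions_list):
        raise ValueError(
            f"min_sources must be in [1, {len(predictions_list)}], got {min_sources}"
        )
    membership: dict[str, set[str]] = {}
    for pred in predictions_list:
        for gene in pred.target_set(mirna_id):
            membership.setdefault(gene, set()).add(pred.source)
    venn: dict[frozenset, int] = {
        frozenset(combo): 0
        for r in range(1, len(labels) + 1)
        for combo in combinations(labels, r)
    }
    for gene, sources in membership.items():
        venn[frozenset(sources)] += 1
    consensus = frozenset(
        gene for gene, sources in membership.items() if len(sources) >= min_sources
    )
    return consensus, venn


def sites_to_table(sites: Sequence[SeedSite], mirna_id: str = ""):
    """Plot/CLI-ready site table (utr_id, start, end, variant, motif)."""
    import pandas as pd

    rows = [
        {
            "mirna_id": mirna_id,
            "utr_id": s.utr_id,
            "start": s.start,
            "end": s.end,
            "variant": s.variant,
            "motif": s.matched_motif,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "utr_id", "start", "end", "variant", "motif"]
    )
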