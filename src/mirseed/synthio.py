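"""Synthetic inputs with planted ground truth.

Every generator is a pure function of its arguments including the seed, so
repeated calls are byte-identical.  Noise is i.i.d. Gaussian on the log2
scale (no intensity-dependent variance), single-channel samples only.

UTR generation guarantees exactness of the planted truth: planted UTRs
carry their sites at recorded positions and nothing else matches the
seed-complement motif anywhere, so a downstream exact-match scan recovers
the truth with zero false positives or negatives by construction.
Accidental motif occurrences are destroyed by single-base substitution and
the set is re-checked until clean.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .candidates import MirnaModelTable
from .formats import MatureMirna, SampleSheet, SequenceSet
from .seedtargets import SEED_VARIANTS, _find_all, seed_sequence

_BASES = "ACGT"


class SynthesisError(RuntimeError):
    """Raised when the generator cannot satisfy its planting constraints."""


@dataclass(frozen=True)
class UtrTruth:
    """Planted site positions: mirna_id -> utr_id -> tuple of starts."""

    sites: dict[str, dict[str, tuple[int, ...]]]
    variant: str

    @property
    def targets(self) -> dict[str, frozenset]:
        return {m: frozenset(per_utr) for m, per_utr in self.sites.items()}


@dataclass(frozen=True)
class ExpressionTruth:
    shifts: dict[str, float]
    n_per_group: int
    noise_sd: float
    seed: int


@dataclass(frozen=True)
class ModelTruth:
    per_model: dict[str, dict[str, int]]  # model -> {mirna: +1/-1}
    common: dict[str, int]


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=length)]


def gen_utrs(
    n_utrs: int,
    length_range: tuple[int, int],
    mirnas: Sequence[MatureMirna],
    planted_fraction: float | Mapping[str, float],
    seed: int,
    variant: str = "seed2_7",
    id_prefix: str = "utr",
    max_rounds: int = 200,
) -> tuple[SequenceSet, UtrTruth]:
    """Generate UTRs with exactly round(n_utrs * fraction) planted per miRNA.

    Planted UTRs carry one site at a uniform-random non-overlapping
    position; all other occurrences of any miRNA's motif anywhere in the
    set are rewritten away.
    """
    lo, hi = length_range
    if lo < 30:
        raise ValueError("minimum UTR length is 30")
    if hi < lo:
        raise ValueError("invalid length range")
    if variant not in SEED_VARIANTS:
        raise ValueError(f"unknown seed variant {variant!r}")
    if isinstance(planted_fraction, Real):
        fractions = {m.mirna_id: float(planted_fraction) for m in mirnas}
    else:
        fractions = {m.mirna_id: float(planted_fraction[m.mirna_id]) for m in mirnas}
    for mid, frac in fractions.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"planted fraction for {mid} outside [0, 1]")

    motifs = {m.mirna_id: seed_sequence(m, variant)[1] for m in mirnas}
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_utrs)))
    ids = [f"{id_prefix}{i:0{width}d}" for i in range(n_utrs)]
    lengths = rng.integers(lo, hi + 1, size=n_utrs)
    seqs = [_random_seq(rng, int(L)) for L in lengths]

    # choose planted UTRs and plant one site each at a free position
    protected: list[list[tuple[int, int]]] = [[] for _ in range(n_utrs)]
    sites: dict[str, dict[str, tuple[int, ...]]] = {}
    for m in mirnas:
        mid = m.mirna_id
        motif = motifs[mid]
        count = int(round(n_utrs * fractions[mid]))
        chosen = sorted(rng.choice(n_utrs, size=count, replace=False)) if count else []
        per_utr: dict[str, tuple[int, ...]] = {}
        for ui in chosen:
            L = len(seqs[ui])
            starts = np.arange(0, L - len(motif) + 1)
            rng.shuffle(starts)
            placed = False
            for start in starts:
                span = (int(start), int(start) + len(motif))
                if any(span[0] < e and s < span[1] for s, e in protected[ui]):
                    continue
                seqs[ui][span[0]:span[1]] = list(motif)
                protected[ui].append(span)
                per_utr[ids[ui]] = (span[0],)
                placed = True
                break
            if not placed:
                raise SynthesisError(
                    f"cannot place a site for {mid} in {ids[ui]} without overlap"
                )
        sites[mid] = per_utr

    # destroy accidental occurrences everywhere outside the planted spans
    id_to_index = {u: i for i, u in enumerate(ids)}
    allowed = {
        mid: {
            id_to_index[u]: set(starts) for u, starts in per_utr.items()
        }
        for mid, per_utr in sites.items()
    }
    for _ in range(max_rounds):
        dirty = False
        for ui in range(n_utrs):
            s = "".join(seqs[ui])
            for mid, motif in motifs.items():
                ok_starts = allowed[mid].get(ui, set())
                for occ in list(_find_all(s, motif)):
                    if occ in ok_starts:
                        continue
                    positions = [
                        p
                        for p in range(occ, occ + len(motif))
                        if not any(st <= p < en for st, en in protected[ui])
                    ]
                    if not positions:
                        raise SynthesisError(
                            "accidental motif occurrence fully inside planted "
                            f"sites in {ids[ui]}; cannot repair"
                        )
                    p = int(rng.choice(positions))
                    alternatives = [b for b in _BASES if b != seqs[ui][p]]
                    seqs[ui][p] = alternatives[int(rng.integers(0, 3))]
                    s = "".join(seqs[ui])
                    dirty = True
        if not dirty:
            break
    else:
        raise SynthesisError("could not eliminate accidental seed sites")

    out = SequenceSet()
    for u, seq in zip(ids, seqs):
        out.add(u, "".join(seq))
    return out, UtrTruth(sites=sites, variant=variant)


def gen_expression(
    features: Sequence[str],
    truth_shifts: Mapping[str, float],
    n_per_group: int = 3,
    noise_sd: float = 0.3,
    baseline_mean: float = 10.0,
    seed: int = 0,
    conditions: tuple[str, str] = ("control", "treatment"),
) -> tuple[pd.DataFrame, SampleSheet, ExpressionTruth]:
    """Two-condition replicated log2 matrix with planted per-feature shifts.

    Control samples are baseline plus Gaussian noise; treatment samples are
    additionally shifted by the planted log2 effect (0 for nulls).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    features = list(features)
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature ids")
    shifts = {f: float(truth_shifts.get(f, 0.0)) for f in features}
    if not all(np.isfinite(v) for v in shifts.values()):
        raise ValueError("planted shifts must be finite")
    control, treatment = conditions

    rng = np.random.default_rng(seed)
    n_feat = len(features)
    noise = rng.normal(0.0, noise_sd, size=(n_feat, 2 * n_per_group))
    data = baseline_mean + noise
    shift_vec = np.array([shifts[f] for f in features])
    data[:, n_per_group:] += shift_vec[:, None]

    samples = [f"{control}_{r}" for r in range(1, n_per_group + 1)] + [
        f"{treatment}_{r}" for r in range(1, n_per_group + 1)
    ]
    matrix = pd.DataFrame(data, index=features, columns=samples)
    sheet = SampleSheet.from_records(
        [(f"{cond}_{r}", cond, r) for cond in conditions for r in range(1, n_per_group + 1)]
    )
    truth = ExpressionTruth(
        shifts=shifts, n_per_group=n_per_group, noise_sd=noise_sd, seed=seed
    )
    return matrix, sheet, truth


def gen_model_tables(
    mirnas: Sequence[str],
    common_up: Iterable[str],
    common_down: Iterable[str],
    per_model_extras: Mapping[str, Mapping[str, int]] | None = None,
    n_per_group: int = 4,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    baseline: float = 8.0,
    seed: int = 0,
    model_names: tuple[str, ...] = ("lung", "liver", "kidney"),
) -> tuple[list[MirnaModelTable], ModelTruth]:
    """Per-model replicate tables with a planted common dysregulated subset.

    ``common_up``/``common_down`` miRNAs are shifted by +/-effect in every
    model; ``per_model_extras`` maps model name -> {mirna: +1/-1} for
    model-private dysregulation.
    """
    mirnas = list(mirnas)
    common_up, common_down = set(common_up), set(common_down)
    if common_up & common_down:
        raise ValueError("common_up and common_down overlap")
    if effect <= 0:
        raise ValueError("effect must be > 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    unknown = (common_up | common_down) - set(mirnas)
    if unknown:
        raise ValueError(f"planted miRNAs not in the universe: {sorted(unknown)}")
    extras = {m: dict(v) for m, v in (per_model_extras or {}).items()}
    for model, signs in extras.items():
        if model not in model_names:
            raise ValueError(f"unknown model {model!r} in per_model_extras")
        if set(signs) & (common_up | common_down):
            raise ValueError("per-model extras overlap the common subsets")
        if not set(signs) <= set(mirnas):
            raise ValueError("extras reference miRNAs outside the universe")
        if not all(s in (-1, 1) for s in signs.values()):
            raise ValueError("extra signs must be +1 or -1")

    rng = np.random.default_rng(seed)
    common = {m: 1 for m in common_up} | {m: -1 for m in common_down}
    tables: list[MirnaModelTable] = []
    per_model_truth: dict[str, dict[str, int]] = {}
    for model in model_names:
        signs = dict(common)
        signs.update(extras.get(model, {}))
        per_model_truth[model] = signs
        shift = np.array([signs.get(m, 0) * effect for m in mirnas])
        data = baseline + rng.normal(0.0, noise_sd, size=(len(mirnas), 2 * n_per_group))
        data[:, n_per_group:] += shift[:, None]
        cols = [f"control_{r}" for r in range(1, n_per_group + 1)] + [
            f"treatment_{r}" for r in range(1, n_per_group + 1)
        ]
        values = pd.DataFrame(data, index=mirnas, columns=cols)
        condition = {c: c.rsplit("_", 1)[0] for c in cols}
        tables.append(MirnaModelTable(model, values, condition))
    return tables, ModelTruth(per_model=per_model_truth, common=common)
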