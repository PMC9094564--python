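"""Negative-control construction and per-tree balanced resampling.

Three schemes produce negative training sets from a pool of benign variants:

* ``random`` — uniform over the pool; the naive genome-wide baseline.
* ``local`` — only variants within a window (default 1,000 bp) of a positive;
  tests discrimination at high genomic resolution.
* ``adjusted`` — restricted to cytogenetic bands containing at least one
  positive, with negative biotype proportions matched to the positives so
  the model learns functional differences rather than location bias.

All samplers are bit-reproducible given a seed and draw without replacement.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import assign_biotype
from .core_io import Biotype, CytoBand, IntervalTrack, Variant, normalize_contig

logger = logging.getLogger(__name__)


class Scheme(str, enum.Enum):
    RANDOM = "random"
    LOCAL = "local"
    ADJUSTED = "adjusted"


@dataclass
class SamplingReport:
    scheme: Scheme
    n_requested: int
    n_obtained: int
    per_biotype_counts: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    dropped_positives: list[Variant] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "n_requested": self.n_requested,
            "n_obtained": self.n_obtained,
            "per_biotype_counts": {
                k: list(v) for k, v in self.per_biotype_counts.items()
            },
            "n_dropped_positives": len(self.dropped_positives),
            "warnings": self.warnings,
        }


def sample_random(pool: Sequence[Variant], n: int, seed: int
                  ) -> tuple[list[Variant], SamplingReport]:
    """Uniform sample without replacement from a pre-filtered pool."""
    rng = np.random.default_rng(seed)
    report = SamplingReport(Scheme.RANDOM, n_requested=n, n_obtained=0)
    if n >= len(pool):
        if n > len(pool):
            report.warnings.append(
                f"requested {n} > pool size {len(pool)}; returning the pool"
            )
        chosen = list(pool)
    else:
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    report.n_obtained = len(chosen)
    return chosen, report


def sample_local(pool: Sequence[Variant], positives: Sequence[Variant],
                 window_bp: int = 1000, seed: int = 0,
                 per_positive_cap: int | None = None,
                 ) -> tuple[list[Variant], SamplingReport]:
    """All pool variants within ``window_bp`` of at least one positive.

    By default the eligible set is taken exhaustively; ``per_positive_cap``
    limits how many negatives each positive may recruit (nearest first).
    Positives that recruit no negative are recorded in
    ``report.dropped_positives``.
    """
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for j, v in enumerate(pool):
        by_contig.setdefault(normalize_contig(v.contig), []).append((v.pos, j))
    for lst in by_contig.values():
        lst.sort()

    chosen_idx: set[int] = set()
    dropped: list[Variant] = []
    for p in positives:
        positions = by_contig.get(normalize_contig(p.contig), [])
        eligible = [
            j for pos, j in positions if abs(pos - p.pos) <= window_bp
        ]
        if not eligible:
            dropped.append(p)
            continue
        if per_positive_cap is not None and len(eligible) > per_positive_cap:
            eligible.sort(key=lambda j: abs(pool[j].pos - p.pos))
            eligible = eligible[:per_positive_cap]
        chosen_idx.update(eligible)

    del rng  # reserved for future subsampling options; draws are exhaustive
    chosen = [pool[j] for j in sorted(chosen_idx)]
    report = SamplingReport(
        Scheme.LOCAL,
        n_requested=len(chosen),
        n_obtained=len(chosen),
        dropped_positives=dropped,
    )
    if dropped:
        report.warnings.append(
            f"{len(dropped)} positives had no negative within {window_bp} bp"
        )
    return chosen, report


def _band_lookup(bands: Sequence[CytoBand]) -> IntervalTrack:
    track = IntervalTrack()
    for b in bands:
        track.add(b.interval, (b.band_name,))
    return track


def band_of(variant: Variant, band_index: IntervalTrack) -> str | None:
    hits = band_index.query(variant.contig, variant.pos0)
    return hits[0][0] if hits else None


def largest_remainder_quotas(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas proportional to ``fractions`` summing exactly to total."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def sample_adjusted(pool: Sequence[Variant], positives: Sequence[Variant],
                    bands: Sequence[CytoBand], gene_index: IntervalTrack,
                    n_total: int, seed: int = 0,
                    tolerance: float = 0.01,
                    ) -> tuple[list[Variant], SamplingReport]:
    """Band-restricted, biotype-matched negative sampling.

    Negatives are drawn only from cytogenetic bands containing at least one
    positive, with per-biotype counts matched to the positive biotype
    proportions by largest-remainder quotas.  A stratum whose eligible pool
    is too small is under-filled with a warning and the positives in that
    stratum are flagged.
    """
    rng = np.random.default_rng(seed)
    band_index = _band_lookup(bands)
    report = SamplingReport(Scheme.ADJUSTED, n_requested=n_total, n_obtained=0)
    if n_total == 0:
        return [], report

    positive_bands = {
        band_of(p, band_index) for p in positives
    } - {None}

    pos_biotypes = [assign_biotype(p, gene_index) for p in positives]
    biotypes = sorted({bt for bt in pos_biotypes}, key=lambda b: b.value)
    pos_counts = np.array(
        [sum(bt == b for bt in pos_biotypes) for b in biotypes], dtype=float
    )
    pos_fracs = pos_counts / pos_counts.sum()
    quotas = largest_remainder_quotas(pos_fracs, n_total)

    # eligible pool per biotype stratum, band-restricted
    strata: dict[Biotype, list[int]] = {b: [] for b in biotypes}
    for j, v in enumerate(pool):
        band = band_of(v, band_index)
        if band not in positive_bands:
            continue
        bt = assign_biotype(v, gene_index)
        if bt in strata:
            strata[bt].append(j)

    chosen_idx: list[int] = []
    obtained = np.zeros(len(biotypes), dtype=int)
    for k, (biotype, quota) in enumerate(zip(biotypes, quotas)):
        eligible = strata[biotype]
        if quota > len(eligible):
            report.warnings.append(
                f"stratum {biotype.value}: pool exhausted "
                f"({len(eligible)} available, {quota} requested)"
            )
            for p, bt in zip(positives, pos_biotypes):
                if bt == biotype:
                    report.dropped_positives.append(p)
            take = eligible
        else:
            pick = rng.choice(len(eligible), size=quota, replace=False)
            take = [eligible[i] for i in sorted(pick)]
        chosen_idx.extend(take)
        obtained[k] = len(take)

    chosen = [pool[j] for j in sorted(chosen_idx)]
    report.n_obtained = len(chosen)
    neg_fracs = obtained / max(obtained.sum(), 1)
    report.per_biotype_counts = {
        b.value: (float(pf), float(nf))
        for b, pf, nf in zip(biotypes, pos_fracs, neg_fracs)
    }
    if not report.warnings:
        worst = float(np.max(np.abs(neg_fracs - pos_fracs)))
        if worst > tolerance:
            report.warnings.append(
                f"biotype proportion mismatch {worst:.4f} > {tolerance}"
            )
    return chosen, report


def balanced_per_tree_samples(y: np.ndarray, n_trees: int, seed: int
                              ) -> list[np.ndarray]:
    """One balanced bootstrap per tree: n draws with replacement per class,
    n = size of the smallest class.  Draws are independent across trees."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(y == c) for c in classes]
    n = min(len(ci) for ci in class_idx)
    samples = []
    for _ in range(n_trees):
        parts = [rng.choice(ci, size=n, replace=True) for ci in class_idx]
        samples.append(np.concatenate(parts))
    return samples
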