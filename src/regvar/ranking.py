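"""Regulatory-region merging, disease-gene filtering and candidate ranking.

Regulatory-region/target-gene resources are integrated by merging any
overlapping intervals (1 bp of overlap suffices) into maximal regions whose
target-gene and evidence sets are the unions over their constituents.  A
resource can be flagged pass-through and kept unmerged when its per-pair
scores should be preserved.  Candidate variants are then filtered to those
falling in a region whose predicted targets intersect a disease-gene list,
and ranked by score (ties broken by coordinate, then alt allele, for
determinism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, IntervalTrack, Variant, normalize_contig
from .model import ScoreRecord, affected_positions


@dataclass
class RegulatoryRegion:
    interval: GenomicInterval
    target_genes: set[str]
    evidence_sources: set[str]

    def __post_init__(self) -> None:
        if not self.target_genes:
            raise ValueError("a regulatory region needs at least one target")
        if not self.evidence_sources:
            raise ValueError("a regulatory region needs an evidence source")


def merge_regulatory_datasets(
    datasets: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    pass_through: Iterable[str] = (),
) -> list[RegulatoryRegion]:
    """Union overlapping (interval, target gene) records across resources.

    ``datasets`` maps a source name to its (interval, gene) pairs.  Sources
    named in ``pass_through`` are emitted unmerged (their per-record
    identity preserved); the rest are swept per contig and chained overlaps
    collapse into one region with unioned targets and sources.
    """
    pass_through = set(pass_through)
    out: list[RegulatoryRegion] = []
    entries: list[tuple[GenomicInterval, str, str]] = []
    for source, records in datasets.items():
        for interval, gene in records:
            if source in pass_through:
                out.append(RegulatoryRegion(interval, {gene}, {source}))
            else:
                entries.append((interval, gene, source))

    by_contig: dict[str, list[tuple[GenomicInterval, str, str]]] = {}
    for interval, gene, source in entries:
        by_contig.setdefault(normalize_contig(interval.contig), []).append(
            (interval, gene, source)
        )
    for contig in sorted(by_contig):
        group = sorted(by_contig[contig], key=lambda e: (e[0].start, e[0].end))
        cur_start = cur_end = None
        cur_contig = None
        genes: set[str] = set()
        sources: set[str] = set()
        for interval, gene, source in group:
            if cur_end is not None and interval.start < cur_end:
                cur_end = max(cur_end, interval.end)
                genes.add(gene)
                sources.add(source)
            else:
                if cur_end is not None:
                    out.append(RegulatoryRegion(
                        GenomicInterval(cur_contig, cur_start, cur_end),
                        genes, sources,
                    ))
                cur_contig, cur_start, cur_end = (
                    interval.contig, interval.start, interval.end
                )
                genes, sources = {gene}, {source}
        if cur_end is not None:
            out.append(RegulatoryRegion(
                GenomicInterval(cur_contig, cur_start, cur_end),
                genes, sources,
            ))
    return out


def build_region_index(regions: Sequence[RegulatoryRegion]) -> IntervalTrack:
    track = IntervalTrack()
    for i, region in enumerate(regions):
        track.add(region.interval, (i,))
    return track


def _variant_positions0(variant: Variant) -> list[int]:
    """0-based positions at which a variant can claim region membership:
    the point for an SNV, every evaluated position for an indel."""
    if variant.is_snv:
        return [variant.pos0]
    return [p - 1 for p in affected_positions(variant) if p >= 1]


def regions_of_variant(variant: Variant, regions: Sequence[RegulatoryRegion],
                       region_index: IntervalTrack) -> list[RegulatoryRegion]:
    hits: list[int] = []
    for pos0 in _variant_positions0(variant):
        for (i,) in region_index.query(variant.contig, pos0):
            if i not in hits:
                hits.append(i)
    return [regions[i] for i in sorted(hits)]


@dataclass
class RankedCandidate:
    variant: Variant
    score: float
    matched_genes: set[str]
    rank: int


def filter_by_disease_genes(scored: Sequence[ScoreRecord],
                            regions: Sequence[RegulatoryRegion],
                            disease_genes: set[str],
                            ) -> list[RankedCandidate]:
    """Retain variants in regions targeting a disease gene; rank by score.

    Ties are broken by (contig, pos, alt) ascending so ranking is
    deterministic.  An empty disease-gene set is an error, distinct from a
    legitimately empty result.
    """
    if not disease_genes:
        raise ValueError("disease gene set is empty")
    index = build_region_index(regions)
    kept: list[tuple[ScoreRecord, set[str]]] = []
    for record in scored:
        matched: set[str] = set()
        for region in regions_of_variant(record.variant, regions, index):
            matched |= region.target_genes & disease_genes
        if matched:
            kept.append((record, matched))
    kept.sort(key=lambda item: (
        -item[0].score,
        normalize_contig(item[0].variant.contig),
        item[0].variant.pos,
        item[0].variant.alt,
    ))
    return [
        RankedCandidate(rec.variant, rec.score, genes, rank)
        for rank, (rec, genes) in enumerate(kept, start=1)
    ]


@dataclass
class SpikeInResult:
    disease: str
    spike_in: Variant
    rank: int | None        # None when unrankable
    candidate_set_size: int
    score: float | None = None


def spike_in_benchmark(
    background: Sequence[ScoreRecord],
    pathogenic: Sequence[tuple[str, ScoreRecord, set[str]]],
    regions: Sequence[RegulatoryRegion],
) -> list[SpikeInResult]:
    """Seed pathogenic variants into a background, filter per disease, rank.

    ``pathogenic`` holds (disease name, scored spike-in, disease gene set).
    For each disease the spike-in is pooled with every background variant,
    the pool is restricted to variants inside regulatory regions targeting
    the disease genes, and the spike-in's rank within that candidate set is
    reported.  A spike-in falling in no region targeting its disease gene is
    unrankable and flagged (rank None).
    """
    background_keys = {r.variant.key for r in background}
    results: list[SpikeInResult] = []
    for disease, spike, genes in pathogenic:
        if spike.variant.key in background_keys:
            raise ValueError(
                f"spike-in {spike.variant.key} already in the background"
            )
        pool = list(background) + [spike]
        candidates = filter_by_disease_genes(pool, regions, genes)
        size = len(candidates)
        rank = next(
            (c.rank for c in candidates
             if c.variant.key == spike.variant.key),
            None,
        )
        results.append(SpikeInResult(
            disease=disease, spike_in=spike.variant, rank=rank,
            candidate_set_size=size, score=spike.score,
        ))
    return results


def median_rank(results: Sequence[SpikeInResult]) -> float:
    """Median rank of rankable spike-ins; unrankable ones are excluded."""
    ranks = [r.rank for r in results if r.rank is not None]
    if not ranks:
        return float("nan")
    return float(np.median(ranks))
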