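"""Statistically controlled synthetic fixtures for the whole pipeline.

The generator emulates the *structure* of the data a regulatory-variant
classifier consumes — a genome with contigs, cytogenetic bands, genes with
biotype segments, regulatory regions with target genes, per-position feature
tracks, and two variant classes — without any real sequence content.  Three
properties of real training data are reproduced because the method's design
responds to them:

* **Biotype imbalance** — positive (disease) variants are biased toward
  gene-proximal biotypes (promoters, introns) while the benign pool is
  uniform, which is what motivates biotype-matched negative sampling.
* **Class-conditional feature shifts** — a configurable subset of features
  differs between classes by a configurable standardized effect size.
* **Spatial autocorrelation** — variants in the same genomic window share a
  latent noise component on the informative features, and positives arrive
  in local clusters; this is the minimal mechanism that makes random-split
  cross-validation optimistic relative to band-aware cross-validation.

Everything is bit-reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import (
    CHROMATIN_STATES,
    Aggregation,
    FeatureSchema,
    default_schema,
)
from .core_io import (
    Biotype,
    CytoBand,
    Gene,
    GenomicInterval,
    IntervalTrack,
    Label,
    Variant,
    VariantType,
    write_gene_table,
    write_interval_table,
    write_vcf,
)
from .ranking import RegulatoryRegion

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    n_contigs: int = 2
    contig_length_bp: int = 10_000_000
    n_bands_per_contig: int = 20
    n_genes: int = 200
    promoter_span_bp: int = 2000
    n_regulatory_regions: int = 500
    targets_per_region: int = 2
    n_informative: int = 5
    effect_size: float = 3.0
    autocorr_window_bp: int = 50_000
    autocorr_sd: float = 1.0
    positive_cluster_size: int = 4
    n_positives: int = 800
    n_negative_pool: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_contigs", "contig_length_bp", "n_bands_per_contig",
                     "n_genes", "n_regulatory_regions", "n_positives",
                     "n_negative_pool"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class Layout:
    contigs: dict[str, int]
    bands: list[CytoBand]
    genes: list[Gene]
    regions: list[RegulatoryRegion]


@dataclass
class SimulatedVariants:
    variants: list[Variant]       # positives first, then the negative pool
    X: np.ndarray                 # aligned feature matrix (schema order)
    y: np.ndarray                 # 1 = positive, 0 = negative
    schema: FeatureSchema
    truth: dict = field(default_factory=dict)

    @property
    def positives(self) -> list[Variant]:
        return [v for v, lab in zip(self.variants, self.y) if lab == 1]

    @property
    def pool(self) -> list[Variant]:
        return [v for v, lab in zip(self.variants, self.y) if lab == 0]


def simulate_layout(cfg: SimulationConfig) -> Layout:
    """Contigs tiled by bands; genes with promoter/UTR/CDS/intron segments;
    regulatory regions anchored near gene promoters with target lists."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    contigs = {
        f"chr{i + 1}": cfg.contig_length_bp for i in range(cfg.n_contigs)
    }

    bands: list[CytoBand] = []
    for ci, (contig, length) in enumerate(contigs.items(), start=1):
        edges = np.linspace(0, length, cfg.n_bands_per_contig + 1, dtype=int)
        for bi, (s, e) in enumerate(zip(edges[:-1], edges[1:]), start=1):
            bands.append(CytoBand(
                GenomicInterval(contig, int(s), int(e)), f"{ci}q{bi:02d}"
            ))

    genes_per_contig = cfg.n_genes // cfg.n_contigs
    slot = cfg.contig_length_bp // max(genes_per_contig, 1)
    max_body = 40_000
    if slot < cfg.promoter_span_bp + max_body + 1000:
        raise ValueError(
            "geometry impossible: too many genes for the contig length"
        )
    genes: list[Gene] = []
    gi = 0
    for contig in contigs:
        for j in range(genes_per_contig):
            tss = j * slot + cfg.promoter_span_bp + int(
                rng.integers(0, slot // 4)
            )
            body_len = int(rng.integers(5_000, max_body))
            gene_id = f"G{gi:04d}"
            segments: list[tuple[GenomicInterval, Biotype]] = [
                (GenomicInterval(contig, tss - cfg.promoter_span_bp, tss),
                 Biotype.PROMOTER),
                (GenomicInterval(contig, tss, tss + 300), Biotype.UTR),
            ]
            if rng.random() < 0.1:  # non-coding gene
                segments.append((
                    GenomicInterval(contig, tss + 300, tss + body_len),
                    Biotype.EXON_NONCODING,
                ))
            else:
                cursor = tss + 300
                exon_len = max(body_len // 8, 100)
                for k in range(3):
                    segments.append((
                        GenomicInterval(contig, cursor, cursor + exon_len),
                        Biotype.CDS,
                    ))
                    cursor += exon_len
                    if k < 2:
                        intron_len = max(
                            (body_len - 3 * exon_len) // 2, 100
                        )
                        segments.append((
                            GenomicInterval(contig, cursor,
                                            cursor + intron_len),
                            Biotype.INTRON,
                        ))
                        cursor += intron_len
            genes.append(Gene(
                gene_id, f"SYM{gi:04d}",
                GenomicInterval(contig, tss, tss + 1), segments,
            ))
            gi += 1

    sources = ("coexpression", "conserved_linkage", "chromatin_link")
    regions: list[RegulatoryRegion] = []
    for _ in range(cfg.n_regulatory_regions):
        g = genes[int(rng.integers(0, len(genes)))]
        tss = g.tss.start
        length = int(rng.integers(800, 2_500))
        start = max(0, tss - cfg.promoter_span_bp - int(rng.integers(0, 500)))
        targets = {g.gene_id}
        while len(targets) < cfg.targets_per_region:
            targets.add(genes[int(rng.integers(0, len(genes)))].gene_id)
        regions.append(RegulatoryRegion(
            GenomicInterval(g.tss.contig, start, start + length),
            targets,
            {sources[int(rng.integers(0, len(sources)))]},
        ))
    return Layout(contigs, bands, genes, regions)


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = "ACGT"[int(rng.integers(0, 4))]
    if rng.random() < 0.5:
        return ref, _TRANSITION_OF[ref]
    others = [b for b in "ACGT" if b != ref and b != _TRANSITION_OF[ref]]
    return ref, others[int(rng.integers(0, 2))]


def simulate_variants(cfg: SimulationConfig, layout: Layout
                      ) -> SimulatedVariants:
    """Labeled variants plus their class-conditional feature matrix.

    The feature matrix is drawn directly at the configured effect sizes
    (the informative features gain ``effect_size`` standard deviations in
    positives) with window-shared latent noise; adding the effect consumes
    no random draws, so two configs differing only in ``effect_size`` yield
    identical variant positions and base noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    schema = default_schema()
    contig_names = list(layout.contigs)

    # -- positions: clustered positives near promoters, uniform negatives
    positions: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    n_clusters = max(1, cfg.n_positives // cfg.positive_cluster_size)
    anchors = [
        layout.genes[int(rng.integers(0, len(layout.genes)))]
        for _ in range(n_clusters)
    ]
    while len(positions) < cfg.n_positives:
        g = anchors[len(positions) % n_clusters]
        u = rng.random()
        if u < 0.45:  # promoter
            pos = g.tss.start - int(rng.integers(1, cfg.promoter_span_bp))
        elif u < 0.80:  # gene body (mostly introns)
            pos = g.tss.start + int(rng.integers(300, 5_000))
        else:  # near-gene intergenic
            pos = g.tss.start + int(rng.integers(6_000, 20_000))
        pos = max(2, min(pos, layout.contigs[g.tss.contig] - 2))
        key = (g.tss.contig, pos)
        if key in seen:
            continue
        seen.add(key)
        positions.append(key)
    n_pos = len(positions)
    while len(positions) < cfg.n_positives + cfg.n_negative_pool:
        contig = contig_names[int(rng.integers(0, len(contig_names)))]
        pos = int(rng.integers(2, layout.contigs[contig] - 2))
        key = (contig, pos)
        if key in seen:
            continue
        seen.add(key)
        positions.append(key)

    variants: list[Variant] = []
    for i, (contig, pos) in enumerate(positions):
        ref, alt = _random_snv_alleles(rng)
        label = Label.POSITIVE if i < n_pos else Label.NEGATIVE
        variants.append(Variant(contig, pos, ref, alt, label))
    y = np.array([1] * n_pos + [0] * cfg.n_negative_pool)

    # -- features
    n = len(variants)
    p = len(schema)
    informative = [
        schema.index(name) for name in (
            "phylop_vertebrate", "phylop_primate", "phastcons_vertebrate",
            "phastcons_primate", "gerp_score", "cdts",
            "tfbs_cluster_max_score", "h3k27ac_median",
        )[: cfg.n_informative]
    ]
    X = np.zeros((n, p))
    latent = {
        contig: rng.normal(0.0, cfg.autocorr_sd,
                           length // cfg.autocorr_window_bp + 1)
        for contig, length in layout.contigs.items()
    }
    window_noise = np.array([
        latent[v.contig][v.pos0 // cfg.autocorr_window_bp] for v in variants
    ])
    for j, spec in enumerate(schema):
        if spec.aggregation is Aggregation.COMPUTED:
            X[:, j] = [
                float(spec.name == f"is_{v.variant_type.value}")
                for v in variants
            ]
        elif spec.dtype == "binary":
            X[:, j] = rng.random(n) < 0.15
        elif spec.dtype == "discrete":
            X[:, j] = rng.poisson(2.0, n)
        else:
            X[:, j] = rng.normal(0.0, 1.0, n)
        if j in informative:
            X[:, j] = X[:, j] + window_noise
    # the effect shift consumes no rng draws (see docstring)
    for j in informative:
        X[y == 1, j] += cfg.effect_size

    truth = {
        "informative_features": [schema.names[j] for j in informative],
        "informative_indices": informative,
        "effect_size": cfg.effect_size,
        "seed": cfg.seed,
        "n_positives": n_pos,
        "n_negative_pool": cfg.n_negative_pool,
    }
    return SimulatedVariants(variants, X, y, schema, truth)


def build_track_compendium(cfg: SimulationConfig, layout: Layout,
                           sim: SimulatedVariants
                           ) -> dict[str, IntervalTrack]:
    """Per-feature interval tracks consistent with the schema.

    Continuous conservation-style tracks tile the genome coarsely with
    Gaussian values; the informative features additionally carry short
    high-value intervals centred on positive variants, so track-based
    annotation recovers the class signal (and nearby negatives inherit
    part of it — local correlation, as in real data).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    schema = sim.schema
    informative = set(sim.truth["informative_features"])
    tracks: dict[str, IntervalTrack] = {}
    tile = 10_000

    def random_intervals(n_per_contig: int, min_len: int, max_len: int):
        for contig, length in layout.contigs.items():
            starts = np.sort(rng.integers(0, length - max_len, n_per_contig))
            for s in starts:
                yield GenomicInterval(contig, int(s),
                                      int(s) + int(rng.integers(min_len,
                                                                max_len)))

    for spec in schema:
        if spec.aggregation is Aggregation.COMPUTED:
            continue
        track = IntervalTrack()
        if spec.dtype == "continuous":
            for contig, length in layout.contigs.items():
                edges = np.arange(0, length + tile, tile)
                vals = rng.normal(0.0, 1.0, len(edges) - 1)
                for s, e, v in zip(edges[:-1], edges[1:], vals):
                    track.add(GenomicInterval(contig, int(s), int(min(e, length))),
                              (float(v),))
            if spec.name in informative:
                for v in sim.positives:
                    track.add(
                        GenomicInterval(v.contig, max(0, v.pos0 - 10),
                                        v.pos0 + 11),
                        (float(cfg.effect_size + rng.normal(0.0, 1.0)),),
                    )
        elif spec.dtype == "discrete":
            for interval in random_intervals(300, 500, 2_000):
                track.add(interval, (float(rng.integers(0, 8)),))
        else:  # binary presence/absence tracks
            for interval in random_intervals(400, 200, 1_000):
                track.add(interval, (1.0,))
        tracks[spec.source] = track

    # structural tracks come from the layout itself
    promoters, utrs = IntervalTrack(), IntervalTrack()
    for g in layout.genes:
        for interval, biotype in g.biotype_segments:
            if biotype is Biotype.PROMOTER:
                promoters.add(interval, (1.0,))
            elif biotype is Biotype.UTR:
                utrs.add(interval, (1.0,))
    tracks["promoters"] = promoters
    tracks["utrs"] = utrs
    merged = IntervalTrack()
    for region in layout.regions:
        merged.add(region.interval, (1.0,))
    tracks["merged_regulatory"] = merged
    return tracks


def write_fixture(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full fixture directory in the formats the pipeline reads.

    Writes positives/pool VCFs, band BED, gene table TSV, region TSV, one
    BED track per schema source, and the ground truth as JSON.  Same config
    (same seed) always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = simulate_layout(cfg)
    sim = simulate_variants(cfg, layout)
    tracks = build_track_compendium(cfg, layout, sim)

    paths: dict[str, Path] = {}
    paths["positives_vcf"] = out / "positives.vcf"
    write_vcf(sim.positives, paths["positives_vcf"])
    paths["pool_vcf"] = out / "pool.vcf"
    write_vcf(sim.pool, paths["pool_vcf"])

    paths["bands_bed"] = out / "bands.bed"
    with open(paths["bands_bed"], "w") as fh:
        for b in layout.bands:
            fh.write(f"{b.interval.contig}\t{b.interval.start}\t"
                     f"{b.interval.end}\t{b.band_name}\n")

    paths["genes_tsv"] = out / "genes.tsv"
    write_gene_table(layout.genes, paths["genes_tsv"])

    paths["regions_tsv"] = out / "regions.tsv"
    with open(paths["regions_tsv"], "w") as fh:
        fh.write("contig\tstart\tend\tgene_id\tsource\n")
        for region in layout.regions:
            for gene_id in sorted(region.target_genes):
                for source in sorted(region.evidence_sources):
                    fh.write(
                        f"{region.interval.contig}\t{region.interval.start}"
                        f"\t{region.interval.end}\t{gene_id}\t{source}\n"
                    )

    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for name, track in tracks.items():
        path = tracks_dir / f"{name}.bed"
        write_interval_table(track, path)
        paths[f"track:{name}"] = path

    paths["truth_json"] = out / "truth.json"
    paths["truth_json"].write_text(json.dumps(sim.truth, indent=2))

    schema_path = out / "schema.yaml"
    sim.schema.to_yaml(schema_path)
    paths["schema_yaml"] = schema_path
    return paths


def read_regions_tsv(path: str | Path) -> list[RegulatoryRegion]:
    """Read a region TSV (contig, start, end, gene_id, source) back into
    regions, re-grouping rows that share an interval."""
    grouped: dict[tuple, RegulatoryRegion] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"unexpected region table header in {path}")
        for line in fh:
            contig, start, end, gene_id, source = line.rstrip("\n").split("\t")
            key = (contig, int(start), int(end))
            if key in grouped:
                grouped[key].target_genes.add(gene_id)
                grouped[key].evidence_sources.add(source)
            else:
                grouped[key] = RegulatoryRegion(
                    GenomicInterval(contig, int(start), int(end)),
                    {gene_id}, {source},
                )
    return list(grouped.values())
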