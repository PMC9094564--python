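import json

import numpy as np
import pytest

from regvar.annotation import Annotator, assign_biotype, build_gene_index
from regvar.core_io import (
    Biotype,
    read_bands_bed,
    read_gene_table,
    read_interval_table,
    read_vcf,
    write_interval_table,
)
from regvar.synthetic_data import (
    SimulationConfig,
    build_track_compendium,
    read_regions_tsv,
    simulate_layout,
    simulate_variants,
    write_fixture,
)

FIXTURE_CFG = SimulationConfig(
    contig_length_bp=1_500_000, n_bands_per_contig=8, n_genes=30,
    n_regulatory_regions=80, n_positives=60, n_negative_pool=600, seed=11,
)


class TestLayout:
    def test_bands_tile_contigs_exactly(self, tiny_cfg, tiny_layout):
        for contig, length in tiny_layout.contigs.items():
            bands = sorted(
                (b for b in tiny_layout.bands if b.interval.contig == contig),
                key=lambda b: b.interval.start,
            )
            assert bands[0].interval.start == 0
            assert bands[-1].interval.end == length
            assert sum(len(b.interval) for b in bands) == length
            for a, b in zip(bands, bands[1:]):
                assert a.interval.end == b.interval.start

    def test_region_targets_exist_in_gene_set(self, tiny_layout):
        gene_ids = {g.gene_id for g in tiny_layout.genes}
        for region in tiny_layout.regions:
            assert region.target_genes <= gene_ids
            assert region.target_genes

    def test_same_seed_identical_layout(self, tiny_cfg):
        a = simulate_layout(tiny_cfg)
        b = simulate_layout(tiny_cfg)
        assert [(x.interval.contig, x.interval.start, x.interval.end)
                for x in a.bands] == \
            [(x.interval.contig, x.interval.start, x.interval.end)
             for x in b.bands]
        assert [(g.gene_id, g.tss.start) for g in a.genes] == \
            [(g.gene_id, g.tss.start) for g in b.genes]

    def test_impossible_geometry_is_an_error(self):
        cfg = SimulationConfig(contig_length_bp=100_000, n_genes=500)
        with pytest.raises(ValueError, match="geometry"):
            simulate_layout(cfg)


class TestVariants:
    def test_reproducible_under_seed(self, tiny_cfg, tiny_layout):
        a = simulate_variants(tiny_cfg, tiny_layout)
        b = simulate_variants(tiny_cfg, tiny_layout)
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        assert np.array_equal(a.X, b.X)

    def test_effect_shift_consumes_no_draws(self, tiny_cfg, tiny_layout):
        a = simulate_variants(tiny_cfg.with_(effect_size=0.0), tiny_layout)
        b = simulate_variants(tiny_cfg.with_(effect_size=2.0), tiny_layout)
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        j = a.truth["informative_indices"][0]
        shift = b.X[a.y == 1, j] - a.X[a.y == 1, j]
        assert np.allclose(shift, 2.0)
        assert np.array_equal(a.X[a.y == 0], b.X[a.y == 0])

    def test_null_effect_gives_matched_class_distributions(self, tiny_cfg,
                                                           tiny_layout):
        sim = simulate_variants(tiny_cfg.with_(effect_size=0.0), tiny_layout)
        for j in sim.truth["informative_indices"]:
            diff = sim.X[sim.y == 1, j].mean() - sim.X[sim.y == 0, j].mean()
            assert abs(diff) < 0.5  # window noise keeps this loose

    def test_positive_biotype_distribution_is_gene_proximal(self, tiny_layout,
                                                            tiny_sim):
        gene_index = build_gene_index(tiny_layout.genes)

        def promoter_fraction(variants):
            biotypes = [assign_biotype(v, gene_index) for v in variants]
            return np.mean([bt is Biotype.PROMOTER for bt in biotypes])

        pos_frac = promoter_fraction(tiny_sim.positives)
        neg_frac = promoter_fraction(tiny_sim.pool[:2000])
        assert pos_frac - neg_frac > 0.1

    def test_unique_variant_keys(self, tiny_sim):
        keys = [v.key for v in tiny_sim.variants]
        assert len(set(keys)) == len(keys)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fx")
    paths = write_fixture(FIXTURE_CFG, out)
    return out, paths


@pytest.fixture(scope="module")
def compendium():
    layout = simulate_layout(FIXTURE_CFG)
    sim = simulate_variants(FIXTURE_CFG, layout)
    return layout, sim, build_track_compendium(FIXTURE_CFG, layout, sim)


class TestFixtureFiles:
    def test_vcfs_round_trip(self, fixture_dir):
        out, paths = fixture_dir
        positives = read_vcf(paths["positives_vcf"])
        pool = read_vcf(paths["pool_vcf"])
        assert len(positives) == FIXTURE_CFG.n_positives
        assert len(pool) == FIXTURE_CFG.n_negative_pool

    def test_bands_genes_regions_readable(self, fixture_dir):
        out, paths = fixture_dir
        bands = read_bands_bed(paths["bands_bed"])
        assert len(bands) == FIXTURE_CFG.n_contigs * \
            FIXTURE_CFG.n_bands_per_contig
        genes = read_gene_table(paths["genes_tsv"])
        assert len(genes) == (FIXTURE_CFG.n_genes // FIXTURE_CFG.n_contigs) \
            * FIXTURE_CFG.n_contigs
        regions = read_regions_tsv(paths["regions_tsv"])
        assert len(regions) == FIXTURE_CFG.n_regulatory_regions

    def test_truth_records_informative_features(self, fixture_dir):
        out, paths = fixture_dir
        truth = json.loads(paths["truth_json"].read_text())
        assert len(truth["informative_features"]) == \
            FIXTURE_CFG.n_informative
        assert truth["effect_size"] == FIXTURE_CFG.effect_size

    def test_fixture_is_byte_reproducible(self, tmp_path):
        import hashlib

        def tree_hash(root):
            digest = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file():
                    digest.update(p.name.encode())
                    digest.update(p.read_bytes())
            return digest.hexdigest()

        a, b = tmp_path / "a", tmp_path / "b"
        write_fixture(FIXTURE_CFG, a)
        write_fixture(FIXTURE_CFG, b)
        assert tree_hash(a) == tree_hash(b)


class TestTrackCompendium:
    def test_covers_every_schema_source(self, compendium):
        _, sim, tracks = compendium
        annotator = Annotator(sim.schema, tracks)  # raises if any is missing
        assert annotator is not None

    def test_tracks_round_trip_through_readers(self, compendium, tmp_path):
        _, _, tracks = compendium
        for name in ("phylop_vertebrate", "dnase_cluster", "promoters"):
            path = tmp_path / f"{name}.bed"
            write_interval_table(tracks[name], path)
            back = read_interval_table(path)
            assert back.n_records == tracks[name].n_records
            original = sorted(
                (iv.contig, iv.start, iv.end, vals)
                for iv, vals in tracks[name]
            )
            reread = sorted(
                (iv.contig, iv.start, iv.end, vals) for iv, vals in back
            )
            for (c1, s1, e1, v1), (c2, s2, e2, v2) in zip(original, reread):
                assert (c1, s1, e1) == (c2, s2, e2)
                assert np.allclose(v1, v2, atol=1e-9)

    def test_annotation_recovers_class_signal(self, compendium):
        layout, sim, tracks = compendium
        annotator = Annotator(sim.schema, tracks)
        j = sim.schema.index(sim.truth["informative_features"][0])
        pos_vals = [annotator.annotate(v)[j] for v in sim.positives[:40]]
        neg_vals = [annotator.annotate(v)[j] for v in sim.pool[:200]]
        assert np.mean(pos_vals) - np.mean(neg_vals) > 1.0
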