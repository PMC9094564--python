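import numpy as np
import pytest

from regvar.annotation import (
    CHROMATIN_STATES,
    Aggregation,
    AnnotationConfigError,
    Annotator,
    FeatureGroup,
    FeatureSchema,
    FeatureSpec,
    aggregate_chromatin_states,
    assign_biotype,
    build_gene_index,
    default_schema,
    median_signal,
)
from regvar.core_io import (
    Biotype,
    Gene,
    GenomicInterval,
    IntervalTrack,
    Variant,
)


class TestChromatinAggregation:
    def test_all_cell_types_one_state(self):
        counts = aggregate_chromatin_states(
            {"c1": "TssA", "c2": "TssA", "c3": "TssA"}
        )
        assert counts[CHROMATIN_STATES.index("TssA")] == 3
        assert counts.sum() == 3

    def test_mixed_states(self):
        counts = aggregate_chromatin_states({"ctA": "EnhA1", "ctB": "Quies"})
        assert counts[CHROMATIN_STATES.index("EnhA1")] == 1
        assert counts[CHROMATIN_STATES.index("Quies")] == 1
        assert counts.sum() == 2

    def test_empty_map_gives_zeros(self):
        assert aggregate_chromatin_states({}).sum() == 0

    def test_unknown_state_is_an_error(self):
        with pytest.raises(ValueError, match="NotAState"):
            aggregate_chromatin_states({"c": "NotAState"})

    def test_counts_conserve_number_of_calls(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(0, 30))
            calls = {
                f"ct{i}": CHROMATIN_STATES[rng.integers(len(CHROMATIN_STATES))]
                for i in range(n)
            }
            assert aggregate_chromatin_states(calls).sum() == n


@pytest.mark.parametrize("values,expected", [
    ([1.0, 3.0, 2.0], 2.0),
    ([1.0, 2.0, 3.0, 4.0], 2.5),
    ([5.0], 5.0),
])
def test_median_signal(values, expected):
    assert median_signal(values) == expected


def test_median_signal_empty_maps_to_missing():
    assert median_signal([], missing_value=-9.0) == -9.0


def _gene_with_overlaps():
    # promoter and intron deliberately overlapping around the TSS region
    return Gene(
        "G1", "S1", GenomicInterval("chr1", 5000, 5001),
        [
            (GenomicInterval("chr1", 3000, 5000), Biotype.PROMOTER),
            (GenomicInterval("chr1", 4000, 6000), Biotype.INTRON),
            (GenomicInterval("chr1", 5000, 5300), Biotype.UTR),
            (GenomicInterval("chr1", 5300, 5600), Biotype.CDS),
        ],
    )


class TestBiotypeAssignment:
    def test_priority_promoter_over_intron(self):
        index = build_gene_index([_gene_with_overlaps()])
        v = Variant("chr1", 4500, "A", "G")  # pos0 4499: promoter + intron
        assert assign_biotype(v, index) is Biotype.PROMOTER

    def test_no_overlap_is_intergenic(self):
        index = build_gene_index([_gene_with_overlaps()])
        assert assign_biotype(Variant("chr1", 100, "A", "G"), index) \
            is Biotype.INTERGENIC

    def test_cds_wins(self):
        index = build_gene_index([_gene_with_overlaps()])
        assert assign_biotype(Variant("chr1", 5400, "A", "G"), index) \
            is Biotype.CDS

    def test_matches_brute_force_overlap_enumeration(self):
        """Oracle: enumerate overlaps directly and take the highest-priority
        biotype by the documented order."""
        from regvar.annotation import BIOTYPE_PRIORITY

        gene = _gene_with_overlaps()
        index = build_gene_index([gene])
        rng = np.random.default_rng(1)
        for pos in rng.integers(1, 7000, size=200):
            v = Variant("chr1", int(pos), "A", "G")
            hits = [bt for iv, bt in gene.biotype_segments
                    if iv.start <= v.pos0 < iv.end]
            expected = Biotype.INTERGENIC
            for bt in BIOTYPE_PRIORITY:
                if bt in hits:
                    expected = bt
                    break
            assert assign_biotype(v, index) is expected


def _mini_schema():
    return FeatureSchema([
        FeatureSpec("cons", FeatureGroup.CONSERVATION, "continuous",
                    aggregation=Aggregation.VALUE, source="cons"),
        FeatureSpec("tfbs_max", FeatureGroup.FUNCTIONAL_GENOMICS,
                    "continuous", aggregation=Aggregation.MAX, source="tfbs"),
        FeatureSpec("open_chromatin", FeatureGroup.FUNCTIONAL_GENOMICS,
                    "binary", aggregation=Aggregation.OR, source="dnase"),
        FeatureSpec("evidence_n", FeatureGroup.ENHANCER_GENE, "discrete",
                    aggregation=Aggregation.COUNT, source="regions"),
        FeatureSpec("histone", FeatureGroup.FUNCTIONAL_GENOMICS,
                    "continuous", aggregation=Aggregation.MEDIAN,
                    source="histone"),
        FeatureSpec("is_transition", FeatureGroup.SEQUENCE, "binary",
                    aggregation=Aggregation.COMPUTED),
        FeatureSpec("is_transversion", FeatureGroup.SEQUENCE, "binary",
                    aggregation=Aggregation.COMPUTED),
        FeatureSpec("is_indel", FeatureGroup.SEQUENCE, "binary",
                    aggregation=Aggregation.COMPUTED),
    ])


def _track(records):
    t = IntervalTrack()
    for start, end, *vals in records:
        t.add(GenomicInterval("chr1", start, end), tuple(vals))
    return t


def _mini_annotator():
    return Annotator(_mini_schema(), {
        "cons": _track([(100, 200, 2.5)]),
        "tfbs": _track([(100, 300, 0.4), (150, 250, 0.9)]),
        "dnase": _track([(400, 500, 1.0)]),
        "regions": _track([(100, 300), (150, 250), (600, 700)]),
        "histone": _track([(100, 200, 1.0), (100, 200, 3.0), (100, 200, 2.0)]),
    })


class TestAnnotator:
    def test_missing_track_is_a_config_error_up_front(self):
        with pytest.raises(AnnotationConfigError, match="cons"):
            Annotator(_mini_schema(), {})

    def test_uncovered_position_gets_missing_values_except_type(self):
        x = _mini_annotator().annotate(Variant("chr1", 1000, "A", "G"))
        assert x[5] == 1.0 and x[6] == 0.0 and x[7] == 0.0
        assert np.all(x[:5] == 0.0)

    def test_max_rule_for_overlapping_continuous(self):
        x = _mini_annotator().annotate(Variant("chr1", 181, "A", "G"))
        assert x[1] == 0.9  # max of 0.4 and 0.9

    def test_exhaustive_overlap_scan_matches_max_rule(self):
        annotator = _mini_annotator()
        track = annotator.tracks["tfbs"]
        for pos in range(90, 310):
            x = annotator.annotate(Variant("chr1", pos + 1, "A", "G"))
            vals = [v[0] for v in track.query("chr1", pos)]
            assert x[1] == (max(vals) if vals else 0.0)

    def test_or_count_and_median_aggregations(self):
        annotator = _mini_annotator()
        x = annotator.annotate(Variant("chr1", 181, "A", "G"))
        assert x[0] == 2.5          # single-valued track
        assert x[2] == 0.0          # no dnase overlap
        assert x[3] == 2.0          # two overlapping region records
        assert x[4] == 2.0          # median of 1, 3, 2
        x2 = annotator.annotate(Variant("chr1", 450, "C", "G"))
        assert x2[2] == 1.0

    def test_annotation_is_pure(self):
        annotator = _mini_annotator()
        v = Variant("chr1", 181, "A", "G")
        assert np.array_equal(annotator.annotate(v), annotator.annotate(v))

    def test_vector_order_matches_schema(self):
        annotator = _mini_annotator()
        x = annotator.annotate(Variant("chr1", 181, "C", "A"))
        by_name = dict(zip(annotator.schema.names, x))
        assert by_name["is_transversion"] == 1.0
        assert by_name["tfbs_max"] == 0.9
        assert list(by_name) == annotator.schema.names


def test_default_schema_has_41_unique_features():
    schema = default_schema()
    assert len(schema) == 41
    assert len(set(schema.names)) == 41
    groups = {spec.group for spec in schema}
    assert groups == set(FeatureGroup)


def test_schema_yaml_round_trip(tmp_path):
    schema = default_schema()
    path = tmp_path / "schema.yaml"
    schema.to_yaml(path)
    back = FeatureSchema.from_yaml(path)
    assert back.names == schema.names
    assert [f.aggregation for f in back] == [f.aggregation for f in schema]
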