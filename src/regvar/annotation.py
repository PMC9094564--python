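"""Turn a variant into the fixed-length feature vector the classifier uses.

The feature compendium is configurable: a :class:`FeatureSchema` lists the
feature names, their group (sequence / conservation / functional genomics /
enhancer-gene association), dtype, missing value and aggregation rule, plus
the name of the source track.  The default schema has 41 features mirroring
the families a regulatory-variant classifier typically draws on: sequence
conservation scores, aggregated chromatin-state counts across cell types,
median histone fold-change signals, TFBS and DNase overlaps, CpG context,
variant type, and regulatory-region/target-gene overlaps.

Missing-value policy: absence of evidence is encoded as 0 for every feature
family (signal, conservation, binary overlap); the value is recorded per
feature in the schema so it is auditable.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core_io import (
    Biotype,
    Gene,
    IntervalTrack,
    Variant,
    VariantType,
)


class FeatureGroup(str, enum.Enum):
    SEQUENCE = "sequence"
    CONSERVATION = "conservation"
    FUNCTIONAL_GENOMICS = "functional_genomics"
    ENHANCER_GENE = "enhancer_gene_association"


class Aggregation(str, enum.Enum):
    """How multiple overlapping track records collapse to one value."""

    MAX = "max"          # continuous: maximum across overlaps
    OR = "or"            # binary: 1 if any overlap
    COUNT = "count"      # discrete: number of overlaps
    VALUE = "value"      # single-valued track; max if several overlap
    MEDIAN = "median"    # median of overlapping values (cell-type stacks)
    COMPUTED = "computed"  # derived from the variant itself


#: Roadmap-style 18-state chromatin model.
CHROMATIN_STATES: tuple[str, ...] = (
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "ZNF_Rpts",
    "Het", "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    group: FeatureGroup
    dtype: str  # binary | discrete | continuous
    missing_value: float = 0.0
    aggregation: Aggregation = Aggregation.VALUE
    source: str | None = None  # track key; None for computed features


@dataclass
class FeatureSchema:
    """Ordered, immutable-for-a-model's-lifetime list of features."""

    features: list[FeatureSpec]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        self._index = {name: i for i, name in enumerate(names)}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def index(self, name: str) -> int:
        return self._index[name]

    def missing_values(self) -> np.ndarray:
        return np.array([f.missing_value for f in self.features])

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {
                "name": f.name,
                "group": f.group.value,
                "dtype": f.dtype,
                "missing_value": f.missing_value,
                "aggregation": f.aggregation.value,
                "source": f.source,
            }
            for f in self.features
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            [
                FeatureSpec(
                    name=d["name"],
                    group=FeatureGroup(d["group"]),
                    dtype=d["dtype"],
                    missing_value=float(d.get("missing_value", 0.0)),
                    aggregation=Aggregation(d.get("aggregation", "value")),
                    source=d.get("source"),
                )
                for d in payload
            ]
        )


def default_schema() -> FeatureSchema:
    """The shipped 41-feature schema.

    Sequence (5), conservation (7), functional genomics (25: 18 chromatin
    state counts + 3 histone medians + 4 TFBS/DNase), enhancer-gene (4).
    """
    f: list[FeatureSpec] = []
    seq = FeatureGroup.SEQUENCE
    cons = FeatureGroup.CONSERVATION
    fg = FeatureGroup.FUNCTIONAL_GENOMICS
    eg = FeatureGroup.ENHANCER_GENE

    f.append(FeatureSpec("cpg_dinucleotide", seq, "binary",
                         aggregation=Aggregation.OR, source="cpg_dinucleotide"))
    f.append(FeatureSpec("cpg_island", seq, "binary",
                         aggregation=Aggregation.OR, source="cpg_island"))
    for vt in ("transition", "transversion", "indel"):
        f.append(FeatureSpec(f"is_{vt}", seq, "binary",
                             aggregation=Aggregation.COMPUTED))

    for name in ("phylop_vertebrate", "phylop_primate",
                 "phastcons_vertebrate", "phastcons_primate",
                 "gerp_score", "cdts"):
        f.append(FeatureSpec(name, cons, "continuous",
                             aggregation=Aggregation.VALUE, source=name))
    f.append(FeatureSpec("gerp_element", cons, "binary",
                         aggregation=Aggregation.OR, source="gerp_element"))

    for state in CHROMATIN_STATES:
        f.append(FeatureSpec(f"state_{state}", fg, "discrete",
                             aggregation=Aggregation.VALUE,
                             source=f"state_{state}"))
    for mark in ("h3k4me1", "h3k4me3", "h3k27ac"):
        f.append(FeatureSpec(f"{mark}_median", fg, "continuous",
                             aggregation=Aggregation.MEDIAN,
                             source=f"{mark}_median"))
    f.append(FeatureSpec("tfbs_conserved", fg, "binary",
                         aggregation=Aggregation.OR, source="tfbs_conserved"))
    f.append(FeatureSpec("tfbs_cluster_max_score", fg, "continuous",
                         aggregation=Aggregation.MAX,
                         source="tfbs_cluster"))
    f.append(FeatureSpec("jaspar_tfbs", fg, "binary",
                         aggregation=Aggregation.OR, source="jaspar_tfbs"))
    f.append(FeatureSpec("dnase_cluster", fg, "binary",
                         aggregation=Aggregation.OR, source="dnase_cluster"))

    f.append(FeatureSpec("enhancer_db_region", eg, "binary",
                         aggregation=Aggregation.OR, source="enhancer_db"))
    f.append(FeatureSpec("regulatory_evidence_count", eg, "discrete",
                         aggregation=Aggregation.COUNT,
                         source="merged_regulatory"))
    f.append(FeatureSpec("promoter_overlap", eg, "binary",
                         aggregation=Aggregation.OR, source="promoters"))
    f.append(FeatureSpec("utr_overlap", eg, "binary",
                         aggregation=Aggregation.OR, source="utrs"))

    schema = FeatureSchema(f)
    assert len(schema) == 41
    return schema


def aggregate_chromatin_states(
    per_cell_type_states: Mapping[str, str],
    state_alphabet: Sequence[str] = CHROMATIN_STATES,
) -> np.ndarray:
    """Count, per state, how many cell types carry that state at a position.

    Cell types with no call contribute to no state; the counts therefore sum
    to the number of cell types with a call.
    """
    index = {s: i for i, s in enumerate(state_alphabet)}
    counts = np.zeros(len(state_alphabet), dtype=int)
    for cell_type, state in per_cell_type_states.items():
        if state not in index:
            raise ValueError(
                f"state {state!r} (cell type {cell_type}) not in alphabet"
            )
        counts[index[state]] += 1
    return counts


def median_signal(values: Sequence[float], missing_value: float = 0.0) -> float:
    """Median across cell types; the empty stack maps to the missing value."""
    values = list(values)
    if not values:
        return missing_value
    return float(statistics.median(values))


#: Most-constrained interpretation wins when segments overlap.
BIOTYPE_PRIORITY: tuple[Biotype, ...] = (
    Biotype.CDS,
    Biotype.SPLICE_SITE,
    Biotype.UTR,
    Biotype.PROMOTER,
    Biotype.EXON_NONCODING,
    Biotype.INTRON,
)


def build_gene_index(genes: Iterable[Gene]) -> IntervalTrack:
    """Index every gene biotype segment for point lookup."""
    track = IntervalTrack()
    for gene in genes:
        for interval, biotype in gene.biotype_segments:
            track.add(interval, (biotype, gene.gene_id))
    return track


def assign_biotype(variant: Variant, gene_index: IntervalTrack) -> Biotype:
    """Single biotype per variant by fixed priority; no overlap → intergenic."""
    hits = {bt for bt, _gid in gene_index.query(variant.contig, variant.pos0)}
    for biotype in BIOTYPE_PRIORITY:
        if biotype in hits:
            return biotype
    return Biotype.INTERGENIC


class AnnotationConfigError(ValueError):
    pass


class Annotator:
    """Resolves every schema feature against a compendium of tracks.

    Configuration errors (a schema feature whose source track is absent)
    surface at construction, before any variant is processed.  Annotation is
    pure: identical (variant, compendium) pairs give identical vectors.
    """

    def __init__(self, schema: FeatureSchema,
                 tracks: Mapping[str, IntervalTrack]) -> None:
        self.schema = schema
        self.tracks = dict(tracks)
        for spec in schema:
            if spec.aggregation is Aggregation.COMPUTED:
                if spec.name not in (
                    "is_transition", "is_transversion", "is_indel"
                ):
                    raise AnnotationConfigError(
                        f"no rule to compute feature {spec.name!r}"
                    )
            elif spec.source not in self.tracks:
                raise AnnotationConfigError(
                    f"feature {spec.name!r} needs track {spec.source!r}, "
                    "which is not in the compendium"
                )

    def annotate(self, variant: Variant) -> np.ndarray:
        return self.annotate_position(
            variant.contig, variant.pos0, variant.variant_type
        )

    def annotate_position(self, contig: str, pos0: int,
                          variant_type: VariantType) -> np.ndarray:
        out = self.schema.missing_values().astype(float)
        for i, spec in enumerate(self.schema):
            agg = spec.aggregation
            if agg is Aggregation.COMPUTED:
                out[i] = float(spec.name == f"is_{variant_type.value}")
                continue
            hits = self.tracks[spec.source].query(contig, pos0)
            if agg is Aggregation.COUNT:
                out[i] = float(len(hits))
                continue
            if not hits:
                continue
            if agg is Aggregation.OR:
                out[i] = 1.0
            elif agg in (Aggregation.MAX, Aggregation.VALUE):
                out[i] = max(float(v[0]) for v in hits)
            elif agg is Aggregation.MEDIAN:
                out[i] = median_signal(
                    [float(v[0]) for v in hits], spec.missing_value
                )
        return out

    def annotate_all(self, variants: Sequence[Variant]) -> np.ndarray:
        return np.array([self.annotate(v) for v in variants])


def write_annotation_tsv(variants: Sequence[Variant], X: np.ndarray,
                         schema: FeatureSchema, path: str | Path) -> None:
    import pandas as pd

    frame = pd.DataFrame(X, columns=schema.names)
    frame.insert(0, "contig", [v.contig for v in variants])
    frame.insert(1, "pos", [v.pos for v in variants])
    frame.insert(2, "ref", [v.ref for v in variants])
    frame.insert(3, "alt", [v.alt for v in variants])
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
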