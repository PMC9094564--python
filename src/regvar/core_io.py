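"""Genomic primitives and readers/writers for the formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (BED convention).  VCF
positions are 1-based and kept 1-based on the :class:`Variant` record, as in
the file; the 0-based point position of an SNV is ``variant.pos - 1``.
Contig names are matched with the ``chr`` prefix stripped but written back
with whatever prefix the input carried.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
_PURINES = frozenset("AG")


class VariantType(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INDEL = "indel"


class Label(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class Biotype(str, enum.Enum):
    """Genomic-feature class a variant falls in, per a gene annotation."""

    CDS = "CDS"
    SPLICE_SITE = "splice_site"
    UTR = "UTR"
    PROMOTER = "promoter"
    EXON_NONCODING = "exon_noncoding"
    INTRON = "intron"
    INTERGENIC = "intergenic"


def normalize_contig(contig: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix for cross-dialect matching."""
    if contig[:3].lower() == "chr":
        return contig[3:]
    return contig


class VcfParseError(ValueError):
    pass


class InvalidVariantError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a contig, 0-based."""

    contig: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos0: int) -> bool:
        return (
            normalize_contig(contig) == normalize_contig(self.contig)
            and self.start <= pos0 < self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            normalize_contig(self.contig) == normalize_contig(other.contig)
            and self.start < other.end
            and other.start < self.end
        )


def classify_variant_type(ref: str, alt: str) -> VariantType:
    """Classify a substitution as transition, transversion or indel.

    An indel is any allele pair of unequal length; a transition swaps within
    the purines (A/G) or within the pyrimidines (C/T); everything else is a
    transversion.
    """
    if not ref or not alt:
        raise InvalidVariantError("alleles must be non-empty")
    if ref == alt:
        raise InvalidVariantError(f"ref and alt are identical ({ref!r})")
    if not set(ref) <= _NUCLEOTIDES or not set(alt) <= _NUCLEOTIDES:
        raise InvalidVariantError(f"non-ACGT allele in ({ref!r}, {alt!r})")
    if len(ref) != len(alt):
        return VariantType.INDEL
    if len(ref) > 1:
        # equal-length multi-nucleotide substitution: treat as indel-like
        return VariantType.INDEL
    if (ref in _PURINES) == (alt in _PURINES):
        return VariantType.TRANSITION
    return VariantType.TRANSVERSION


@dataclass
class Variant:
    """A single (record, alt allele) pair; ``pos`` is 1-based as in VCF."""

    contig: str
    pos: int
    ref: str
    alt: str
    label: Label = Label.UNKNOWN
    variant_type: VariantType | None = None

    def __post_init__(self) -> None:
        if self.variant_type is None:
            self.variant_type = classify_variant_type(self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based point position of the reference base."""
        return self.pos - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (normalize_contig(self.contig), self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.variant_type is not VariantType.INDEL


@dataclass(frozen=True)
class CytoBand:
    interval: GenomicInterval
    band_name: str


@dataclass
class Gene:
    gene_id: str
    symbol: str
    tss: GenomicInterval
    biotype_segments: list[tuple[GenomicInterval, Biotype]] = field(
        default_factory=list
    )


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a VCF (plain or bgzip) into a list of variants.

    Multi-allelic records are split: one :class:`Variant` per alternate
    allele, scored independently downstream.  Records whose REF contains a
    non-ACGT character are skipped with a warning.  Labels are ``unknown``.
    """
    out: list[Variant] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf, start=1):
            ref = (rec.ref or "").upper()
            if not set(ref) <= _NUCLEOTIDES or not ref:
                logger.warning(
                    "skipping record %d (%s:%s): non-ACGT ref %r",
                    i, rec.contig, rec.pos, rec.ref,
                )
                continue
            for alt in rec.alts or ():
                alt = alt.upper()
                if not set(alt) <= _NUCLEOTIDES:
                    logger.warning(
                        "skipping alt %r of record %d (%s:%s)",
                        alt, i, rec.contig, rec.pos,
                    )
                    continue
                out.append(Variant(rec.contig, rec.pos, ref, alt))
    return out


def write_vcf(variants: Iterable[Variant], path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write variants to a minimal VCFv4.2 file (uncompressed)."""
    variants = list(variants)
    contigs = dict.fromkeys(v.contig for v in variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=LABEL,Number=1,Type=String,'
                 'Description="Training class label">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"LABEL={v.label.value}\n"
            )


class IntervalTrack:
    """Queryable set of (possibly overlapping) scored genomic intervals.

    Point and interval lookups return hits in input order; boundaries follow
    the half-open contract (a query at ``start`` hits, a query at ``end``
    does not).
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._records: list[tuple[GenomicInterval, tuple]] = []

    @property
    def n_records(self) -> int:
        return len(self._records)

    def add(self, interval: GenomicInterval, values: tuple = ()) -> None:
        idx = len(self._records)
        self._records.append((interval, values))
        contig = normalize_contig(interval.contig)
        self._trees.setdefault(contig, IntervalTree()).addi(
            interval.start, interval.end, idx
        )

    def _hits(self, contig: str, start: int, end: int) -> list[int]:
        tree = self._trees.get(normalize_contig(contig))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def query(self, contig: str, pos0: int) -> list[tuple]:
        """Values of all intervals covering the 0-based position."""
        return [self._records[i][1] for i in self._hits(contig, pos0, pos0 + 1)]

    def query_interval(self, contig: str, start: int, end: int) -> list[tuple]:
        return [self._records[i][1] for i in self._hits(contig, start, end)]

    def query_records(self, contig: str, start: int,
                      end: int) -> list[tuple[GenomicInterval, tuple]]:
        return [self._records[i] for i in self._hits(contig, start, end)]

    def __iter__(self):
        return iter(self._records)


def read_interval_table(path: str | Path,
                        value_columns: Sequence[int] | None = None,
                        ) -> IntervalTrack:
    """Read a BED3+ style tab-delimited interval file into a track.

    The first three columns are contig / start / end (0-based half-open).
    ``value_columns`` selects further 0-based column indices parsed as floats
    (default: every column past the third, as float where possible, else
    string).  Rows must be start-sorted within each contig; overlaps are
    allowed.
    """
    track = IntervalTrack()
    last_start: dict[str, int] = {}
    opener = pysam.BGZFile if str(path).endswith(".gz") else open
    with opener(str(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if isinstance(raw, bytes):
                raw = raw.decode()
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            key = normalize_contig(contig)
            if last_start.get(key, -1) > start:
                raise ValueError(
                    f"{path}:{lineno}: unsorted input (start {start} after "
                    f"{last_start[key]} on {contig})"
                )
            last_start[key] = start
            if value_columns is not None:
                values = tuple(float(parts[c]) for c in value_columns)
            else:
                values = tuple(_maybe_float(p) for p in parts[3:])
            track.add(GenomicInterval(contig, start, end), values)
    return track


def _maybe_float(text: str):
    try:
        return float(text)
    except ValueError:
        return text


def write_interval_table(track: IntervalTrack, path: str | Path) -> None:
    records = sorted(
        track, key=lambda r: (normalize_contig(r[0].contig), r[0].start)
    )
    with open(path, "w") as fh:
        for interval, values in records:
            cols = [interval.contig, str(interval.start), str(interval.end)]
            cols += [_fmt(v) for v in values]
            fh.write("\t".join(cols) + "\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def read_bands_bed(path: str | Path) -> list[CytoBand]:
    """Read cytogenetic bands from BED4 (contig, start, end, band name)."""
    bands: list[CytoBand] = []
    for interval, values in read_interval_table(path):
        name = str(values[0]) if values else f"{interval.contig}:{interval.start}"
        bands.append(CytoBand(interval, name))
    _check_bands(bands)
    return bands


def _check_bands(bands: Sequence[CytoBand]) -> None:
    by_contig: dict[str, list[CytoBand]] = {}
    for b in bands:
        by_contig.setdefault(normalize_contig(b.interval.contig), []).append(b)
    for contig, group in by_contig.items():
        group = sorted(group, key=lambda b: b.interval.start)
        for a, b in zip(group, group[1:]):
            if a.interval.end > b.interval.start:
                raise ValueError(
                    f"overlapping bands {a.band_name} and {b.band_name} "
                    f"on {contig}"
                )


_GENE_COLUMNS = ["gene_id", "symbol", "contig", "start", "end", "biotype"]


def write_gene_table(genes: Iterable[Gene], path: str | Path) -> None:
    """Write genes as a TSV of biotype segments plus a TSS row per gene."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.tss.contig}\t{g.tss.start}\t"
                f"{g.tss.end}\tTSS\n"
            )
            for interval, biotype in g.biotype_segments:
                fh.write(
                    f"{g.gene_id}\t{g.symbol}\t{interval.contig}\t"
                    f"{interval.start}\t{interval.end}\t{biotype.value}\n"
                )


def read_gene_table(path: str | Path) -> list[Gene]:
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise ValueError(f"unexpected gene table header in {path}")
        for line in fh:
            gene_id, symbol, contig, start, end, biotype = (
                line.rstrip("\n").split("\t")
            )
            interval = GenomicInterval(contig, int(start), int(end))
            if biotype == "TSS":
                genes[gene_id] = Gene(gene_id, symbol, interval)
            else:
                genes[gene_id].biotype_segments.append(
                    (interval, Biotype(biotype))
                )
    return list(genes.values())
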