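"""Genomic interval arithmetic, annotation parsing and overlap indexing.

All internal coordinates are 0-based, half-open (``[start, end)``); GTF and
GFF input/output converts between the on-disk 1-based closed convention and
the internal one at the boundary, so interval arithmetic in the rest of the
package never has to think about it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: biotypes treated as "other RNA species" during read prefiltering
OTHER_RNA_BIOTYPES = frozenset({"rRNA", "tRNA", "snoRNA", "miRNA", "snRNA"})

KNOWN_BIOTYPES = frozenset(
    {"protein_coding", "rRNA", "tRNA", "snoRNA", "miRNA", "snRNA", "lncRNA", "other"}
)


class GtfParseError(ValueError):
    """Raised for malformed annotation records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript; ``rank`` counts 1.. in 5'->3' transcript order."""

    interval: GenomicInterval
    rank: int = 1

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("exon rank must be >= 1")


@dataclass
class TranscriptModel:
    """A transcript as an ordered exon chain with provenance and scores.

    Exons are stored sorted by genomic start and must be non-overlapping and
    share one chromosome and strand.  ``cds`` optionally carries coding
    intervals (used for read-region classification of protein-coding genes).
    """

    id: str
    gene_id: str
    exons: list[Exon]
    strand: str = "."
    source_samples: set[str] = field(default_factory=set)
    novelty: str = "unassigned"
    coding_potential: Optional[float] = None
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        ivs = sorted(e.interval for e in self.exons)
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom != b.chrom:
                raise ValueError(f"transcript {self.id}: exons on multiple chromosomes")
            if b.start < a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        self.exons = [Exon(iv, rank=i + 1) for i, iv in enumerate(ivs)]
        if self.strand == "-":  # rank is 5'->3' on the transcript strand
            self.exons = [
                Exon(e.interval, rank=len(ivs) - i) for i, e in enumerate(self.exons)
            ]
        if self.novelty not in ("known", "novel", "unassigned"):
            raise ValueError(f"bad novelty label {self.novelty!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def length_nt(self) -> int:
        return sum(e.interval.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.exons[0].interval.start,
            self.exons[-1].interval.end,
            self.strand,
        )

    @property
    def exon_intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.exons]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Splice junctions as (intron_start, intron_end) pairs; the merge key."""
        ivs = self.exon_intervals
        return tuple((a.end, b.start) for a, b in zip(ivs, ivs[1:]))


@dataclass
class GenomeAnnotation:
    """A collection of transcripts with per-transcript biotype labels."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    biotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for tid in self.transcripts:
            self.biotype.setdefault(tid, "other")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def add(self, tx: TranscriptModel, biotype: str = "other") -> None:
        if tx.id in self.transcripts:
            existing = self.transcripts[tx.id]
            if existing.chrom != tx.chrom:
                raise ValueError(
                    f"transcript id {tx.id} reused on different chromosomes"
                )
        self.transcripts[tx.id] = tx
        self.biotype[tx.id] = biotype if biotype in KNOWN_BIOTYPES else "other"

    def lncrna_loci(self) -> dict[tuple[str, str, str], list[GenomicInterval]]:
        """Merged exonic intervals of annotated lncRNAs, keyed by (gene, chrom, strand)."""
        per_gene: dict[tuple[str, str, str], list[GenomicInterval]] = {}
        for tx in self:
            if self.biotype.get(tx.id) != "lncRNA":
                continue
            key = (tx.gene_id, tx.chrom, tx.strand)
            per_gene.setdefault(key, []).extend(tx.exon_intervals)
        return {k: merge_intervals(v) for k, v in per_gene.items()}


# ---------------------------------------------------------------------------
# interval utilities


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals (single chromosome assumed per call site per key)."""
    ivs = sorted(intervals, key=lambda x: (x.chrom, x.start, x.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def overlap_bases(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> int:
    """Total number of bases shared by two interval sets (after merging each)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    for x in ma:
        for y in mb:
            total += x.overlap_len(y)
    return total


# ---------------------------------------------------------------------------
# GTF / GFF parsing

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]*)")

_BIOTYPE_KEYS = ("transcript_biotype", "gene_biotype", "transcript_type", "gene_type")


def _parse_attributes(attr_field: str, dialect: str, line_number: int) -> dict[str, str]:
    if dialect == "gtf":
        attrs = dict(_GTF_ATTR_RE.findall(attr_field))
    else:  # gff3-lite: key=value pairs; Parent doubles as transcript_id
        attrs = {k: v.strip() for k, v in _GFF_ATTR_RE.findall(attr_field)}
        if "transcript_id" not in attrs and "Parent" in attrs:
            attrs["transcript_id"] = attrs["Parent"]
        if "gene_id" not in attrs and "Parent" in attrs:
            attrs["gene_id"] = attrs["Parent"]
    if not attrs:
        raise GtfParseError(f"malformed attribute string {attr_field!r}", line_number)
    return attrs


def parse_gtf(path: str, dialect: str = "gtf") -> GenomeAnnotation:
    """Parse exon and CDS records of a GTF (or GFF3-like) file.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Records missing ``gene_id``/``transcript_id``, or with ``end < start``,
    raise :class:`GtfParseError` naming the offending line.
    """
    if dialect not in ("gtf", "gff3-lite"):
        raise ValueError(f"unknown dialect {dialect!r}")
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    biotype_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"non-integer coordinates {start_s},{end_s}", lineno)
            if end1 < start1:
                raise GtfParseError(f"end {end1} < start {start1}", lineno)
            attrs = _parse_attributes(attr, dialect, lineno)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                raise GtfParseError("record lacks gene_id/transcript_id", lineno)
            iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in STRANDS else ".")
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
            gene_of[tid] = gid
            for key in _BIOTYPE_KEYS:
                if key in attrs:
                    biotype_of.setdefault(tid, attrs[key])
                    break
    ann = GenomeAnnotation()
    for tid, ivs in exons.items():
        strand = ivs[0].strand
        try:
            tx = TranscriptModel(
                id=tid,
                gene_id=gene_of[tid],
                exons=[Exon(iv) for iv in ivs],
                strand=strand,
                cds=sorted(cds.get(tid, [])),
            )
        except ValueError as exc:
            raise GtfParseError(str(exc)) from exc
        ann.add(tx, biotype_of.get(tid, "other"))
    return ann


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write exon (and CDS) records, converting back to 1-based closed coordinates."""
    with open(path, "w") as fh:
        for tx in annotation:
            bt = annotation.biotype.get(tx.id, "other")
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}"; '
                f'gene_biotype "{bt}";'
            )
            extra = ""
            if tx.novelty != "unassigned":
                extra += f' novelty "{tx.novelty}";'
            if tx.coding_potential is not None:
                extra += f' coding_potential "{tx.coding_potential:.4f}";'
            for e in tx.exons:
                iv = e.interval
                fh.write(
                    f"{iv.chrom}\tflora\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}{extra}\n"
                )
            for iv in tx.cds:
                fh.write(
                    f"{iv.chrom}\tflora\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# overlap index


class AnnotationIndex:
    """Overlap-queryable index over exon intervals of selected biotypes.

    Query results are (transcript_id, Exon) pairs; each indexed interval maps
    back to exactly one such pair.
    """

    def __init__(self, annotation: GenomeAnnotation, keep_biotypes: set[str]):
        if not len(annotation):
            raise ValueError("annotation is empty")
        if not keep_biotypes:
            raise ValueError("keep_biotypes must be non-empty")
        self.annotation = annotation
        self.keep_biotypes = frozenset(keep_biotypes)
        self._trees: dict[str, IntervalTree] = {}
        for tx in annotation:
            if annotation.biotype.get(tx.id, "other") not in self.keep_biotypes:
                continue
            for exon in tx.exons:
                iv = exon.interval
                self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, (tx.id, exon)
                )

    def query(
        self, interval: GenomicInterval, same_strand: bool = False
    ) -> list[tuple[str, Exon]]:
        """All indexed exons overlapping ``interval`` by >= 1 bp."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(interval.start, interval.end)]
        if same_strand and interval.strand != ".":
            hits = [
                (tid, exon)
                for tid, exon in hits
                if self.annotation.transcripts[tid].strand in (interval.strand, ".")
            ]
        return sorted(hits, key=lambda h: (h[0], h[1].interval.start))


def build_index(
    annotation: GenomeAnnotation, keep_biotypes: Optional[set[str]] = None
) -> AnnotationIndex:
    """Build the overlap index every other stage queries."""
    if keep_biotypes is None:
        keep_biotypes = set(KNOWN_BIOTYPES)
    return AnnotationIndex(annotation, keep_biotypes)


# ---------------------------------------------------------------------------
# novelty classification


def locus_overlap(
    tx: TranscriptModel, annotation: GenomeAnnotation, min_frac: float = 0.5
) -> str:
    """Label a transcript ``known`` or ``novel`` against annotated lncRNA loci.

    A transcript is *known* when its exonic bases overlap the merged exonic
    bases of any single annotated lncRNA locus on a compatible strand by at
    least ``min_frac`` of the transcript's own exonic length.  Unstranded
    transcripts ('.') are compared against both strands.
    """
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    tx_len = tx.length_nt
    for (gene, chrom, strand), merged in annotation.lncrna_loci().items():
        if chrom != tx.chrom:
            continue
        if tx.strand != "." and strand != "." and strand != tx.strand:
            continue
        shared = overlap_bases(tx.exon_intervals, merged)
        if shared >= min_frac * tx_len:
            return "known"
    return "novel"
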