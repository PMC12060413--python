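"""Transcript models, locus construction and RTE-usage classification.

Transcripts are read from GTF (via gffutils), grouped into loci either by
annotated gene id or by strand-agnostic genomic overlap — the latter is the
default because antisense transcripts initiated inside a retroelement must
fall into the same locus as the sense gene they disrupt — and each
transcript is classified against merged repeat elements as exonised,
RTE-initiated, RTE-terminated and/or antisense-initiated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from .intervals import GenomicInterval, ValidationError
from .repeats import MergedElement


class ParseError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """An exon-resolved transcript on one chromosome and strand.

    ``tss`` is the first transcribed base (0-based) in transcription
    direction and ``tes`` the last: on "+" tss = first exon start, on "-"
    tss = last exon end - 1.
    """

    transcript_id: str
    exons: list[GenomicInterval]
    strand: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(f"{self.transcript_id}: exons on multiple chroms")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    @property
    def tes(self) -> int:
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start


@dataclass
class Locus:
    """A group of transcripts sharing a genomic locus."""

    locus_id: str
    interval: GenomicInterval
    transcripts: list[str]
    strand: str = "."
    canonical_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.canonical_ids) - set(self.transcripts)
        if missing:
            raise ValidationError(f"canonical ids not members: {sorted(missing)}")


@dataclass
class RTEUsage:
    """How a transcript uses one merged repeat element."""

    transcript_id: str
    element: MergedElement
    relations: frozenset[str]
    overlap_bp: int


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF into :class:`TranscriptModel` objects.

    GENCODE and generic ``key "value";`` attribute dialects are accepted.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, set[str]] = {}
    genes: dict[str, str | None] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if "transcript_id" not in feat.attributes:
            raise ParseError(f"exon at {feat.seqid}:{feat.start} lacks transcript_id")
        tid = feat.attributes["transcript_id"][0]
        if tid not in exons:
            exons[tid] = []
            strands[tid] = set()
            genes[tid] = None
            order.append(tid)
        exons[tid].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
        strands[tid].add(feat.strand)
        if "gene_id" in feat.attributes:
            genes[tid] = feat.attributes["gene_id"][0]
    models: list[TranscriptModel] = []
    for tid in order:
        if len(strands[tid]) > 1:
            raise ValidationError(f"{tid}: exons on mixed strands")
        strand = next(iter(strands[tid]))
        models.append(
            TranscriptModel(transcript_id=tid, exons=exons[tid], strand=strand, gene_id=genes[tid])
        )
    return models


def build_loci(
    transcripts: Sequence[TranscriptModel],
    mode: str = "by_overlap",
    canonical_ids: Iterable[str] = (),
) -> tuple[list[Locus], dict[str, str]]:
    """Partition transcripts into loci.

    ``by_overlap`` clusters transcripts whose genomic spans overlap by at
    least 1 bp, regardless of strand, with single linkage; ``by_gene_id``
    groups by the annotated gene id. Locus ids are ``chrom:start-end`` of
    the cluster span, so they are deterministic and comparable across runs
    on the same annotation.

    Returns the loci and a transcript_id -> locus_id map (a partition).
    """
    canonical = set(canonical_ids)
    clusters: list[list[TranscriptModel]] = []
    if mode == "by_overlap":
        for chrom in sorted({t.chrom for t in transcripts}):
            chrom_txs = sorted(
                (t for t in transcripts if t.chrom == chrom),
                key=lambda t: (t.span.start, t.span.end),
            )
            current: list[TranscriptModel] = []
            current_end = -1
            for t in chrom_txs:
                if current and t.span.start < current_end:
                    current.append(t)
                    current_end = max(current_end, t.span.end)
                else:
                    if current:
                        clusters.append(current)
                    current = [t]
                    current_end = t.span.end
            if current:
                clusters.append(current)
    elif mode == "by_gene_id":
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            key = t.gene_id if t.gene_id is not None else t.transcript_id
            by_gene.setdefault(key, []).append(t)
        clusters = [sorted(v, key=lambda t: (t.span.start, t.span.end)) for v in by_gene.values()]
    else:
        raise ValidationError(f"mode must be by_overlap or by_gene_id, got {mode!r}")

    loci: list[Locus] = []
    tx2locus: dict[str, str] = {}
    for cluster in clusters:
        start = min(t.span.start for t in cluster)
        end = max(t.span.end for t in cluster)
        chrom = cluster[0].chrom
        members = [t.transcript_id for t in cluster]
        canon = [tid for tid in members if tid in canonical]
        strands = {t.strand for t in (cluster if not canon else [t for t in cluster if t.transcript_id in canon])}
        locus = Locus(
            locus_id=f"{chrom}:{start}-{end}",
            interval=GenomicInterval(chrom, start, end, "."),
            transcripts=members,
            strand=strands.pop() if len(strands) == 1 else ".",
            canonical_ids=canon,
        )
        loci.append(locus)
        for tid in members:
            tx2locus[tid] = locus.locus_id
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start))
    return loci, tx2locus


def index_elements(elements: Sequence[MergedElement]) -> dict[str, IntervalTree]:
    """Build per-chromosome interval trees over merged elements."""
    trees: dict[str, IntervalTree] = {}
    for e in elements:
        trees.setdefault(e.interval.chrom, IntervalTree()).addi(
            e.interval.start, e.interval.end, e
        )
    return trees


def classify_rte_usage(
    transcript: TranscriptModel,
    elements: Sequence[MergedElement] | Mapping[str, IntervalTree],
    min_overlap: int = 10,
    host_strand: str | None = None,
) -> list[RTEUsage]:
    """Classify how a transcript uses overlapping repeat elements.

    For each element overlapping the transcript span: ``exonised`` when any
    exon overlaps it by >= ``min_overlap`` bp; ``initiated_in_rte`` /
    ``terminated_in_rte`` when the TSS/TES falls inside the element;
    ``antisense_initiated`` when RTE-initiated on the strand opposite
    ``host_strand``. Elements with no qualifying relation are omitted.
    """
    if min_overlap <= 0:
        raise ValidationError(f"min_overlap must be positive, got {min_overlap}")
    trees = elements if isinstance(elements, Mapping) else index_elements(elements)
    tree = trees.get(transcript.chrom)
    if tree is None:
        return []
    span = transcript.span
    usages: list[RTEUsage] = []
    hits = sorted(tree.overlap(span.start, span.end), key=lambda h: (h.begin, h.end))
    for hit in hits:
        element: MergedElement = hit.data
        relations: set[str] = set()
        exon_overlap = sum(e.overlap_bp(element.interval) for e in transcript.exons)
        if any(e.overlap_bp(element.interval) >= min_overlap for e in transcript.exons):
            relations.add("exonised")
        if element.interval.contains_point(transcript.tss):
            relations.add("initiated_in_rte")
            if host_strand is not None and transcript.strand != host_strand:
                relations.add("antisense_initiated")
        if element.interval.contains_point(transcript.tes):
            relations.add("terminated_in_rte")
        if relations:
            usages.append(
                RTEUsage(
                    transcript_id=transcript.transcript_id,
                    element=element,
                    relations=frozenset(relations),
                    overlap_bp=exon_overlap,
                )
            )
    return usages


def write_locus_map(tx2locus: Mapping[str, str], path) -> None:
    """Write the transcript -> locus partition as two-column TSV."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tlocus_id\n")
        for tid in sorted(tx2locus):
            fh.write(f"{tid}\t{tx2locus[tid]}\n")
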