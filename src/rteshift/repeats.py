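"""RepeatMasker annotation handling.

Reads the whitespace-delimited RepeatMasker ``.out`` dialect, merges
fragmented annotations — in particular the separately annotated LTR and
internal ("-int") portions of ERV proviruses — into element-level features,
and maps repeat families onto the coarse retrotransposon subgroups used for
enrichment analysis (Alu, MIR, L1, L2, ERV/LTR, SVA, other).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, ValidationError


class ParseError(ValueError):
    """Raised for malformed input rows; carries the 1-based line number."""


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation row in internal coordinates."""

    interval: GenomicInterval
    family: str
    repeat_class: str
    rm_id: int
    divergence_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ValidationError("family must be non-empty")
        if self.divergence_pct is not None and not (0.0 <= self.divergence_pct <= 100.0):
            raise ValidationError(f"divergence_pct out of [0,100]: {self.divergence_pct}")


@dataclass
class MergedElement:
    """An element-level feature spanning one or more merged fragments.

    For ERV proviruses the canonical ``name`` is the internal family with its
    ``-int`` suffix stripped (e.g. LTR2B + HERVE-int + LTR2B -> "HERVE") and
    ``is_provirus`` is set; otherwise the shared family name is used.
    """

    interval: GenomicInterval
    members: list[RepeatFeature] = field(default_factory=list)
    name: str = ""
    is_provirus: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("MergedElement requires at least one member")
        chroms = {m.interval.chrom for m in self.members}
        strands = {m.interval.strand for m in self.members}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError("members must share chrom and strand")
        starts = [m.interval.start for m in self.members]
        if starts != sorted(starts):
            raise ValidationError("members must be sorted by start")
        if self.interval.start != min(m.interval.start for m in self.members):
            raise ValidationError("element start must equal min member start")
        if self.interval.end != max(m.interval.end for m in self.members):
            raise ValidationError("element end must equal max member end")


#: Default family-name-prefix -> subgroup map, applied longest-prefix wins.
DEFAULT_SUBGROUP_PREFIXES: dict[str, str] = {
    "Alu": "Alu",
    "FLAM": "Alu",
    "FRAM": "Alu",
    "MIR": "MIR",
    "L1": "L1",
    "HAL1": "L1",
    "L2": "L2",
    "SVA": "SVA",
}

_LTR_CLASS_RE = re.compile(r"(^|/)(LTR|ERV)", re.IGNORECASE)


def is_internal_family(family: str, repeat_class: str = "") -> bool:
    """Heuristic for ERV internal (coding) fragments per Dfam naming practice."""
    if family.endswith("-int"):
        return True
    return "ERV" in repeat_class.upper() and not family.upper().startswith("LTR")


def is_ltr_family(family: str, repeat_class: str = "") -> bool:
    """Whether a fragment is an LTR (promoter-bearing terminus), not internal."""
    if is_internal_family(family, repeat_class):
        return False
    return bool(_LTR_CLASS_RE.search(repeat_class)) or family.upper().startswith("LTR")


def assign_subgroup(
    family: str,
    repeat_class: str = "",
    mapping: Mapping[str, str] | None = None,
) -> str:
    """Map a repeat family to its subgroup label.

    Name prefixes decide first (Alu*, MIR*, L1*, L2*, SVA*); any LTR/ERV
    class string falls into "ERV/LTR"; everything else is "other".
    Unknown families are labelled, never rejected.
    """
    prefixes = dict(DEFAULT_SUBGROUP_PREFIXES if mapping is None else mapping)
    for prefix in sorted(prefixes, key=len, reverse=True):
        if family.startswith(prefix):
            return prefixes[prefix]
    if _LTR_CLASS_RE.search(repeat_class) or family.upper().startswith("LTR"):
        return "ERV/LTR"
    return "other"


_RM_HEADER = (
    "   SW   perc perc perc  query     position in query     matching"
    "          repeat           position in repeat\n"
    "score   div. del. ins.  sequence  begin  end    (left)  repeat"
    "           class/family   begin  end    (left)  ID\n"
    "\n"
)


def parse_repeatmasker(path) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` file into :class:`RepeatFeature` rows.

    The standard 3-line header is skipped; rows are whitespace-delimited with
    1-based inclusive query coordinates and complement strand written "C".
    Rows are returned in file order.
    """
    features: list[RepeatFeature] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(("SW", "score")) or raw.startswith(("   SW", "score")):
            continue  # header lines
        fields = line.split()
        if len(fields) < 15:
            raise ParseError(f"line {lineno}: expected >= 15 columns, got {len(fields)}")
        try:
            div = float(fields[1])
            start1 = int(fields[5])
            end1 = int(fields[6])
            rm_id = int(fields[14])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
        strand = fields[8]
        if strand == "C":
            strand = "-"
        elif strand != "+":
            raise ParseError(f"line {lineno}: strand must be '+' or 'C', got {strand!r}")
        start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if start0 >= end0:
            raise ValidationError(f"line {lineno}: start >= end after conversion")
        features.append(
            RepeatFeature(
                interval=GenomicInterval(fields[4], start0, end0, strand),
                family=fields[9],
                repeat_class=fields[10],
                rm_id=rm_id,
                divergence_pct=div,
            )
        )
    return features


def write_repeatmasker(features: Iterable[RepeatFeature], path) -> None:
    """Write features back in the ``.out`` dialect (round-trips through
    :func:`parse_repeatmasker` on interval, strand, family and rm_id)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for f in features:
            iv = f.interval
            strand = "C" if iv.strand == "-" else "+"
            div = 0.0 if f.divergence_pct is None else f.divergence_pct
            fh.write(
                f" 1000 {div:5.1f}  0.0  0.0  {iv.chrom} {iv.start + 1} {iv.end} "
                f"(0) {strand} {f.family} {f.repeat_class} 1 {len(iv)} (0) {f.rm_id}\n"
            )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _mergeable_by_adjacency(a: RepeatFeature, b: RepeatFeature) -> bool:
    if a.family == b.family:
        return True
    a_int = is_internal_family(a.family, a.repeat_class)
    b_int = is_internal_family(b.family, b.repeat_class)
    if a_int and is_ltr_family(b.family, b.repeat_class):
        return True
    if b_int and is_ltr_family(a.family, a.repeat_class):
        return True
    return False


def merge_elements(
    features: Sequence[RepeatFeature],
    max_gap: int = 100,
    use_rm_id: bool = True,
    use_adjacency: bool = True,
) -> list[MergedElement]:
    """Merge fragmented repeat annotations into element-level features.

    Two fragments join the same element when (a) they share the RepeatMasker
    fragment-linking ID (no distance limit), or (b) they lie on the same
    strand within ``max_gap`` bp and either share a family name or form an
    LTR/internal pair (internal fragment flanked by an LTR). Merging is
    transitive; every input feature ends up in exactly one element.
    """
    if max_gap < 0:
        raise ValidationError(f"max_gap must be non-negative, got {max_gap}")
    feats = list(features)
    n = len(feats)
    uf = _UnionFind(n)

    if use_rm_id:
        by_id: dict[tuple[str, str, int], list[int]] = {}
        for i, f in enumerate(feats):
            by_id.setdefault((f.interval.chrom, f.interval.strand, f.rm_id), []).append(i)
        for group in by_id.values():
            for j in group[1:]:
                uf.union(group[0], j)

    if use_adjacency:
        by_cs: dict[tuple[str, str], list[int]] = {}
        for i, f in enumerate(feats):
            by_cs.setdefault((f.interval.chrom, f.interval.strand), []).append(i)
        for idxs in by_cs.values():
            idxs.sort(key=lambda i: (feats[i].interval.start, feats[i].interval.end))
            for pos, i in enumerate(idxs):
                for j in idxs[pos + 1:]:
                    gap = feats[i].interval.gap_to(feats[j].interval)
                    if feats[j].interval.start - feats[i].interval.end > max_gap:
                        break
                    if gap <= max_gap and _mergeable_by_adjacency(feats[i], feats[j]):
                        uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    elements: list[MergedElement] = []
    for idxs in groups.values():
        members = sorted(
            (feats[i] for i in idxs),
            key=lambda f: (f.interval.start, f.interval.end, f.family),
        )
        internals = [m for m in members if is_internal_family(m.family, m.repeat_class)]
        has_ltr = any(is_ltr_family(m.family, m.repeat_class) for m in members)
        is_provirus = bool(internals) and has_ltr
        if internals:
            name = re.sub(r"-int$", "", internals[0].family)
        else:
            name = members[0].family
        iv0 = members[0].interval
        elements.append(
            MergedElement(
                interval=GenomicInterval(
                    iv0.chrom,
                    min(m.interval.start for m in members),
                    max(m.interval.end for m in members),
                    iv0.strand,
                ),
                members=members,
                name=name,
                is_provirus=is_provirus,
            )
        )
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return elements


def write_bed6(elements: Iterable[MergedElement], path) -> None:
    """Export merged elements as BED6 (name = element name, score = member count)."""
    with open(path, "w") as fh:
        for e in elements:
            iv = e.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.name}\t{len(e.members)}\t{iv.strand}\n"
            )
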