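"""Genomic data model, GTF/GFF3/BED I/O, deduplication, locus clustering.

The atom of every downstream analysis is the :class:`Transcript` — an ordered
chain of exons on one chromosome and strand.  Coordinates are 0-based
half-open internally; GTF/GFF3 files are 1-based inclusive and are converted
at the I/O boundary, BED files are 0-based half-open as on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

from .errors import ParseError, StructuralViolation
from ._util import fetch_seq, revcomp

log = logging.getLogger(__name__)

DEFAULT_MAX_INTRON = 100_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome.

    strand is '+', '-' or '.' (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise StructuralViolation(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise StructuralViolation(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """An ordered, non-overlapping exon chain; the unit of all AS analyses."""

    id: str
    exons: tuple[GenomicInterval, ...]
    source_tag: str = ""

    def __post_init__(self):
        if not self.exons:
            raise StructuralViolation(f"transcript {self.id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chrom, strand = exons[0].chrom, exons[0].strand
        for e in exons:
            if e.chrom != chrom or e.strand != strand:
                raise StructuralViolation(
                    f"transcript {self.id}: exons on mixed chromosome/strand"
                )
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start <= prev.end:
                raise StructuralViolation(
                    f"transcript {self.id}: exons overlap or are adjacent "
                    f"({prev.start}-{prev.end} vs {nxt.start}-{nxt.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def extent(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, prev.end, nxt.start, self.strand)
            for prev, nxt in zip(self.exons, self.exons[1:])
        )

    @property
    def internal_exons(self) -> tuple[GenomicInterval, ...]:
        return self.exons[1:-1]

    @property
    def structure_key(self) -> tuple:
        """Hashable identity: (chrom, strand, exact exon chain)."""
        return (
            self.chrom,
            self.strand,
            tuple((e.start, e.end) for e in self.exons),
        )


@dataclass(frozen=True)
class Locus:
    """A single-linkage cluster of transcripts connected by exonic overlap."""

    id: str
    transcripts: tuple[Transcript, ...]
    span: GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    """A reference-annotation transcript structure with its spliced cDNA."""

    id: str
    transcript: Transcript
    cdna: str

    def __post_init__(self):
        expected = sum(e.length for e in self.transcript.exons)
        if len(self.cdna) != expected:
            raise StructuralViolation(
                f"gene model {self.id}: cDNA length {len(self.cdna)} != "
                f"summed exon length {expected}"
            )


def get_introns(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons of ``t`` (empty for single-exon)."""
    return list(t.introns)


def get_internal_exons(t: Transcript) -> list[GenomicInterval]:
    """All exons except the first and last; empty for <=2-exon transcripts."""
    return list(t.internal_exons)


def spliced_sequence(t: Transcript, genome) -> str:
    """Mature (spliced) sequence of a transcript in transcript orientation."""
    seq = "".join(fetch_seq(genome, t.chrom, e.start, e.end) for e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


def unique_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Deduplicate intervals by (chrom, strand, start, end), input order kept."""
    seen: set[tuple] = set()
    out = []
    for iv in intervals:
        key = (iv.chrom, iv.strand, iv.start, iv.end)
        if key not in seen:
            seen.add(key)
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# GTF / GFF3 / BED I/O
# ---------------------------------------------------------------------------

def _prescan(path) -> None:
    """Cheap line-level validation so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise ParseError(
                    f"{path}: line {lineno}: bad coordinate range {start}-{end}"
                )


def parse_gtf(path, source_tag: Optional[str] = None) -> list[Transcript]:
    """Read exon features from a GTF (or GFF3) file into Transcripts.

    1-based inclusive coordinates on disk are converted to 0-based half-open.
    Non-exon features are ignored.  Transcript grouping comes from the
    ``transcript_id`` attribute (GTF) or ``Parent`` (GFF3).
    """
    _prescan(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=False,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils internal failures
        raise ParseError(f"{path}: {exc}") from exc

    grouped: dict[str, list[GenomicInterval]] = {}
    sources: dict[str, str] = {}
    for f in db.features_of_type("exon"):
        attrs = f.attributes
        if "transcript_id" in attrs:
            tid = attrs["transcript_id"][0]
        elif "Parent" in attrs:
            tid = attrs["Parent"][0]
        else:
            raise ParseError(
                f"{path}: exon at {f.seqid}:{f.start}-{f.end} has no "
                "transcript_id/Parent attribute"
            )
        strand = f.strand if f.strand in ("+", "-") else "."
        grouped.setdefault(tid, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, strand)
        )
        sources.setdefault(tid, f.source or "")

    transcripts = []
    for tid, exons in grouped.items():
        tag = source_tag if source_tag is not None else sources[tid]
        t = Transcript(tid, tuple(exons), source_tag=tag)
        for intron in t.introns:
            if intron.length <= 3:
                log.warning(
                    "transcript %s has a suspiciously short intron (%d bp) at "
                    "%s:%d-%d", tid, intron.length, intron.chrom,
                    intron.start, intron.end,
                )
        transcripts.append(t)
    transcripts.sort(key=lambda t: (t.chrom, t.extent.start, t.id))
    return transcripts


def write_gtf(transcripts: Sequence[Transcript], path,
              gene_ids: Optional[Mapping[str, str]] = None) -> None:
    """Write transcripts as exon features (1-based inclusive GTF).

    Ordering is deterministic: (chrom, extent start, transcript id).
    ``gene_ids`` optionally maps transcript id -> gene_id attribute; by
    default the transcript id doubles as the gene id.
    """
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.extent.start, t.id))
    with open(path, "w") as fh:
        fh.write("##gtf: exon features written by asland\n")
        for t in ordered:
            gid = gene_ids.get(t.id, t.id) if gene_ids else t.id
            src = t.source_tag or "asland"
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{src}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f'{t.strand}\t.\tgene_id "{gid}"; transcript_id "{t.id}";\n'
                )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open on disk)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 fields")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tte{i}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Deduplication, clustering, filtering
# ---------------------------------------------------------------------------

def merge_identical(transcripts: Sequence[Transcript]) -> list[Transcript]:
    """Collapse transcripts with byte-identical exon chains.

    Transcripts sharing an intron chain but differing in terminal exon
    extents are *kept distinct*.  Provenance tags of merged duplicates are
    concatenated (comma separated, deduplicated, input order).
    """
    merged: dict[tuple, Transcript] = {}
    tags: dict[tuple, list[str]] = {}
    for t in transcripts:
        key = t.structure_key
        if key not in merged:
            merged[key] = t
            tags[key] = [t.source_tag] if t.source_tag else []
        else:
            if t.source_tag and t.source_tag not in tags[key]:
                tags[key].append(t.source_tag)
    out = []
    for key, t in merged.items():
        tag = ",".join(tags[key])
        out.append(replace(t, source_tag=tag) if tag != t.source_tag else t)
    return out


def _strands_compatible(a: str, b: str, policy: str) -> bool:
    if policy == "lenient":
        return True
    return a == b or a == "." or b == "."


def _exons_overlap(a: Transcript, b: Transcript) -> bool:
    """Any >=1 bp exon-exon overlap, by two-pointer merge."""
    i = j = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        if ea[i].start < eb[j].end and eb[j].start < ea[i].end:
            return True
        if ea[i].end <= eb[j].end:
            i += 1
        else:
            j += 1
    return False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_loci(transcripts: Sequence[Transcript],
                 strand_policy: str = "strict") -> list[Locus]:
    """Single-linkage clustering by same-strand exonic overlap.

    Two transcripts share a locus iff they are connected by a chain of
    pairwise >=1 bp exon-exon overlaps on compatible strands.  Under the
    default ``strict`` policy only identical strands connect, except that
    unknown-strand transcripts may join either strand's cluster; ``lenient``
    ignores strand entirely.  Loci are ordered by (chrom, span start).
    """
    by_chrom: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda t: (t.extent.start, t.id))
        # coarse pass: components of the span-overlap chain bound the search
        components: list[list[int]] = []
        current: list[int] = []
        reach = -1
        for idx, t in enumerate(group):
            if current and t.extent.start >= reach:
                components.append(current)
                current = []
                reach = -1
            current.append(idx)
            reach = max(reach, t.extent.end)
        if current:
            components.append(current)

        for comp in components:
            uf = _UnionFind(len(comp))
            for i in range(len(comp)):
                for j in range(i + 1, len(comp)):
                    a, b = group[comp[i]], group[comp[j]]
                    if _strands_compatible(a.strand, b.strand, strand_policy) \
                            and a.extent.overlaps(b.extent) \
                            and _exons_overlap(a, b):
                        uf.union(i, j)
            clusters: dict[int, list[Transcript]] = {}
            for i, idx in enumerate(comp):
                clusters.setdefault(uf.find(i), []).append(group[idx])
            for members in clusters.values():
                start = min(t.extent.start for t in members)
                end = max(t.extent.end for t in members)
                strands = {t.strand for t in members} - {"."}
                strand = strands.pop() if len(strands) == 1 else "."
                loci.append(
                    Locus("", tuple(members), GenomicInterval(chrom, start, end, strand))
                )

    loci.sort(key=lambda l: (l.span.chrom, l.span.start, l.span.end))
    return [
        Locus(f"locus_{i + 1:06d}", l.transcripts, l.span)
        for i, l in enumerate(loci)
    ]


def filter_long_introns(
    transcripts: Sequence[Transcript],
    max_intron: int = DEFAULT_MAX_INTRON,
) -> tuple[list[Transcript], list[Transcript]]:
    """Remove transcripts with ANY intron strictly longer than ``max_intron``.

    Guards against chimeric mappings; an intron of exactly ``max_intron`` bp
    is kept (strictly-greater rule).  Returns (kept, removed).
    """
    if max_intron <= 0:
        raise ValueError("max_intron must be positive")
    kept, removed = [], []
    for t in transcripts:
        if any(i.length > max_intron for i in t.introns):
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed
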