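"""Pairwise splice-chain comparison and AS event classification.

Every intron contributes a donor site (its 5' boundary in transcript
orientation) and an acceptor site (its 3' boundary).  Comparing the splice
chains of two isoforms over the intersection of their genomic extents and
splitting at shared sites yields *variant regions* — maximal stretches where
the chains disagree.  Each region is classified into one of the four basic
event types (intron retention, exon skipping, alternative donor, alternative
acceptor) or, when it combines more than one basic variation, as Complex
("Others").
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .genomic_model import GenomicInterval, Locus, Transcript
from ._util import pct

DONOR = "D"
ACCEPTOR = "A"

BASIC_TYPES = ("AltA", "AltD", "ExonS", "IntronR")
EVENT_TYPES = BASIC_TYPES + ("Complex",)
#: presentation name used in summary tables for the complex class
OTHERS_LABEL = "Others"


class Site(NamedTuple):
    pos: int
    kind: str  # DONOR or ACCEPTOR


@dataclass(frozen=True)
class SpliceChain:
    """The ordered donor/acceptor sites of one transcript.

    ``sites`` are in transcript orientation (5'->3'), alternating donor,
    acceptor, donor, ...; on the minus strand this runs right-to-left along
    the genome.
    """

    transcript_id: str
    chrom: str
    strand: str
    extent: GenomicInterval
    sites: tuple[Site, ...]

    @property
    def sites_genomic(self) -> tuple[Site, ...]:
        return self.sites if self.strand != "-" else tuple(reversed(self.sites))

    def exon_boundaries(self) -> list[int]:
        """Sorted genomic positions at which exonic/intronic state flips."""
        bounds = [self.extent.start]
        bounds.extend(sorted(s.pos for s in self.sites))
        bounds.append(self.extent.end)
        return bounds

    def exonic_at(self, pos: int) -> bool:
        """Whether ``pos`` (a point between bases) lies in a closed exon."""
        bounds = self.exon_boundaries()
        if pos < bounds[0] or pos > bounds[-1]:
            return False
        # segments alternate exon, intron, exon, ... between boundaries;
        # boundary points themselves count as exonic.
        idx = bisect_right(bounds, pos) - 1
        if idx >= len(bounds) - 1:
            return True  # pos == extent end
        if pos == bounds[idx]:
            return True
        return idx % 2 == 0


@dataclass(frozen=True)
class VariantRegion:
    """A maximal run of non-shared splice sites between two common anchors."""

    chrom: str
    strand: str
    left_anchor: int
    right_anchor: int
    sites_a: tuple[Site, ...]  # genomic ascending, strictly inside anchors
    sites_b: tuple[Site, ...]


@dataclass(frozen=True)
class ASEvent:
    locus_id: str
    tx_a: str
    tx_b: str
    region: VariantRegion
    as_type: str
    code: str
    fragment_size: Optional[int]
    #: transcript retaining the intron, for IntronR events
    retained_by: Optional[str] = None

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def strand(self) -> str:
        return self.region.strand


def splice_chain(t: Transcript) -> SpliceChain:
    """Extract the donor/acceptor chain of a transcript.

    Plus strand: each intron (s, e) yields (s, donor) and (e, acceptor).
    Minus strand the kinds are swapped so the donor is always the 5' end of
    the intron in transcript orientation.
    """
    sites: list[Site] = []
    if t.strand == "-":
        for intron in reversed(t.introns):
            sites.append(Site(intron.end, DONOR))
            sites.append(Site(intron.start, ACCEPTOR))
    else:
        for intron in t.introns:
            sites.append(Site(intron.start, DONOR))
            sites.append(Site(intron.end, ACCEPTOR))
    return SpliceChain(t.id, t.chrom, t.strand, t.extent, tuple(sites))


def variant_regions(a: SpliceChain, b: SpliceChain) -> list[VariantRegion]:
    """Decompose the difference between two chains into variant regions.

    Comparison is restricted to the intersection of the two extents.  Shared
    (position, kind) sites are anchors; the intersection boundaries also act
    as anchors provided *both* transcripts are exonic there.  Runs of
    non-shared sites that are not bounded by anchors on both sides are
    dropped (the variation is not resolvable inside the shared window).
    Identical chains (or disjoint extents) yield an empty list.
    """
    if a.chrom != b.chrom:
        return []
    lo = max(a.extent.start, b.extent.start)
    hi = min(a.extent.end, b.extent.end)
    if lo >= hi:
        return []
    strand = a.strand if a.strand != "." else b.strand

    in_a = [s for s in a.sites_genomic if lo < s.pos < hi]
    in_b = [s for s in b.sites_genomic if lo < s.pos < hi]
    common = set(in_a) & set(in_b)

    anchors: list[int] = []
    if a.exonic_at(lo) and b.exonic_at(lo):
        anchors.append(lo)
    anchors.extend(sorted(s.pos for s in common))
    if a.exonic_at(hi) and b.exonic_at(hi):
        anchors.append(hi)

    regions: list[VariantRegion] = []
    for left, right in zip(anchors, anchors[1:]):
        sa = tuple(s for s in in_a if left < s.pos < right and s not in common)
        sb = tuple(s for s in in_b if left < s.pos < right and s not in common)
        if sa or sb:
            regions.append(VariantRegion(a.chrom, strand, left, right, sa, sb))
    return regions


def _oriented(sites: Sequence[Site], strand: str) -> tuple[Site, ...]:
    return tuple(reversed(sites)) if strand == "-" else tuple(sites)


def classify_variant(r: VariantRegion) -> str:
    """Match a variant region against the four basic templates.

    IntronR: one side carries exactly one complete intron (donor then
    acceptor in transcript orientation), the other side is spliced-site free
    — i.e. the empty side's transcript retains the intron.  ExonS: one side
    carries exactly one included internal exon (acceptor then donor).  AltD /
    AltA: one site per side, both donors / both acceptors at different
    positions, the opposite boundary being a shared anchor.  Anything else is
    Complex.
    """
    sa = _oriented(r.sites_a, r.strand)
    sb = _oriented(r.sites_b, r.strand)
    if not sa or not sb:
        full, _empty = (sa, sb) if sa else (sb, sa)
        if len(full) == 2:
            kinds = (full[0].kind, full[1].kind)
            if kinds == (DONOR, ACCEPTOR):
                return "IntronR"
            if kinds == (ACCEPTOR, DONOR):
                return "ExonS"
        return "Complex"
    if len(sa) == 1 and len(sb) == 1 and sa[0].pos != sb[0].pos:
        if sa[0].kind == sb[0].kind == DONOR:
            return "AltD"
        if sa[0].kind == sb[0].kind == ACCEPTOR:
            return "AltA"
    return "Complex"


def fragment_size(r: VariantRegion, as_type: str) -> Optional[int]:
    """Type-specific size of the DNA fragment involved in the event.

    IntronR -> retained-intron length, ExonS -> skipped-exon length,
    AltD/AltA -> distance between the alternative sites; Complex -> None.
    """
    if as_type in ("IntronR", "ExonS"):
        full = r.sites_a if r.sites_a else r.sites_b
        return abs(full[1].pos - full[0].pos)
    if as_type in ("AltD", "AltA"):
        return abs(r.sites_a[0].pos - r.sites_b[0].pos)
    return None


def event_code(r: VariantRegion) -> str:
    """Canonical code: relative-coordinate site lists, smaller side first.

    The code is identical for structurally identical events regardless of
    which transcript is "a" and which is "b".
    """
    def side(sites: Sequence[Site]) -> str:
        if not sites:
            return "-"
        return "+".join(f"{s.kind}{s.pos - r.left_anchor}" for s in sites)

    return "|".join(sorted((side(r.sites_a), side(r.sites_b))))


def retained_intron(event: ASEvent) -> GenomicInterval:
    """The genomic interval of the retained intron of an IntronR event."""
    if event.as_type != "IntronR":
        raise ValueError("not an IntronR event")
    r = event.region
    full = r.sites_a if r.sites_a else r.sites_b
    lo, hi = sorted(s.pos for s in full)
    return GenomicInterval(r.chrom, lo, hi, r.strand)


def events_between(a: SpliceChain, b: SpliceChain,
                   locus_id: str = "") -> list[ASEvent]:
    """All classified events between one ordered pair of chains."""
    events = []
    for region in variant_regions(a, b):
        as_type = classify_variant(region)
        retained = None
        if as_type == "IntronR":
            retained = b.transcript_id if region.sites_a else a.transcript_id
        events.append(
            ASEvent(
                locus_id=locus_id,
                tx_a=a.transcript_id,
                tx_b=b.transcript_id,
                region=region,
                as_type=as_type,
                code=event_code(region),
                fragment_size=fragment_size(region, as_type),
                retained_by=retained,
            )
        )
    return events


def enumerate_events(locus: Locus, strand_policy: str = "strict") -> list[ASEvent]:
    """Compare all unordered transcript pairs of a locus.

    Each variant region of each pair yields one event (pair-level counting:
    one pair can contribute several events).  Events are sorted by
    (pair, left anchor); a locus of identical-structure transcripts yields
    an empty list.
    """
    chains = {t.id: splice_chain(t) for t in locus.transcripts}
    ordered = sorted(chains)
    events: list[ASEvent] = []
    for ia, ib in combinations(ordered, 2):
        a, b = chains[ia], chains[ib]
        if strand_policy != "lenient" and "." not in (a.strand, b.strand) \
                and a.strand != b.strand:
            continue
        events.extend(events_between(a, b, locus_id=locus.id))
    events.sort(key=lambda e: (e.tx_a, e.tx_b, e.region.left_anchor))
    return events


def count_unique_events(events: Iterable[ASEvent]) -> int:
    """Deduplicated event count: unique (locus, left anchor, code)."""
    return len({(e.locus_id, e.region.left_anchor, e.code) for e in events})


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

_SUMMARY_COLS = ("AltA", "AltD", "ExonS", "IntronR", OTHERS_LABEL)


def summarize_counts(counts: Mapping[str, int]) -> dict:
    """One summary row: per-type counts, one-decimal percentages, total."""
    total = sum(int(counts.get(c, 0)) for c in _SUMMARY_COLS)
    row: dict = {}
    for c in _SUMMARY_COLS:
        n = int(counts.get(c, 0))
        row[c] = n
        row[f"{c} (%)"] = pct(n, total) if total else 0.0
    row["Total"] = total
    return row


def event_summary(events: Sequence[ASEvent], by: Optional[str] = None) -> pd.DataFrame:
    """Event counts and percentages per type, optionally per chromosome.

    Percentages are computed within each row; a Total row is always present
    and the per-type counts sum to the total.
    """
    def tally(evs: Iterable[ASEvent]) -> dict[str, int]:
        counts = {c: 0 for c in _SUMMARY_COLS}
        for e in evs:
            label = OTHERS_LABEL if e.as_type == "Complex" else e.as_type
            counts[label] += 1
        return counts

    rows: dict[str, dict] = {}
    if by == "chromosome":
        by_chrom: dict[str, list[ASEvent]] = {}
        for e in events:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom in sorted(by_chrom):
            rows[chrom] = summarize_counts(tally(by_chrom[chrom]))
    rows["Total"] = summarize_counts(tally(events))
    return pd.DataFrame.from_dict(rows, orient="index")
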