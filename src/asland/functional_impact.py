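"""ORF prediction, domain-impact categorization, AS rate, TE overlap.

The functional layer consumes classified events plus optional side tables:
a transcript -> protein-domain-set annotation (precomputed, e.g. from a
Pfam scan) and a transposable-element interval track.  Domain comparison of
the two isoforms of each event pair yields four mutually exclusive impact
categories; the "loss or change" aggregate is the share of events whose
isoforms differ in annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .as_classifier import ASEvent
from .genomic_model import (
    GeneModel, GenomicInterval, Transcript, spliced_sequence, unique_intervals,
)
from ._util import pct

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

IMPACT_CATEGORIES = ("both_none", "same", "one_lost", "different")


@dataclass(frozen=True)
class ORFRecord:
    """One predicted open reading frame in transcript coordinates."""

    transcript_id: str
    frame: int
    start: int  # 0-based, inclusive
    end: int    # exclusive; includes the stop codon when has_stop
    has_start: bool
    has_stop: bool
    longest: bool = False

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - (1 if self.has_stop else 0)

    @property
    def full_length(self) -> bool:
        return self.has_start and self.has_stop


@dataclass(frozen=True)
class ImpactReport:
    """Counts and percentages of the four domain-impact categories."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float]
    loss_or_change: int
    loss_or_change_pct: float

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts), "total": self.total,
            "percentages": dict(self.percentages),
            "loss_or_change": self.loss_or_change,
            "loss_or_change_pct": self.loss_or_change_pct,
        }


@dataclass(frozen=True)
class ASRateReport:
    as_gene_models: int
    expressed_gene_models: int
    all_gene_models: int
    rate_expressed: float
    rate_all: float

    @classmethod
    def from_counts(cls, as_models: int, expressed: int,
                    all_models: int) -> "ASRateReport":
        if all_models == 0:
            raise ValueError("no gene models")
        rate_all = pct(as_models, all_models)
        rate_expressed = pct(as_models, expressed) if expressed else 0.0
        return cls(as_models, expressed, all_models, rate_expressed, rate_all)

    def to_dict(self) -> dict:
        return {
            "as_gene_models": self.as_gene_models,
            "expressed_gene_models": self.expressed_gene_models,
            "all_gene_models": self.all_gene_models,
            "rate_expressed": self.rate_expressed,
            "rate_all": self.rate_all,
        }


@dataclass(frozen=True)
class TEOverlapReport:
    retained_total: int
    retained_with_te: int
    fraction_retained: float
    all_total: int
    all_with_te: int
    fraction_all: float

    @classmethod
    def from_counts(cls, retained_with_te: int, retained_total: int,
                    all_with_te: int, all_total: int) -> "TEOverlapReport":
        return cls(
            retained_total, retained_with_te,
            pct(retained_with_te, retained_total) if retained_total else 0.0,
            all_total, all_with_te,
            pct(all_with_te, all_total) if all_total else 0.0,
        )

    def to_dict(self) -> dict:
        return {
            "retained_total": self.retained_total,
            "retained_with_te": self.retained_with_te,
            "fraction_retained": self.fraction_retained,
            "all_total": self.all_total,
            "all_with_te": self.all_with_te,
            "fraction_all": self.fraction_all,
        }


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def find_orfs(seq: str, min_aa: int = 30,
              transcript_id: str = "") -> list[ORFRecord]:
    """Predict ORFs in the three forward frames of a spliced transcript.

    Transcripts are orientation-resolved upstream, so only forward frames
    are scanned.  Within each frame, stop codons delimit segments; an ORF
    runs from the first ATG of a segment to its stop (complete) or to the
    sequence end (start only).  The leading segment of a frame, when it has
    no ATG, is itself reported (stop only, or neither flag when the frame
    has no stop at all).  Records below ``min_aa`` residues are dropped; the
    longest surviving ORF (ties: smallest start) is flagged.
    """
    seq = seq.upper()
    records: list[ORFRecord] = []
    for frame in range(3):
        atg: Optional[int] = None
        leading = True
        seg_start = frame
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if atg is None and codon == "ATG":
                atg = i
            if codon in STOP_CODONS:
                end = i + 3
                if atg is not None:
                    records.append(ORFRecord(transcript_id, frame, atg, end, True, True))
                elif leading and end - seg_start >= 3:
                    records.append(ORFRecord(transcript_id, frame, seg_start, end, False, True))
                atg = None
                leading = False
                seg_start = end
            i += 3
        # open tail (no terminating stop)
        if atg is not None and i - atg >= 3:
            records.append(ORFRecord(transcript_id, frame, atg, i, True, False))
        elif leading and i - seg_start >= 3:
            records.append(ORFRecord(transcript_id, frame, seg_start, i, False, False))

    records = [r for r in records if r.aa_length >= min_aa and r.aa_length > 0]
    if records:
        best = max(records, key=lambda r: (r.aa_length, -r.start))
        records = [
            ORFRecord(r.transcript_id, r.frame, r.start, r.end,
                      r.has_start, r.has_stop, longest=(r is best))
            for r in records
        ]
    records.sort(key=lambda r: (r.start, r.frame))
    return records


# ---------------------------------------------------------------------------
# Domain-impact categorization
# ---------------------------------------------------------------------------

def _category(da: frozenset, db: frozenset) -> str:
    if not da and not db:
        return "both_none"
    if da and db:
        return "same" if da == db else "different"
    return "one_lost"


def impact_percentages(counts: Mapping[str, int]) -> ImpactReport:
    """Percentage report from raw category counts (partition of events)."""
    total = sum(int(counts.get(c, 0)) for c in IMPACT_CATEGORIES)
    percentages = {
        c: pct(int(counts.get(c, 0)), total) if total else 0.0
        for c in IMPACT_CATEGORIES
    }
    loss = int(counts.get("one_lost", 0)) + int(counts.get("different", 0))
    return ImpactReport(
        counts={c: int(counts.get(c, 0)) for c in IMPACT_CATEGORIES},
        total=total,
        percentages=percentages,
        loss_or_change=loss,
        loss_or_change_pct=pct(loss, total) if total else 0.0,
    )


def categorize_event_domains(
    events: Sequence[ASEvent],
    domains: Mapping[str, Iterable[str]],
) -> ImpactReport:
    """Four-way domain comparison of the isoform pair of every event.

    A transcript absent from ``domains`` (or mapped to an empty set) counts
    as unannotated.  Every event falls in exactly one category, so the four
    counts partition the events.
    """
    sets = {k: frozenset(v) for k, v in domains.items()}
    counts = {c: 0 for c in IMPACT_CATEGORIES}
    for e in events:
        da = sets.get(e.tx_a, frozenset())
        db = sets.get(e.tx_b, frozenset())
        counts[_category(da, db)] += 1
    return impact_percentages(counts)


def pair_category(domains: Mapping[str, Iterable[str]],
                  tx_a: str, tx_b: str) -> str:
    sets = {k: frozenset(v) for k, v in domains.items()}
    return _category(sets.get(tx_a, frozenset()), sets.get(tx_b, frozenset()))


# ---------------------------------------------------------------------------
# Transcript -> gene-model assignment and AS rate
# ---------------------------------------------------------------------------

def _shares_block(seq: str, target: str, k: int) -> bool:
    """True iff seq and target share an exact common substring of >= k nt."""
    if len(seq) < k or len(target) < k:
        return False
    for i in range(len(seq) - k + 1):
        if seq[i:i + k] in target:
            return True
    return False


def _longest_shared(seq: str, target: str, lo: int) -> int:
    """Length of the longest exact common substring, given >= lo exists."""
    hi = min(len(seq), len(target))
    best = lo
    while lo <= hi:
        mid = (lo + hi) // 2
        kmers = {target[i:i + mid] for i in range(len(target) - mid + 1)}
        if any(seq[i:i + mid] in kmers for i in range(len(seq) - mid + 1)):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def assign_transcripts_to_gene_models(
    transcripts: Sequence[Transcript],
    models: Sequence[GeneModel],
    genome,
    min_match: int = 80,
    mode: str = "sequence",
) -> tuple[dict[str, str], set[str]]:
    """Map transcripts to annotated gene models.

    ``sequence`` mode (default): a transcript matches a model iff its
    spliced sequence shares an exact, ungapped common substring of at least
    ``min_match`` nt with the model cDNA.  Models whose genomic span
    overlaps the transcript are tried first; only if none of those match is
    the full model set scanned.  Among several matches the locus-overlapping
    model wins, then the longest shared substring, then model id.
    ``overlap`` mode is a sequence-free fallback using span overlap alone.

    Returns (transcript id -> model id, set of matched "expressed" models).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.transcript.chrom, []).append(m)

    assignment: dict[str, str] = {}
    for t in transcripts:
        span = t.extent
        local = [m for m in by_chrom.get(t.chrom, ())
                 if m.transcript.extent.overlaps(span)]
        if mode == "overlap":
            if local:
                local.sort(key=lambda m: m.id)
                assignment[t.id] = local[0].id
            continue
        seq = spliced_sequence(t, genome)
        hits: list[tuple[int, int, GeneModel]] = []  # (overlap, shared, model)
        candidates = local if local else []
        matched_local = False
        for m in local:
            if _shares_block(seq, m.cdna, min_match):
                hits.append((1, 0, m))
                matched_local = True
        if not matched_local:
            for m in (m for m in models if m not in local):
                if _shares_block(seq, m.cdna, min_match):
                    hits.append((0, 0, m))
        if not hits:
            continue
        if len(hits) > 1:
            hits = [
                (ov, _longest_shared(seq, m.cdna, min_match), m)
                for ov, _, m in hits
            ]
        hits.sort(key=lambda h: (-h[0], -h[1], h[2].id))
        assignment[t.id] = hits[0][2].id

    expressed = set(assignment.values())
    return assignment, expressed


def as_rate(
    events: Sequence[ASEvent],
    assignment: Mapping[str, str],
    models: Sequence[GeneModel],
) -> ASRateReport:
    """AS rate over expressed and over all annotated gene models.

    A model undergoes AS iff it is matched by at least one transcript that
    participates in at least one event.
    """
    event_txs = {tx for e in events for tx in (e.tx_a, e.tx_b)}
    as_models = {assignment[tx] for tx in event_txs if tx in assignment}
    expressed = set(assignment.values())
    return ASRateReport.from_counts(len(as_models), len(expressed), len(models))


# ---------------------------------------------------------------------------
# Transposable elements in introns
# ---------------------------------------------------------------------------

def te_overlap_fraction(
    retained_introns: Sequence[GenomicInterval],
    all_introns: Sequence[GenomicInterval],
    te_intervals: Sequence[GenomicInterval],
    min_intron_bp: int = 50,
) -> TEOverlapReport:
    """Fraction of introns containing a TE, for retained vs all introns.

    An intron "contains a TE" iff any TE interval overlaps it by >= 1 bp
    (strand-agnostic).  Fractions are over unique introns strictly longer
    than ``min_intron_bp``.
    """
    trees: dict[str, IntervalTree] = {}
    for te in te_intervals:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end)

    def stats(introns: Sequence[GenomicInterval]) -> tuple[int, int]:
        usable = [iv for iv in unique_intervals(introns)
                  if iv.length > min_intron_bp]
        with_te = sum(
            1 for iv in usable
            if iv.chrom in trees and trees[iv.chrom].overlap(iv.start, iv.end)
        )
        return with_te, len(usable)

    r_te, r_n = stats(retained_introns)
    a_te, a_n = stats(all_introns)
    return TEOverlapReport.from_counts(r_te, r_n, a_te, a_n)
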