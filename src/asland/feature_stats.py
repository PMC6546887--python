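"""Length distributions, splice-site dinucleotide usage, junction matrices.

Covers the descriptive layer of the pipeline: summary statistics and
right-inclusive histograms of internal-exon / intron / AS-fragment lengths,
the donor..acceptor dinucleotide usage table with a chi-square homogeneity
test between introns of AS and non-AS loci, and per-position base
probability matrices across the 5' and 3' exon-intron junctions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .as_classifier import ASEvent
from .genomic_model import GenomicInterval
from ._util import chrom_length, fetch_seq, pct, revcomp

log = logging.getLogger(__name__)

#: splice-site categories in table order; every other dinucleotide pair
#: (including N-containing boundaries) is counted under "Others"
SITE_CATEGORIES = (
    "GT..AG", "GC..AG", "GC..AT", "AT..AC", "CT..AC", "GT..AT", "Others",
)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class LengthSummary:
    """Sample statistics and a right-inclusive histogram of lengths in bp."""

    n: int
    min: Optional[int]
    max: Optional[int]
    mean: Optional[float]
    sd: Optional[float]
    bin_width: int
    histogram: dict[int, int] = field(default_factory=dict)

    @classmethod
    def empty(cls, bin_width: int = 100) -> "LengthSummary":
        return cls(0, None, None, None, None, bin_width, {})

    def to_dict(self) -> dict:
        return {
            "n": self.n, "min": self.min, "max": self.max,
            "mean": self.mean, "sd": self.sd,
        }


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    pooled_categories: tuple[str, ...]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value,
            "pooled_categories": list(self.pooled_categories),
        }


@dataclass(frozen=True)
class JunctionProfile:
    """Base-probability matrices across the two exon-intron junctions.

    ``five_prime``: columns 1-10 are the last exonic bases upstream of the
    intron, columns 11-20 the first intronic bases.  ``three_prime``:
    columns 1-10 the last intronic bases, 11-20 the first exonic bases of
    the next exon.  Rows are A/C/G/T; each covered column sums to 1.
    """

    five_prime: pd.DataFrame
    three_prime: pd.DataFrame
    n_introns: int


def _lengths(items: Iterable[Union[int, GenomicInterval]]) -> np.ndarray:
    vals = [it.length if isinstance(it, GenomicInterval) else int(it) for it in items]
    return np.asarray(vals, dtype=np.int64)


def length_summary(
    intervals: Iterable[Union[int, GenomicInterval]],
    bin_width: int = 100,
) -> LengthSummary:
    """Summarize lengths (sample mean/sd) with right-inclusive binning.

    Bin ``w`` comprises lengths in (w - bin_width, w]; e.g. with the default
    width, bin 100 holds lengths 1-100 bp.  An empty input returns the
    explicit empty sentinel.
    """
    lengths = _lengths(intervals)
    if lengths.size == 0:
        return LengthSummary.empty(bin_width)
    mean = float(lengths.mean())
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    bins = (np.ceil(lengths / bin_width) * bin_width).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)
    histogram = {int(u): int(c) for u, c in zip(uniq, counts)}
    return LengthSummary(
        n=int(lengths.size), min=int(lengths.min()), max=int(lengths.max()),
        mean=mean, sd=sd, bin_width=bin_width, histogram=histogram,
    )


def as_fragment_sizes(events: Sequence[ASEvent],
                      bin_width: int = 100) -> dict[str, LengthSummary]:
    """Per-type summaries of the DNA fragment sizes involved in AS events.

    IntronR -> retained-intron length; ExonS -> skipped-exon length;
    AltD/AltA -> distance between the two alternative sites.  Complex events
    carry no single fragment and are excluded.
    """
    per_type: dict[str, list[int]] = {t: [] for t in ("IntronR", "AltA", "AltD", "ExonS")}
    for e in events:
        if e.as_type in per_type and e.fragment_size is not None:
            per_type[e.as_type].append(e.fragment_size)
    return {t: length_summary(v, bin_width) for t, v in per_type.items()}


# ---------------------------------------------------------------------------
# Splice-site dinucleotides
# ---------------------------------------------------------------------------

def site_category(donor2: str, acceptor2: str) -> str:
    name = f"{donor2}..{acceptor2}"
    return name if name in SITE_CATEGORIES[:-1] else "Others"


def boundary_dinucleotides(
    introns: Iterable[GenomicInterval], genome
) -> list[tuple[str, str]]:
    """(donor, acceptor) dinucleotides of each intron, transcript-oriented.

    Minus-strand introns are reverse complemented so the canonical pair
    always reads (GT, AG).  Introns shorter than 4 bp are skipped with a
    warning; N-containing boundaries are returned as read and fall into the
    "Others" usage category.
    """
    out = []
    for intron in introns:
        if intron.length < 4:
            log.warning(
                "intron %s:%d-%d shorter than 4 bp; skipped",
                intron.chrom, intron.start, intron.end,
            )
            continue
        left = fetch_seq(genome, intron.chrom, intron.start, intron.start + 2)
        right = fetch_seq(genome, intron.chrom, intron.end - 2, intron.end)
        if intron.strand == "-":
            donor2, acceptor2 = revcomp(right), revcomp(left)
        else:
            donor2, acceptor2 = left, right
        out.append((donor2.upper(), acceptor2.upper()))
    return out


def usage_counts(dinucs: Iterable[tuple[str, str]]) -> dict[str, int]:
    counts = {c: 0 for c in SITE_CATEGORIES}
    for d2, a2 in dinucs:
        counts[site_category(d2, a2)] += 1
    return counts


def usage_table(counts_non_as: Mapping[str, int],
                counts_as: Mapping[str, int]) -> pd.DataFrame:
    """Usage table with Total / Non-AS / AS columns and one-decimal %.

    Row order follows :data:`SITE_CATEGORIES` plus a Total row; percentages
    are computed within each column.
    """
    non_total = sum(int(counts_non_as.get(c, 0)) for c in SITE_CATEGORIES)
    as_total = sum(int(counts_as.get(c, 0)) for c in SITE_CATEGORIES)
    grand = non_total + as_total
    rows = {}
    for c in SITE_CATEGORIES:
        n_non = int(counts_non_as.get(c, 0))
        n_as = int(counts_as.get(c, 0))
        n_tot = n_non + n_as
        rows[c] = {
            "Total": n_tot,
            "Total (%)": pct(n_tot, grand) if grand else 0.0,
            "Non-AS": n_non,
            "Non-AS (%)": pct(n_non, non_total) if non_total else 0.0,
            "AS": n_as,
            "AS (%)": pct(n_as, as_total) if as_total else 0.0,
        }
    rows["Total"] = {
        "Total": grand, "Total (%)": 100.0 if grand else 0.0,
        "Non-AS": non_total, "Non-AS (%)": 100.0 if non_total else 0.0,
        "AS": as_total, "AS (%)": 100.0 if as_total else 0.0,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def chi_square_homogeneity(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    pool_threshold: float = 5.0,
) -> ChiSquareResult:
    """Uncorrected Pearson chi-square test of homogeneity across two groups.

    Categories whose expected count falls below ``pool_threshold`` in either
    group are pooled into "Others" before testing (all-zero categories are
    dropped).  Significance threshold downstream is 0.05.
    """
    cats = [c for c in SITE_CATEGORIES
            if counts_a.get(c, 0) or counts_b.get(c, 0)]
    if not cats:
        raise ValueError("no non-empty categories to test")
    obs = np.array(
        [[int(counts_a.get(c, 0)), int(counts_b.get(c, 0))] for c in cats],
        dtype=np.float64,
    )
    if obs.sum(axis=0).min() == 0:
        raise ValueError("one group has zero usable introns")
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    expected = row_tot @ col_tot / obs.sum()

    pool_mask = (expected < pool_threshold).any(axis=1)
    pooled: list[str] = []
    if pool_mask.any():
        keep = [i for i, c in enumerate(cats) if not pool_mask[i] and c != "Others"]
        pool = [i for i, c in enumerate(cats) if pool_mask[i] or c == "Others"]
        pooled = [cats[i] for i in pool if cats[i] != "Others"]
        merged = obs[pool].sum(axis=0, keepdims=True)
        obs = np.vstack([obs[keep], merged])
    if obs.shape[0] < 2:
        raise ValueError("fewer than two categories after pooling")

    stat, p, df, _ = chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), tuple(pooled))


def splice_site_usage(
    as_introns: Sequence[GenomicInterval],
    non_as_introns: Sequence[GenomicInterval],
    genome,
) -> tuple[pd.DataFrame, ChiSquareResult]:
    """Usage table and AS vs non-AS chi-square test from intron intervals."""
    counts_as = usage_counts(boundary_dinucleotides(as_introns, genome))
    counts_non = usage_counts(boundary_dinucleotides(non_as_introns, genome))
    if sum(counts_as.values()) == 0 or sum(counts_non.values()) == 0:
        raise ValueError("a group has zero usable introns")
    table = usage_table(counts_non, counts_as)
    chi = chi_square_homogeneity(counts_non, counts_as)
    return table, chi


# ---------------------------------------------------------------------------
# Junction position-probability matrices
# ---------------------------------------------------------------------------

def _count_window(counts: np.ndarray, window: str) -> None:
    for j, base in enumerate(window):
        if base in BASES:
            counts[BASES.index(base), j] += 1


def junction_matrix(
    introns: Iterable[GenomicInterval],
    genome,
    exonic_flank: int = 10,
    intronic_flank: int = 10,
) -> JunctionProfile:
    """Per-position base probabilities across both intron junctions.

    The 5' matrix covers ``exonic_flank`` exonic positions followed by
    ``intronic_flank`` intronic positions (canonical G, T at the first two
    intronic columns); the 3' matrix covers the intronic then exonic side.
    All windows are read in transcript orientation.  Introns whose flanks
    extend past a chromosome end are skipped with a warning.  Positions with
    an undetermined base (N) are excluded from that column's denominator.
    """
    width = exonic_flank + intronic_flank
    counts5 = np.zeros((4, width), dtype=np.int64)
    counts3 = np.zeros((4, width), dtype=np.int64)
    n_used = 0
    for intron in introns:
        clen = chrom_length(genome, intron.chrom)
        lo = intron.start - max(exonic_flank, intronic_flank)
        hi = intron.end + max(exonic_flank, intronic_flank)
        if lo < 0 or hi > clen:
            log.warning(
                "intron %s:%d-%d flank extends past chromosome end; skipped",
                intron.chrom, intron.start, intron.end,
            )
            continue
        if intron.strand == "-":
            w5 = revcomp(fetch_seq(genome, intron.chrom,
                                   intron.end - intronic_flank,
                                   intron.end + exonic_flank))
            w3 = revcomp(fetch_seq(genome, intron.chrom,
                                   intron.start - exonic_flank,
                                   intron.start + intronic_flank))
        else:
            w5 = fetch_seq(genome, intron.chrom,
                           intron.start - exonic_flank,
                           intron.start + intronic_flank)
            w3 = fetch_seq(genome, intron.chrom,
                           intron.end - intronic_flank,
                           intron.end + exonic_flank)
        _count_window(counts5, w5)
        _count_window(counts3, w3)
        n_used += 1

    def normalize(counts: np.ndarray) -> pd.DataFrame:
        denom = counts.sum(axis=0, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(denom > 0, counts / denom, 0.0)
        return pd.DataFrame(probs, index=list(BASES),
                            columns=range(1, counts.shape[1] + 1))

    return JunctionProfile(normalize(counts5), normalize(counts3), n_used)
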