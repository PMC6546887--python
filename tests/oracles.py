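"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by the most naive route available
(exhaustive enumeration, pairwise comparison, BFS) and share no code with
the paths they validate.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from asland.genomic_model import GenomicInterval, Transcript

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Variant-region decomposition
# ---------------------------------------------------------------------------

def transcript_sites(t: Transcript) -> list[tuple[int, str]]:
    """(position, kind) splice sites, genomic ascending, kinds by strand."""
    sites = []
    for intron in t.introns:
        if t.strand == "-":
            sites.append((intron.start, "A"))
            sites.append((intron.end, "D"))
        else:
            sites.append((intron.start, "D"))
            sites.append((intron.end, "A"))
    return sorted(sites)


def brute_regions(ta: Transcript, tb: Transcript) -> list[tuple]:
    """Enumerate common sites, split at anchors — the naive decomposition.

    Returns [(left, right, sites_a, sites_b)] with genomic-ascending site
    tuples, for comparison against the production decomposition.
    """
    lo = max(ta.extent.start, tb.extent.start)
    hi = min(ta.extent.end, tb.extent.end)
    if lo >= hi:
        return []

    def inside(sites):
        return [s for s in sites if lo < s[0] < hi]

    sa, sb = inside(transcript_sites(ta)), inside(transcript_sites(tb))
    common = set(sa) & set(sb)

    def exonic(t: Transcript, p: int) -> bool:
        return any(e.start <= p <= e.end for e in t.exons)

    anchors = []
    if exonic(ta, lo) and exonic(tb, lo):
        anchors.append(lo)
    anchors.extend(sorted(p for p, _ in common))
    if exonic(ta, hi) and exonic(tb, hi):
        anchors.append(hi)

    out = []
    for left, right in zip(anchors, anchors[1:]):
        ra = tuple(s for s in sa if left < s[0] < right and s not in common)
        rb = tuple(s for s in sb if left < s[0] < right and s not in common)
        if ra or rb:
            out.append((left, right, ra, rb))
    return out


# ---------------------------------------------------------------------------
# Random structures
# ---------------------------------------------------------------------------

def random_isoform_pair(rng: np.random.Generator,
                        window: int = 10_000) -> tuple[Transcript, Transcript]:
    """Two same-strand isoforms over a shared window with related chains.

    A pool of disjoint candidate introns is drawn; each isoform includes,
    drops, or boundary-shifts each candidate independently, producing a mix
    of shared sites, single-site differences and multi-site tangles.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    blocks = []
    pos = 50 + int(rng.integers(0, 100))
    while pos + 80 < window - 50 and len(blocks) < 8:
        length = int(rng.integers(30, 200))
        if pos + length > window - 50:
            break
        blocks.append((pos, pos + length))
        pos += length + 20 + int(rng.integers(0, 200))

    def realize(block):
        s, e = block
        choice = rng.random()
        if choice < 0.25:
            return None  # intron absent (exonic here)
        if choice < 0.55:
            return (s, e)  # shared as-is
        ds = int(rng.integers(1, 5)) * (1 if rng.random() < 0.5 else -1)
        de = int(rng.integers(1, 5)) * (1 if rng.random() < 0.5 else -1)
        if choice < 0.75:
            return (s + ds, e)
        if choice < 0.9:
            return (s, e + de)
        return (s + ds, e + de)

    def build(tid):
        introns = [r for b in blocks if (r := realize(b)) is not None]
        exons = []
        prev = 0
        for s, e in introns:
            exons.append(GenomicInterval("c", prev, s, strand))
            prev = e
        exons.append(GenomicInterval("c", prev, window, strand))
        return Transcript(tid, tuple(exons))

    return build("iso_a"), build("iso_b")


def random_transcript(rng: np.random.Generator, chrom: str = "c",
                      tid: str = "t", origin: int = 0) -> Transcript:
    """A random valid multi-exon transcript for structural identities."""
    n_exons = int(rng.integers(1, 9))
    pos = origin + int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(1, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length,
                                     "+" if rng.random() < 0.5 else "+"))
        pos += length + int(rng.integers(1, 2000))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = tuple(GenomicInterval(e.chrom, e.start, e.end, strand) for e in exons)
    return Transcript(tid, exons)


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

def brute_orfs(seq: str, min_aa: int) -> list[tuple[int, int, bool, bool]]:
    """All (start, end, has_start, has_stop) ORFs by position enumeration."""
    seq = seq.upper()
    out = []
    for frame in range(3):
        codon_starts = list(range(frame, len(seq) - 2, 3))
        stops = [i for i in codon_starts if seq[i:i + 3] in STOPS]
        atgs = [i for i in codon_starts if seq[i:i + 3] == "ATG"]
        frame_end = frame + 3 * ((len(seq) - frame) // 3)
        for a in atgs:
            nxt = [s for s in stops if s >= a]
            if nxt:
                out.append((a, nxt[0] + 3, True, True))
            elif frame_end - a >= 3:
                out.append((a, frame_end, True, False))
        lead_stop = stops[0] if stops else None
        lead_end = (lead_stop + 3) if lead_stop is not None else frame_end
        if not any(a < lead_end for a in atgs) and lead_end - frame >= 3:
            out.append((frame, lead_end, False, lead_stop is not None))

    def aa(rec):
        start, end, _, has_stop = rec
        return (end - start) // 3 - (1 if has_stop else 0)

    return [r for r in out if aa(r) >= min_aa and aa(r) > 0]


def brute_longest_orf(seq: str, min_aa: int):
    """(aa_length, start, end, has_start, has_stop) of the best brute ORF."""
    orfs = brute_orfs(seq, min_aa)
    if not orfs:
        return None
    def aa(rec):
        return (rec[1] - rec[0]) // 3 - (1 if rec[3] else 0)
    best = max(orfs, key=lambda r: (aa(r), -r[0]))
    return (aa(best), best[0], best[1], best[2], best[3])


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# Locus clustering by BFS over pairwise exonic overlap
# ---------------------------------------------------------------------------

def brute_clusters(transcripts) -> list[frozenset]:
    """Connected components under same-strand pairwise exonic overlap."""
    def compatible(a, b):
        return a.strand == b.strand or "." in (a.strand, b.strand)

    def exon_overlap(a, b):
        return any(
            ea.chrom == eb.chrom and ea.start < eb.end and eb.start < ea.end
            for ea in a.exons for eb in b.exons
        )

    n = len(transcripts)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = transcripts[i], transcripts[j]
            if compatible(a, b) and exon_overlap(a, b):
                adj[i].append(j)
                adj[j].append(i)
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = set()
        queue = deque([i])
        while queue:
            k = queue.popleft()
            if k in comp:
                continue
            comp.add(k)
            queue.extend(adj[k])
        seen |= comp
        comps.append(frozenset(transcripts[k].id for k in comp))
    return comps
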