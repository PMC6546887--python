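"""Seeded simulator of genomes and isoform sets with planted AS events.

The generator emulates a plant-like multi-exon transcriptome: gene models
with lognormal exon/intron length laws, splice-site dinucleotides written
into the genome at configurable type frequencies, a reference isoform per
gene carrying an embedded full-length ORF, and, for a configurable fraction
of genes, alternative isoforms each carrying exactly one planted AS event
(intron retention, exon skipping, alternative donor/acceptor, or a complex
combination).  Every planted feature is recorded in a ground-truth ledger so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .feature_stats import site_category
from .genomic_model import (
    GeneModel, GenomicInterval, Transcript, write_bed, write_gtf,
)
from ._util import write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

_STOPS = ("TAA", "TAG", "TGA")
_ALL_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP = np.array([c for c in _ALL_CODONS if c not in _STOPS])

#: splice-site types with their boundary dinucleotides; Others is sampled
#: from the remaining dinucleotide pairs
SITE_TYPE_DINUCS = {
    "GT..AG": ("GT", "AG"),
    "GC..AG": ("GC", "AG"),
    "GC..AT": ("GC", "AT"),
    "AT..AC": ("AT", "AC"),
    "CT..AC": ("CT", "AC"),
    "GT..AT": ("GT", "AT"),
}

#: observed genome-wide splice-site type counts used as default frequencies
_DEFAULT_SITE_COUNTS = {
    "GT..AG": 255669, "GC..AG": 7571, "GC..AT": 3060, "AT..AC": 2751,
    "CT..AC": 2067, "GT..AT": 2036, "Others": 9142,
}

#: genome-wide basic event counts used as the default planted-type mix
_DEFAULT_EVENT_COUNTS = {
    "IntronR": 70035, "AltA": 47721, "AltD": 26973, "ExonS": 22161,
}

_DEFAULT_DOMAIN_MIX = {
    "both_none": 0.310, "same": 0.445, "one_lost": 0.173, "different": 0.072,
}


def _normalized(mix: dict[str, float]) -> dict[str, float]:
    total = float(sum(mix.values()))
    if total <= 0:
        raise ConfigError("mixture weights must sum to a positive value")
    return {k: v / total for k, v in mix.items() if v > 0}


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the emulated study conditions."""

    n_genes: int = 200
    #: fraction of gene models supported by at least one transcript
    p_expressed: float = 0.965
    #: fraction of expressed genes carrying alternative isoforms
    p_as: float = 0.65
    #: P(1, 2, 3 alternative isoforms | gene has AS)
    alt_isoform_probs: tuple[float, ...] = (0.7, 0.25, 0.05)
    #: exon count per gene ~ 2 + Poisson(lambda)
    exon_count_lambda: float = 3.0
    exon_count_max: Optional[int] = None
    exon_len_mean: float = 282.0
    exon_len_sd: float = 547.0
    min_exon: int = 2
    intron_len_mean: float = 1352.0
    intron_len_sd: float = 7609.0
    min_intron: int = 5
    site_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_SITE_COUNTS))
    event_mix: dict = field(default_factory=lambda: dict(_DEFAULT_EVENT_COUNTS))
    domain_mix: dict = field(default_factory=lambda: dict(_DEFAULT_DOMAIN_MIX))
    te_density: float = 0.023
    te_length: int = 150
    te_min_intron: int = 50
    #: mean of the geometric part of alternative-site offsets (3 + Geom)
    alt_offset_mean: float = 100.0
    #: candidate intron/exon choice for planting: inverse_length | uniform
    site_choice: str = "inverse_length"
    intergenic: int = 300
    genes_per_chrom: int = 500
    domain_pool_size: int = 50

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in ("p_expressed", "p_as", "te_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.alt_isoform_probs) - 1.0) > 1e-9:
            raise ConfigError("alt_isoform_probs must sum to 1")
        if self.site_choice not in ("inverse_length", "uniform"):
            raise ConfigError(f"unknown site_choice {self.site_choice!r}")
        mix = _normalized(self.event_mix)
        unknown = set(mix) - {"IntronR", "AltA", "AltD", "ExonS", "Complex"}
        if unknown:
            raise ConfigError(f"unknown event types in mix: {sorted(unknown)}")
        if self.exon_count_max is not None:
            if self.exon_count_max < 2:
                raise ConfigError("exon_count_max must be >= 2")
            if mix.get("ExonS", 0) > 0 and self.exon_count_max < 3:
                raise ConfigError(
                    "event mix requests ExonS (needs >= 3 exons) but "
                    f"exon_count_max is {self.exon_count_max}"
                )
        unknown = set(self.site_freqs) - set(SITE_TYPE_DINUCS) - {"Others"}
        if unknown:
            raise ConfigError(f"unknown splice-site types: {sorted(unknown)}")
        _normalized(self.site_freqs)
        _normalized(self.domain_mix)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted.

    ``events``: one row per alternative isoform (gene, reference isoform,
    alternative isoform, planted type, genomic region, fragment size).
    ``introns``: one row per unique intron with its planted splice-site type,
    boundary dinucleotides, origin (ref/alt) and TE presence.
    ``pairs``: planted domain-impact category per (reference, alternative)
    isoform pair.
    """

    events: pd.DataFrame
    introns: pd.DataFrame
    pairs: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        self.events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
        self.introns.to_csv(out / "truth_introns.tsv", sep="\t", index=False)
        self.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)


@dataclass
class SyntheticBundle:
    """In-memory result of one simulation, plus optional file export."""

    genome: dict[str, str]
    transcripts: list[Transcript]
    models: list[GeneModel]
    domains: dict[str, frozenset]
    te_intervals: list[GenomicInterval]
    truth: SyntheticTruth
    config: SimConfig
    seed: int

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "transcripts": out / "transcripts.gtf",
            "models": out / "models.gtf",
            "cdna": out / "models_cdna.fa",
            "domains": out / "domains.tsv",
            "te": out / "te.bed",
            "config": out / "sim_config.yaml",
        }
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.transcripts, paths["transcripts"])
        write_gtf([m.transcript for m in self.models], paths["models"])
        write_fasta({m.id: m.cdna for m in self.models}, paths["cdna"])
        with open(paths["domains"], "w") as fh:
            for tid in sorted(self.domains):
                fh.write(f"{tid}\t{','.join(sorted(self.domains[tid]))}\n")
        write_bed(self.te_intervals, paths["te"])
        cfg = asdict(self.config)
        cfg["seed"] = self.seed
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        self.truth.write(out)
        return paths


def sample_lengths(rng: np.random.Generator, mean: float, sd: float,
                   minimum: int, n: int) -> np.ndarray:
    """Integer lengths from a lognormal law with the given mean and sd.

    The (mu, sigma) of the underlying normal are solved from the target
    moments; draws are rounded and floored at ``minimum``.
    """
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    draws = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.maximum(np.rint(draws).astype(np.int64), minimum)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def _sample_site(rng: np.random.Generator,
                 names: list[str], probs: np.ndarray) -> tuple[str, str, str]:
    """Draw a splice-site type; Others gets a random non-listed dinuc pair."""
    name = names[int(rng.choice(len(names), p=probs))]
    if name != "Others":
        d2, a2 = SITE_TYPE_DINUCS[name]
        return name, d2, a2
    while True:
        d2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 2))
        a2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 2))
        if site_category(d2, a2) == "Others":
            return name, d2, a2


def _coding_sequence(rng: np.random.Generator, length: int) -> str:
    """A spliced cDNA of the given length carrying a full-length ORF.

    ATG at position 0, a single stop at the last full codon, no internal
    in-frame stops; any remainder bases after the stop are random.
    """
    k = length // 3
    tail = length - 3 * k
    if k < 2:
        body = "".join(_NONSTOP[rng.integers(0, len(_NONSTOP), k)])
    else:
        middle = "".join(_NONSTOP[rng.integers(0, len(_NONSTOP), k - 2)])
        body = "ATG" + middle + _STOPS[int(rng.integers(0, 3))]
    return body + "".join("ACGT"[i] for i in rng.integers(0, 4, tail))


def _choose(rng: np.random.Generator, candidates: list[int],
            lengths: list[int], mode: str) -> int:
    if mode == "inverse_length":
        w = np.array([1.0 / max(lengths[i], 1) for i in candidates])
        w /= w.sum()
        return int(rng.choice(candidates, p=w))
    return int(rng.choice(candidates))


def _draw_offset(rng: np.random.Generator, mean: float, cap: int) -> int:
    off = 3 + int(rng.geometric(1.0 / mean))
    return min(off, cap)


def plant_event(
    exon_lens: list[int],
    intron_lens: list[int],
    as_type: str,
    rng: np.random.Generator,
    config: Optional[SimConfig] = None,
    offset: Optional[int] = None,
) -> Optional[dict]:
    """Derive one alternative isoform structure from a reference structure.

    Operates in transcript space (concatenated exon/intron blocks starting
    at 0).  Returns None when the requested type is infeasible on this gene
    (caller resamples), otherwise a dict with:

    ``alt_exons``   transcript-space (start, end) exon intervals,
    ``region``      transcript-space (start, end) of the varied fragment,
    ``fragment``    fragment size in bp (None for Complex),
    ``patches``     [(ts position, 2-nt string role)] new splice-site
                    dinucleotide positions: ('donor', pos) / ('acceptor', pos),
    ``new_introns`` transcript-space intervals of introns absent from the
                    reference chain.
    """
    cfg = config or SimConfig()
    n = len(exon_lens)
    if n < 2 or len(intron_lens) != n - 1:
        return None

    starts = [0]
    for k in range(1, n):
        starts.append(starts[k - 1] + exon_lens[k - 1] + intron_lens[k - 1])
    exons = [(starts[k], starts[k] + exon_lens[k]) for k in range(n)]
    introns = [(exons[k][1], exons[k + 1][0]) for k in range(n - 1)]

    def pick_intron(min_len: int) -> Optional[int]:
        cand = [k for k in range(n - 1) if intron_lens[k] >= min_len]
        if not cand:
            return None
        return _choose(rng, cand, intron_lens, cfg.site_choice)

    if as_type == "IntronR":
        j = pick_intron(1)
        if j is None:
            return None
        alt = exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2:]
        return {
            "alt_exons": alt, "region": introns[j],
            "fragment": intron_lens[j], "patches": [], "new_introns": [],
        }

    if as_type == "ExonS":
        if n < 3:
            return None
        cand = list(range(1, n - 1))
        j = _choose(rng, cand, exon_lens, cfg.site_choice)
        alt = exons[:j] + exons[j + 1:]
        fused = (introns[j - 1][0], introns[j][1])
        return {
            "alt_exons": alt, "region": exons[j],
            "fragment": exon_lens[j], "patches": [], "new_introns": [fused],
        }

    if as_type in ("AltD", "AltA"):
        j = pick_intron(7)
        if j is None:
            return None
        u, v = introns[j]
        off = offset if offset is not None else \
            _draw_offset(rng, cfg.alt_offset_mean, intron_lens[j] - 4)
        if not 3 <= off <= intron_lens[j] - 4:
            return None
        if as_type == "AltD":
            new_intron = (u + off, v)
            alt = list(exons)
            alt[j] = (exons[j][0], u + off)
            patches = [("donor", u + off)]
        else:
            new_intron = (u, v - off)
            alt = list(exons)
            alt[j + 1] = (v - off, exons[j + 1][1])
            patches = [("acceptor", v - off)]
        return {
            "alt_exons": alt,
            "region": tuple(sorted((new_intron[0], u)) if as_type == "AltD"
                            else sorted((new_intron[1], v))),
            "fragment": off, "patches": patches, "new_introns": [new_intron],
        }

    if as_type == "Complex":
        j = pick_intron(10)
        if j is None:
            return None
        u, v = introns[j]
        budget = intron_lens[j] - 4
        d_off = _draw_offset(rng, cfg.alt_offset_mean, budget - 3)
        a_off = _draw_offset(rng, cfg.alt_offset_mean, budget - d_off)
        new_intron = (u + d_off, v - a_off)
        alt = list(exons)
        alt[j] = (exons[j][0], u + d_off)
        alt[j + 1] = (v - a_off, exons[j + 1][1])
        return {
            "alt_exons": alt, "region": (u, v), "fragment": None,
            "patches": [("donor", u + d_off), ("acceptor", v - a_off)],
            "new_introns": [new_intron],
        }

    raise ConfigError(f"unknown event type {as_type!r}")


def _feasible(as_type: str, exon_lens: list[int], intron_lens: list[int]) -> bool:
    if as_type == "ExonS" and len(exon_lens) < 3:
        return False
    if as_type in ("AltD", "AltA") and not any(i >= 7 for i in intron_lens):
        return False
    if as_type == "Complex" and not any(i >= 10 for i in intron_lens):
        return False
    return len(exon_lens) >= 2


def generate(config: SimConfig, seed: int,
             out_dir: Optional[str] = None) -> SyntheticBundle:
    """Run one simulation; fully reproducible for a given (config, seed).

    Genes are placed without overlap on synthetic chromosomes.  Each gene
    gets a reference isoform; expressed AS genes additionally get 1-3
    alternative isoforms, each carrying exactly one planted event drawn from
    the configured type mix.  Splice-site dinucleotides are written into the
    genome per the configured frequencies (alternative sites inherit the
    parent intron's type), domain annotations are planted per the impact
    mix, and TEs are planted into introns at the configured density.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    site_names = list(config.site_freqs)
    site_probs = np.array([config.site_freqs[k] for k in site_names], float)
    site_probs /= site_probs.sum()
    event_mix = _normalized(config.event_mix)
    event_names = sorted(event_mix)
    event_probs = np.array([event_mix[k] for k in event_names])
    domain_mix = _normalized(config.domain_mix)
    domain_pool = np.array(
        [f"PF{i:05d}" for i in range(1, config.domain_pool_size + 1)]
    )

    chrom_parts: dict[str, list[np.ndarray]] = {}
    chrom_offset: dict[str, int] = {}

    transcripts: list[Transcript] = []
    models: list[GeneModel] = []
    domains: dict[str, frozenset] = {}
    te_intervals: list[GenomicInterval] = []
    truth_events: list[dict] = []
    truth_introns: list[dict] = []
    truth_pairs: list[dict] = []

    def draw_domain_set() -> frozenset:
        size = int(rng.integers(1, 4))
        return frozenset(rng.choice(domain_pool, size=size, replace=False))

    def mutate_domain_set(ref: frozenset) -> frozenset:
        drop = str(rng.choice(sorted(ref)))
        remaining = [d for d in domain_pool if d not in ref]
        add = str(rng.choice(remaining))
        return (ref - {drop}) | {add}

    def draw_category(allowed: list[str]) -> str:
        w = np.array([domain_mix.get(c, 0.0) for c in allowed])
        if w.sum() == 0:
            w = np.ones(len(allowed))
        w /= w.sum()
        return allowed[int(rng.choice(len(allowed), p=w))]

    for g in range(config.n_genes):
        gid = f"g{g:05d}"
        chrom = f"chr{g // config.genes_per_chrom + 1}"
        if chrom not in chrom_parts:
            chrom_parts[chrom] = [_random_bases(rng, config.intergenic)]
            chrom_offset[chrom] = config.intergenic
        g0 = chrom_offset[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        expressed = rng.random() < config.p_expressed
        has_as = expressed and rng.random() < config.p_as
        n_alt = (
            1 + int(rng.choice(len(config.alt_isoform_probs),
                               p=config.alt_isoform_probs))
            if has_as else 0
        )
        alt_types = [
            event_names[int(rng.choice(len(event_names), p=event_probs))]
            for _ in range(n_alt)
        ]

        # structure: resample until every requested event type is feasible
        for attempt in range(50):
            n_exons = 2 + int(rng.poisson(config.exon_count_lambda))
            if config.exon_count_max is not None:
                n_exons = min(n_exons, config.exon_count_max)
            if any(t == "ExonS" for t in alt_types) and n_exons < 3:
                continue
            exon_lens = sample_lengths(
                rng, config.exon_len_mean, config.exon_len_sd,
                config.min_exon, n_exons).tolist()
            intron_lens = sample_lengths(
                rng, config.intron_len_mean, config.intron_len_sd,
                config.min_intron, n_exons - 1).tolist()
            if all(_feasible(t, exon_lens, intron_lens) for t in alt_types):
                break
        else:
            raise ConfigError(
                f"could not draw a feasible gene structure for events "
                f"{alt_types} under the configured length laws"
            )

        starts = [0]
        for k in range(1, n_exons):
            starts.append(starts[k - 1] + exon_lens[k - 1] + intron_lens[k - 1])
        exons_ts = [(starts[k], starts[k] + exon_lens[k]) for k in range(n_exons)]
        introns_ts = [(exons_ts[k][1], exons_ts[k + 1][0])
                      for k in range(n_exons - 1)]
        gene_len = exons_ts[-1][1]

        def to_genomic(ts: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (g0 + ts[0], g0 + ts[1])
            return (g0 + gene_len - ts[1], g0 + gene_len - ts[0])

        # sequence in transcript space: random background, coding exons,
        # splice-site dinucleotides at every intron boundary
        arr = _random_bases(rng, gene_len)
        cdna_len = sum(exon_lens)
        cdna = _coding_sequence(rng, cdna_len)
        pos = 0
        for (s, e) in exons_ts:
            chunk = cdna[pos:pos + (e - s)]
            arr[s:e] = np.frombuffer(chunk.encode(), dtype=np.uint8)
            pos += e - s

        intron_sites = []
        for (u, v) in introns_ts:
            name, d2, a2 = _sample_site(rng, site_names, site_probs)
            arr[u:u + 2] = np.frombuffer(d2.encode(), dtype=np.uint8)
            arr[v - 2:v] = np.frombuffer(a2.encode(), dtype=np.uint8)
            intron_sites.append((name, d2, a2))

        seen_introns: set[tuple[int, int]] = set()
        for k, (u, v) in enumerate(introns_ts):
            gs, ge = to_genomic((u, v))
            name, d2, a2 = intron_sites[k]
            has_te = False
            ilen = v - u
            if ilen > config.te_min_intron and rng.random() < config.te_density:
                te_len = min(config.te_length, ilen - 4)
                off = int(rng.integers(2, ilen - te_len - 1))
                t_gs, t_ge = to_genomic((u + off, u + off + te_len))
                te_intervals.append(GenomicInterval(chrom, t_gs, t_ge, strand))
                has_te = True
            seen_introns.add((u, v))
            truth_introns.append({
                "chrom": chrom, "strand": strand, "start": gs, "end": ge,
                "site_type": name, "donor2": d2, "acceptor2": a2,
                "origin": "ref", "has_te": has_te,
            })

        def make_transcript(tid: str, ts_exons, tag: str) -> Transcript:
            g_exons = tuple(
                GenomicInterval(chrom, *to_genomic(ts), strand)
                for ts in ts_exons
            )
            return Transcript(tid, g_exons, source_tag=tag)

        ref_id = f"{gid}.r"
        ref_tx = make_transcript(ref_id, exons_ts, "sim_ref")
        model_tx = make_transcript(f"{gid}.m", exons_ts, "model")
        models.append(GeneModel(gid, model_tx, cdna))

        alt_txs: list[Transcript] = []
        for a_i, as_type in enumerate(alt_types, start=1):
            planted = None
            for _ in range(50):
                planted = plant_event(exon_lens, intron_lens, as_type, rng, config)
                if planted is not None:
                    break
            if planted is None:
                raise ConfigError(
                    f"could not plant a {as_type} event on gene {gid}"
                )
            alt_id = f"{gid}.a{a_i}"
            for role, p in planted["patches"]:
                dn = [k for k, (u, v) in enumerate(introns_ts)
                      if u <= p <= v][0]
                _, d2, a2 = intron_sites[dn]
                di = d2 if role == "donor" else a2
                if role == "donor":
                    arr[p:p + 2] = np.frombuffer(di.encode(), dtype=np.uint8)
                else:
                    arr[p - 2:p] = np.frombuffer(di.encode(), dtype=np.uint8)
            for (u, v) in planted["new_introns"]:
                if (u, v) in seen_introns:
                    continue
                seen_introns.add((u, v))
                parent_d = [k for k, (pu, pv) in enumerate(introns_ts)
                            if pu <= u < pv or u == pu][0]
                parent_a = [k for k, (pu, pv) in enumerate(introns_ts)
                            if pu < v <= pv][0]
                d2 = intron_sites[parent_d][1]
                a2 = intron_sites[parent_a][2]
                gs, ge = to_genomic((u, v))
                truth_introns.append({
                    "chrom": chrom, "strand": strand, "start": gs, "end": ge,
                    "site_type": site_category(d2, a2), "donor2": d2,
                    "acceptor2": a2, "origin": "alt", "has_te": False,
                })
            alt_txs.append(make_transcript(alt_id, planted["alt_exons"], "sim_alt"))
            r_gs, r_ge = to_genomic(tuple(planted["region"]))
            truth_events.append({
                "gene_id": gid, "ref_id": ref_id, "alt_id": alt_id,
                "event_type": as_type, "chrom": chrom, "strand": strand,
                "left": r_gs, "right": r_ge,
                "fragment_size": planted["fragment"],
            })

        if expressed:
            transcripts.append(ref_tx)
            transcripts.extend(alt_txs)

        if alt_txs:
            ref_annotated: Optional[bool] = None
            ref_set: frozenset = frozenset()
            for alt in alt_txs:
                if ref_annotated is None:
                    cat = draw_category(list(domain_mix))
                    if cat in ("same", "different"):
                        ref_annotated = True
                    elif cat == "both_none":
                        ref_annotated = False
                    else:
                        ref_annotated = bool(rng.random() < 0.5)
                    if ref_annotated:
                        ref_set = draw_domain_set()
                        domains[ref_id] = ref_set
                else:
                    allowed = (["same", "different", "one_lost"]
                               if ref_annotated else ["both_none", "one_lost"])
                    cat = draw_category(allowed)
                if cat == "same":
                    domains[alt.id] = ref_set
                elif cat == "different":
                    domains[alt.id] = mutate_domain_set(ref_set)
                elif cat == "one_lost" and not ref_annotated:
                    domains[alt.id] = draw_domain_set()
                truth_pairs.append({
                    "ref_id": ref_id, "alt_id": alt.id, "category": cat,
                })

        if strand == "-":
            arr = _revcomp_arr(arr)
        chrom_parts[chrom].append(arr)
        chrom_parts[chrom].append(_random_bases(rng, config.intergenic))
        chrom_offset[chrom] = g0 + gene_len + config.intergenic

    genome = {
        chrom: np.concatenate(parts).tobytes().decode("ascii")
        for chrom, parts in chrom_parts.items()
    }

    truth = SyntheticTruth(
        events=pd.DataFrame(truth_events, columns=[
            "gene_id", "ref_id", "alt_id", "event_type", "chrom", "strand",
            "left", "right", "fragment_size"]),
        introns=pd.DataFrame(truth_introns, columns=[
            "chrom", "strand", "start", "end", "site_type", "donor2",
            "acceptor2", "origin", "has_te"]),
        pairs=pd.DataFrame(truth_pairs, columns=["ref_id", "alt_id", "category"]),
    )
    bundle = SyntheticBundle(
        genome=genome, transcripts=transcripts, models=models,
        domains=domains, te_intervals=te_intervals, truth=truth,
        config=config, seed=seed,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def read_domain_table(path) -> dict[str, frozenset]:
    """Read a transcript-id -> comma-separated-domain-ids TSV."""
    out: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tid = parts[0]
            doms = parts[1].split(",") if len(parts) > 1 and parts[1] else []
            out[tid] = frozenset(d for d in doms if d)
    return out
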