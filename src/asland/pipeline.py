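"""Pipeline orchestration and report assembly.

Stages run in a fixed order — parse, deduplicate, long-intron filter, locus
clustering, event classification, feature statistics, ORF prediction, then
the optional functional-impact stages (domain comparison, gene-model
assignment and AS rate, TE overlap).  The result is a :class:`PipelineReport`
serialized as JSON plus per-stage TSV artifacts with fixed filenames.
Identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from . import as_classifier as asc
from . import feature_stats as fs
from . import functional_impact as fi
from . import genomic_model as gm
from .errors import AslandError, StageError
from ._util import pct  # noqa: F401  (re-exported: the report's rounding rule)

log = logging.getLogger(__name__)

ARTIFACTS = (
    "report.json", "events.tsv", "lengths.tsv", "usage.tsv",
    "junction_matrices.tsv", "orf.tsv", "impact.json", "rates.json",
)


@dataclass
class PipelineReport:
    """Nested, JSON-serializable summary of one pipeline run."""

    counts: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    lengths: dict = field(default_factory=dict)
    usage: Optional[dict] = None
    chi_square: Optional[dict] = None
    junctions: dict = field(default_factory=dict)
    orf: dict = field(default_factory=dict)
    impact: Optional[dict] = None
    rates: Optional[dict] = None
    te: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "events": self.events,
            "lengths": self.lengths,
            "usage": self.usage,
            "chi_square": self.chi_square,
            "junctions": self.junctions,
            "orf": self.orf,
            "impact": self.impact,
            "rates": self.rates,
            "te": self.te,
        }

    def to_json(self) -> str:
        return json.dumps(_jsonify(self.to_dict()), indent=2, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage(name: str):
    """Decorator-free stage wrapper: logs timing, wraps failures."""
    class _Ctx:
        def __init__(self):
            self.t0 = 0.0

        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False
    return _Ctx()


def events_dataframe(events: Sequence[asc.ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": e.locus_id, "tx_a": e.tx_a, "tx_b": e.tx_b,
            "chrom": e.chrom, "strand": e.strand,
            "left_anchor": e.region.left_anchor,
            "right_anchor": e.region.right_anchor,
            "type": "Others" if e.as_type == "Complex" else e.as_type,
            "code": e.code,
            "fragment_size": e.fragment_size if e.fragment_size is not None else "",
            "retained_by": e.retained_by or "",
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=[
        "locus_id", "tx_a", "tx_b", "chrom", "strand", "left_anchor",
        "right_anchor", "type", "code", "fragment_size", "retained_by"])


def analyze(
    transcripts: Sequence[gm.Transcript],
    genome,
    models: Optional[Sequence[gm.GeneModel]] = None,
    domains: Optional[dict] = None,
    te_intervals: Optional[Sequence[gm.GenomicInterval]] = None,
    max_intron: int = gm.DEFAULT_MAX_INTRON,
    strand_policy: str = "strict",
    bin_width: int = 100,
    min_aa: int = 30,
) -> tuple[PipelineReport, dict]:
    """Run every analysis stage on in-memory objects.

    Returns the report plus an artifact dict holding the event list, the
    intermediate DataFrames, and the junction profile for serialization.
    """
    report = PipelineReport()
    artifacts: dict = {}

    with _stage("deduplicate"):
        unique = gm.merge_identical(transcripts)
    with _stage("filter_long_introns"):
        kept, removed = gm.filter_long_introns(unique, max_intron)
    with _stage("cluster"):
        loci = gm.cluster_loci(kept, strand_policy)
    with _stage("classify"):
        events = [e for locus in loci for e in asc.enumerate_events(locus, strand_policy)]
        artifacts["events"] = events
        artifacts["loci"] = loci

    loci_with_events = {e.locus_id for e in events}
    txs_in_events = {t for e in events for t in (e.tx_a, e.tx_b)}
    report.counts = {
        "transcripts_input": len(transcripts),
        "transcripts_unique": len(unique),
        "transcripts_removed_long_intron": len(removed),
        "transcripts_analyzed": len(kept),
        "loci": len(loci),
        "loci_with_events": len(loci_with_events),
        "transcripts_in_events": len(txs_in_events),
    }

    with _stage("event_summary"):
        summary = asc.event_summary(events, by="chromosome")
        artifacts["event_summary"] = summary
        report.events = {
            "total": len(events),
            "unique_codes": asc.count_unique_events(events),
            "summary": {str(k): v for k, v in summary.to_dict(orient="index").items()},
        }

    with _stage("length_stats"):
        internal = gm.unique_intervals(
            iv for t in kept for iv in t.internal_exons)
        introns = gm.unique_intervals(iv for t in kept for iv in t.introns)
        summaries = {
            "internal_exons": fs.length_summary(internal, bin_width),
            "introns": fs.length_summary(introns, bin_width),
        }
        fragments = fs.as_fragment_sizes(events, bin_width)
        summaries["retained_introns"] = fragments["IntronR"]
        summaries["alt_acceptor_sites"] = fragments["AltA"]
        summaries["alt_donor_sites"] = fragments["AltD"]
        summaries["skipped_exons"] = fragments["ExonS"]
        artifacts["length_summaries"] = summaries
        report.lengths = {k: v.to_dict() for k, v in summaries.items()}

    with _stage("splice_sites"):
        as_introns = gm.unique_intervals(
            iv
            for locus in loci if locus.id in loci_with_events
            for t in locus.transcripts for iv in t.introns)
        non_as_introns = gm.unique_intervals(
            iv
            for locus in loci if locus.id not in loci_with_events
            for t in locus.transcripts for iv in t.introns)
        counts_as = fs.usage_counts(fs.boundary_dinucleotides(as_introns, genome))
        counts_non = fs.usage_counts(
            fs.boundary_dinucleotides(non_as_introns, genome))
        usage = fs.usage_table(counts_non, counts_as)
        artifacts["usage"] = usage
        report.usage = {str(k): v
                        for k, v in usage.to_dict(orient="index").items()}
        try:
            report.chi_square = fs.chi_square_homogeneity(
                counts_non, counts_as).to_dict()
        except ValueError as exc:
            # an empty group or a sample too small to test: report no result
            log.warning("chi-square not computed: %s", exc)
            report.chi_square = None

    with _stage("junction_matrices"):
        profile = fs.junction_matrix(introns, genome)
        artifacts["junction_profile"] = profile
        report.junctions = {"n_introns": profile.n_introns}

    with _stage("orf"):
        orf_records: list[fi.ORFRecord] = []
        full_length_txs = 0
        for t in kept:
            recs = fi.find_orfs(gm.spliced_sequence(t, genome), min_aa, t.id)
            orf_records.extend(recs)
            if any(r.full_length for r in recs):
                full_length_txs += 1
        artifacts["orfs"] = orf_records
        aa = [r.aa_length for r in orf_records]
        report.orf = {
            "n_orfs": len(orf_records),
            "mean_aa_length": float(np.mean(aa)) if aa else None,
            "full_length_orfs": sum(1 for r in orf_records if r.full_length),
            "transcripts_with_full_length_orf": full_length_txs,
        }

    if domains is not None:
        with _stage("domain_impact"):
            report.impact = fi.categorize_event_domains(events, domains).to_dict()

    if models:
        with _stage("as_rate"):
            assignment, expressed = fi.assign_transcripts_to_gene_models(
                kept, models, genome)
            artifacts["assignment"] = assignment
            report.rates = fi.as_rate(events, assignment, models).to_dict()

    if te_intervals is not None:
        with _stage("te_overlap"):
            retained = [asc.retained_intron(e) for e in events
                        if e.as_type == "IntronR"]
            model_introns = (
                [iv for m in models for iv in m.transcript.introns]
                if models else introns
            )
            report.te = fi.te_overlap_fraction(
                retained, model_introns, te_intervals).to_dict()

    return report, artifacts


def write_artifacts(report: PipelineReport, artifacts: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    events_dataframe(artifacts["events"]).to_csv(
        out / "events.tsv", sep="\t", index=False)

    rows = {name: s.to_dict() for name, s in artifacts["length_summaries"].items()}
    pd.DataFrame.from_dict(rows, orient="index").to_csv(
        out / "lengths.tsv", sep="\t", index_label="feature")
    hist_rows = []
    for name, s in artifacts["length_summaries"].items():
        for b, c in sorted(s.histogram.items()):
            hist_rows.append({"feature": name, "bin": b, "count": c})
    pd.DataFrame(hist_rows, columns=["feature", "bin", "count"]).to_csv(
        out / "length_histograms.tsv", sep="\t", index=False)

    artifacts["usage"].to_csv(out / "usage.tsv", sep="\t", index_label="site_type")

    profile = artifacts["junction_profile"]
    mats = []
    for label, m in (("five_prime", profile.five_prime),
                     ("three_prime", profile.three_prime)):
        df = m.copy()
        df.insert(0, "junction", label)
        mats.append(df)
    pd.concat(mats).to_csv(out / "junction_matrices.tsv", sep="\t",
                           index_label="base")

    orf_rows = [
        {
            "transcript_id": r.transcript_id, "frame": r.frame,
            "start": r.start, "end": r.end, "aa_length": r.aa_length,
            "has_start": r.has_start, "has_stop": r.has_stop,
            "full_length": r.full_length, "longest": r.longest,
        }
        for r in artifacts["orfs"]
    ]
    pd.DataFrame(orf_rows, columns=[
        "transcript_id", "frame", "start", "end", "aa_length", "has_start",
        "has_stop", "full_length", "longest"]).to_csv(
        out / "orf.tsv", sep="\t", index=False)

    if report.impact is not None:
        (out / "impact.json").write_text(
            json.dumps(_jsonify(report.impact), indent=2, sort_keys=True) + "\n")
    if report.rates is not None:
        (out / "rates.json").write_text(
            json.dumps(_jsonify(report.rates), indent=2, sort_keys=True) + "\n")
    if report.te is not None:
        (out / "te.json").write_text(
            json.dumps(_jsonify(report.te), indent=2, sort_keys=True) + "\n")


def run_pipeline(
    gtf,
    genome_fasta,
    out_dir,
    models_gtf=None,
    cdna_fasta=None,
    domains_tsv=None,
    te_bed=None,
    max_intron: int = gm.DEFAULT_MAX_INTRON,
    strand_policy: str = "strict",
    bin_width: int = 100,
    min_aa: int = 30,
) -> PipelineReport:
    """File-level entry point: load inputs, analyze, write artifacts."""
    from .synthetic_data import read_domain_table

    with _stage("load"):
        transcripts = gm.parse_gtf(gtf)
        genome = pyfaidx.Fasta(str(genome_fasta))
        models = None
        if models_gtf is not None and cdna_fasta is not None:
            model_txs = gm.parse_gtf(models_gtf)
            cdnas = pyfaidx.Fasta(str(cdna_fasta))
            models = []
            for t in model_txs:
                mid = t.id[:-2] if t.id.endswith(".m") else t.id
                key = mid if mid in cdnas.keys() else t.id
                models.append(gm.GeneModel(mid, t, str(cdnas[key][:]).upper()))
        domains = read_domain_table(domains_tsv) if domains_tsv else None
        te = gm.read_bed(te_bed) if te_bed else None

    report, artifacts = analyze(
        transcripts, genome, models=models, domains=domains,
        te_intervals=te, max_intron=max_intron, strand_policy=strand_policy,
        bin_width=bin_width, min_aa=min_aa,
    )
    with _stage("write_artifacts"):
        write_artifacts(report, artifacts, out_dir)
    return report
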