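"""Shared fixtures: synthetic bundles at several scales, classified events."""

from collections import defaultdict

import pytest

from asland import cluster_loci, enumerate_events
from asland.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def bundle_small():
    """A desk-sized simulation under default study conditions."""
    return generate(SimConfig(n_genes=60), seed=11)


@pytest.fixture(scope="session")
def bundle_large():
    """A large all-AS simulation with an equal basic-type planting mix.

    Sized so that every basic event type is planted >= 1,000 times and the
    reference intron pool exceeds 10,000, which powers the recovery and
    splice-site frequency checks.
    """
    cfg = SimConfig(
        n_genes=3200,
        p_as=1.0,
        event_mix={"IntronR": 0.25, "AltA": 0.25, "AltD": 0.25, "ExonS": 0.25},
    )
    return generate(cfg, seed=20240613)


@pytest.fixture(scope="session")
def large_events(bundle_large):
    """Loci, events and a pair-indexed event map for the large bundle."""
    loci = cluster_loci(bundle_large.transcripts)
    events = [e for locus in loci for e in enumerate_events(locus)]
    by_pair = defaultdict(list)
    for e in events:
        by_pair[(e.tx_a, e.tx_b)].append(e)
    return loci, events, by_pair


@pytest.fixture(scope="session")
def small_run_dir(bundle_small, tmp_path_factory):
    """The small bundle written to disk once for file-level tests."""
    out = tmp_path_factory.mktemp("bundle_small")
    bundle_small.write(out)
    return out
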