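"""Shared fixtures: synthetic study-condition bundles built once per session.

The four standard bundles use the full study conditions (300 kb locus,
15-25 kb reads at 0.3% error, 30x per haplotype) with a fixed seed, since
truth recovery is specified as deterministic given the seed.  Small-scale
specs are provided for unit tests where the full conditions would only
cost time.
"""

from __future__ import annotations

import pytest

from igassess import RunConfig, evaluate_assembly, make_fixture_bundle
from igassess.synth_fixtures import default_spec

BUNDLE_SEED = 1
BUNDLE_NAMES = ("clean", "dropped_segment", "inversion_gap", "collapsed_dup")


def small_spec(name: str, seed: int = 1, locus_len: int = 60_000, **overrides):
    """A scaled-down spec for fast unit tests (6 kb flank, 3-5 kb reads)."""
    defaults = dict(
        locus_len=locus_len,
        flank=6_000,
        read_len_mean=4_000.0,
        read_len_sd=500.0,
        read_len_min=3_000,
        read_len_max=5_000,
        n_v=20,
        n_d=8,
        n_j=4,
    )
    defaults.update(overrides)
    return default_spec(name, seed=seed, **defaults)


@pytest.fixture(scope="session")
def bundles(tmp_path_factory):
    """The four standard full-scale fixture bundles, keyed by name."""
    base = tmp_path_factory.mktemp("bundles")
    return {
        name: make_fixture_bundle(name, base / name, seed=BUNDLE_SEED)
        for name in BUNDLE_NAMES
    }


@pytest.fixture(scope="session")
def evaluated(bundles):
    """Library-level evaluation results for each bundle (no report I/O)."""
    config = RunConfig()
    out = {}
    for name, b in bundles.items():
        out[name] = evaluate_assembly(
            b.sim.assembly, b.sim.regions, b.sim.genes, config,
            bam_path=b.bam, out_dir=None,
        )
    return out


@pytest.fixture(scope="session")
def small_bundles(tmp_path_factory):
    """Scaled-down bundles for unit/CLI tests."""
    base = tmp_path_factory.mktemp("small_bundles")
    return {
        name: make_fixture_bundle(
            name, base / name, seed=BUNDLE_SEED, spec=small_spec(name)
        )
        for name in ("clean", "dropped_segment", "inversion_gap")
    }
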