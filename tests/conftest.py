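"""Shared fixtures: small toy universes and the heavier session-scoped
simulation runs reused across test modules."""

from __future__ import annotations

import pytest

from xrseqtools import workflows as W
from xrseqtools.simulate import make_species_pair


@pytest.fixture(scope="session")
def small_pair():
    """A compact two-species universe for unit-level tests."""
    return make_species_pair(
        42,
        target_kwargs=dict(n_chroms=1, chrom_len=60_000, n_genes=4,
                           gene_len_range=(6_000, 7_000), min_gap=5_200),
        spike_kwargs=dict(n_chroms=1, chrom_len=30_000, n_genes=2,
                          gene_len_range=(6_000, 7_000), min_gap=5_200),
    )


@pytest.fixture(scope="session")
def wt_run():
    """A processed wild-type library (>=10^4 filtered reads)."""
    return W.run_wt_geometry(11)


@pytest.fixture(scope="session")
def qxr_recovery():
    """Knockout-to-wild-type repair recovery across 20 replicate seeds."""
    return W.run_qxr_recovery(
        5,
        {"XPC_CSB_KO": 0.003, "XPC_CSB_CSA_KO": 0.0005},
        n_seeds=20,
        intergenic_shares={"XPC_CSB_KO": 0.27},
    )
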