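"""Shared fixtures: trees and simulated alignments reused across tests.

Expensive simulations are session-scoped so the whole suite pays for them
once; every generator is explicitly seeded.
"""

import numpy as np
import pytest

import kinevo as kv


@pytest.fixture(scope="session")
def paper17():
    return kv.paper17_tree()


@pytest.fixture(scope="session")
def uniform_freqs():
    return kv.CodonFrequencies.uniform()


@pytest.fixture(scope="session")
def small_tree():
    """8-taxon balanced tree, moderate divergence, unequal branch lengths."""
    return kv.read_newick(
        "(((A:0.12,B:0.08):0.05,(C:0.1,D:0.15):0.07):0.04,"
        "((E:0.09,F:0.11):0.06,(G:0.14,H:0.1):0.05):0.04);"
    )


@pytest.fixture(scope="session")
def m0_alignment_500(paper17):
    """17-taxon, 500-codon alignment simulated under M0 (omega 0.3, kappa 2)."""
    spec = kv.SimulationSpec("M0", {"kappa": 2.0, "omega": 0.3}, 500, seed=0)
    aln, labels = kv.simulate_alignment(spec)
    return aln


@pytest.fixture(scope="session")
def small_m0_alignment(small_tree):
    """8-taxon, 150-codon M0 alignment for fast fitting tests."""
    spec = kv.SimulationSpec(
        "M0", {"kappa": 2.0, "omega": 0.25}, 150, seed=7, tree=small_tree
    )
    aln, _ = kv.simulate_alignment(spec)
    return aln
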