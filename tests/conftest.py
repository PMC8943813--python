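"""Shared fixtures: small synthetic chains and force fields."""

import numpy as np
import pytest

from chromatinmc.chain import NucleosomeGeometry, build_chain, initial_configuration
from chromatinmc.forcefield import ForceField
from chromatinmc.regions import GenomicInterval, NucleosomeSet


@pytest.fixture
def small_set() -> NucleosomeSet:
    """Five regularly spaced nucleosomes (NRL 183 bp) on a 1.2-kb interval."""
    iv = GenomicInterval("chrT", 0, 1200)
    starts = np.array([50, 233, 416, 599, 782])
    scores = np.array([5.0, 2.0, 9.0, 1.0, 7.0])
    return NucleosomeSet(iv, starts, None, scores)


@pytest.fixture
def naked_topology():
    """Pure-DNA chain: 300 nm of naked DNA in 30 segments."""
    iv = GenomicInterval("chrT", 0, int(round(300 / 0.34)))
    ns = NucleosomeSet(iv, np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0))
    return build_chain(ns)


@pytest.fixture
def elastic_ff() -> ForceField:
    """Elastic-only force field (no charges, no excluded volume)."""
    return ForceField(linear_charge=0.0, enable_ev=False, emax=0.0)


@pytest.fixture
def geometry() -> NucleosomeGeometry:
    return NucleosomeGeometry()


@pytest.fixture
def straight_config(naked_topology):
    return initial_configuration(naked_topology, "straight")
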