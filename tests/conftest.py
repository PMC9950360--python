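"""Shared fixtures: small hand-built matrices and one default two-clade
simulation reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from haplodistill import HaplotypeMatrix, SimParams, VariantRecord, simulate_two_clade


def make_matrix(rows, sample_ids=None, start_pos=100, spacing=10, population=None):
    """Build a HaplotypeMatrix from a list of per-variant allele lists."""
    alleles = np.asarray(rows, dtype=np.int8)
    n_hap = alleles.shape[1]
    if sample_ids is None:
        sample_ids = [f"S{i // 2}" for i in range(n_hap)]
    variants = [
        VariantRecord("chr4", start_pos + i * spacing, f"v{i}", "A", "G")
        for i in range(alleles.shape[0])
    ]
    return HaplotypeMatrix(variants, alleles, sample_ids, population)


@pytest.fixture(scope="session")
def two_clade_default():
    """One default-parameter two-clade replicate (70 kb locus, 135+65
    haplotypes) shared by distill/archaic/eqtl tests."""
    return simulate_two_clade(SimParams(seed=7, L=70_000))


@pytest.fixture(scope="session")
def two_clade_small():
    """A cheap two-clade replicate for tree-building tests."""
    return simulate_two_clade(SimParams(seed=3, L=30_000, n1=14, n2=8))


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(1234))
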