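"""Coalescent generator: neutral expectations, fixed-S conditioning,
two-clade construction, reproducibility, and the downstream synthetic
layers (expression, ancient samples)."""

import numpy as np
import pytest

from haplodistill import (
    SimParams,
    beta_for_r2,
    neutral_replicates,
    simulate_ancient_samples,
    simulate_expression,
    simulate_neutral,
    simulate_two_clade,
)
from haplodistill.scan import harmonic_a1


def test_fixed_s_mode_gives_exact_segregating_sites():
    for seed in range(5):
        m = simulate_neutral(SimParams(n=10, theta=None, S_fixed=5, seed=seed))
        assert m.n_variants == 5
        # every site is polymorphic (infinite sites)
        counts = m.alleles.sum(axis=1)
        assert ((counts > 0) & (counts < 10)).all()


def test_infinite_sites_no_position_reused():
    m = simulate_neutral(SimParams(n=12, theta=30, seed=4, L=500))
    pos = [v.pos for v in m.variants]
    assert len(pos) == len(set(pos))
    assert all(1 <= p <= 500 for p in pos)


def test_reproducibility_bit_identical():
    a = simulate_neutral(SimParams(n=8, theta=6, seed=11))
    b = simulate_neutral(SimParams(n=8, theta=6, seed=11))
    assert a == b
    r1 = simulate_two_clade(SimParams(seed=11, n1=10, n2=6, L=20_000))
    r2 = simulate_two_clade(SimParams(seed=11, n1=10, n2=6, L=20_000))
    assert r1.matrix == r2.matrix
    assert r1.archaic.calls == r2.archaic.calls
    np.testing.assert_array_equal(r1.outgroup, r2.outgroup)
    assert r1.truth.clade_labels == r2.truth.clade_labels


def test_pairwise_diversity_expectation_n2():
    """E[pi] = theta for a sample of two."""
    reps = neutral_replicates(n=2, theta=4.0, n_reps=20_000, seed=3)
    assert reps["pi_total"].mean() == pytest.approx(4.0, rel=0.03)


def test_watterson_expectation_matches_msprime_oracle():
    """E[S] = theta * a1; cross-checked against msprime as an independent
    coalescent implementation on the same parameters."""
    n, theta, reps = 10, 5.0, 3000
    mine = neutral_replicates(n=n, theta=theta, n_reps=reps, seed=9)["S"].mean()
    expected = theta * harmonic_a1(n)
    assert mine == pytest.approx(expected, rel=0.05)
    msprime = pytest.importorskip("msprime")
    s_ms = []
    for i, ts in enumerate(
        msprime.sim_ancestry(
            samples=n, ploidy=1, sequence_length=1, num_replicates=reps,
            random_seed=17,
        )
    ):
        # theta = 4 N mu L with N = 1/2 (coalescent units): mu = theta / 2
        mts = msprime.sim_mutations(
            ts, rate=theta / 2, random_seed=10_000 + i, discrete_genome=False
        )
        s_ms.append(mts.num_sites)
    assert np.mean(s_ms) == pytest.approx(expected, rel=0.05)
    assert mine == pytest.approx(np.mean(s_ms), rel=0.07)


def test_two_clade_inter_clade_differences_scale_with_split_time():
    """Fixed inter-clade differences grow linearly with T_split: slope per
    generation of total stem within 10% of 2 mu L."""
    mu, L = 1.25e-8, 50_000
    grid = [40_000.0, 80_000.0, 160_000.0]
    mean_fixed, mean_stemlen = [], []
    for T in grid:
        n_fixed, stem_len = [], []
        for seed in range(60):
            p = SimParams(
                seed=seed, n1=8, n2=6, L=L, T_split=T, T_archaic=10_000.0,
                mu_per_site=mu, N_e=2_000.0,
            )
            r = simulate_two_clade(p)
            n_fixed.append(len(r.truth.stem_positions))
            stem_len.append(2 * T - r.truth.tmrca1_gens - r.truth.tmrca2_gens)
        mean_fixed.append(np.mean(n_fixed))
        mean_stemlen.append(np.mean(stem_len))
    slope = np.polyfit(mean_stemlen, mean_fixed, 1)[0]
    assert slope == pytest.approx(mu * L, rel=0.10)


def test_archaic_matches_clade2_at_pre_attachment_stem_sites(two_clade_default):
    """By construction the archaic carries every clade-defining mutation
    older than its attachment time."""
    r = two_clade_default
    m = r.matrix
    labels = r.truth.clade_labels
    hids = m.haplotype_ids
    c2 = [j for j, h in enumerate(hids) if labels[h] == 2]
    shared = set(r.truth.stem_positions) - set(r.truth.post_archaic_stem_positions)
    assert shared
    for i, v in enumerate(m.variants):
        if v.pos in shared:
            clade2_allele = m.alleles[i, c2][0]
            arch = r.archaic_alleles[i]
            if arch == 0.5:  # simulated het: one allele matches by construction
                continue
            assert arch == clade2_allele


def test_archaic_table_uses_iupac_for_het_sites(two_clade_default):
    r = two_clade_default
    het_positions = [
        v.pos for i, v in enumerate(r.matrix.variants) if r.archaic_alleles[i] == 0.5
    ]
    for pos in het_positions:
        assert r.archaic.is_het(pos)
        assert len(r.archaic.bases(pos)) == 2


def test_outgroup_is_maximally_divergent(two_clade_default):
    """Ingroup-outgroup path length (2 T_outgroup) dwarfs modern pairwise
    distances (at most 2 T_split)."""
    r = two_clade_default
    m = r.matrix
    d_out = np.abs(m.alleles[:, 0].astype(float) - r.outgroup).sum()
    d_in = np.abs(m.alleles[:, 0] - m.alleles[:, -1]).astype(float).sum()
    assert d_out > 2 * d_in


def test_clade_labels_partition_into_configured_sizes(two_clade_default):
    labels = list(two_clade_default.truth.clade_labels.values())
    assert labels.count(1) == 135 and labels.count(2) == 65


# ---------------------------------------------------------------------------
# Expression and ancient layers
# ---------------------------------------------------------------------------


def test_expression_exact_levels_at_zero_noise():
    dosages = {"a": 0, "b": 1, "c": 2}
    t = simulate_expression(dosages, beta=2.0, sigma=0.0, seed=0, intercept=1.0)
    assert dict(zip(t.samples, t.values)) == {"a": 1.0, "b": 3.0, "c": 5.0}


def test_expression_floor_at_zero():
    t = simulate_expression({"a": 0}, beta=0.0, sigma=1.0, seed=1, intercept=-100.0)
    assert t.values == [0.0]


def test_beta_for_r2_identity():
    beta = beta_for_r2(0.235, sigma=1.0, clade2_freq=0.325)
    var_g = 2 * 0.325 * 0.675
    r2 = beta**2 * var_g / (beta**2 * var_g + 1.0)
    assert r2 == pytest.approx(0.235, abs=1e-12)


def test_ancient_zero_frequency_all_ancestral():
    anc = simulate_ancient_samples(lambda a: 0.0, {"t1": 1, "t2": 0}, n_per_bin=3, seed=5)
    for g in anc.genotypes:
        assert g.get("t1", 0) == 0
        # clade-2 allele is REF at t2, so derived(ALT) count is 2 - 0
        assert g.get("t2", 2) == 2


def test_ancient_missingness_reported_not_dropped():
    anc = simulate_ancient_samples(
        lambda a: 0.3, {"t1": 1}, n_per_bin=4, missing_rate=0.9, seed=6
    )
    assert len(anc) >= 80  # every bin keeps its samples
    n_missing = sum("t1" not in g for g in anc.genotypes)
    assert n_missing > 0  # genotypes absent, samples retained
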