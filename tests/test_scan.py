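"""Diversity statistics, Tajima's D, window geometry and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodistill import (
    DataError,
    diversity_stats,
    empirical_p,
    nucleotide_diversity,
    rank_windows,
    seg_sites,
    sliding_scan,
    tajimas_d,
    watterson_theta,
)
from haplodistill.scan import tajima_constants, tajimas_d_from_parts

from conftest import make_matrix

# the 4-haplotype, 2-derived-site alignment used throughout: two haplotypes
# carry both derived alleles, two carry neither (10 bp window)
FOUR_HAP = [[1, 1, 0, 0], [1, 1, 0, 0]]


def brute_pi_total(alleles):
    """Mean pairwise Hamming distance, independent double loop."""
    n = alleles.shape[1]
    total = sum(
        np.sum(alleles[:, i] != alleles[:, j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def brute_tajimas_d(alleles):
    """Independent transcription of Tajima's (1989) D from first principles."""
    n = alleles.shape[1]
    S = int(np.sum([0 < alleles[s].sum() < n for s in range(alleles.shape[0])]))
    if S == 0:
        return None
    pi = brute_pi_total(alleles)
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_pi_hand_example():
    m = make_matrix(FOUR_HAP, sample_ids=list("abcd"), start_pos=101, spacing=3)
    per_site, total = nucleotide_diversity(m, interval=(101, 110))
    assert total == pytest.approx(8 / 6)  # six pairs, total difference 8
    assert per_site == pytest.approx((8 / 6) / 10)


def test_pi_zero_for_identical_haplotypes():
    m = make_matrix([[0, 0, 0]], sample_ids=list("abc"))
    assert nucleotide_diversity(m, L=10) == (0.0, 0.0)


def test_seg_sites_counts_polymorphic_only():
    m = make_matrix([[0, 1, 0], [1, 1, 1], [0, 0, 1]], sample_ids=list("abc"))
    assert seg_sites(m) == 2  # middle row monomorphic
    # a site monomorphic after missing removal does not count
    m2 = make_matrix([[0, 1, 0], [0, 0, -1], [1, 0, 0]], sample_ids=list("abc"))
    assert seg_sites(m2) == 2


@pytest.mark.parametrize(
    "S,n,L,expected",
    [
        (2, 4, 1.0, 2 / (1 + 1 / 2 + 1 / 3)),  # ~1.0909
        (0, 10, 1.0, 0.0),
        (7, 2, 1.0, 7.0),  # a1 = 1 at n = 2
    ],
)
def test_watterson_theta_values(S, n, L, expected):
    assert watterson_theta(S, n, L) == pytest.approx(expected, rel=1e-12)


def test_tajimas_d_hand_example():
    """n=4, S=2, pi_total=4/3: D ~ 1.89 via e1~0.005510, e2~0.002690."""
    e1, e2 = tajima_constants(4)
    assert e1 == pytest.approx(0.005510, abs=5e-6)
    assert e2 == pytest.approx(0.002690, abs=5e-6)
    m = make_matrix(FOUR_HAP, sample_ids=list("abcd"))
    d = tajimas_d(m)
    assert d == pytest.approx(1.892, abs=2e-3)
    assert d == pytest.approx(brute_tajimas_d(np.array(FOUR_HAP, dtype=np.int8)))


def test_tajimas_d_zero_numerator_and_undefined():
    assert tajimas_d_from_parts(0, 0.0, 10) is None  # S = 0: undefined, not 0
    a1 = sum(1 / i for i in range(1, 10))
    assert tajimas_d_from_parts(5, 5 / a1, 10) == pytest.approx(0.0, abs=1e-12)


def test_statistics_match_brute_force_on_random_matrices(rng):
    for _ in range(100):
        n = int(rng.integers(4, 11))
        s = int(rng.integers(1, 21))
        alleles = rng.integers(0, 2, size=(s, n)).astype(np.int8)
        m = make_matrix(alleles, sample_ids=[f"h{i}" for i in range(n)])
        _, pi_total = nucleotide_diversity(m, L=1000)
        assert pi_total == pytest.approx(brute_pi_total(alleles), abs=1e-12)
        bd = brute_tajimas_d(alleles)
        d = tajimas_d(m)
        if bd is None:
            assert d is None
        else:
            assert d == pytest.approx(bd, abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_statistics_invariant_to_column_order_and_allele_swap(seed):
    rng = np.random.Generator(np.random.Philox(seed))
    n, s = int(rng.integers(4, 10)), int(rng.integers(2, 15))
    alleles = rng.integers(0, 2, size=(s, n)).astype(np.int8)
    m = make_matrix(alleles, sample_ids=[f"h{i}" for i in range(n)])
    perm = rng.permutation(n)
    m_perm = make_matrix(alleles[:, perm], sample_ids=[f"h{i}" for i in range(n)])
    m_swap = make_matrix(1 - alleles, sample_ids=[f"h{i}" for i in range(n)])
    for other in (m_perm, m_swap):
        assert seg_sites(other) == seg_sites(m)
        assert nucleotide_diversity(other, L=10)[1] == pytest.approx(
            nucleotide_diversity(m, L=10)[1], abs=1e-12
        )


# ---------------------------------------------------------------------------
# Sliding scan
# ---------------------------------------------------------------------------


def _spread_matrix(rng, start, end, n_sites, n_hap=8):
    pos = np.sort(rng.choice(np.arange(start, end + 1), n_sites, replace=False))
    from haplodistill import HaplotypeMatrix, VariantRecord

    alleles = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.int8)
    variants = [
        VariantRecord("chr4", int(p), f"v{i}", "A", "G") for i, p in enumerate(pos)
    ]
    return HaplotypeMatrix(variants, alleles, [f"h{i}" for i in range(n_hap)])


def test_window_count_geometry(rng):
    m = _spread_matrix(rng, 1, 3000, 60)
    ws = sliding_scan(m, (1, 3000), window_size=1500, step=100)
    assert len(ws.windows) == 16  # floor((3000-1500)/100) + 1
    assert ws.windows["start"].iloc[0] == 1
    assert (ws.windows["end"] - ws.windows["start"] + 1 == 1500).all()
    single = sliding_scan(m, (1, 1500), window_size=1500, step=100)
    assert len(single.windows) == 1
    with pytest.raises(DataError):
        sliding_scan(m, (1, 1000), window_size=1500)


def test_window_stats_agree_with_direct_interval_stats(rng):
    m = _spread_matrix(rng, 1, 4000, 80)
    ws = sliding_scan(m, (1, 4000), window_size=1500, step=500)
    for _, w in ws.windows.iterrows():
        direct = diversity_stats(m, (int(w["start"]), int(w["end"])))
        assert w["S"] == direct.S
        assert w["pi_total"] == pytest.approx(direct.pi_total, abs=1e-12)


def test_rank_windows_top_and_tie_flag(rng):
    m = _spread_matrix(rng, 1, 4000, 80)
    ws = sliding_scan(m, (1, 4000), window_size=1500, step=500)
    ranked = rank_windows(ws)
    top = ranked.ranked.iloc[0]
    assert top["rank_sum"] == ranked.ranked["rank_sum"].min()
    # the reported segment covers the top window
    assert ranked.top_segment[0] <= top["start"] <= ranked.top_segment[1]


def test_scan_peak_overlaps_generator_target(two_clade_default):
    r = two_clade_default
    m = r.matrix
    pos = m.positions
    ws = sliding_scan(m, (int(pos[0]), int(pos[-1])))
    ranked = rank_windows(ws)
    lo, hi = r.truth.target_segment
    s, e = ranked.top_segment
    assert s <= hi and e >= lo


def test_windows_below_min_s_have_undefined_d(rng):
    m = _spread_matrix(rng, 1, 3000, 4)  # sparse: most windows S < 3
    ws = sliding_scan(m, (1, 3000))
    sparse = ws.windows[ws.windows["S"] < 3]
    assert sparse["tajima_d"].isna().all()


# ---------------------------------------------------------------------------
# Empirical p
# ---------------------------------------------------------------------------


def test_empirical_p_add_one_rule():
    null = list(np.linspace(-2, 2, 999))
    assert empirical_p(3.0, null) == pytest.approx(1 / 1000)
    assert empirical_p(0.0, null) == pytest.approx((1 + 500) / 1000, abs=2e-3)


def test_empirical_p_uniform_under_null(rng):
    """Neutral observations scored against a neutral null give p-values
    uniform on (0, 1]."""
    from scipy import stats

    null = rng.normal(size=2000)
    obs = rng.normal(size=500)
    ps = np.array([empirical_p(o, null) for o in obs])
    assert stats.kstest(ps, "uniform").pvalue > 0.01
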