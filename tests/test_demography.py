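import math

import numpy as np
import pytest
import sympy

from ventpop import demography as dm
from ventpop.synthetic_data import simulate_infinite_sites


def test_tajima_toy_matches_hand_evaluation(tajima_toy):
    pop, exp = tajima_toy
    assert dm.tajima_d(pop) == pytest.approx(exp["tajima_d"], abs=1e-4)
    assert dm.r2_statistic(pop) == pytest.approx(exp["r2"])


def test_tajima_d_zero_when_k_equals_watterson():
    # force the numerator to zero through a hand-built statistics record
    n, S = 8, 6
    a1 = dm.tajima_constants(n)["a1"]
    st = dm.SampleStats(n=n, S=S, k=S / a1, u=np.zeros(n),
                        pair_diffs=np.zeros(n * (n - 1) // 2), n_hap=3)
    assert dm.tajima_d(st) == pytest.approx(0.0)


def test_tajima_d_undefined_without_segregating_sites(mono):
    pop, _ = mono
    with pytest.raises(ValueError, match="no segregating"):
        dm.tajima_d(pop)


def test_ewens_distribution_is_proper():
    p = dm.ewens_k_distribution(12, 2.0)
    assert p[0] == 0.0
    assert p.sum() == pytest.approx(1.0)


def test_ewens_matches_sympy_stirling_enumeration():
    """Exact oracle: P(K=j) = |s(n,j)| theta^j / theta^(n) via sympy."""
    n, theta = 10, 2.0
    rising = math.prod(theta + i for i in range(n))
    expected = np.array(
        [float(sympy.functions.combinatorial.numbers.stirling(
            n, j, kind=1, signed=False)) * theta**j / rising
         for j in range(n + 1)]
    )
    np.testing.assert_allclose(dm.ewens_k_distribution(n, theta), expected,
                               rtol=1e-10)


def test_ewens_matches_chinese_restaurant_simulation():
    """Independent stochastic oracle for P(K >= k)."""
    n, theta, k_obs = 12, 1.5, 5
    rng = np.random.default_rng(8)
    reps = 40000
    hits = 0
    for _ in range(reps):
        k = 1
        for i in range(1, n):
            if rng.random() < theta / (theta + i):
                k += 1
        hits += k >= k_obs
    mc = hits / reps
    exact = float(dm.ewens_k_distribution(n, theta)[k_obs:].sum())
    assert abs(mc - exact) < 4 * math.sqrt(exact * (1 - exact) / reps)


def test_fs_saturates_and_is_clamped_when_all_haplotypes_trivial():
    st = dm.SampleStats(n=4, S=2, k=1.0, u=np.array([1, 1, 0, 0]),
                        pair_diffs=np.array([2, 1, 1, 1, 1, 0]), n_hap=1)
    res = dm.fu_fs_detail(st)
    assert res.clamped and res.s_prime == 1.0
    assert res.value == pytest.approx(math.log((1 - dm.FS_CLAMP) / dm.FS_CLAMP))


def test_fs_negative_under_haplotype_excess(tajima_toy):
    pop, _ = tajima_toy
    res = dm.fu_fs_detail(pop)
    # K_obs = 3 of 4 sequences at k = 1: S' = 7/24 exactly (Ewens at theta=1)
    assert res.s_prime == pytest.approx(7 / 24)
    assert res.value == pytest.approx(math.log((7 / 24) / (17 / 24)))


def test_r2_vanishes_for_perfect_star():
    # every sequence carries exactly k/2 singletons
    n = 4
    u = np.ones(n)
    pair_diffs = np.full(n * (n - 1) // 2, 2)
    st = dm.SampleStats(n=n, S=4, k=2.0, u=u, pair_diffs=pair_diffs, n_hap=4)
    assert dm.r2_statistic(st) == 0.0


def test_mismatch_distribution_counts_all_pairs(tajima_toy):
    pop, _ = tajima_toy
    mismatch, rg = dm.mismatch_and_raggedness(pop)
    assert mismatch.n_pairs == 6
    assert mismatch.counts.sum() == 6
    # diffs 0:1, 1:4, 2:1 -> x = (1/6, 4/6, 1/6)
    np.testing.assert_array_equal(mismatch.counts, [1, 4, 1])
    expected = (1 / 6) ** 2 + (3 / 6) ** 2 + (3 / 6) ** 2 + (1 / 6) ** 2
    assert rg == pytest.approx(expected)


def test_raggedness_boundary_conventions(mono):
    pop, _ = mono
    _, rg = dm.mismatch_and_raggedness(pop)
    assert rg == pytest.approx(2.0)  # point mass: both boundary steps
    st = dm.SampleStats(n=2, S=1, k=0.5, u=np.array([1, 0]),
                        pair_diffs=np.array([0, 1]), n_hap=2)
    _, rg2 = dm.mismatch_and_raggedness(st)
    assert rg2 == pytest.approx(0.5)  # {0.5, 0.5}: three squared steps


def test_statistics_invariant_to_column_and_row_order():
    seqs = ["ACGTAA", "ACGTAT", "TCGTAA", "ACGCAA", "ACGTAA"]
    perm_rows = [seqs[i] for i in (3, 1, 4, 0, 2)]
    cols = [5, 2, 0, 3, 1, 4]
    perm_cols = ["".join(s[c] for c in cols) for s in seqs]
    base = dm.SampleStats.from_seqs(seqs)
    for other in (perm_rows, perm_cols):
        st = dm.SampleStats.from_seqs(other)
        assert dm.tajima_d(st) == pytest.approx(dm.tajima_d(base))
        assert dm.fu_fs(st) == pytest.approx(dm.fu_fs(base))
        assert dm.r2_statistic(st) == pytest.approx(dm.r2_statistic(base))
        assert dm.raggedness(st) == pytest.approx(dm.raggedness(base))


def test_null_pvalue_at_median_is_half():
    """A statistic sitting at its null median gets P close to 0.5."""
    n, theta = 12, 4.0
    rng = np.random.default_rng(21)
    ds = []
    for _ in range(400):
        st = dm.SampleStats.from_matrix(simulate_infinite_sites(n, theta,
                                                                seed=rng))
        if st.S > 0:
            ds.append(dm.tajima_d(st))
    median_d = float(np.median(ds))
    # build an observation with that D by picking the closest simulated one
    rng = np.random.default_rng(22)
    while True:
        mat = simulate_infinite_sites(n, theta, seed=rng)
        st = dm.SampleStats.from_matrix(mat)
        if st.S > 0 and abs(dm.tajima_d(st) - median_d) < 0.02:
            break
    p = dm.coalescent_pvalues(st, reps=1000, seed=7,
                              theta=theta)["tajima_d"]
    assert 0.4 < p < 0.6


def test_null_pvalues_are_roughly_uniform():
    """P-values of null data pass a coarse KS sanity check."""
    from scipy.stats import kstest

    rng = np.random.default_rng(23)
    pvals = []
    for _ in range(60):
        mat = simulate_infinite_sites(10, 4.0, seed=rng)
        st = dm.SampleStats.from_matrix(mat)
        if st.S == 0:
            continue
        p = dm.coalescent_pvalues(st, reps=200,
                                  seed=int(rng.integers(2**31 - 1)))["tajima_d"]
        pvals.append(p)
    assert kstest(pvals, "uniform").pvalue > 1e-3


def test_growth_data_give_small_tajima_pvalues():
    # Tajima's D has only moderate power, so the expansion needs to be
    # strong and well-sampled for a majority of runs to reach P < 0.05
    rng = np.random.default_rng(24)
    small = total = 0
    for _ in range(20):
        mat = simulate_infinite_sites(30, 30.0, seed=rng, growth=300.0)
        st = dm.SampleStats.from_matrix(mat)
        if st.S == 0:
            continue
        total += 1
        p = dm.coalescent_pvalues(st, reps=300,
                                  seed=int(rng.integers(2**31 - 1)))["tajima_d"]
        small += p < 0.05
    assert small / total > 0.5


def test_demography_summary_reports_dashes_below_gate(mono):
    from ventpop.io_align import PopulationSample
    pop, _ = mono
    small = PopulationSample(pop.alignment.subset(["m1", "m2"]), pop.mask,
                             species="sp", site="X", excluded=True)
    out = dm.demography_summary(small, reps=10, seed=0)
    assert out.tajima_d is None and out.p_d is None
    table = dm.demography_table([out])
    assert table.iloc[0]["Tajima D"] == "-"
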