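import math

import numpy as np
import pytest

from ventpop import divergence as dg
from ventpop import im_model as im


def test_migrant_number_arithmetic():
    cfg = im.IMConfig(N=10000, m12=1e-4, m21=1e-4)
    assert cfg.migrants_per_generation == pytest.approx(1.0)
    assert cfg.theta_frag == pytest.approx(4 * 10000 * 1e-8 * 600)
    assert cfg.n_hap == 40


def test_config_validation():
    with pytest.raises(ValueError):
        im.IMConfig(m12=-1)
    with pytest.raises(ValueError):
        im.IMConfig(n_ind=0)
    asym = im.IMConfig.asymmetric(m=2e-4)
    assert asym.m12 == 2e-4 and asym.m21 == 0.0


def test_config_file_with_table_aliases(tmp_path):
    p = tmp_path / "im.yaml"
    p.write_text(
        "tau: 1000\nNe: 10000\nbp: 600\nmigration_rate: 1.0e-4\n"
        "migration_type: asymmetric\nn_fragments: 10\nseed: 3\n"
    )
    cfg = im.IMConfig.from_file(p)
    assert cfg.T_div == 1000 and cfg.N == 10000 and cfg.L == 600
    assert cfg.m12 == 1e-4 and cfg.m21 == 0.0 and cfg.n_frag == 10


def test_fold_preserves_total_mass():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 5, size=(9, 9)).astype(float)
    folded = im.fold_matrix(counts)
    assert folded.sum() == pytest.approx(counts.sum())
    # everything above the fold line is zero
    k = 8
    for i in range(9):
        for j in range(9):
            if i + j > k:
                assert folded[i, j] == 0.0


def test_fragment_shuffling_leaves_sfs_unchanged():
    cfg = im.IMConfig(T_div=1e4, n_frag=20, n_ind=5, seed=9)
    sim = im.simulate_im(cfg)
    n1 = cfg.n_hap
    def sfs_from(frags):
        counts = np.zeros((n1 + 1, n1 + 1))
        for f in frags:
            for col in f.T:
                counts[int(col[:n1].sum()), int(col[n1:].sum())] += 1
        return im.fold_matrix(counts)
    rng = np.random.default_rng(1)
    order = rng.permutation(len(sim.fragments))
    a = sfs_from(sim.fragments)
    b = sfs_from([sim.fragments[i] for i in order])
    np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(a, sim.sfs.counts)


def test_single_deme_reduction_segregating_sites():
    """T_div = 0 and no migration is a panmictic sample of 2n lineages:
    E[S] = theta * a1 within 3 Monte-Carlo SE."""
    svals = []
    n_frag = 250
    for seed in (20, 21, 22, 23):
        cfg = im.IMConfig(T_div=0.0, m12=0.0, m21=0.0, n_frag=n_frag,
                          n_ind=10, seed=seed)
        svals.append(im.simulate_im(cfg).n_sites / n_frag)
    theta = 4 * 10000 * 1e-8 * 600
    a1 = sum(1 / i for i in range(1, 40))
    se = math.sqrt(1.2 / (n_frag * 4))
    assert abs(np.mean(svals) - theta * a1) < 3 * se


def test_panmictic_marginal_sfs_is_neutral():
    """Unfolded marginal expected branch lengths follow E[l_i] = 2/i."""
    cells = im.expected_branch_cells(10, 10, 0.0, 0.0, 0.0, 3000, seed=5)
    total = np.zeros(21)
    for i in range(11):
        for j in range(11):
            if 0 < i + j < 20:
                total[i + j] += cells[i, j]
    expected = 2.0 / np.arange(1, 20)
    np.testing.assert_allclose(total[1:20], expected, rtol=0.12)


def test_deme_swap_symmetry():
    a = im.expected_branch_cells(6, 10, 2.0, 1.5, 0.5, 4000, seed=6)
    b = im.expected_branch_cells(10, 6, 2.0, 0.5, 1.5, 4000, seed=7)
    # aggregate marginals to tame Monte-Carlo noise
    np.testing.assert_allclose(a.sum(axis=1), b.sum(axis=0), rtol=0.15,
                               atol=0.05)


def test_agreement_with_msprime_marginal_sfs():
    """Cross-simulator check against an established coalescent simulator."""
    msprime = pytest.importorskip("msprime")
    n_mc = 300
    cells = im.expected_branch_cells(20, 20, 5.0, 2.0, 2.0, n_mc, seed=9)
    marg = cells.sum(axis=1)
    dem = msprime.Demography()
    dem.add_population(name="d1", initial_size=10000)
    dem.add_population(name="d2", initial_size=10000)
    dem.add_population(name="anc", initial_size=10000)
    dem.set_migration_rate("d1", "d2", 1e-4)
    dem.set_migration_rate("d2", "d1", 1e-4)
    dem.add_population_split(time=5 * 20000, derived=["d1", "d2"],
                             ancestral="anc")
    acc = np.zeros(21)
    for ts in msprime.sim_ancestry(samples={"d1": 10, "d2": 10},
                                   demography=dem, ploidy=2,
                                   num_replicates=n_mc, random_seed=11):
        afs = ts.allele_frequency_spectrum(
            sample_sets=[ts.samples(population=0)], mode="branch",
            polarised=True, span_normalise=False,
        )
        acc += afs
    acc /= n_mc * 20000  # convert to units of 2N generations
    # compare low-frequency classes, where both estimates are precise
    np.testing.assert_allclose(marg[1:5], acc[1:5], rtol=0.2)
    assert abs(marg[1:20].sum() - acc[1:20].sum()) / acc[1:20].sum() < 0.1


def test_no_divergence_means_no_differentiation():
    rng = np.random.default_rng(31)
    fsts = []
    for _ in range(30):
        cfg = im.IMConfig(T_div=0.0, n_frag=12, n_ind=8,
                          seed=int(rng.integers(2**31 - 1)))
        sim = im.simulate_im(cfg)
        n1 = cfg.n_hap
        mat = np.hstack([f for f in sim.fragments if f.shape[1]]) \
            if any(f.shape[1] for f in sim.fragments) else None
        if mat is None:
            continue
        seqs = ["".join(map(str, row)) for row in mat]
        fsts.append(dg.amova_fst([seqs[:n1], seqs[n1:]]).fst)
    assert abs(np.mean(fsts)) < 0.03


def test_isolation_beats_migration_in_fst():
    def mean_fst(m, seed0):
        rng = np.random.default_rng(seed0)
        vals = []
        for _ in range(25):
            cfg = im.IMConfig(T_div=3e5, m12=m, m21=m, n_frag=12, n_ind=8,
                              seed=int(rng.integers(2**31 - 1)))
            sim = im.simulate_im(cfg)
            n1 = cfg.n_hap
            frags = [f for f in sim.fragments if f.shape[1]]
            if not frags:
                continue
            mat = np.hstack(frags)
            seqs = ["".join(map(str, row)) for row in mat]
            vals.append(dg.amova_fst([seqs[:n1], seqs[n1:]]).fst)
        return np.mean(vals)
    assert mean_fst(0.0, 40) > mean_fst(1e-4, 41)


def test_expected_sfs_proportions_are_normalised():
    cfg = im.IMConfig(T_div=1e4, n_ind=5, seed=3)
    prop = im.expected_sfs(cfg, n_mc=300, seed=3)
    mask = im.polymorphic_mask(prop.shape)
    assert prop[mask].sum() == pytest.approx(1.0)
    assert prop[0, 0] == 0.0 and prop[-1, -1] == 0.0


def test_composite_loglik_gibbs_inequality():
    rng = np.random.default_rng(2)
    shape = (7, 7)
    mask = im.polymorphic_mask(shape)
    p = np.zeros(shape)
    p[mask] = rng.random(mask.sum())
    p /= p[mask].sum()
    obs = im.JointSFS((p * 500).round(), folded=True)
    ll_true = im.composite_loglik(obs, p)
    # any permutation of the expected proportions can only lower the value
    for _ in range(5):
        q = np.zeros(shape)
        q[mask] = rng.permutation(p[mask])
        assert im.composite_loglik(obs, q) <= ll_true + 1e-9


def test_composite_loglik_hand_value():
    counts = np.zeros((3, 3))
    counts[0, 1] = 3
    counts[1, 0] = 1
    obs = im.JointSFS(counts, folded=True)
    exp = np.zeros((3, 3))
    exp[0, 1] = 0.75
    exp[1, 0] = 0.25
    assert im.composite_loglik(obs, exp) == pytest.approx(
        3 * math.log(0.75) + math.log(0.25)
    )


def test_composite_loglik_dimension_mismatch():
    obs = im.JointSFS(np.zeros((3, 3)), folded=True)
    with pytest.raises(ValueError, match="dimension"):
        im.composite_loglik(obs, np.zeros((4, 4)))


def test_estimation_recovers_interior_truth_roughly():
    """Reduced-budget self-consistency: estimates land near the truth."""
    cfg = im.IMConfig(T_div=1e5, n_frag=100, seed=55)
    sim = im.simulate_im(cfg)
    est = im.estimate_params(sim.sfs, model="symmetric", n_frag=100, seed=6,
                             n_mc_grid=80, n_mc_refine=200, grid_size=4,
                             maxiter=25)
    assert 10000 / 3 < est.N_hat < 10000 * 3
    assert 1e-4 / 5 < est.m_hat < 1e-4 * 5
    assert est.trace and math.isfinite(est.logCL)


def test_estimation_errors_without_polymorphism():
    obs = im.JointSFS(np.zeros((5, 5)), folded=True)
    with pytest.raises(ValueError, match="no polymorphic"):
        im.estimate_params(obs, n_frag=10)


def test_performance_study_smoke():
    report = im.run_performance_study(
        models=["symmetric"], t_divs=[1e4], fragment_counts=[10],
        n_pseudo=2, seed=3,
        config_kw={"n_ind": 5},
        estimate_kw={"n_mc_grid": 40, "n_mc_refine": 80, "grid_size": 3,
                     "maxiter": 10},
    )
    assert len(report) == 2
    summary = im.summarize_performance(report)
    assert {"N_median", "m_median", "T_median"} <= set(summary.columns)
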