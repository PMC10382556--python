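import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from driftscan.diversity import allele_frequencies
from driftscan.selection_scan import (
    ScanConfig,
    bh_fdr,
    build_population_tree,
    calibrate_dcms,
    dcms,
    ehh,
    flk_kinship_for_pair,
    flk_test,
    fractional_rank_pvalues,
    ihh,
    kinship_from_tree,
    mcd_covariance,
    run_pairwise_scan,
    standardize_xpehh,
    xpehh,
)
from driftscan.genotype_io import HaplotypeSet, make_variant_table
from driftscan.synthetic_data import SimulationConfig, SweepSpec, simulate


def dm(values, labels):
    return pd.DataFrame(values, index=labels, columns=labels, dtype=float)


def make_hapset(haplos, positions=None, chrom="1"):
    haplos = np.asarray(haplos, dtype=np.uint8)
    m = haplos.shape[1]
    if positions is None:
        positions = list(range(10_000, 10_000 + m * 10_000, 10_000))
    variants = make_variant_table(
        [(f"snp{j}", chrom, positions[j], "A", "C") for j in range(m)]
    )
    n = haplos.shape[0] // 2
    sample_of = [f"s{i}" for i in range(n) for _ in range(2)]
    return HaplotypeSet(variants, haplos, sample_of)


def split_haplotypes(sim):
    g = sim.genotypes
    out = []
    for pop in g.populations:
        ids = set(g.samples.loc[g.samples["population"] == pop, "sample_id"])
        out.append(
            {c: h.subset_samples([s for s in h.sample_ids if s in ids])
             for c, h in sim.haplotypes.items()}
        )
    return out


class TestPopulationTree:
    def test_additive_four_taxon_recovery(self):
        # additive matrix from tree ((A:1,B:2):1,(C:3,D:4)) with root split
        d = dm(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 5 + 2, 0],
            ],
            list("ABCD"),
        )
        d.loc["C", "D"] = d.loc["D", "C"] = 7.0
        tree = build_population_tree(d, drift_scale=1.0)
        k = kinship_from_tree(tree)
        # pairwise path lengths must reproduce the additive distances
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    path = k.loc[a, a] + k.loc[b, b] - 2 * k.loc[a, b]
                    assert path == pytest.approx(d.loc[a, b], abs=1e-9)

    def test_two_population_convention(self):
        tree = build_population_tree(dm([[0, 0.4], [0.4, 0]], ["A", "B"]),
                                     drift_scale=1.0)
        np.testing.assert_allclose(np.diag(tree.shared_path), [0.2, 0.2])
        assert tree.shared_path[0, 1] == 0.0

    def test_zero_matrix_star(self):
        tree = build_population_tree(dm(np.zeros((3, 3)), list("ABC")),
                                     drift_scale=1.0)
        np.testing.assert_allclose(tree.shared_path, 0.0, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            build_population_tree(dm([[0, np.inf], [np.inf, 0]], ["A", "B"]))


class TestKinship:
    def test_nested_unit_branches(self):
        # ((A,B),C): path-sum by hand gives F_AB = 1, F_AC = 0
        d = dm([[0, 2, 4], [2, 0, 4], [4, 4, 0]], list("ABC"))
        tree = build_population_tree(d, drift_scale=1.0)
        k = kinship_from_tree(tree)
        assert k.loc["A", "B"] == pytest.approx(1.0, abs=1e-9)
        assert k.loc["A", "C"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_psd(self, drift_dataset):
        from driftscan.diversity import distance_matrix

        d = distance_matrix(drift_dataset.genotypes, metric="reynolds")
        k = kinship_from_tree(build_population_tree(d)).to_numpy()
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() >= -1e-10

    def test_drift_transform(self):
        d = dm([[0, 0.4], [0.4, 0]], ["A", "B"])
        tree = build_population_tree(d, drift_scale=1.0)
        k = kinship_from_tree(tree, transform="drift")
        assert k.loc["A", "A"] == pytest.approx(1 - np.exp(-0.2))


class TestFlk:
    def test_equal_frequencies_zero(self):
        k = dm([[0.05, 0], [0, 0.05]], ["A", "B"])
        stat, p = flk_test(np.array([0.3, 0.3]), k)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_population_hand_value(self):
        # algebraic reduction: T = (p1-p2)^2 / (2 f p0 q0) = 25.6
        k = dm([[0.05, 0], [0, 0.05]], ["A", "B"])
        stat, p = flk_test(np.array([0.9, 0.1]), k)
        assert stat == pytest.approx(25.6, abs=1e-9)

    def test_fixed_everywhere_undefined(self):
        k = dm([[0.05, 0], [0, 0.05]], ["A", "B"])
        stat, p = flk_test(np.array([1.0, 1.0]), k)
        assert np.isnan(stat) and np.isnan(p)

    def test_star_tree_reduces_to_scaled_lk(self):
        # under F = f*I the GLS mean is the simple mean and
        # T = sum (p_i - pbar)^2 / (f p0 q0)
        rng = np.random.default_rng(0)
        f = 0.08
        k = dm(np.eye(4) * f, list("ABCD"))
        for _ in range(20):
            p = rng.uniform(0.05, 0.95, 4)
            stat, _ = flk_test(p, k)
            pbar = p.mean()
            expected = ((p - pbar) ** 2).sum() / (f * pbar * (1 - pbar))
            assert stat == pytest.approx(expected, rel=1e-9)

    def test_null_chi2_moments(self):
        # matched neutral simulation: mean of T close to df = 1
        sim = simulate(
            SimulationConfig(seed=31, n_populations=2, ne_per_population=400,
                             generations_divergence=12, n_chromosomes=2,
                             n_snps_per_chrom=1000, sample_sizes=[400, 400],
                             ancestral_freq_distribution=("uniform", 0.2, 0.8))
        )
        freqs = allele_frequencies(sim.genotypes)
        k = flk_kinship_for_pair(freqs, "pop1", "pop2")
        from driftscan.selection_scan import flk_scan

        stat, _ = flk_scan(freqs.p, k)
        t = stat[~np.isnan(stat)]
        assert t.mean() == pytest.approx(1.0, abs=0.1)


class TestEhh:
    def test_all_identical_is_one(self):
        hs = make_hapset(np.zeros((6, 10)))
        prof = ehh(hs.haplos, core=4, direction=+1)
        np.testing.assert_allclose(prof, 1.0)

    def test_all_distinct_adjacent_counting_oracle(self):
        # 4 haplotypes split 2/2 by the adjacent marker and 1/1 within
        # each core-allele class: groups {2, 1, 1} -> EHH = C(2,2-ish)
        haps = np.array(
            [
                [0, 0, 0],
                [0, 0, 0],
                [0, 1, 0],
                [1, 1, 0],
            ],
            dtype=np.uint8,
        )
        prof = ehh(haps, core=0, direction=+1)
        # groups over (core, adjacent): (0,0)x2, (0,1), (1,1) -> sizes 2,1,1
        expected = (2 * 1 / 2) / (4 * 3 / 2)
        assert prof[1] == pytest.approx(expected)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        haps = (rng.random((12, 40)) < 0.5).astype(np.uint8)
        for core in (0, 20, 39):
            for direction in (+1, -1):
                prof = ehh(haps, core, direction)
                assert (np.diff(prof) <= 1e-12).all()

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError):
            ehh(np.zeros((3, 5), dtype=np.uint8), 0, +1)


class TestXpehh:
    def _diverse_haps(self, seed, n=12, m=60):
        rng = np.random.default_rng(seed)
        return (rng.random((n, m)) < 0.5).astype(np.uint8)

    def test_identical_sets_zero(self):
        haps = self._diverse_haps(0)
        a = make_hapset(haps)
        b = make_hapset(haps)
        for core in range(20, 40):
            v = xpehh(a, b, core)
            if np.isfinite(v):
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_swap_negates(self):
        a = make_hapset(self._diverse_haps(1))
        b = make_hapset(self._diverse_haps(2))
        for core in range(20, 40):
            ab = xpehh(a, b, core)
            ba = xpehh(b, a, core)
            if np.isfinite(ab):
                assert ba == pytest.approx(-ab, abs=1e-12)

    def test_no_truncation_excluded(self):
        a = make_hapset(np.zeros((6, 10)))  # EHH stays 1 to the border
        b = make_hapset(self._diverse_haps(3, m=10, n=6))
        assert np.isnan(xpehh(a, b, 5))

    def test_gap_exclusion(self):
        haps = self._diverse_haps(4, m=10)
        pos = [10_000, 20_000, 30_000, 40_000, 50_000,
               400_000, 410_000, 420_000, 430_000, 440_000]
        a = make_hapset(haps, positions=pos)
        val, reason = ihh(a.haplos, np.array(pos), 4, max_gap_bp=200_000)
        assert reason == "gap"

    def test_standardize(self):
        raw = np.array([0.1, -0.4, 0.7, 0.2])
        z = standardize_xpehh(raw)
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-9)


class TestFractionalRanks:
    def test_worked_example(self):
        p = fractional_rank_pvalues(np.array([10.0, 3.0, 2.0, 1.0]))
        np.testing.assert_allclose(p, [0.2, 0.4, 0.6, 0.8])

    def test_all_tied(self):
        p = fractional_rank_pvalues(np.ones(5))
        np.testing.assert_allclose(p, 0.5)

    def test_max_gets_min(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        p = fractional_rank_pvalues(x)
        assert p[np.argmax(x)] == p.min()
        assert ((p > 0) & (p < 1)).all()


class TestMcd:
    def _gauss(self, seed, m=10_000, rho=0.5):
        rng = np.random.default_rng(seed)
        cov = np.full((3, 3), rho)
        np.fill_diagonal(cov, 1.0)
        return rng.multivariate_normal(np.zeros(3), cov, size=m), cov

    def test_clean_gaussian(self):
        x, cov = self._gauss(0)
        corr = mcd_covariance(x, seed=0)
        np.testing.assert_allclose(corr, cov, atol=0.05)

    def test_robust_to_planted_outliers(self):
        x, cov = self._gauss(1)
        rng = np.random.default_rng(2)
        bad = rng.choice(len(x), size=len(x) // 10, replace=False)
        x_contaminated = x.copy()
        x_contaminated[bad] = rng.normal(10.0, 0.1, size=(len(bad), 3))
        corr = mcd_covariance(x_contaminated, seed=0)
        np.testing.assert_allclose(corr, cov, atol=0.05)
        classical = np.corrcoef(x_contaminated, rowvar=False)
        assert np.abs(classical - cov).max() > 0.05

    def test_independent_columns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10_000, 3))
        corr = mcd_covariance(x, seed=1)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 0.05

    def test_subsample_deterministic(self):
        x, _ = self._gauss(4, m=40_000)
        a = mcd_covariance(x, subsample=5_000, seed=7)
        b = mcd_covariance(x, subsample=5_000, seed=7)
        np.testing.assert_array_equal(a, b)


class TestDcms:
    def test_single_statistic(self):
        out = dcms(np.array([[0.5], [0.1]]), np.array([[1.0]]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(np.log(9))

    def test_duplicated_statistic_decorrelates(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 50)
        single = dcms(p[:, None], np.array([[1.0]]))
        double = dcms(np.column_stack([p, p]),
                      np.array([[1.0, 1.0], [1.0, 1.0]]))
        np.testing.assert_allclose(double, single, atol=1e-12)

    def test_two_independent(self):
        out = dcms(np.array([[0.1, 0.1]]), np.eye(2))
        assert out[0] == pytest.approx(2 * np.log(9), abs=1e-12)

    def test_rejects_boundary_p(self):
        with pytest.raises(ValueError):
            dcms(np.array([[0.0, 0.5]]), np.eye(2))


class TestCalibrate:
    def test_standard_normal_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        p, mu, sigma = calibrate_dcms(x)
        assert abs(mu) < 0.05
        assert abs(sigma - 1) < 0.05

    def test_contaminated_location_robust(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        x[:500] += 20.0
        _, mu, sigma = calibrate_dcms(x)
        # Huber (c = 1.345) retains a location bias of roughly eps * c
        # under one-sided 5% contamination; ~0.1 here, vs ~1.0 classical
        assert abs(mu) < 0.15
        assert abs(x.mean()) > 0.9

    def test_p_strictly_decreasing_in_value(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.normal(size=200))
        p, _, _ = calibrate_dcms(x)
        assert (np.diff(p) < 0).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            calibrate_dcms(np.ones(100))


class TestBhFdr:
    def test_worked_example(self):
        q, sig = bh_fdr(np.array([0.01, 0.02, 0.03, 0.9]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9])
        assert list(sig) == [True, True, True, False]

    def test_all_ones(self):
        q, sig = bh_fdr(np.ones(10))
        assert not sig.any()

    def test_null_uniform_fdr_controlled(self):
        rng = np.random.default_rng(3)
        false_hits = []
        for _ in range(100):
            p = rng.uniform(size=200)
            _, sig = bh_fdr(p, 0.05)
            false_hits.append(sig.any())
        assert np.mean(false_hits) <= 0.10  # E[any rejection] <= alpha + noise

    def test_q_monotone_wrt_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=500)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def sweep_scan():
    sim = simulate(
        SimulationConfig(
            seed=50, n_populations=2, ne_per_population=1000,
            generations_divergence=80, n_chromosomes=2,
            chrom_length_bp=30_000_000, n_snps_per_chrom=900,
            sample_sizes=[40, 40],
            ancestral_freq_distribution=("uniform", 0.1, 0.9),
            sweep=SweepSpec(population=0, chrom="1", pos=15_000_000, s=0.1,
                            initial_freq=0.15, condition_on_fixation=True),
        )
    )
    haps_a, haps_b = split_haplotypes(sim)
    res = run_pairwise_scan(
        sim.genotypes, haps_a, haps_b, "pop1", "pop2", ScanConfig(seed=1)
    )
    return sim, res


class TestPairwiseScan:
    def test_sweep_detected_and_localized(self, sweep_scan):
        sim, res = sweep_scan
        sig = res.significant
        assert len(sig) >= 1
        true_pos = sim.truth["sweep"]["pos"]
        near = sig[(sig["chrom"] == "1")
                   & ((sig["pos"] - true_pos).abs() <= 500_000)]
        assert len(near) >= 1

    def test_deterministic(self, sweep_scan):
        sim, res = sweep_scan
        haps_a, haps_b = split_haplotypes(sim)
        res2 = run_pairwise_scan(
            sim.genotypes, haps_a, haps_b, "pop1", "pop2", ScanConfig(seed=1)
        )
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_permuted_labels_destroy_signal(self, sweep_scan):
        sim, _ = sweep_scan
        g = sim.genotypes
        rng = np.random.default_rng(9)
        shuffled = g.samples["population"].to_numpy()[
            rng.permutation(g.n_samples)
        ]
        g_perm = g.take_samples(np.arange(g.n_samples))
        g_perm.samples["population"] = shuffled
        ids_a = set(
            g_perm.samples.loc[g_perm.samples["population"] == "pop1",
                               "sample_id"]
        )
        ids_b = set(
            g_perm.samples.loc[g_perm.samples["population"] == "pop2",
                               "sample_id"]
        )
        haps_a = {c: h.subset_samples([s for s in h.sample_ids if s in ids_a])
                  for c, h in sim.haplotypes.items()}
        haps_b = {c: h.subset_samples([s for s in h.sample_ids if s in ids_b])
                  for c, h in sim.haplotypes.items()}
        res = run_pairwise_scan(
            g_perm, haps_a, haps_b, "pop1", "pop2", ScanConfig(seed=1)
        )
        true_pos = sim.truth["sweep"]["pos"]
        window = res.table[
            (res.table["chrom"] == "1")
            & ((res.table["pos"] - true_pos).abs() <= 500_000)
        ]
        assert window["q_value"].dropna().median() > 0.05

    def test_table_invariants(self, sweep_scan):
        _, res = sweep_scan
        sub = res.table.dropna(subset=["dcms"])
        for col in ("p_frac_fst", "p_frac_flk", "p_frac_xpehh"):
            assert ((sub[col] > 0) & (sub[col] < 1)).all()
        assert (sub["q_value"] >= sub["dcms_p"] - 1e-12).all()
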