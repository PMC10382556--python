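import numpy as np
import pytest
from scipy.stats import spearmanr

from driftscan.diversity import (
    afd,
    allele_frequencies,
    chord_distance,
    distance_matrix,
    ld_at_distance,
    ld_decay_curve,
    pairwise_fst_multilocus,
    per_snp_wc_fst,
    reynolds_distance,
    zfst,
)
from driftscan.genotype_io import MISSING
from driftscan.synthetic_data import SimulationConfig, simulate

from .conftest import build_matrix


def drift_expected_fst(ne, t):
    return 1.0 - (1.0 - 1.0 / (2 * ne)) ** t


class TestAlleleFrequencies:
    def test_all_homozygous_b(self):
        g = build_matrix(np.full((3, 2), 2, dtype=np.int8))
        f = allele_frequencies(g)
        assert (f.p == 1.0).all()

    def test_balanced(self):
        g = build_matrix(np.array([[0], [1], [2]]))
        f = allele_frequencies(g)
        assert f.p[0, 0] == pytest.approx(0.5)

    def test_hand_counted_with_missing(self):
        dos = np.array([[0, 2], [1, MISSING], [2, 1], [1, 1]], dtype=np.int8)
        g = build_matrix(dos, populations=["a", "a", "b", "b"])
        f = allele_frequencies(g)
        # population a, snp0: (0+1)/4; snp1: dosage 2 of 1 called -> 1.0
        assert f.p[f.row("a"), 0] == pytest.approx(0.25)
        assert f.p[f.row("a"), 1] == pytest.approx(1.0)
        assert f.n_called[f.row("a"), 1] == 1
        # population b: (2+1)/4, (1+1)/4
        assert f.p[f.row("b"), 0] == pytest.approx(0.75)
        assert f.p[f.row("b"), 1] == pytest.approx(0.5)

    def test_uncalled_cell_is_nan(self):
        dos = np.array([[MISSING], [1]], dtype=np.int8)
        g = build_matrix(dos, populations=["a", "b"])
        f = allele_frequencies(g)
        assert np.isnan(f.p[f.row("a"), 0])


class TestAfd:
    def _freqs(self, pa, pb):
        dos = np.array(
            [np.round(np.array(pa) * 2), np.round(np.array(pb) * 2)],
            dtype=np.int8,
        )
        g = build_matrix(dos, populations=["a", "b"])
        return allele_frequencies(g)

    def test_identity_zero(self):
        f = self._freqs([0.5, 1.0], [0.5, 1.0])
        per_snp, mean, _ = afd(f, "a", "b")
        assert mean == pytest.approx(0.0)

    def test_fixed_opposite_is_one(self):
        f = self._freqs([1.0], [0.0])
        _, mean, _ = afd(f, "a", "b")
        assert mean == pytest.approx(1.0)

    def test_worked_example(self):
        # direct evaluation: (|0.8-0.3| + |0.2-0.7|)/2 = 0.5
        g = build_matrix(
            np.array([[2, 2, 2, 1, 1, 2, 1, 0, 0, 0]], dtype=np.int8).T,
            populations=["a"] * 5 + ["b"] * 5,
        )
        f = allele_frequencies(g)
        assert f.p[f.row("a"), 0] == pytest.approx(0.8)
        assert f.p[f.row("b"), 0] == pytest.approx(0.3)
        per_snp, mean, _ = afd(f, "a", "b")
        assert per_snp[0] == pytest.approx(0.5, abs=1e-12)


class TestChord:
    def test_identical_zero(self):
        g = build_matrix(np.array([[1, 2], [1, 2]]), populations=["a", "b"])
        f = allele_frequencies(g)
        assert chord_distance(f, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_single_fixed_locus_closed_form(self):
        g = build_matrix(np.array([[2], [0]]), populations=["a", "b"])
        f = allele_frequencies(g)
        assert chord_distance(f, "a", "b") == pytest.approx(
            2 * np.sqrt(2) / np.pi, abs=1e-12
        )

    def test_monotone_in_divergence(self):
        last = -1.0
        for pb in (0.5, 0.4, 0.2, 0.0):
            nb = int(pb * 10)
            dos_b = np.array([2] * nb + [0] * (10 - nb))
            dos = np.concatenate([np.array([1] * 10), dos_b])[:, None]
            g = build_matrix(dos.astype(np.int8),
                             populations=["a"] * 10 + ["b"] * 10)
            f = allele_frequencies(g)
            d = chord_distance(f, "a", "b")
            assert d >= last - 1e-12
            last = d


class TestReynolds:
    def test_identical_near_zero(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, size=(100, 500)).astype(np.int8)
        g = build_matrix(dos, populations=["a", "b"] * 50)
        f = allele_frequencies(g)
        assert abs(reynolds_distance(f, "a", "b")) < 0.01

    def test_symmetry(self, drift_dataset):
        f = allele_frequencies(drift_dataset.genotypes)
        assert reynolds_distance(f, "pop1", "pop2") == pytest.approx(
            reynolds_distance(f, "pop2", "pop1")
        )

    def test_drift_simulation_matches_expectation(self):
        ne, t = 100, 20
        vals = []
        for seed in range(12):
            sim = simulate(
                SimulationConfig(
                    seed=100 + seed, n_populations=2, ne_per_population=ne,
                    generations_divergence=t, n_chromosomes=2,
                    n_snps_per_chrom=400, sample_sizes=[50, 50],
                )
            )
            f = allele_frequencies(sim.genotypes)
            vals.append(reynolds_distance(f, "pop1", "pop2"))
        expected = -np.log(1 - drift_expected_fst(ne, t))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se


class TestPerSnpFst:
    def test_fixed_difference_is_one(self):
        dos = np.concatenate([np.full(50, 2), np.zeros(50)])[:, None]
        g = build_matrix(dos.astype(np.int8),
                         populations=["a"] * 50 + ["b"] * 50)
        theta = per_snp_wc_fst(g, "a", "b")
        assert theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_frequencies_nonpositive(self):
        dos = np.array([[0], [1], [2], [0], [1], [2]], dtype=np.int8)
        g = build_matrix(dos, populations=["a"] * 3 + ["b"] * 3)
        theta = per_snp_wc_fst(g, "a", "b")
        assert theta[0] <= 0

    def test_monomorphic_undefined(self):
        g = build_matrix(np.zeros((4, 1), dtype=np.int8),
                         populations=["a", "a", "b", "b"])
        assert np.isnan(per_snp_wc_fst(g, "a", "b")[0])

    def test_against_independent_formula(self):
        rng = np.random.default_rng(42)
        dos = rng.integers(0, 3, size=(30, 50), dtype=np.int8)
        g = build_matrix(dos, populations=["a"] * 14 + ["b"] * 16)
        theta = per_snp_wc_fst(g, "a", "b")
        # second, scalar implementation straight from the variance components
        for j in range(50):
            d1, d2 = dos[:14, j], dos[14:, j]
            n1, n2 = 14.0, 16.0
            p1, p2 = d1.mean() / 2, d2.mean() / 2
            h1, h2 = (d1 == 1).mean(), (d2 == 1).mean()
            r = 2
            nbar = (n1 + n2) / r
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2
            if a + b + c == 0:
                assert np.isnan(theta[j])
            else:
                assert theta[j] == pytest.approx(a / (a + b + c), abs=1e-10)


class TestMultilocusFst:
    def test_identical_populations(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, rng.uniform(0.3, 0.7, 400), size=(60, 400))
        g = build_matrix(dos.astype(np.int8), populations=["a", "b"] * 30)
        theta, lo, hi = pairwise_fst_multilocus(g, "a", "b", n_boot=200)
        assert theta <= 0.01
        assert lo <= 0 <= hi or theta <= 0

    def test_single_locus_equals_per_snp(self):
        dos = np.array([[0], [1], [2], [2], [2], [1]], dtype=np.int8)
        g = build_matrix(dos, populations=["a"] * 3 + ["b"] * 3)
        theta, _, _ = pairwise_fst_multilocus(g, "a", "b", n_boot=0)
        assert theta == pytest.approx(per_snp_wc_fst(g, "a", "b")[0])

    def test_drift_calibration(self, drift_dataset):
        theta, lo, hi = pairwise_fst_multilocus(
            drift_dataset.genotypes, "pop1", "pop2", n_boot=300
        )
        assert lo < theta < hi
        assert theta == pytest.approx(drift_expected_fst(100, 20), abs=0.03)

    def test_ci_narrows_with_more_loci(self):
        rng = np.random.default_rng(9)
        widths = []
        for m in (300, 3000):
            p0 = rng.uniform(0.2, 0.8, m)
            pa = np.clip(p0 + rng.normal(0, 0.1, m), 0.01, 0.99)
            pb = np.clip(p0 - rng.normal(0, 0.1, m), 0.01, 0.99)
            dos = np.concatenate(
                [rng.binomial(2, pa, size=(30, m)), rng.binomial(2, pb, size=(30, m))]
            ).astype(np.int8)
            g = build_matrix(dos, populations=["a"] * 30 + ["b"] * 30)
            _, lo, hi = pairwise_fst_multilocus(g, "a", "b", n_boot=200)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestZfst:
    def test_normalization(self):
        z = zfst(np.array([1.0, 2.0, 3.0, 10.0]))
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_shift_and_scale_invariance(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        np.testing.assert_allclose(zfst(x), zfst(x + 3.0), atol=1e-9)
        np.testing.assert_allclose(zfst(x), zfst(x * 7.0), atol=1e-9)

    def test_hand_fixture(self):
        x = np.array([1.0, 3.0])
        np.testing.assert_allclose(
            zfst(x), [-np.sqrt(2) / 2, np.sqrt(2) / 2], atol=1e-9
        )

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            zfst(np.array([1.0, 1.0, 1.0]))


class TestLdDecay:
    def test_single_pair_bin_equals_ld_r2(self):
        from driftscan.qc import ld_r2

        dos = np.array([[0, 0], [1, 2], [2, 2], [0, 1]], dtype=np.int8)
        g = build_matrix(dos, pos=[1000, 40_000])
        curve = ld_decay_curve(g, max_dist_bp=100_000, bin_width_bp=50_000)
        assert curve["n_pairs"].sum() == 1
        assert curve["mean_r2"].iloc[0] == pytest.approx(ld_r2(g, 0, 1))

    def test_permuted_genotypes_flat(self, drift_dataset):
        rng = np.random.default_rng(3)
        g = drift_dataset.genotypes.take_samples(
            drift_dataset.genotypes.population_index("pop1")
        )
        dos = g.dosage.copy()
        for j in range(dos.shape[1]):  # destroy LD, keep frequencies
            dos[:, j] = dos[rng.permutation(dos.shape[0]), j]
        g2 = build_matrix(dos, chrom=list(g.variants["chrom"]),
                          pos=list(g.variants["pos"]))
        curve = ld_decay_curve(g2, max_dist_bp=2_000_000, bin_width_bp=500_000)
        background = 1.0 / g2.n_samples
        assert (curve["mean_r2"].dropna() < 3 * background).all()

    def test_simulated_decay_monotone_trend(self, drift_dataset):
        curve = ld_decay_curve(
            drift_dataset.genotypes,
            max_dist_bp=5_000_000,
            bin_width_bp=500_000,
            population="pop1",
        )
        ok = curve.dropna(subset=["mean_r2"])
        rho, _ = spearmanr(ok["bin_start"], ok["mean_r2"])
        assert rho < 0

    def test_ld_at_distance_lookup(self):
        import pandas as pd

        curve = pd.DataFrame(
            {"bin_start": [1, 50_001], "bin_end": [50_000, 100_000],
             "mean_r2": [0.5, 0.25], "n_pairs": [10, 10]}
        )
        assert ld_at_distance(curve, 100_000) == 0.25


class TestDistanceMatrixProperties:
    def test_symmetric_zero_diagonal(self, drift_dataset):
        for metric in ("chord", "reynolds", "afd_mean", "fst"):
            d = distance_matrix(drift_dataset.genotypes, metric=metric)
            assert np.allclose(d, d.T, atol=1e-12)
            assert np.allclose(np.diag(d), 0)

    def test_monotone_in_divergence_time(self):
        stats = {"afd": [], "fst": [], "reynolds": []}
        for t in (5, 20, 80):
            a_vals, f_vals, r_vals = [], [], []
            for seed in range(4):
                sim = simulate(
                    SimulationConfig(
                        seed=1000 + 17 * seed + t, n_populations=2,
                        ne_per_population=100, generations_divergence=t,
                        n_chromosomes=2, n_snps_per_chrom=300,
                        sample_sizes=[40, 40],
                    )
                )
                f = allele_frequencies(sim.genotypes)
                a_vals.append(afd(f, "pop1", "pop2")[1])
                f_vals.append(
                    pairwise_fst_multilocus(sim.genotypes, "pop1", "pop2",
                                            n_boot=0)[0]
                )
                r_vals.append(reynolds_distance(f, "pop1", "pop2"))
            stats["afd"].append(np.mean(a_vals))
            stats["fst"].append(np.mean(f_vals))
            stats["reynolds"].append(np.mean(r_vals))
        for key, vals in stats.items():
            assert vals[0] < vals[1] < vals[2], key
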