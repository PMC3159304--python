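import numpy as np
import pytest
from scipy import stats as sps

from fratio import (
    FeatureDataset,
    SimulationParams,
    classical_mixed_f,
    decompose,
    eigen_contributions,
    estimate_variance_components,
    manova_f,
    simulate_dataset,
)
from fratio.manova import STATTYPES, DegenerateEffectError, _f_from_eigenvalues

from .conftest import random_dataset


def brute_force_sscp(ds):
    """Independent SSCP oracle: explicit loops over groups, conditions, subjects."""
    n = ds.n_measures
    labels = ds.group_labels
    grand = np.zeros(n)
    count = 0
    for s in ds.subjects:
        for c in ds.conditions:
            grand += [ds.value(s, c, m) for m in ds.measures]
            count += 1
    grand /= count

    H = np.zeros((n, n))
    E = np.zeros((n, n))
    for g in labels:
        members = [s for s in ds.subjects if ds.group_of[s] == g]
        gm = np.zeros(n)
        for s in members:
            for c in ds.conditions:
                gm += [ds.value(s, c, m) for m in ds.measures]
        gm /= len(members) * ds.n_conditions
        dev = gm - grand
        H += len(members) * ds.n_conditions * np.outer(dev, dev)
        for c in ds.conditions:
            cell = np.array(
                [[ds.value(s, c, m) for m in ds.measures] for s in members]
            )
            dev_cell = cell - cell.mean(axis=0)
            E += dev_cell.T @ dev_cell
    return H, E


class TestDecompose:
    def test_hand_computed_univariate_sums_of_squares(self, tiny_dataset):
        dec = decompose(tiny_dataset)
        assert dec.H[0, 0] == pytest.approx(13.5)
        assert dec.E[0, 0] == pytest.approx(4.0)
        assert dec.eigenvalues[0] == pytest.approx(3.375)
        assert dec.df_h == 1 and dec.df_e == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n_measures", [1, 2, 3])
    def test_agrees_with_brute_force_oracle(self, seed, n_measures):
        ds = random_dataset(seed, n_measures=n_measures)
        dec = decompose(ds)
        H, E = brute_force_sscp(ds)
        np.testing.assert_allclose(dec.H, H, atol=1e-10)
        np.testing.assert_allclose(dec.E, E, atol=1e-10)

    def test_trace_equals_sum_of_eigenvalues(self):
        ds = random_dataset(7, n_measures=2, subjects_per_group=8)
        dec = decompose(ds)
        trace = np.trace(dec.H @ np.linalg.inv(dec.E))
        assert abs(trace - dec.eigenvalues.sum()) < 1e-10

    def test_zero_effect_is_degenerate(self):
        ds = FeatureDataset(
            subjects=("a", "b", "c", "d"),
            groups=("g1", "g1", "g2", "g2"),
            conditions=("c1", "c2"),
            measures=("x",),
            data=np.tile([1.0, 2.0], (4, 1))[:, :, None],
        )
        dec = decompose(ds)
        assert dec.s == 0
        with pytest.raises(DegenerateEffectError):
            manova_f(dec)

    def test_location_shift_leaves_h_e_unchanged(self):
        ds = random_dataset(5, n_measures=2)
        shifted_data = ds.data.copy()
        shifted_data[:, :, 0] += 17.3
        shifted = FeatureDataset(
            ds.subjects, ds.groups, ds.conditions, ds.measures, shifted_data
        )
        d0, d1 = decompose(ds), decompose(shifted)
        np.testing.assert_allclose(d0.H, d1.H, atol=1e-9)
        np.testing.assert_allclose(d0.E, d1.E, atol=1e-9)


class TestManovaF:
    def test_hand_value_s1_all_stattypes_agree(self):
        # c=0.5, df_e=28, df_h=1: all three give 14
        for st in STATTYPES:
            assert _f_from_eigenvalues(np.array([0.5]), 1, 28, st) == pytest.approx(
                14.0, abs=1e-12
            )

    def test_pillai_hand_value_two_eigenvalues(self):
        assert _f_from_eigenvalues(np.array([1.0, 1.0]), 1, 28, "pillai") == pytest.approx(28.0)

    def test_s1_equality_on_data(self, tiny_dataset):
        dec = decompose(tiny_dataset)
        values = [manova_f(dec, st).value for st in STATTYPES]
        assert max(values) - min(values) < 1e-12

    def test_univariate_reduction(self, tiny_dataset):
        dec = decompose(tiny_dataset)
        expected = 13.5 / 4.0 * dec.df_e / dec.df_h
        for st in STATTYPES:
            assert manova_f(dec, st).value == pytest.approx(expected)


class TestEigenContributions:
    def test_reconstruction_identity(self):
        for seed in (0, 4, 9):
            ds = random_dataset(seed, n_measures=2, subjects_per_group=6)
            dec = decompose(ds)
            K = eigen_contributions(dec)
            F = dec.univariate_f()
            target = dec.eigenvalues * dec.df_e / dec.df_h
            np.testing.assert_allclose(K @ F, target, rtol=1e-10)
            assert np.all(K >= 0)

    def test_total_reconstructs_trace_of_univariate_sum(self):
        ds = random_dataset(3, n_measures=3, subjects_per_group=6)
        dec = decompose(ds)
        K = eigen_contributions(dec)
        F = dec.univariate_f()
        total = (K @ F).sum()
        assert total == pytest.approx(dec.eigenvalues.sum() * dec.df_e / dec.df_h)

    def test_diagonal_case_is_selection(self):
        # two orthogonal measures: group contrast on x only, noise-free y pattern
        rng = np.random.default_rng(0)
        S = 8
        x = np.array([0.0, 1, 2, 3, 10.0, 11, 12, 13])  # group effect on x
        y = rng.permutation(np.arange(S, dtype=float))  # same per-group mean by design
        y[:4] = [1.0, 2, 3, 4]
        y[4:] = [4.0, 3, 2, 1]  # equal group means: H diagonal with zero y-entry
        data = np.stack([x, y], axis=1)[:, None, :]
        ds = FeatureDataset(
            subjects=tuple(f"s{i}" for i in range(S)),
            groups=("g1",) * 4 + ("g2",) * 4,
            conditions=("c1",),
            measures=("x", "y"),
            data=data,
        )
        dec = decompose(ds)
        K = eigen_contributions(dec)
        # all effect mass attributed to the x measure
        assert K.shape[0] == dec.s
        assert K[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert (K[0] @ dec.univariate_f()) == pytest.approx(
            dec.eigenvalues[0] * dec.df_e / dec.df_h
        )


class TestVarianceComponents:
    def test_parameter_recovery(self):
        params = SimulationParams(subjects_per_group=100, sigma_e=1.0, sigma_p=2.0)
        ds = simulate_dataset(params, seed=0)
        vc = estimate_variance_components(ds, "x1")
        assert vc.sigma_e2 == pytest.approx(1.0, rel=0.15)
        assert vc.sigma_p2 == pytest.approx(4.0, rel=0.15)

    def test_zero_noise_gives_zero_components(self):
        params = SimulationParams(sigma_e=0.0, sigma_p=0.0)
        ds = simulate_dataset(params, seed=0)
        vc = estimate_variance_components(ds, "x1")
        assert vc.sigma_e2 == pytest.approx(0.0, abs=1e-20)
        assert vc.sigma_p2 == 0.0

    def test_negative_estimate_clamped(self):
        # no person effect: MS_subject fluctuates below MS_residual for some seeds
        params = SimulationParams(subjects_per_group=4, sigma_p=0.0)
        clamped = 0
        for seed in range(20):
            ds = simulate_dataset(params, seed=seed)
            vc = estimate_variance_components(ds, "x1")
            assert vc.sigma_p2 >= 0.0
            clamped += vc.sigma_p2 == 0.0
        assert clamped > 0

    def test_single_condition_not_separable(self):
        params = SimulationParams(k=1, condition_offsets=(0.0,))
        ds = simulate_dataset(params, seed=0)
        with pytest.raises(ValueError, match="conditions"):
            estimate_variance_components(ds, "x1")


class TestClassicalMixedF:
    def test_hand_computed_mean_squares(self):
        # 2 groups x 2 subjects, 2 conditions; subject means {1, 3} and {5, 7}
        data = np.array(
            [[0.0, 2.0], [2.0, 4.0], [4.0, 6.0], [6.0, 8.0]]
        )[:, :, None]
        ds = FeatureDataset(
            subjects=("a", "b", "c", "d"),
            groups=("g1", "g1", "g2", "g2"),
            conditions=("c1", "c2"),
            measures=("x",),
            data=data,
        )
        # subject means: 1,3,5,7; group means 2, 6; grand 4
        # SS_group = 2*(2-4)^2 + 2*(6-4)^2 = 16; MS_group = k*16/1 = 32
        # SS_within = (1-2)^2+(3-2)^2+(5-6)^2+(7-6)^2 = 4; MS_within = k*4/2 = 4
        f, p = classical_mixed_f(ds, "x")
        assert f == pytest.approx(8.0)
        assert p == pytest.approx(float(sps.f.sf(8.0, 1, 2)))

    def test_matches_anova_on_subject_means_oracle(self):
        ds = simulate_dataset(SimulationParams(), seed=21)
        f, p = classical_mixed_f(ds, "x1")
        # independent route: one-way ANOVA on per-subject condition means
        j = ds.measures.index("x1")
        means = ds.data[:, :, j].mean(axis=1)
        codes = ds.group_codes()
        f_ref, p_ref = sps.f_oneway(means[codes == 0], means[codes == 1])
        assert f == pytest.approx(float(f_ref), rel=1e-10)
        assert p == pytest.approx(float(p_ref), rel=1e-10)

    def test_type_one_calibration_uniform_p(self):
        """Under H0 the mixed-test tail probability is uniform on (0,1)."""
        params = SimulationParams()
        ps = []
        for child in np.random.SeedSequence(42).spawn(500):
            ds = simulate_dataset(params, seed=child)
            ps.append(classical_mixed_f(ds, "x1")[1])
        stat = sps.kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_power_in_strong_effect_limit(self):
        params = SimulationParams(group_effects=(0.0, 25.0))
        ds = simulate_dataset(params, seed=1)
        _, p = classical_mixed_f(ds, "x1")
        assert p < 0.001
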