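import numpy as np
import pytest

from pbmkit.core import (
    FeatureModel,
    IntensityModel,
    PositionalBias,
    predict_batch,
    view_codes,
)
from pbmkit.fitting import (
    FitConfig,
    FitState,
    fit_block,
    fit_model,
    fit_positional_bias,
    irls_fit,
    polyGC_strand_policy,
    r_squared,
)
from pbmkit.simulate import (
    SimSpec,
    gamma_profile,
    simulate_dataset,
)


def _truth_state(table, truth_model, gamma):
    codes = view_codes(table.encoded(), truth_model.L, truth_model.strand_policy)
    state = FitState(
        model=truth_model.copy(),
        bias=PositionalBias(gamma.copy()),
        im=IntensityModel(),
        weights=np.ones(len(table)),
    )
    return state, codes


class TestFitConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            FitConfig(trim_probes_frac=0.6)
        with pytest.raises(ValueError):
            FitConfig(alpha=0.0)
        with pytest.raises(ValueError):
            FitConfig(symmetry="maybe")


class TestIRLS:
    def test_clean_data_matches_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        beta = np.array([1.0, 2.0])
        y = X @ beta + rng.normal(0, 0.01, 200)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rob, w = irls_fit(X, y, FitConfig(trim_probes_frac=0.0))
        # Huber reweighting trims the Gaussian tails a little, so demand
        # agreement with plain least squares only to ~0.1%
        np.testing.assert_allclose(rob, ols, rtol=1e-3)
        plain, w0 = irls_fit(X, y, FitConfig(robust=False))
        np.testing.assert_allclose(plain, ols, atol=1e-10)
        assert np.all(w0 == 1.0)

    def test_resists_shifted_outliers(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 500)
        y = 2.0 * x + rng.normal(0, 0.01, 500)
        y[:50] += 100.0
        X = np.column_stack([np.ones(500), x])
        coef, _ = irls_fit(X, y, FitConfig())
        assert coef[1] == pytest.approx(2.0, abs=0.01)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert abs(ols[1] - 2.0) > 0.1  # plain least squares fails here

    def test_equal_residuals_keep_unit_weights(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = X @ np.array([1.0, 1.0])
        _, w = irls_fit(X, y, FitConfig())
        assert np.all(w == 1.0)

    def test_trim_count_is_exact(self):
        rng = np.random.default_rng(2)
        n = 503
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([0.5, 1.5]) + rng.normal(0, 1.0, n)
        _, w = irls_fit(X, y, FitConfig(trim_probes_frac=0.20))
        assert int((w == 0).sum()) == int(np.floor(0.20 * n))

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(50), np.arange(50.0), 2 * np.arange(50.0)])
        with pytest.raises(ValueError, match="collinear columns"):
            irls_fit(X, np.zeros(50), FitConfig())

    def test_matches_statsmodels_rlm_without_trimming(self):
        """Cross-check the Huber IRLS against the reference implementation
        in statsmodels (no hard trimming in either)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(400), rng.normal(size=400)])
        y = X @ np.array([1.0, 3.0]) + rng.standard_t(2, 400)
        ours, _ = irls_fit(X, y, FitConfig(trim_probes_frac=0.0))
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        np.testing.assert_allclose(ours, ref.params, rtol=0.05, atol=0.05)


class TestBlockFit:
    def test_truth_is_a_fixed_point(self, sym_truth):
        spec = SimSpec(
            n_probes=1500, probe_len=30, modes=[(sym_truth, 1.0)],
            noise_sd_frac=0.0, rng_seed=5,
        )
        table, _ = simulate_dataset(spec)
        gamma = gamma_profile("ramp", 30, 8)
        state, codes = _truth_state(table, sym_truth, gamma)
        before = state.model.mono.copy()
        for p in range(8):
            fit_block(p, "mono", state, codes, table.intensities, FitConfig())
        assert np.abs(state.model.mono - before).max() < 1e-6

    def test_di_truth_is_a_fixed_point(self, sym_truth):
        """With beta_PSAM at the generating scale, a di block re-fit on
        noiseless data returns the generating di values."""
        di = np.zeros((7, 16))
        di[1, 2] = 0.6
        di[5, 11] = 0.6
        truth = FeatureModel("GCACGTGC", sym_truth.mono.copy(), di)
        spec = SimSpec(
            n_probes=1500, probe_len=30, modes=[(truth, 1.0)],
            noise_sd_frac=0.0, beta0=0.0, beta1=1.0, rng_seed=13,
        )
        table, _ = simulate_dataset(spec)
        gamma = gamma_profile("ramp", 30, 8)
        state, codes = _truth_state(table, truth, gamma)
        state.beta_psam = 1.0
        before = state.model.di.copy()
        for p in range(7):
            fit_block(p, "di", state, codes, table.intensities, FitConfig())
        assert np.abs(state.model.di - before).max() < 1e-6


class TestPositionalBias:
    def test_flat_profile_recovered(self, sym_truth):
        spec = SimSpec(
            n_probes=2000, probe_len=30, modes=[(sym_truth, 1.0)],
            gamma_profile="flat", noise_sd_frac=0.01, rng_seed=6,
        )
        table, _ = simulate_dataset(spec)
        state, codes = _truth_state(
            table, sym_truth, np.ones(2 * (30 - 8 + 1))
        )
        bias = fit_positional_bias(state, codes, table.intensities, FitConfig())
        assert np.all(bias.gamma > 0.95) and np.all(bias.gamma <= 1.0)

    def test_ramp_profile_recovered(self, sym_truth):
        spec = SimSpec(
            n_probes=2000, probe_len=30, modes=[(sym_truth, 1.0)],
            gamma_profile="ramp", noise_sd_frac=0.01, rng_seed=7,
        )
        table, _ = simulate_dataset(spec)
        g_true = gamma_profile("ramp", 30, 8)
        state, codes = _truth_state(table, sym_truth, np.ones_like(g_true))
        bias = fit_positional_bias(state, codes, table.intensities, FitConfig())
        r = np.corrcoef(bias.gamma, g_true)[0, 1]
        assert r >= 0.95

    def test_too_few_probes_raises(self, sym_truth):
        spec = SimSpec(
            n_probes=20, probe_len=30, modes=[(sym_truth, 1.0)], rng_seed=8,
        )
        table, _ = simulate_dataset(spec)
        state, codes = _truth_state(
            table, sym_truth, np.ones(2 * (30 - 8 + 1))
        )
        with pytest.raises(ValueError, match="fewer probes than views"):
            fit_positional_bias(state, codes, table.intensities, FitConfig())


class TestNonlinear:
    def test_nested_fit_never_much_worse_than_linear(self, sym_truth):
        spec = SimSpec(
            n_probes=1500, probe_len=30, modes=[(sym_truth, 1.0)],
            noise_sd_frac=0.05, rng_seed=9,
        )
        table, _ = simulate_dataset(spec)
        lin = fit_model(table, FitConfig(), seed_kmer="GCACGTGC")
        sat = fit_model(table, FitConfig(saturation=True), seed_kmer="GCACGTGC")
        y, enc = table.intensities, table.encoded()
        r2_lin = r_squared(y, predict_batch(enc, lin.model, lin.bias.gamma, lin.im))
        r2_sat = r_squared(y, predict_batch(enc, sat.model, sat.bias.gamma, sat.im))
        assert r2_sat >= r2_lin - 0.01

    def test_strong_saturation_needs_the_saturating_model(self, sym_truth):
        spec = SimSpec(
            n_probes=2000, probe_len=30, modes=[(sym_truth, 1.0)],
            noise_sd_frac=0.02, saturating=True, protein_scale=100.0,
            ddG_ns=6.0, beta0=50.0, beta1=1000.0, rng_seed=10,
        )
        table, _ = simulate_dataset(spec)
        lin = fit_model(table, FitConfig(), seed_kmer="GCACGTGC")
        sat = fit_model(table, FitConfig(saturation=True), seed_kmer="GCACGTGC")
        y, enc = table.intensities, table.encoded()
        r2_lin = r_squared(y, predict_batch(enc, lin.model, lin.bias.gamma, lin.im))
        r2_sat = r_squared(y, predict_batch(enc, sat.model, sat.bias.gamma, sat.im))
        assert r2_sat >= r2_lin + 0.05


class TestFitModel:
    def test_recovery_with_fixed_seed(self, small_fit, sym_truth):
        st = small_fit
        assert st.model.reference_seq == sym_truth.reference_seq
        r = np.corrcoef(st.model.mono.ravel(), sym_truth.mono.ravel())[0, 1]
        assert r >= 0.95

    def test_monotone_training_objective(self, small_fit):
        """The trimmed mean squared residual is non-increasing over the
        mono rounds (within numerical tolerance)."""
        tmse = [h["trimmed_mse"] for h in small_fit.history if h["phase"] == "mono"]
        assert len(tmse) >= 2
        for a, b in zip(tmse, tmse[1:]):
            assert b <= a * 1.01 + 1e-9

    def test_weights_trim_count(self, small_fit, small_sim):
        table, _ = small_sim
        n = len(table)
        assert int((small_fit.weights == 0).sum()) == int(np.floor(0.20 * n))

    def test_robust_beats_ols_under_outliers(self, sym_truth):
        spec = SimSpec(
            n_probes=1200, probe_len=30, modes=[(sym_truth, 1.0)],
            noise_sd_frac=0.05, outlier_frac=0.10, rng_seed=11,
        )
        table, _ = simulate_dataset(spec)
        rob = fit_model(table, FitConfig(), seed_kmer="GCACGTGC")
        ols = fit_model(table, FitConfig(robust=False), seed_kmer="GCACGTGC")
        rmse = lambda st: np.sqrt(((st.model.mono - sym_truth.mono) ** 2).mean())
        assert rmse(rob) < rmse(ols)

    def test_di_blocks_never_decrease_training_r2(self, sym_truth):
        spec = SimSpec(
            n_probes=1200, probe_len=30, modes=[(sym_truth, 1.0)],
            noise_sd_frac=0.05, rng_seed=12,
        )
        table, _ = simulate_dataset(spec)
        mono = fit_model(table, FitConfig(), seed_kmer="GCACGTGC")
        fsam = fit_model(
            table, FitConfig(include_di=True), seed_kmer="GCACGTGC"
        )
        y, enc = table.intensities, table.encoded()
        r2_mono = r_squared(
            y, predict_batch(enc, mono.model, mono.bias.gamma, mono.im)
        )
        r2_fsam = r_squared(
            y, predict_batch(enc, fsam.model, fsam.bias.gamma, fsam.im)
        )
        assert r2_fsam >= r2_mono - 1e-6

    def test_polygc_rule_applied_at_seed(self):
        assert polyGC_strand_policy("ACCCCACG") == "forward_only"
        assert polyGC_strand_policy("AGGGGACG") == "reverse_only"
        assert polyGC_strand_policy("GCACGTGC") == "both"
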