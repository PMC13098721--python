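import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smfretsim import (
    BurstConfig,
    ExperimentModel,
    RatePath,
    SpringModelSpec,
    preset_config,
    run_experiment,
    sample_transfer_time,
    sample_transfer_times,
    sample_transfer_times_thinning,
    simulate_burst,
    simulate_excitation,
)
from smfretsim.photon_engine import simulate_excitations


def frozen_spring_model(separation=5.0, k=0.05):
    """Both dyes pinned at their anchors (sigma = 0)."""
    spring = SpringModelSpec.isotropic(k=k, sigma=0.0)
    return ExperimentModel(
        kind="iso_spring",
        attach_A=np.array([0.0, 0.0, separation]),
        spring_D=spring,
        spring_A=spring,
    )


def sawtooth_path(k_max=1.2, t_max=12.0, n=600):
    t = np.linspace(0.0, t_max, n)
    k = k_max * np.abs((t % 4.0) - 2.0) / 2.0
    return RatePath(t, np.full_like(t, 2 / 3), k)


class TestTransferTimeSamplers:
    def test_constant_rate_is_exponential(self, rng):
        c = 0.25
        path = RatePath.constant(c, 60.0)
        draws = sample_transfer_times(path, 100_000, rng)
        finite = draws[np.isfinite(draws)]
        assert len(finite) > 99_000
        p = stats.kstest(finite, stats.expon(scale=1 / c).cdf).pvalue
        assert p > 0.01

    def test_zero_rate_always_censored(self, rng):
        path = RatePath.constant(0.0, 50.0)
        draws = sample_transfer_times(path, 1000, rng)
        assert np.all(np.isinf(draws))

    def test_scalar_api(self):
        path = RatePath.constant(1.0, 50.0)
        t = sample_transfer_time(path, seed=0)
        assert 0 < t < 50.0

    def test_sawtooth_inversion_matches_thinning(self, rng):
        path = sawtooth_path()
        a = sample_transfer_times(path, 100_000, rng)
        b = sample_transfer_times_thinning(path, 100_000, rng)
        cens_a, cens_b = np.isinf(a).mean(), np.isinf(b).mean()
        assert abs(cens_a - cens_b) < 3 * np.sqrt(cens_a * (1 - cens_a) / 100_000) + 1e-4
        p = stats.ks_2samp(a[np.isfinite(a)], b[np.isfinite(b)]).pvalue
        assert p > 0.01


class TestSimulateExcitation:
    def test_at_r0_static_acceptor_probability_half(self, params, rng):
        t = np.linspace(0, 40.0, 400)
        r = np.full_like(t, params.R0_iso)
        k2 = np.full_like(t, 2 / 3)
        n = 100_000
        outcomes, _ = simulate_excitations(t, k2, r, params, n, seed=rng,
                                           kappa2_mode="static")
        frac = (outcomes == 1).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_no_transfer_donor_delays_exponential(self, params, rng):
        t = np.linspace(0, 40.0, 400)
        r = np.full_like(t, 100.0)  # k_ET ~ 0
        k2 = np.full_like(t, 2 / 3)
        outcomes, delays = simulate_excitations(t, k2, r, params, 50_000, seed=rng,
                                                kappa2_mode="static")
        assert (outcomes == 0).mean() > 0.999
        p = stats.kstest(delays[outcomes == 0],
                         stats.expon(scale=params.tau_D0).cdf).pvalue
        assert p > 0.01

    def test_competing_exponentials_closed_form(self, params, rng):
        # constant k_ET = k_D: donor delays ~ Exp(2 k_D), acceptor fraction 1/2
        t = np.linspace(0, 40.0, 400)
        r = np.full_like(t, params.R0_iso)
        k2 = np.full_like(t, 2 / 3)
        n = 100_000
        outcomes, delays = simulate_excitations(t, k2, r, params, n, seed=rng,
                                                kappa2_mode="static")
        don = delays[outcomes == 0]
        p = stats.kstest(don, stats.expon(scale=1 / (2 * params.k_D)).cdf).pvalue
        assert p > 0.01
        assert abs((outcomes == 1).mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_scalar_event_fields(self, params):
        t = np.linspace(0, 40.0, 400)
        r = np.full_like(t, 3.0)  # strong transfer
        k2 = np.full_like(t, 2 / 3)
        ev = simulate_excitation(t, k2, r, params, seed=1, kappa2_mode="static")
        assert ev.outcome in ("donor_photon", "acceptor_photon", "censored")
        if ev.outcome == "acceptor_photon":
            assert ev.transfer_time is not None and ev.delay > ev.transfer_time


class TestSimulateBurst:
    def test_static_everything_on_static_line(self, params):
        cfg = BurstConfig(n_excitations=800, eff_donor=1.0, eff_acceptor=1.0)
        table = run_experiment(frozen_spring_model(), "static", 60, params, cfg, seed=5)
        # E -> 0.5 and tau_norm -> 0.5 at r = R0
        assert table.E_I.mean() == pytest.approx(0.5, abs=0.01)
        assert table.tau_norm.mean() == pytest.approx(0.5, abs=0.01)

    def test_zero_detection_all_excluded(self, params):
        cfg = BurstConfig(n_excitations=50, eff_donor=0.0, eff_acceptor=0.0)
        table = run_experiment(frozen_spring_model(), "static", 10, params, cfg, seed=1)
        assert table.excluded.all()

    def test_determinism_same_master_seed(self, params):
        model = preset_config("pendulum_dynamic").experiment_model()
        cfg = BurstConfig(n_excitations=60)
        t1 = run_experiment(model, "dynamic", 8, params, cfg, seed=33)
        t2 = run_experiment(model, "dynamic", 8, params, cfg, seed=33)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_burst_api_and_photons(self, params):
        cfg = BurstConfig(n_excitations=200, eff_donor=1.0, eff_acceptor=1.0)
        summary, photons = simulate_burst(frozen_spring_model(), params, cfg,
                                          seed=2, kappa2_mode="static")
        assert summary.I_D + summary.I_A + summary.n_censored == 200
        assert (photons.delay_ns > 0).all()
        assert summary.I_D == int(
            ((photons.channel == "donor") & photons.detected).sum()
        )

    def test_burst_reproducible_in_isolation(self, params):
        # burst b of an n-burst run equals the same burst re-run alone
        model = frozen_spring_model()
        cfg = BurstConfig(n_excitations=100)
        full = run_experiment(model, "static", 5, params, cfg, seed=77)
        from smfretsim.photon_engine import _burst_seeds

        seeds = _burst_seeds(77, 5)
        # re-running with a single-burst seed array is not public API; check
        # instead that prefix runs agree burst-by-burst
        prefix = run_experiment(model, "static", 3, params, cfg, seed=77)
        pd.testing.assert_frame_equal(full.iloc[:3].reset_index(drop=True), prefix)
        assert len(np.unique(seeds)) == 5


class TestRunExperiment:
    def test_row_count_and_no_exclusions_at_full_detection(self, params):
        cfg = BurstConfig(n_excitations=60, eff_donor=1.0, eff_acceptor=1.0)
        model = preset_config("iso_spring").experiment_model()
        table = run_experiment(model, "static", 100, params, cfg, seed=3)
        assert len(table) == 100
        assert not table.excluded.any()

    def test_shot_noise_variance_shrinks_with_photons(self, params):
        # frozen distance: per-burst E_I variance is binomial, ~1/n
        model = frozen_spring_model()
        var = {}
        for n_exc in (100, 400):
            cfg = BurstConfig(n_excitations=n_exc, eff_donor=1.0, eff_acceptor=1.0)
            t = run_experiment(model, "static", 300, params, cfg, seed=8)
            var[n_exc] = t.E_I.var()
        ratio = var[100] / var[400]
        assert 2.5 < ratio < 6.0

    def test_mean_kappa2_two_thirds_dynamic(self, params):
        model = preset_config("pendulum_dynamic").experiment_model()
        cfg = BurstConfig(n_excitations=150)
        t = run_experiment(model, "dynamic", 60, params, cfg, seed=4)
        se = t.mean_kappa2.std() / np.sqrt(len(t))
        assert abs(t.mean_kappa2.mean() - 2 / 3) < max(4 * se, 0.02)

    def test_static_mode_reports_isotropic_kappa2(self, params):
        cfg = BurstConfig(n_excitations=20)
        t = run_experiment(frozen_spring_model(), "static", 5, params, cfg, seed=1)
        np.testing.assert_allclose(t.mean_kappa2, 2 / 3)

    def test_invalid_mode_rejected(self, params):
        with pytest.raises(ValueError, match="kappa2_mode"):
            run_experiment(frozen_spring_model(), "both", 5, params, seed=1)
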