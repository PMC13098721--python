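import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfretsim import (
    BurstConfig,
    TwoStateSpec,
    dynamic_shift,
    moment_difference,
    moment_static_reference,
    shift_distribution,
    two_state_reference,
)
from smfretsim.shift_analysis import moment_hat, moment_shift_distance


def make_table(E, tau):
    E = np.asarray(E, float)
    return pd.DataFrame(
        {
            "burst_id": np.arange(len(E)),
            "I_D": 50,
            "I_A": 50,
            "E_I": E,
            "tau_norm": np.asarray(tau, float),
            "mean_kappa2": 2 / 3,
            "n_excitations": 100,
            "n_censored": 0,
            "excluded": False,
        }
    )


class TestDynamicShift:
    def test_on_static_line(self):
        assert dynamic_shift(0.3, 0.7) == pytest.approx(0.0, abs=1e-12)
        assert dynamic_shift(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_corner_value(self):
        assert dynamic_shift(1.0, 1.0) == pytest.approx(1 / math.sqrt(2))

    def test_origin_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            dynamic_shift(0.0, 0.0)
        out = dynamic_shift(np.array([0.0, 0.5]), np.array([0.0, 0.5]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.0)

    def test_sign_convention(self):
        assert dynamic_shift(0.6, 0.6) > 0  # E + tau > 1
        assert dynamic_shift(0.4, 0.4) < 0  # E + tau < 1

    @settings(max_examples=200, deadline=None)
    @given(E=st.floats(0.001, 0.999))
    def test_exactly_zero_on_line_property(self, E):
        assert abs(dynamic_shift(E, 1.0 - E)) < 1e-12

    def test_bounded_away_from_origin(self, rng):
        # |delta| <= 1/sqrt(2) in the unit square away from the origin;
        # below the static line the normalization diverges as (E, tau) -> 0
        E = rng.uniform(0.0, 1.0, 10_000)
        tau = rng.uniform(0.0, 1.0, 10_000)
        away = (E**2 + tau**2 >= 0.5) | (E + tau >= 1.0)
        d = dynamic_shift(E[away], tau[away])
        assert np.all(np.abs(d) <= 1 / math.sqrt(2) + 1e-9)


class TestShiftDistribution:
    def test_all_on_line_gives_zero(self, rng):
        E = rng.uniform(0.1, 0.9, 50)
        res = shift_distribution(make_table(E, 1 - E))
        assert res.mu_delta == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_delta == pytest.approx(0.0, abs=1e-12)

    def test_known_deltas_arithmetic_oracle(self):
        pts = [(0.5, 0.7), (0.6, 0.6), (0.2, 0.5)]
        deltas = [(e + t - 1) / math.hypot(e, t) for e, t in pts]
        res = shift_distribution(make_table([p[0] for p in pts], [p[1] for p in pts]))
        assert res.mu_delta == pytest.approx(np.mean(deltas))
        assert res.sigma_delta == pytest.approx(np.std(deltas, ddof=1))

    def test_too_few_bursts(self):
        with pytest.raises(ValueError, match="at least 2"):
            shift_distribution(make_table([0.5], [0.5]))

    def test_excluded_bursts_ignored(self):
        t = make_table([0.5, 0.5, 0.9], [0.5, 0.5, 0.9])
        t.loc[2, "excluded"] = True
        res = shift_distribution(t)
        assert res.n_bursts == 2
        assert res.mu_delta == pytest.approx(0.0, abs=1e-12)


class TestMomentDifference:
    def test_hand_built_delays(self):
        # normalized delays {0.5, 1.5}: m = mean(d) - mean(d^2)/2
        assert moment_hat([0.5, 1.5]) == pytest.approx(1.0 - 1.25 / 2)

    def test_static_reference_curve(self):
        assert moment_static_reference(0.3) == pytest.approx(0.21)

    def test_static_bursts_on_reference(self, params):
        # frozen r = R0, static kappa2: delays ~ Exp(2 k_D); m -> 0.25 = E(1-E)
        rng = np.random.default_rng(0)
        rows, photons = [], []
        for b in range(40):
            n = 600
            ia = rng.binomial(n, 0.5)
            d = rng.exponential(scale=1 / (2 * params.k_D), size=n - ia)
            rows.append({"burst_id": b, "I_D": n - ia, "I_A": ia,
                         "E_I": ia / n, "tau_norm": d.mean() / params.tau_D0,
                         "mean_kappa2": 2 / 3, "n_excitations": n,
                         "n_censored": 0, "excluded": False})
            photons.append(pd.DataFrame({
                "burst_id": b, "channel": "donor", "delay_ns": d, "detected": True}))
        table = pd.DataFrame(rows)
        ph = pd.concat(photons, ignore_index=True)
        md = moment_difference(table, ph, params)
        resid = md.m_hat - moment_static_reference(md.E_I)
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(resid))

    def test_two_state_mixing_falls_below_reference(self, params):
        # fast-switching mixture of lifetimes at matched E
        rng = np.random.default_rng(1)
        taus = np.array([0.2, 0.8]) * params.tau_D0
        rows, photons = [], []
        for b in range(40):
            n = 400
            which = rng.random(n) < 0.5
            d = rng.exponential(scale=np.where(which, taus[0], taus[1]))
            E = 1 - d.mean() / params.tau_D0
            rows.append({"burst_id": b, "I_D": n, "I_A": 0, "E_I": E,
                         "tau_norm": d.mean() / params.tau_D0,
                         "mean_kappa2": 2 / 3, "n_excitations": n,
                         "n_censored": 0, "excluded": False})
            photons.append(pd.DataFrame({
                "burst_id": b, "channel": "donor", "delay_ns": d, "detected": True}))
        md = moment_difference(pd.DataFrame(rows), pd.concat(photons), params)
        resid = md.m_hat - moment_static_reference(md.E_I)
        assert resid.mean() < 0
        assert (resid < 0).mean() > 0.9

    def test_insufficient_photons_skipped(self, params):
        table = make_table([0.5, 0.5], [0.5, 0.5])
        ph = pd.DataFrame({"burst_id": [0, 0, 1], "channel": "donor",
                           "delay_ns": [1.0, 2.0, 1.5], "detected": True})
        md = moment_difference(table, ph, params)
        assert list(md.burst_id) == [0]

    def test_signed_distance_to_curve(self):
        E = 0.5
        above = moment_shift_distance(E, moment_static_reference(E) + 0.05)
        below = moment_shift_distance(E, moment_static_reference(E) - 0.05)
        assert above > 0 > below
        assert moment_shift_distance(E, moment_static_reference(E)) == pytest.approx(
            0.0, abs=1e-6
        )


class TestTwoStateReference:
    def test_validation(self):
        with pytest.raises(ValueError, match="E1"):
            TwoStateSpec(E1=0.0, E2=0.5, lam=1.0)
        with pytest.raises(ValueError, match="lam"):
            TwoStateSpec(E1=0.3, E2=0.5, lam=-1.0)

    def test_rates_match_static_efficiencies(self, params):
        spec = TwoStateSpec(E1=0.25, E2=0.8, lam=0.0)
        k1, k2 = spec.rates(params)
        assert k1 / (k1 + params.k_D) == pytest.approx(0.25)
        assert k2 / (k2 + params.k_D) == pytest.approx(0.8)

    def test_frozen_states_two_clusters_each_on_line(self, params):
        cfg = BurstConfig(n_excitations=600, eff_donor=1.0, eff_acceptor=1.0)
        table = two_state_reference(TwoStateSpec(0.3, 0.8, lam=0.0), 120,
                                    params=params, burst_cfg=cfg, seed=0)
        lo = table[table.E_I < 0.55]
        hi = table[table.E_I >= 0.55]
        assert len(lo) > 30 and len(hi) > 30
        assert lo.E_I.mean() == pytest.approx(0.3, abs=0.02)
        assert hi.E_I.mean() == pytest.approx(0.8, abs=0.02)
        for cluster in (lo, hi):
            res = shift_distribution(cluster)
            assert abs(res.mu_delta) < 0.02

    def test_equal_states_stay_on_line_any_lambda(self, params):
        cfg = BurstConfig(n_excitations=500, eff_donor=1.0, eff_acceptor=1.0)
        for lam in (0.0, 0.05):
            table = two_state_reference(TwoStateSpec(0.5, 0.5, lam=lam), 60,
                                        params=params, burst_cfg=cfg, seed=1)
            res = shift_distribution(table)
            assert abs(res.mu_delta) < 0.02

    def test_fast_switching_single_cluster_positive_shift(self, params):
        cfg = BurstConfig(n_excitations=400, eff_donor=1.0, eff_acceptor=1.0)
        table = two_state_reference(TwoStateSpec(0.3, 0.8, lam=0.05), 80,
                                    params=params, burst_cfg=cfg, seed=2)
        res = shift_distribution(table)
        assert res.mu_delta > 0.1
        assert table.E_I.std() < 0.1  # single cluster, not two
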