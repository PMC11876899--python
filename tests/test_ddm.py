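import math

import numpy as np
import pytest

from lagddm.ddm import (
    DDMParams,
    LatencySchedule,
    OptionPair,
    STATUSES,
    VARIANTS,
    drift_rate,
    effective_params,
    params_from_vector,
    params_to_dict,
    simulate_trial,
    simulate_trial_distribution,
)

V2 = VARIANTS[2]


class TestVariants:
    def test_free_param_counts(self):
        assert {v.variant_id: v.n_free_params for v in VARIANTS.values()} == {
            1: 9,
            2: 8,
            3: 10,
            4: 12,
        }

    def test_vector_round_trip(self, v2_params):
        vec = np.array([params_to_dict(v2_params, V2)[k] for k in V2.slot_names])
        p = params_from_vector(vec, V2)
        assert params_to_dict(p, V2) == pytest.approx(params_to_dict(v2_params, V2))


class TestEffectiveParams:
    def test_variant2_status_lookup(self, v2_params):
        ws, wo, rst = effective_params(v2_params, V2, "better")
        assert (ws, wo, rst) == (0.08, 0.05, 0.5)

    def test_variant1_rst_always_zero(self):
        p = DDMParams(
            omega_s={s: 0.1 for s in STATUSES},
            omega_o={s: 0.05 for s in STATUSES},
            rst=0.0,
            threshold=1.0,
            ndt=0.3,
            bias=0.0,
        )
        for s in STATUSES:
            assert effective_params(p, VARIANTS[1], s)[2] == 0.0

    def test_variant4_all_slots_differ(self):
        p = DDMParams(
            omega_s={"better": 0.1, "equal": 0.2, "worse": 0.3},
            omega_o={"better": 0.01, "equal": 0.02, "worse": 0.03},
            rst={"better": 0.5, "equal": 0.0, "worse": -0.5},
            threshold=1.0,
            ndt=0.3,
            bias=0.0,
        )
        b = effective_params(p, VARIANTS[4], "better")
        w = effective_params(p, VARIANTS[4], "worse")
        assert all(x != y for x, y in zip(b, w))

    def test_missing_status_slot_fails(self):
        p = DDMParams(
            omega_s=0.1, omega_o=0.05, rst={"better": 0.5},
            threshold=1.0, ndt=0.3, bias=0.0,
        )
        with pytest.raises(KeyError, match="worse"):
            effective_params(p, V2, "worse")

    def test_unknown_status_rejected(self, v2_params):
        with pytest.raises(ValueError):
            effective_params(v2_params, V2, "Better ")


class TestLatencySchedule:
    def test_positive_rst_delays_other(self):
        s = LatencySchedule.from_rst(0.5, 0.01)
        assert s.entry_step_s == 0 and s.entry_step_o == 50

    def test_negative_rst_delays_self(self):
        s = LatencySchedule.from_rst(-0.3, 0.01)
        assert s.entry_step_s == 30 and s.entry_step_o == 0

    def test_zero_rst_synchronous(self):
        s = LatencySchedule.from_rst(0.0, 0.01)
        assert s.entry_step_s == 0 and s.entry_step_o == 0
        assert s.gate_s(0) == s.gate_o(0) == 1

    def test_one_entry_always_zero(self):
        for rst in (-1.2, -0.01, 0.0, 0.01, 1.7):
            s = LatencySchedule.from_rst(rst, 0.01)
            assert min(s.entry_step_s, s.entry_step_o) == 0


class TestDriftRate:
    def test_direct_substitution(self):
        pair = OptionPair(ms1=15, mo1=6, ms2=5, mo2=10)  # dms=10, dmo=-4
        s = LatencySchedule.from_rst(0.0, 0.01)
        nu = drift_rate(0.01, 0.005, s, pair, step=0)
        assert nu == pytest.approx(0.1 - 0.02)

    def test_gated_before_entry(self):
        pair = OptionPair(ms1=15, mo1=6, ms2=5, mo2=10)
        s = LatencySchedule.from_rst(0.5, 0.01)
        assert drift_rate(0.01, 0.005, s, pair, 10) == pytest.approx(0.1)
        assert drift_rate(0.01, 0.005, s, pair, 50) == pytest.approx(0.08)

    def test_constant_when_synchronous(self):
        pair = OptionPair(ms1=15, mo1=6, ms2=5, mo2=10)
        s = LatencySchedule.from_rst(0.0, 0.01)
        vals = {drift_rate(0.01, 0.005, s, pair, t) for t in range(100)}
        assert len(vals) == 1

    def test_negative_step_rejected(self, option_pair):
        with pytest.raises(ValueError):
            drift_rate(0.1, 0.1, LatencySchedule.from_rst(0, 0.01), option_pair, -1)


class TestParamValidation:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(omega_s=float("nan"), omega_o=0.0, rst=0.0,
                      threshold=1.0, ndt=0.3, bias=0.0)

    def test_bias_bound(self):
        with pytest.raises(ValueError):
            DDMParams(omega_s=0.1, omega_o=0.0, rst=0.0,
                      threshold=1.0, ndt=0.3, bias=1.0)

    def test_threshold_positive(self):
        with pytest.raises(ValueError):
            DDMParams(omega_s=0.1, omega_o=0.0, rst=0.0,
                      threshold=0.0, ndt=0.3, bias=0.0)


def _constant_drift_params(nu, threshold, bias=0.0):
    # dms == 1 via the pair below, so omega_s is the drift directly
    return DDMParams(omega_s=nu, omega_o=0.0, rst=0.0,
                     threshold=threshold, ndt=0.0, bias=bias)


PAIR_UNIT_DMS = OptionPair(ms1=2, mo1=10, ms2=1, mo2=10)


class TestSimulateTrial:
    def test_driftless_symmetric(self):
        p = _constant_drift_params(0.0, 1.0)
        rng = np.random.default_rng(0)
        batch = simulate_trial_distribution(p, V2, "equal", PAIR_UNIT_DMS, 20_000, rng, t_max=30.0)
        ok = batch.choices >= 0
        phat = np.mean(batch.choices[ok] == 1)
        assert abs(phat - 0.5) <= 3 * math.sqrt(0.25 / ok.sum())

    @pytest.mark.parametrize("nu,threshold", [(0.1, 1.0), (-0.08, 1.2), (0.05, 1.5)])
    def test_closed_form_absorption(self, nu, threshold):
        """Discrete walk matches Brownian 1/(1+exp(-2*nu*B/sigma_c^2))."""
        p = _constant_drift_params(nu, threshold)
        rng = np.random.default_rng(99)
        n = 20_000
        batch = simulate_trial_distribution(p, V2, "equal", PAIR_UNIT_DMS, n, rng, t_max=40.0)
        sigma_c2 = p.sigma**2 / p.dt
        pred = 1.0 / (1.0 + math.exp(-2 * nu * threshold / sigma_c2))
        phat = np.mean(batch.choices == 1)
        se = math.sqrt(pred * (1 - pred) / n)
        assert abs(phat - pred) <= 3.5 * se

    def test_bias_at_threshold_immediate_upper(self):
        p = _constant_drift_params(0.0, 1.0, bias=0.999)
        rng = np.random.default_rng(1)
        batch = simulate_trial_distribution(p, V2, "equal", PAIR_UNIT_DMS, 2000, rng)
        assert np.mean(batch.choices == 1) > 0.9
        assert np.nanmean(batch.rts) < 0.3  # a handful of steps at most

    def test_rt_at_least_ndt(self, v2_params, option_pair):
        rng = np.random.default_rng(2)
        for _ in range(50):
            out = simulate_trial(v2_params, V2, "equal", option_pair, rng)
            if not out.censored:
                assert out.rt >= v2_params.ndt

    def test_evidence_path_invariant(self, v2_params, option_pair):
        rng = np.random.default_rng(3)
        out, path = simulate_trial(v2_params, V2, "worse", option_pair, rng, return_path=True)
        if not out.censored:
            assert np.all(np.abs(path.evidence[:-1]) < v2_params.threshold)
            assert abs(path.evidence[-1]) >= v2_params.threshold

    def test_nonfinite_param_fails_before_sim(self, option_pair):
        p = DDMParams(omega_s=0.1, omega_o=0.0, rst=0.0, threshold=1.0, ndt=0.3, bias=0.0)
        object.__setattr__(p, "omega_s", float("inf"))
        with pytest.raises((ValueError, OverflowError)):
            simulate_trial(p, V2, "equal", option_pair, np.random.default_rng(0))


class TestSimulateDistribution:
    def test_n_outcomes_and_censoring_accounting(self, v2_params, option_pair):
        rng = np.random.default_rng(4)
        batch = simulate_trial_distribution(v2_params, V2, "equal", option_pair, 3000, rng)
        assert batch.n == 3000
        ok = batch.choices >= 0
        assert np.mean(batch.choices[ok] == 1) + np.mean(batch.choices[ok] == 0) == pytest.approx(1.0)
        assert batch.censored_fraction == pytest.approx(1 - ok.mean())

    def test_determinism_same_seed(self, v2_params, option_pair):
        b1 = simulate_trial_distribution(
            v2_params, V2, "worse", option_pair, 500, np.random.default_rng(7)
        )
        b2 = simulate_trial_distribution(
            v2_params, V2, "worse", option_pair, 500, np.random.default_rng(7)
        )
        assert np.array_equal(b1.choices, b2.choices)
        assert np.array_equal(b1.rts, b2.rts, equal_nan=True)

    def test_choice_monotone_in_dmo(self):
        """Larger other-payoff difference -> lower P(choose larger-Ms option)."""
        p = DDMParams(omega_s=0.05, omega_o=0.05, rst=0.0, threshold=1.0, ndt=0.3, bias=0.0)
        lo = OptionPair(ms1=10, mo1=5, ms2=5, mo2=10)   # dmo = -5
        hi = OptionPair(ms1=10, mo1=12, ms2=5, mo2=4)   # dmo = +8
        p_lo = np.mean(
            simulate_trial_distribution(p, V2, "equal", lo, 50_000, np.random.default_rng(8)).choices == 1
        )
        p_hi = np.mean(
            simulate_trial_distribution(p, V2, "equal", hi, 50_000, np.random.default_rng(9)).choices == 1
        )
        assert p_hi > p_lo

    def test_censored_fraction_vanishes_with_small_threshold(self, option_pair):
        rng = np.random.default_rng(10)
        p = DDMParams(omega_s=0.0, omega_o=0.0, rst=0.0, threshold=0.15, ndt=0.1, bias=0.0)
        batch = simulate_trial_distribution(p, V2, "equal", option_pair, 2000, rng)
        assert batch.censored_fraction == 0.0


class TestLagEffects:
    """Qualitative onset-lag signatures on the simulated distributions."""

    def _sim(self, rst, n=30_000, seed=0):
        p = DDMParams(omega_s=0.06, omega_o=0.08, rst=rst, threshold=1.0, ndt=0.2, bias=0.0)
        pair = OptionPair(ms1=12, mo1=14, ms2=6, mo2=4)  # dmo = +10 favours upper
        return simulate_trial_distribution(
            p, V2, "equal", pair, n, np.random.default_rng(seed)
        )

    def test_rt_shifts_right_with_lag(self):
        b0 = self._sim(0.0)
        b1 = self._sim(1.0)
        assert np.nanmean(b1.rts) > np.nanmean(b0.rts)

    def test_choice_moves_away_from_late_attribute(self):
        # with dmo > 0 favouring upper, delaying dmo lowers P(upper)
        b0 = self._sim(0.0)
        b1 = self._sim(1.0)
        assert np.mean(b1.choices == 1) < np.mean(b0.choices == 1)

    def test_early_choices_independent_of_late_attribute(self):
        """Choices resolved before the late attribute's entry carry no dmo
        information: logistic beta for dmo on that subset is ~0."""
        import statsmodels.api as sm

        p = DDMParams(omega_s=0.08, omega_o=0.08, rst=0.6, threshold=1.0, ndt=0.2, bias=0.0)
        rng = np.random.default_rng(42)
        rows = []
        pairs = [
            OptionPair(int(ms1), int(mo1), int(ms2), int(mo2))
            for ms1, mo1, ms2, mo2 in zip(
                rng.integers(8, 21, 60), rng.integers(1, 21, 60),
                rng.integers(1, 8, 60), rng.integers(1, 21, 60),
            )
        ]
        for pair in pairs:
            b = simulate_trial_distribution(p, V2, "equal", pair, 300, rng)
            early = (b.rts - p.ndt < 0.6) & (b.choices >= 0)
            for c in b.choices[early]:
                rows.append((pair.delta_ms, pair.delta_mo, c))
        arr = np.array(rows, dtype=float)
        X = sm.add_constant(arr[:, :2])
        fit = sm.GLM(arr[:, 2], X, family=sm.families.Binomial()).fit()
        # dmo has not entered yet: |z| small
        assert abs(fit.tvalues[2]) < 2.5
        assert fit.tvalues[1] > 2.5  # dms is driving early choices
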