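"""Global double-exponential analysis of incubation-chase dissociation data."""

import warnings

import numpy as np
import pytest

from rnpkinetics import (
    BoundFractionSeries,
    CoupledExperiment,
    ValidationError,
    closed_form_dilution_response,
    disentangle_rates,
    estimate_kcat,
    fit_amplitude_decay,
    global_double_exp_fit,
    model_selection,
    pre_dilution_state,
)
from rnpkinetics.reaction_scheme import RateSet
from rnpkinetics.synthetic_data import (
    NoiseSpec,
    ScenarioTruth,
    make_coupled_experiment,
)
from rnpkinetics.units import minutes, uM


def noiseless_experiment(rates, T_grid=None):
    truth = ScenarioTruth(
        rates=rates, T_grid=tuple(T_grid or (minutes(x) for x in (5, 62, 121, 177, 231, 293)))
    )
    return make_coupled_experiment(truth, NoiseSpec(sigma=0.0))


class TestGlobalDoubleExpFit:
    def test_single_exponential_limit_when_no_conversion(self):
        """kcat = 0: no fast component ever develops; the shared slow rate
        equals the generating koff_S and fast amplitudes stay ~0."""
        rates = RateSet(koff_S=1.2e-3, kcat=0.0, koff_P=6.4e-3, Kd_P=0.32e-6)
        t = np.arange(30.0, 3600.0, 30.0)
        series = []
        for _ in range(3):
            p = 0.95 * np.exp(-1.2e-3 * t)
            series.append(BoundFractionSeries(t, p, kind="dissociation"))
        exp = CoupledExperiment(
            T=[minutes(5), minutes(60), minutes(120)], series=series,
            CS=uM(2), CE=uM(6),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = global_double_exp_fit(exp)
        assert abs(res.k2 - 1.2e-3) / 1.2e-3 < 0.01
        assert all(a <= 0.02 for a in res.A1)

    def test_noiseless_exact_model_recovers_fast_rate(self, slow_complex_rates):
        """Fit on data from the exact 3-term solution: the fitted fast rate
        approaches koff_P to within the conversion-flux approximation error."""
        exp = noiseless_experiment(slow_complex_rates)
        res = global_double_exp_fit(exp)
        r = slow_complex_rates
        flux = r.kcat / (r.koff_P - r.kcat - r.koff_S)  # ~0.033
        assert abs(res.k1 - r.koff_P) / r.koff_P < flux
        assert abs(res.k2 - (r.kcat + r.koff_S)) / (r.kcat + r.koff_S) < flux

    def test_amplitude_complementarity_noiseless(self, slow_complex_rates):
        """A1(T) + A2(T) reproduces the pre-dilution bound fraction p(0)."""
        exp = noiseless_experiment(slow_complex_rates)
        res = global_double_exp_fit(exp)
        r = slow_complex_rates
        for T, a1, a2 in zip(exp.T, res.A1, res.A2):
            fS0, fPb, _ = pre_dilution_state(uM(2), uM(6), r.Kd_P, r.kcat, T)
            assert abs((a1 + a2) - (fS0 + fPb)) < 1e-6

    def test_rate_consistency_across_T_subsets(self, slow_complex_rates):
        """Any pair of incubation times yields the same shared rates on
        noiseless data."""
        exp = noiseless_experiment(slow_complex_rates)
        res_all = global_double_exp_fit(exp)
        sub = CoupledExperiment(
            T=exp.T[:2], series=exp.series[:2], CS=exp.CS, CE=exp.CE
        )
        res_sub = global_double_exp_fit(sub)
        assert abs(res_sub.k1 - res_all.k1) / res_all.k1 < 0.02
        assert abs(res_sub.k2 - res_all.k2) / res_all.k2 < 0.02

    def test_requires_two_incubation_times(self, slow_complex_rates):
        exp = noiseless_experiment(slow_complex_rates)
        with pytest.raises(ValidationError):
            CoupledExperiment(T=exp.T[:1], series=exp.series[:1],
                              CS=exp.CS, CE=exp.CE)


class TestFitAmplitudeDecay:
    def test_noiseless_recovery_both_components(self):
        kcat = 1.9e-4
        T = np.array([minutes(x) for x in (5, 62, 121, 177, 231, 293)])
        slow = 0.97 * np.exp(-kcat * T)
        fast = 0.91 * (1 - np.exp(-kcat * T))
        f_slow = fit_amplitude_decay(T, slow, "slow")
        f_fast = fit_amplitude_decay(T, fast, "fast")
        assert abs(f_slow["kcat"] - kcat) / kcat < 1e-6
        assert abs(f_fast["kcat"] - kcat) / kcat < 1e-6
        # the two parameterizations are symmetric on clean data
        assert f_slow["kcat"] == pytest.approx(f_fast["kcat"], rel=1e-6)

    def test_non_monotone_amplitudes_warn(self):
        T = np.array([100.0, 200.0, 300.0, 400.0])
        with pytest.warns(UserWarning, match="not monotonically"):
            fit_amplitude_decay(T, np.array([0.9, 0.2, 0.8, 0.1]), "slow")

    def test_estimate_kcat_mean_and_sd(self, slow_complex_rates):
        exp = noiseless_experiment(slow_complex_rates)
        res = estimate_kcat(global_double_exp_fit(exp))
        assert res.kcat is not None and res.kcat_sd is not None
        assert abs(res.kcat - slow_complex_rates.kcat) / slow_complex_rates.kcat < 0.10


class TestModelSelection:
    def test_nested_ssr_ordering_holds(self, rng):
        """SSR(double) <= SSR(single) on arbitrary inputs: the single model
        is nested in the double one and the fit is seeded from it."""
        t = np.arange(30.0, 3000.0, 30.0)
        for seed in range(5):
            g = np.random.default_rng(seed)
            p = 0.8 * np.exp(-2e-3 * t) + g.normal(0, 0.02, t.size)
            sel = model_selection(BoundFractionSeries(t, p, kind="dissociation"))
            assert sel["ssr_double"] <= sel["ssr_single"] + 1e-12

    def test_type_I_error_controlled_under_null(self):
        """Pure single-exponential truth: the F-test rejects at alpha = 0.05
        in about 5% of seeds (<= 6 of 50 allowed as binomial slack)."""
        t = np.arange(30.0, 3000.0, 60.0)
        rejections = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            p = 0.9 * np.exp(-1.5e-3 * t) + g.normal(0, 0.02, t.size)
            sel = model_selection(BoundFractionSeries(t, p, kind="dissociation"))
            rejections += sel["prefer_double"]
        assert rejections <= 6

    def test_double_preferred_on_mid_incubation_chase(self, slow_complex_rates):
        """The 62 min incubation chase carries a genuine fast component:
        the double model wins in >= 90% of seeds."""
        r = slow_complex_rates
        fS0, fPb, _ = pre_dilution_state(uM(2), uM(6), r.Kd_P, r.kcat, minutes(62))
        t = np.arange(30.0, 5400.0, 30.0)
        resp = closed_form_dilution_response(r, fS0, fPb, t)
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            p = resp.exact + g.normal(0, 0.02, t.size)
            sel = model_selection(BoundFractionSeries(t, p, kind="dissociation"))
            wins += sel["prefer_double"]
        assert wins >= 0.9 * n_seeds


class TestDisentangleRates:
    def test_tabulated_rates_recovered(self):
        class R:
            k1, k2, k1_sd, k2_sd = 6.4e-3, 0.64e-3, 1e-4, 2e-5

        result = _mk_result(6.4e-3, 0.64e-3)
        rates, sd = disentangle_rates(result, kcat=0.19e-3, kcat_sd=5e-5)
        assert rates.koff_P == 6.4e-3
        assert rates.koff_S == pytest.approx(0.45e-3, rel=1e-12)
        assert sd["koff_S"] == pytest.approx(np.hypot(result.k2_sd, 5e-5), rel=1e-12)

    def test_zero_kcat_passthrough(self):
        result = _mk_result(6.4e-3, 0.64e-3)
        rates, _ = disentangle_rates(result, kcat=0.0)
        assert rates.koff_S == result.k2

    def test_inconsistent_kcat_rejected(self):
        result = _mk_result(6.4e-3, 0.64e-3)
        with pytest.raises(ValidationError, match="inconsistent"):
            disentangle_rates(result, kcat=1e-3)


def _mk_result(k1, k2):
    from rnpkinetics.coupled_kinetics import CoupledFitResult

    return CoupledFitResult(
        k1=k1, k2=k2, k1_sd=1e-4, k2_sd=2e-5,
        T=[300.0, 3720.0], A1=[0.1, 0.4], A2=[0.8, 0.5],
        ssr=0.0, converged=True,
    )


class TestFullRecovery:
    def test_full_pipeline_recovery_small(self, slow_complex_rates):
        """Generate -> global fit -> amplitude fits -> disentangle at the
        tabulated truth, 3 noisy seeds: every rate lands within tolerance
        of its generating value (the 20-seed study runs in the acceptance
        suite)."""
        truth = ScenarioTruth(rates=slow_complex_rates)
        k1s, k2s, kcats = [], [], []
        for seed in range(3):
            exp = make_coupled_experiment(truth, NoiseSpec(sigma=0.02, seed=seed))
            res = estimate_kcat(global_double_exp_fit(exp))
            k1s.append(res.k1)
            k2s.append(res.k2)
            kcats.append(res.kcat)
        r = slow_complex_rates
        assert abs(np.median(k1s) - r.koff_P) / r.koff_P < 0.15
        assert abs(np.median(kcats) - r.kcat) / r.kcat < 0.25
        koff_S = np.median(k2s) - np.median(kcats)
        assert abs(koff_S - r.koff_S) / r.koff_S < 0.25
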