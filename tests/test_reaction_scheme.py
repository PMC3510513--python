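"""Forward simulator, closed-form dilution response and equilibrium isotherm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnpkinetics import (
    LinearScheme,
    RateSet,
    ValidationError,
    closed_form_dilution_response,
    equilibrium_occupancy,
    pre_dilution_state,
    simulate_association,
    simulate_dilution,
    simulate_linear_scheme,
)
from rnpkinetics.reaction_scheme import dilution_scheme

from conftest import bisect_bound_concentration


class TestSimulateLinearScheme:
    def test_two_state_matches_closed_form(self):
        k = 0.013
        scheme = LinearScheme(["A", "B"], {("A", "B"): k}, {"A": 1.0})
        t = np.array([1.0, 10.0, math.log(2) / k, 500.0])
        traj = simulate_linear_scheme(scheme, t)
        np.testing.assert_allclose(traj["A"], np.exp(-k * t), atol=1e-8)
        assert abs(traj["A"][2] - 0.5) < 1e-8

    def test_occupancies_sum_to_one(self):
        scheme = LinearScheme(
            ["A", "B", "C"], {("A", "B"): 0.1, ("B", "C"): 0.02, ("B", "A"): 0.05},
            {"A": 0.7, "B": 0.3},
        )
        traj = simulate_linear_scheme(scheme, np.linspace(1, 200, 40))
        total = sum(traj.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-8)

    def test_decoupled_limit_kcat_zero(self):
        """With no conversion, ES and EP decay independently single-exponentially."""
        rates = RateSet(koff_S=1.2e-2, kcat=0.0, koff_P=5e-3)
        scheme = dilution_scheme(rates)
        scheme.initial = {"ES": 0.6, "EP": 0.4}
        t = np.array([10.0, 100.0, 400.0])
        traj = simulate_linear_scheme(scheme, t)
        np.testing.assert_allclose(traj["ES"], 0.6 * np.exp(-1.2e-2 * t), atol=1e-8)
        np.testing.assert_allclose(traj["EP"], 0.4 * np.exp(-5e-3 * t), atol=1e-8)

    def test_rejects_negative_rate_naming_transition(self):
        with pytest.raises(ValidationError, match="A->B"):
            LinearScheme(["A", "B"], {("A", "B"): -1.0}, {"A": 1.0})

    def test_rejects_unknown_state_and_bad_occupancy(self):
        with pytest.raises(ValidationError, match="unknown state"):
            LinearScheme(["A"], {("A", "Z"): 1.0}, {"A": 1.0})
        with pytest.raises(ValidationError, match="sum to 1"):
            LinearScheme(["A", "B"], {("A", "B"): 1.0}, {"A": 0.5})

    def test_rejects_nonmonotone_times(self):
        scheme = LinearScheme(["A", "B"], {("A", "B"): 1.0}, {"A": 1.0})
        with pytest.raises(ValidationError):
            simulate_linear_scheme(scheme, [1.0, 0.5])


class TestClosedFormDilutionResponse:
    def test_no_conversion_reduces_to_single_exponential(self):
        rates = RateSet(koff_S=1.2e-2, kcat=0.0, koff_P=5e-3)
        t = np.linspace(0, 600, 50)
        resp = closed_form_dilution_response(rates, 0.8, 0.0, t)
        np.testing.assert_allclose(resp.exact, 0.8 * np.exp(-1.2e-2 * t), rtol=1e-12)
        np.testing.assert_allclose(resp.exact, resp.approx, rtol=1e-12)
        assert resp.max_deviation < 1e-15

    def test_exact_matches_ode_oracle(self, slow_complex_rates):
        t = np.array([0.0, 100.0, 1000.0, 5000.0])
        resp = closed_form_dilution_response(slow_complex_rates, 1.0, 0.0, t)
        scheme = dilution_scheme(slow_complex_rates)
        traj = simulate_linear_scheme(scheme, t)
        np.testing.assert_allclose(traj["ES"] + traj["EP"], resp.exact, atol=1e-8)

    def test_two_term_approximation_error_is_small(self, slow_complex_rates):
        """Conversion is slow relative to the rate gap, so the two-exponential
        reading deviates little from the exact solution over a 90 min chase."""
        t = np.arange(0.0, 5400.0, 30.0)
        resp = closed_form_dilution_response(slow_complex_rates, 1.0, 0.0, t)
        r = slow_complex_rates
        flux_ratio = r.kcat / (r.koff_P - r.kcat - r.koff_S)
        assert resp.max_deviation <= 2 * flux_ratio * 1.0
        assert resp.max_deviation < 0.1  # small relative to p(0) = 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        koff_S=st.floats(1e-5, 1e-2),
        kcat=st.floats(0.0, 1e-2),
        koff_P=st.floats(1e-5, 5e-2),
        fS0=st.floats(0.0, 1.0),
    )
    def test_oracle_equivalence_random_rates(self, koff_S, kcat, koff_P, fS0):
        """Closed form equals numeric ODE integration for random rate sets."""
        if abs(koff_P - kcat - koff_S) < 1e-6 * max(koff_P, kcat + koff_S, 1e-12):
            return  # distinct eigenvalues only; the confluent case is tested below
        rates = RateSet(koff_S=koff_S, kcat=kcat, koff_P=koff_P)
        fP0 = (1.0 - fS0) * 0.5
        t = np.linspace(0.0, 3.0 / max(min(koff_P, kcat + koff_S), 1e-5), 20)
        resp = closed_form_dilution_response(rates, fS0, fP0, t)
        scheme = dilution_scheme(rates)
        scheme.initial = {"ES": fS0, "EP": fP0, "S_free": 1.0 - fS0 - fP0}
        traj = simulate_linear_scheme(scheme, t[1:])
        np.testing.assert_allclose(
            traj["ES"] + traj["EP"], resp.exact[1:], atol=1e-8
        )

    def test_degenerate_eigenvalues_use_confluent_form(self):
        rates = RateSet(koff_S=2e-3, kcat=1e-3, koff_P=3e-3)  # koff_P = kcat+koff_S
        t = np.linspace(0, 2000, 30)
        resp = closed_form_dilution_response(rates, 0.9, 0.05, t)
        assert resp.degenerate
        scheme = dilution_scheme(rates)
        scheme.initial = {"ES": 0.9, "EP": 0.05, "S_free": 0.05}
        traj = simulate_linear_scheme(scheme, t[1:])
        np.testing.assert_allclose(traj["ES"] + traj["EP"], resp.exact[1:], atol=1e-8)

    def test_rejects_bad_fractions(self, slow_complex_rates):
        with pytest.raises(ValidationError):
            closed_form_dilution_response(slow_complex_rates, 0.8, 0.4, [0.0, 1.0])


class TestPreDilutionState:
    def test_zero_incubation_is_all_substrate(self):
        assert pre_dilution_state(2e-6, 6e-6, 0.32e-6, 1.9e-4, 0.0) == (1.0, 0.0, 0.0)

    def test_infinite_incubation_fully_converted(self):
        fS0, fPb, fPf = pre_dilution_state(2e-6, 6e-6, 0.32e-6, 1.9e-4, 1e9)
        assert fS0 == 0.0
        expected = equilibrium_occupancy(2e-6, 6e-6, 0.32e-6)
        assert abs(fPb - expected) < 1e-12
        assert abs(fS0 + fPb + fPf - 1.0) < 1e-12

    def test_partition_matches_bisection_oracle(self):
        """62 min incubation of the 2 uM / 6 uM pre-dilution mix."""
        CS, CE, Kd, kcat, T = 2e-6, 6e-6, 0.32e-6, 1.9e-4, 62 * 60.0
        fS0, fPb, fPf = pre_dilution_state(CS, CE, Kd, kcat, T)
        assert abs(fS0 - math.exp(-kcat * T)) < 1e-15
        CP = CS * (1.0 - fS0)
        bound = bisect_bound_concentration(CP, CE - CS * fS0, Kd)
        assert abs(fPb - bound / CS) < 1e-10
        assert abs(fS0 + fPb + fPf - 1.0) < 1e-12


class TestEquilibriumOccupancy:
    def test_limits(self):
        assert equilibrium_occupancy(1e-8, 0.0, 1e-7) == 0.0
        # stoichiometric (Kd = 0) limit
        assert abs(equilibrium_occupancy(1e-8, 4e-9, 0.0) - 0.4) < 1e-12
        assert equilibrium_occupancy(1e-8, 2e-8, 0.0) == 1.0

    def test_matches_bisection_oracle_on_grid(self):
        grid = np.geomspace(1e-9, 1e-5, 7)
        for CS in grid:
            for CE in grid:
                for Kd in grid:
                    p = equilibrium_occupancy(CS, CE, Kd)
                    x = bisect_bound_concentration(CS, CE, Kd)
                    assert abs(p - x / CS) < 1e-10

    def test_example_at_tabulated_affinity(self):
        p = equilibrium_occupancy(10e-9, 31e-9, 31e-9)
        x = bisect_bound_concentration(10e-9, 31e-9, 31e-9)
        assert abs(p - x / 10e-9) < 1e-10

    def test_monotone_in_CE_and_Kd(self):
        ces = np.geomspace(1e-9, 1e-5, 40)
        ps = [equilibrium_occupancy(1e-8, ce, 5e-8) for ce in ces]
        assert np.all(np.diff(ps) >= -1e-14)
        kds = np.geomspace(1e-9, 1e-5, 40)
        ps = [equilibrium_occupancy(1e-8, 1e-7, kd) for kd in kds]
        assert np.all(np.diff(ps) <= 1e-14)

    def test_hyperbolic_limit_at_trace_ligand(self):
        Kd = 1e-7
        CS = Kd / 100.0
        for CE in np.geomspace(1e-8, 1e-5, 10):
            p = equilibrium_occupancy(CS, CE, Kd)
            assert abs(p - CE / (CE + Kd)) <= 0.01 * (CE / (CE + Kd))


class TestSimulateAssociation:
    def test_irreversible_saturates(self):
        t = np.linspace(1, 5000, 60)
        p = simulate_association(1e-8, 1e-6, 2.7e4, 0.0, t)
        assert p[-1] > 0.999

    def test_starts_unbound(self):
        p = simulate_association(1e-8, 5e-7, 2.7e4, 1.2e-2, np.array([0.0, 10.0]))
        assert p[0] == 0.0

    def test_pseudo_first_order_rate(self):
        """Under enzyme excess the ODE trajectory is single-exponential with
        kobs = kon*CE + koff to within 2%."""
        CS, CE, kon, koff = 1e-8, 5e-7, 2.7e4, 1.2e-2
        t = np.arange(5.0, 600.0, 5.0)
        p = simulate_association(CS, CE, kon, koff, t)
        from rnpkinetics import BoundFractionSeries, fit_association

        fit = fit_association(BoundFractionSeries(t, p, CE, CS, "association"))
        kobs_expected = kon * CE + koff
        assert abs(fit["kobs"] - kobs_expected) / kobs_expected < 0.02

    def test_converges_to_equilibrium_occupancy(self):
        CS, CE, kon, koff = 1e-8, 1e-7, 2.7e4, 1.2e-2
        t = np.array([1.0, 10.0, 20.0 / (kon * CE + koff) * 10])
        p = simulate_association(CS, CE, kon, koff, t)
        assert abs(p[-1] - equilibrium_occupancy(CS, CE, koff / kon)) < 1e-7


class TestSimulateDilution:
    def test_mass_conservation(self, slow_complex_rates):
        t = np.linspace(1, 5000, 50)
        CS, CE = 0.5e-9, 1.5e-9
        traj = simulate_dilution(
            slow_complex_rates, 0.5, 0.45, 0.05, CS, CE, t,
            include_reassociation=False,
        )
        rna = traj["S_free"] + traj["ES"] + traj["P_free"] + traj["EP"]
        enz = traj["E_free"] + traj["ES"] + traj["EP"]
        np.testing.assert_allclose(rna, CS, rtol=1e-8)
        np.testing.assert_allclose(enz, CE, rtol=1e-8)

    def test_reassociation_negligible_at_subnanomolar(self, slow_complex_rates):
        """The linear treatment is justified at the 4000-fold diluted
        concentrations: switching re-association on shifts p(t) by only a
        few percent (kon*CE ~ 4e-5 s^-1, an order below the slowest
        dissociation rate)."""
        rates = RateSet(
            kon=2.7e4, koff_S=slow_complex_rates.koff_S,
            kcat=slow_complex_rates.kcat, koff_P=slow_complex_rates.koff_P,
            Kd_P=slow_complex_rates.Kd_P,
        )
        t = np.linspace(1, 5000, 50)
        off = simulate_dilution(rates, 0.6, 0.3, 0.1, 0.5e-9, 1.5e-9, t, False)
        on = simulate_dilution(rates, 0.6, 0.3, 0.1, 0.5e-9, 1.5e-9, t, True)
        assert np.max(np.abs(on["p_bound"] - off["p_bound"])) < 0.05
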