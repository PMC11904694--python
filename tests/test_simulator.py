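"""ODE right-hand side, integration accuracy and pathway-rate analysis."""

import numpy as np
import pytest

from kinwfi.reaction_network import (
    ArrheniusParams,
    ElementaryStep,
    KineticModel,
    Species,
    borderline_model,
)
from kinwfi.simulator import (
    Conditions,
    TimeCourse,
    build_rate_equations,
    pathway_rates,
    pathway_rates_at,
    read_timecourses,
    simulate,
    simulate_concentrations,
    write_timecourses,
)


def _single_step_model(k, reactants, products, species):
    return KineticModel(
        name="custom",
        species=[Species(n, observable=True) for n in species],
        steps=[
            ElementaryStep(reactants, products, ArrheniusParams(A=k, Ea=0.0), "only")
        ],
    )


class TestRateEquations:
    def test_first_order_decay_rhs(self):
        model = _single_step_model(0.3, {"A": 1}, {"B": 1}, ["A", "B"])
        rhs = build_rate_equations(model)
        dc = rhs(0.0, np.array([2.0, 0.0]), 300.0)
        np.testing.assert_allclose(dc, [-0.6, 0.6], rtol=1e-12)

    def test_bimolecular_mass_action_rhs(self):
        model = _single_step_model(0.5, {"1": 1, "BnBr": 1}, {"2": 1}, ["1", "BnBr", "2"])
        rhs = build_rate_equations(model)
        dc = rhs(0.0, np.array([0.4, 0.3, 0.0]), 300.0)
        np.testing.assert_allclose(dc, [-0.06, -0.06, 0.06], rtol=1e-12)

    def test_borderline_rhs_matches_per_step_loop_oracle(self):
        """Vectorized RHS equals a naive per-step flux summation."""
        model = borderline_model()
        rhs = build_rate_equations(model)
        rng = np.random.default_rng(42)
        T = 310.0
        for _ in range(5):
            c = rng.uniform(0.0, 0.5, size=len(model.species))
            state = dict(zip(model.species_names, c))
            expected = {name: 0.0 for name in model.species_names}
            for step in model.steps:
                rate = step.rate_params.k(T)
                for name, nu in step.reactants.items():
                    rate *= state[name] ** nu
                for name in model.species_names:
                    expected[name] += step.net_stoichiometry(name) * rate
            np.testing.assert_allclose(
                rhs(0.0, c, T),
                [expected[n] for n in model.species_names],
                rtol=1e-12,
            )

    def test_analytic_jacobian_matches_finite_differences(self):
        model = borderline_model()
        rhs = build_rate_equations(model)
        c = np.array([0.3, 0.4, 0.1, 0.05, 1e-6])
        T = 313.0
        J = rhs.jacobian(0.0, c, T)
        h = 1e-7
        for i in range(c.size):
            dc = c.copy()
            dc[i] += h
            col = (rhs(0.0, dc, T) - rhs(0.0, c, T)) / h
            np.testing.assert_allclose(J[:, i], col, rtol=1e-4, atol=1e-8)


class TestSimulate:
    def test_zero_rates_keep_initial_values(self):
        model = borderline_model(
            {s.label: ArrheniusParams(0.0, 0.0) for s in borderline_model().steps}
        )
        cond = Conditions({"1": 0.2, "BnBr": 0.3}, 25.0, 100.0)
        tc = simulate(model, cond, [1, 10, 100])
        np.testing.assert_allclose(tc.yields["1"], 1.0, rtol=1e-10)
        np.testing.assert_allclose(tc.yields["2"], 0.0, atol=1e-12)

    def test_second_order_equal_concentrations_closed_form(self):
        # A + B -> P with [A]0 = [B]0: 1/[A] = 1/[A]0 + k t
        k, a0 = 0.05, 0.4
        model = _single_step_model(k, {"A": 1, "B": 1}, {"P": 1}, ["A", "B", "P"])
        cond = Conditions({"A": a0, "B": a0}, 25.0, 60.0)
        times = np.array([0.5, 1, 2, 5, 10, 30, 60])
        _, conc = simulate_concentrations(model, cond, times)
        expected = 1.0 / (1.0 / a0 + k * times * 60.0)
        np.testing.assert_allclose(conc["A"], expected, rtol=1e-6)

    def test_pseudo_first_order_limit(self):
        # large excess of B: [A] decays as exp(-k [B]0 t); the limit error
        # scales with [A]0/[B]0, so 1e4 equivalents reach 1e-4 agreement
        k, a0, b0 = 2e-3, 1e-4, 1.0
        model = _single_step_model(k, {"A": 1, "B": 1}, {"P": 1}, ["A", "B", "P"])
        cond = Conditions({"A": a0, "B": b0}, 25.0, 30.0)
        times = np.array([0.5, 1, 2, 5, 10, 30])
        _, conc = simulate_concentrations(model, cond, times, atol=1e-12)
        yield_p = conc["P"] / a0
        expected = 1.0 - np.exp(-k * b0 * times * 60.0)
        np.testing.assert_allclose(yield_p, expected, rtol=1e-4, atol=1e-4)

    def test_times_outside_duration_rejected(self):
        cond = Conditions({"1": 0.3, "BnBr": 0.3}, 25.0, 10.0)
        with pytest.raises(ValueError, match=r"\[0, 10"):
            simulate(borderline_model(), cond, [1, 20])

    def test_unknown_initial_species_rejected(self):
        cond = Conditions({"1": 0.3, "XX": 0.3}, 25.0, 10.0)
        with pytest.raises(ValueError, match="XX"):
            simulate(borderline_model(), cond, [1, 2])

    def test_tolerance_convergence(self):
        """Tightening integrator tolerances 10x barely changes the yields."""
        model = borderline_model()
        cond = Conditions({"1": 0.344, "BnBr": 0.344 * 1.2}, 40.0, 256.0)
        times = [1, 4, 16, 64, 256]
        a = simulate(model, cond, times, rtol=1e-8, atol=1e-10)
        b = simulate(model, cond, times, rtol=1e-9, atol=1e-11)
        for sp in a.species:
            np.testing.assert_allclose(a.yields[sp], b.yields[sp], atol=1e-6)

    def test_nonnegative_yields(self):
        model = borderline_model()
        cond = Conditions({"1": 0.344, "BnBr": 0.344 * 1.4}, 20.0, 512.0)
        tc = simulate(model, cond, [1, 8, 64, 512])
        for y in tc.yields.values():
            assert (y >= 0).all()

    def test_constant_profile_equals_flat_piecewise_profile(self):
        model = borderline_model()
        times = [1, 4, 16, 64]
        c1 = Conditions({"1": 0.344, "BnBr": 0.413}, 40.0, 64.0)
        c2 = Conditions({"1": 0.344, "BnBr": 0.413}, [(0.0, 40.0), (64.0, 40.0)], 64.0)
        a, b = simulate(model, c1, times), simulate(model, c2, times)
        for sp in a.species:
            np.testing.assert_allclose(a.yields[sp], b.yields[sp], rtol=1e-7, atol=1e-9)

    def test_ramp_profile_lies_between_isothermal_extremes(self):
        model = borderline_model()
        times = [1, 4, 16, 64]
        ramp = Conditions({"1": 0.344, "BnBr": 0.413}, [(0.0, 20.0), (64.0, 50.0)], 64.0)
        cold = Conditions({"1": 0.344, "BnBr": 0.413}, 20.0, 64.0)
        hot = Conditions({"1": 0.344, "BnBr": 0.413}, 50.0, 64.0)
        y_ramp = simulate(model, ramp, times).yields["1"]
        y_cold = simulate(model, cold, times).yields["1"]
        y_hot = simulate(model, hot, times).yields["1"]
        assert ((y_hot - 1e-9 <= y_ramp) & (y_ramp <= y_cold + 1e-9)).all()


class TestPathwayRates:
    state = {"1": 0.3, "2": 0.05, "di-2": 0.0, "BnBr": 0.35, "BnCation": 0.0}

    def test_zero_ionization_gives_zero_ratio(self):
        model = borderline_model({"ionization": ArrheniusParams(0.0, 0.0)})
        pr = pathway_rates(model, self.state, 313.15)
        assert pr.defined and pr.ratio == 0.0

    def test_equal_branch_rates_give_unit_ratio(self):
        # constructed so k_ion = k_sn2 * [1]: rates match exactly
        k_sn2 = 1e-3
        model = borderline_model(
            {
                "sn2_mono": ArrheniusParams(k_sn2, 0.0),
                "ionization": ArrheniusParams(k_sn2 * self.state["1"], 0.0),
            }
        )
        pr = pathway_rates(model, self.state, 298.15)
        assert pr.ratio == pytest.approx(1.0, rel=1e-12)

    def test_both_rates_zero_flagged_not_nan_raised(self):
        model = borderline_model(
            {
                "sn2_mono": ArrheniusParams(0.0, 0.0),
                "ionization": ArrheniusParams(0.0, 0.0),
            }
        )
        pr = pathway_rates(model, self.state, 298.15)
        assert not pr.defined

    def test_ratio_monotone_in_temperature_with_higher_sn2_ea(self):
        """SN1/SN2 rate ratio falls with T when the SN2 branch has higher Ea."""
        model = borderline_model()  # default params: Ea(sn2) > Ea(ion)
        ratios = [
            pathway_rates(model, self.state, T).ratio
            for T in np.linspace(273.15, 352.15, 15)
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_rates_along_trajectory(self):
        model = borderline_model()
        cond = Conditions({"1": 0.344, "BnBr": 0.344 * 1.1}, 40.0, 60.0)
        pr = pathway_rates_at(model, cond, t_min=10.0)
        assert pr.defined and pr.sn1_rate > 0 and pr.sn2_rate > 0


class TestTimeCourseIO:
    def _course(self):
        return TimeCourse(
            times_min=np.array([1.0, 2.0, 4.0]),
            yields={"1": np.array([0.9, 0.8, 0.6]), "2": np.array([0.1, 0.2, 0.4])},
            source="experimental",
            temps_C=np.array([40.0, 40.1, 39.9]),
        )

    def test_roundtrip_is_idempotent(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_timecourses({"e1": self._course()}, p1)
        back = read_timecourses(p1)
        write_timecourses(back, p2)
        assert p1.read_text() == p2.read_text()

    def test_roundtrip_preserves_values(self, tmp_path):
        p = tmp_path / "a.csv"
        tc = self._course()
        write_timecourses({"e1": tc}, p)
        back = read_timecourses(p)["e1"]
        np.testing.assert_allclose(back.times_min, tc.times_min)
        for sp in tc.yields:
            np.testing.assert_allclose(back.yields[sp], tc.yields[sp], rtol=1e-12)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("experiment_id,time_min,species\ne1,1,1\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_timecourses(p)

    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeCourse(times_min=np.array([1.0, 1.0]), yields={"1": np.array([0.5, 0.5])})
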