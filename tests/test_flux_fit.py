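import numpy as np
import pytest
from scipy.stats import chi2

from emuflux.atom_network import FluxVector, InfeasibleConstraintsError
from emuflux.emu import InputLabeling
from emuflux.flux_fit import (
    ConfidenceInterval,
    FitResult,
    PrecursorDemand,
    build_constraints,
    chi_square_threshold,
    compare_ci,
    fit_fluxes,
    goodness_of_fit,
    grid_search_ci,
    objective_rss,
)
from emuflux.measurements import FragmentDef, MeasuredMID
from emuflux.rates import SpecificRates
from emuflux.synthetic import make_scenario, precursor_demand, simulate_measurements

TABLE_RATES = SpecificRates(
    mu=0.46, mu_se=0.01,
    rates={"glucose": 5.9, "acetate": 2.7, "succinate": 0.2},
    rate_se={"glucose": 0.7, "acetate": 0.6, "succinate": 0.1})


def cmp_model(toy_cmp, scenario, **kwargs):
    return build_constraints(
        toy_cmp, TABLE_RATES, precursor_demand("TOY_CMP"),
        analyte_map=scenario.analyte_map, fragments=scenario.fragments,
        labeling=scenario.labeling, **kwargs)


def exact_cmp_model(toy_cmp, scenario, **kwargs):
    """Constraints pinned to the scenario's exact ground-truth values."""
    truth = scenario.true_fluxes.net
    return build_constraints(
        toy_cmp, fixed={"upt": truth["upt"], "ova": truth["ova"],
                        "bm_b": truth["bm_b"]},
        fragments=scenario.fragments, labeling=scenario.labeling, **kwargs)


class TestBuildConstraints:
    def test_measured_uptake_is_pinned(self, toy_cmp, cmp_scenario):
        model = cmp_model(toy_cmp, cmp_scenario)
        assert model.constraints["upt"] == pytest.approx(5.9)
        assert model.constraints["ova"] == pytest.approx(2.7)
        # biomass efflux = demand coefficient (2.0) * mu (0.46)
        assert model.constraints["bm_b"] == pytest.approx(0.92)

    def test_unmapped_trace_analyte_is_ignored(self, toy_cmp, cmp_scenario):
        model = cmp_model(toy_cmp, cmp_scenario)
        assert "succinate" not in model.constraints

    def test_toy1_zero_demand_is_feasible(self, toy1, toy1_scenario):
        model = build_constraints(
            toy1, fixed={"upt": 1.0}, fragments=toy1_scenario.fragments,
            labeling=toy1_scenario.labeling)
        _, slack = model.chebyshev_center()
        assert slack > 0

    def test_missing_analyte_mapping_raises(self, toy_cmp, cmp_scenario):
        with pytest.raises(KeyError, match="pyruvate"):
            build_constraints(toy_cmp, TABLE_RATES,
                              analyte_map={"pyruvate": "upt"},
                              fragments=cmp_scenario.fragments,
                              labeling=cmp_scenario.labeling)

    def test_carbon_balance_violation_is_infeasible(self, toy_cmp,
                                                    cmp_scenario):
        # acetate secretion cannot exceed the carbon supplied by uptake
        with pytest.raises(InfeasibleConstraintsError):
            build_constraints(toy_cmp,
                              fixed={"upt": 5.9, "ova": 20.0},
                              fragments=cmp_scenario.fragments,
                              labeling=cmp_scenario.labeling)


class TestObjective:
    def test_zero_noise_gives_zero_rss_at_truth(self, toy_cmp):
        sc = make_scenario("TOY_CMP", mid_sd=0.0)
        mids, _ = simulate_measurements(sc, seed=0)
        model = exact_cmp_model(toy_cmp, sc)
        assert objective_rss(model, sc.true_fluxes, mids) == pytest.approx(
            0.0, abs=1e-12)

    def test_one_channel_off_by_one_sd_gives_rss_one(self, toy_cmp):
        sc = make_scenario("TOY_CMP", mid_sd=0.0)
        mids, _ = simulate_measurements(sc, seed=0)
        mids[0].sd[:] = 0.003
        mids[0].fractions[0] += 0.003  # exactly one SD on one channel
        model = exact_cmp_model(toy_cmp, sc)
        assert objective_rss(model, sc.true_fluxes, mids) == pytest.approx(
            1.0, abs=1e-9)

    def test_unweighted_mode(self, toy_cmp):
        sc = make_scenario("TOY_CMP", mid_sd=0.0)
        mids, _ = simulate_measurements(sc, seed=0)
        mids[0].fractions[0] += 0.01
        model = exact_cmp_model(toy_cmp, sc, weighted=False)
        assert objective_rss(model, sc.true_fluxes, mids) == pytest.approx(
            1e-4, abs=1e-10)


class TestFitFluxes:
    def test_noiseless_toy1_recovers_branch_split(self, toy1, toy1_scenario):
        sc = make_scenario("TOY1", mid_sd=0.0)
        mids, _ = simulate_measurements(sc, seed=0)
        model = build_constraints(
            toy1, fixed={"upt": 10.0}, fragments=sc.fragments,
            labeling=sc.labeling)
        fit = fit_fluxes(model, mids, n_starts=5, seed=0)
        assert fit.fluxes.net["v1"] == pytest.approx(6.0, abs=1e-4)
        assert fit.fluxes.net["v3"] == pytest.approx(4.0, abs=1e-4)
        assert fit.rss < 1e-8

    def test_multistart_no_worse_than_single_start(self, toy_cmp,
                                                   cmp_scenario):
        mids, _ = simulate_measurements(cmp_scenario, seed=3)
        model = exact_cmp_model(toy_cmp, cmp_scenario)
        one = fit_fluxes(model, mids, n_starts=1, seed=7)
        many = fit_fluxes(model, mids, n_starts=10, seed=7)
        assert many.rss <= one.rss + 1e-9

    def test_fit_is_reproducible_given_seed(self, toy_cmp, cmp_scenario):
        mids, _ = simulate_measurements(cmp_scenario, seed=5)
        model = exact_cmp_model(toy_cmp, cmp_scenario)
        a = fit_fluxes(model, mids, n_starts=5, seed=11)
        b = fit_fluxes(model, mids, n_starts=5, seed=11)
        assert np.array_equal(a.theta, b.theta)
        assert a.rss == b.rss
        assert a.start_rss == b.start_rss

    def test_fitted_rss_not_above_rss_at_truth(self, toy_cmp, cmp_scenario):
        mids, _ = simulate_measurements(cmp_scenario, seed=9)
        model = exact_cmp_model(toy_cmp, cmp_scenario)
        fit = fit_fluxes(model, mids, n_starts=10, seed=1)
        assert fit.rss <= objective_rss(model, cmp_scenario.true_fluxes,
                                        mids) + 1e-9

    def test_n_starts_must_be_positive(self, toy_cmp, cmp_scenario):
        mids, _ = simulate_measurements(cmp_scenario, seed=0)
        model = exact_cmp_model(toy_cmp, cmp_scenario)
        with pytest.raises(ValueError):
            fit_fluxes(model, mids, n_starts=0)


class TestChiSquare:
    def test_published_scale_threshold(self):
        # 111 independent data, 16 model degrees of freedom, alpha 0.05
        assert chi_square_threshold(111, 16, 0.05) == pytest.approx(118.8,
                                                                    abs=0.05)

    def test_single_df_quantile(self):
        assert chi_square_threshold(2, 1, 0.05) == pytest.approx(3.84,
                                                                 abs=0.005)

    def test_monotone_in_n_data(self):
        values = [chi_square_threshold(n, 16) for n in (20, 50, 111, 300)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            chi_square_threshold(5, 5)

    @pytest.mark.parametrize("rss,expected", [
        (65.5, True), (87.1, True), (118.8001, False)])
    def test_goodness_of_fit_decision(self, rss, expected):
        fit = FitResult(fluxes=None, theta=np.zeros(0), rss=rss, n_data=111,
                        n_free=16, threshold=chi_square_threshold(111, 16),
                        passed=None, start_rss=[], seed=0)
        assert goodness_of_fit(fit)["passed"] is expected


class TestGridSearchCI:
    def quadratic_setup(self, toy1):
        """Linear measurement model on TOY1: with uptake fixed at 1 the
        predicted MIDs are affine in v1, so the RSS surface is exactly
        quadratic and the profile CI has the closed form vhat +/- 1.96*s."""
        fragments = {
            "frag_C": FragmentDef("frag_C", "syn", (("C", (1,)),)),
            "frag_D": FragmentDef("frag_D", "syn", (("D", (1,)),)),
        }
        labeling = InputLabeling({"Aex": [("10", 1.0)]})
        model = build_constraints(toy1, fixed={"upt": 1.0},
                                  fragments=fragments, labeling=labeling)
        s = 0.01
        mids = [MeasuredMID("frag_C", [0.45, 0.55], [s, s]),
                MeasuredMID("frag_D", [0.42, 0.58], [s, s])]
        # predictions: C = [1-v, v], D = [v, 1-v]
        a = np.array([1.0, 0.0, 0.0, 1.0])
        g = np.array([-1.0, 1.0, 1.0, -1.0])
        y = np.array([0.45, 0.55, 0.42, 0.58])
        vhat = g @ (y - a) / (g @ g)
        s_eff = s / np.sqrt(g @ g)
        return model, mids, vhat, s_eff

    def test_quadratic_surface_matches_wald_closed_form(self, toy1):
        model, mids, vhat, s_eff = self.quadratic_setup(toy1)
        fit = fit_fluxes(model, mids, n_starts=3, seed=0)
        assert fit.fluxes.net["v1"] == pytest.approx(vhat, abs=1e-8)
        ci = grid_search_ci(model, mids, fit, "v1")
        half = np.sqrt(chi2.ppf(0.95, 1)) * s_eff  # 1.96 * s
        assert ci.lower == pytest.approx(vhat - half, abs=1e-3)
        assert ci.upper == pytest.approx(vhat + half, abs=1e-3)

    def test_width_shrinks_with_measurement_sd(self, toy_cmp):
        widths = []
        for sd in (0.006, 0.002):
            sc = make_scenario("TOY_CMP", mid_sd=0.0)
            mids, _ = simulate_measurements(sc, seed=0)
            for m in mids:
                m.sd[:] = sd
            model = exact_cmp_model(toy_cmp, sc)
            fit = fit_fluxes(model, mids, n_starts=3, seed=0)
            ci = grid_search_ci(model, mids, fit, "emp")
            assert ci.lower <= sc.true_fluxes.net["emp"] <= ci.upper
            widths.append(ci.upper - ci.lower)
        assert widths[1] < widths[0]

    def test_unknown_flux_rejected(self, toy_cmp, cmp_scenario):
        mids, _ = simulate_measurements(cmp_scenario, seed=0)
        model = exact_cmp_model(toy_cmp, cmp_scenario)
        fit = fit_fluxes(model, mids, n_starts=2, seed=0)
        with pytest.raises(KeyError):
            grid_search_ci(model, mids, fit, "nope")


class TestCompareCI:
    def test_published_scale_intervals_are_disjoint(self):
        # upper-glycolysis flux CIs of the two strains: 3.8-4.5 vs 2.3-3.0
        a = ConfidenceInterval("pgi", 3.8, 4.5)
        b = ConfidenceInterval("pgi", 2.3, 3.0)
        assert compare_ci(a, b) is True

    def test_overlapping_not_significant(self):
        assert compare_ci(ConfidenceInterval("f", 1.0, 3.0),
                          ConfidenceInterval("f", 2.0, 4.0)) is False

    def test_touching_endpoints_not_significant(self):
        assert compare_ci(ConfidenceInterval("f", 1.0, 2.0),
                          ConfidenceInterval("f", 2.0, 3.0)) is False

    def test_mismatched_flux_ids_rejected(self):
        with pytest.raises(ValueError):
            compare_ci(ConfidenceInterval("f", 0, 1),
                       ConfidenceInterval("g", 0, 1))


def test_precursor_demand_rejects_negative_coefficients():
    with pytest.raises(ValueError):
        PrecursorDemand({"B": -1.0})
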