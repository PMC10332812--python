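"""Flux fitting: SSR, chi-square intervals, recovery, confidence intervals."""

import numpy as np
import pandas as pd
import pytest

from cellflux.fitting import (
    FitOptions,
    MeasurementSet,
    SteadyStateModel,
    chi2_acceptance_interval,
    compute_ssr,
    confidence_intervals,
    fit_fluxes,
    flux_ratio_table,
    growth_normalized_fluxes,
)
from cellflux.network import FluxMap, packaged_flux_table, parse_network
from cellflux.simulate import simulate_steady_state_mids
from cellflux.tracers import TracerSpec


# a small identifiable network used throughout: condensation + exchange
TOY_TEXT = """
% unbalanced: A.x Q.x P.x R.x CO2
AIN: A.x (ab) -> A (ab)
QIN: Q.x (abc) -> Q (abc)
QA: Q (abc) -> A (bc) + CO2 (a)
COND: A (ab) + Q (cde) <-> Z (abcde)
ZOUT: Z (abcde) -> P.x (abcde)
AOUT: A (ab) -> R.x (ab)
"""
TOY_TRUE = FluxMap(
    net={"AIN": 2.0, "QIN": 5.0, "QA": 1.5, "COND": 3.5, "ZOUT": 3.5, "AOUT": 0.0},
    exch={"COND": 0.8},
)
TOY_TRACERS = {
    "e1": [TracerSpec("A.x", (1,))],
    "e2": [TracerSpec("Q.x", (1, 2, 3))],
}
TOY_OBS = [("Z", None), ("A", None), ("Q", None)]


@pytest.fixture(scope="module")
def toy_net():
    return parse_network(TOY_TEXT)


def toy_measurements(toy_net, seed, sd=0.003, flux_cv=0.05):
    """SD-matched noisy measurements from the toy truth."""
    rng = np.random.default_rng([seed, 1234])
    rows = []
    for exp, tracers in TOY_TRACERS.items():
        res = simulate_steady_state_mids(toy_net, TOY_TRUE, tracers, observed=TOY_OBS)
        for met, _ in TOY_OBS:
            for shift, frac in enumerate(res.mid(met)):
                rows.append(
                    {"experiment": exp, "metabolite": met, "mass_shift": shift,
                     "fraction": frac + rng.normal(0, sd), "sd": sd}
                )
    fobs = []
    for rid in ("AIN", "QIN"):
        v = TOY_TRUE.net[rid]
        s = flux_cv * v
        fobs.append({"reaction": rid, "value": v + rng.normal(0, s), "sd": s})
    return MeasurementSet(mids=pd.DataFrame(rows), fluxes=pd.DataFrame(fobs),
                          tracers=TOY_TRACERS)


class TestSSR:
    def test_identical_vectors_give_zero(self):
        x = np.array([0.1, 0.5, 0.4])
        assert compute_ssr(x, x, np.full(3, 0.003)) == 0.0

    def test_two_sigma_residual_gives_four(self):
        assert compute_ssr(np.array([1.006]), np.array([1.0]), np.array([0.003])) == pytest.approx(4.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        sim, meas, sd = rng.normal(size=20), rng.normal(size=20), rng.uniform(0.1, 1, 20)
        direct = sum(((a - b) / s) ** 2 for a, b, s in zip(sim, meas, sd))
        assert compute_ssr(sim, meas, sd) == pytest.approx(direct, rel=1e-12)


class TestChi2Interval:
    @pytest.mark.parametrize(
        "dof,lo,hi",
        [(362, 311.2, 416.6), (359, 308.4, 413.4), (563, 499.1, 630.6), (545, 482.2, 611.6)],
    )
    def test_published_intervals(self, dof, lo, hi):
        got = chi2_acceptance_interval(dof)
        assert round(got[0], 1) == lo
        assert round(got[1], 1) == hi

    def test_single_dof(self):
        lo, hi = chi2_acceptance_interval(1)
        assert lo == pytest.approx(0.000982, rel=1e-3)
        assert hi == pytest.approx(5.024, rel=1e-3)

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            chi2_acceptance_interval(0)


class TestModel:
    def test_jacobian_matches_finite_differences(self, toy_net):
        ms = toy_measurements(toy_net, seed=0)
        model = SteadyStateModel(toy_net, ms)
        th = model.basis.from_fluxmap(TOY_TRUE) + 0.05
        _, J = model.residuals(th, need_jac=True)
        for p in range(model.n_params):
            d = np.zeros_like(th)
            d[p] = 1e-6 * max(1.0, abs(th[p]))
            fd = (model.residuals(th + d) - model.residuals(th - d)) / (2 * d[p])
            assert np.max(np.abs(J[:, p] - fd)) < 1e-4 * max(1.0, np.max(np.abs(fd)))

    def test_ssr_at_truth_on_noiseless_data(self, toy_net):
        ms = toy_measurements(toy_net, seed=0, sd=1e-4, flux_cv=1e-6)
        # replace noisy values with exact ones
        ms = toy_measurements(toy_net, seed=0)
        ms.mids["fraction"] = ms.mids.apply(
            lambda r: simulate_steady_state_mids(
                toy_net, TOY_TRUE, TOY_TRACERS[r["experiment"]], observed=TOY_OBS
            ).mid(r["metabolite"])[int(r["mass_shift"])],
            axis=1,
        )
        ms.fluxes["value"] = [TOY_TRUE.net[r] for r in ms.fluxes["reaction"]]
        model = SteadyStateModel(toy_net, ms)
        # small floor: the sign-split smoothing leaves a sub-noise residual
        assert model.ssr(model.basis.from_fluxmap(TOY_TRUE)) < 0.01


class TestFitting:
    def test_noiseless_recovery(self, toy_net):
        ms = toy_measurements(toy_net, seed=0)
        ms.mids["fraction"] = ms.mids.apply(
            lambda r: simulate_steady_state_mids(
                toy_net, TOY_TRUE, TOY_TRACERS[r["experiment"]], observed=TOY_OBS
            ).mid(r["metabolite"])[int(r["mass_shift"])],
            axis=1,
        )
        ms.fluxes["value"] = [TOY_TRUE.net[r] for r in ms.fluxes["reaction"]]
        fit = fit_fluxes(toy_net, ms, FitOptions(restarts=3, seed=0))
        assert fit.ssr < 1e-3
        for rid in ("QIN", "QA", "COND", "ZOUT"):
            assert fit.fluxmap.net[rid] == pytest.approx(TOY_TRUE.net[rid], rel=1e-3, abs=1e-3)

    def test_best_of_restarts_monotone_in_restart_count(self, toy_net):
        ms = toy_measurements(toy_net, seed=3)
        ssrs = []
        for n in (1, 2, 4):
            fit = fit_fluxes(toy_net, ms, FitOptions(restarts=n, seed=123, polish_nfev=0))
            ssrs.append(fit.ssr)
        assert ssrs[1] <= ssrs[0] + 1e-9
        assert ssrs[2] <= ssrs[1] + 1e-9

    def test_deterministic_given_seed(self, toy_net):
        ms = toy_measurements(toy_net, seed=1)
        f1 = fit_fluxes(toy_net, ms, FitOptions(restarts=2, seed=42))
        f2 = fit_fluxes(toy_net, ms, FitOptions(restarts=2, seed=42))
        assert f1.ssr == f2.ssr
        assert np.array_equal(f1.theta, f2.theta)

    def test_dof_computed_not_hard_coded(self, toy_net):
        ms = toy_measurements(toy_net, seed=0)
        fit = fit_fluxes(toy_net, ms, FitOptions(restarts=1, seed=0))
        model = SteadyStateModel(toy_net, ms)
        assert fit.dof == model.n_meas - model.n_params
        assert fit.dof == len(ms.mids) + len(ms.fluxes) - model.n_params


class TestConfidenceIntervals:
    def test_linear_model_ci_matches_analytic(self, toy_net):
        """On a near-quadratic SSR surface the profile bound equals the
        analytic 1.96-sigma interval of the linearized model."""
        ms = toy_measurements(toy_net, seed=5)
        fit = fit_fluxes(toy_net, ms, FitOptions(restarts=2, seed=5))
        ci = confidence_intervals(fit, ["QIN"])
        row = ci.iloc[0]
        se = row["se_lin"]
        half_widths = (row["flux"] - row["lb"], row["ub"] - row["flux"])
        for hw in half_widths:
            assert hw == pytest.approx(1.96 * se, rel=0.30)

    def test_truth_inside_ci_for_determined_fluxes(self, toy_net):
        ms = toy_measurements(toy_net, seed=6)
        fit = fit_fluxes(toy_net, ms, FitOptions(restarts=2, seed=6))
        ci = confidence_intervals(fit, ["QIN", "QA", "COND"])
        for _, row in ci.iterrows():
            assert row["lb"] <= TOY_TRUE.net[row["reaction"]] <= row["ub"]

    def test_irreversible_zero_flux_lower_bound_is_zero(self, toy_net):
        ms = toy_measurements(toy_net, seed=7)
        fit = fit_fluxes(toy_net, ms, FitOptions(restarts=2, seed=7))
        ci = confidence_intervals(fit, ["AOUT"])
        assert ci.iloc[0]["lb"] == 0.0


class TestReporting:
    def test_identical_fits_have_unit_ratios(self):
        a = packaged_flux_table("lf_21")
        out = flux_ratio_table(a, a)
        net = out[out["type"] == "NET"]
        assert np.allclose(net["ratio"].dropna(), 1.0)
        assert not out["non_overlapping"].any()

    def test_published_ratio_examples(self):
        t1 = flux_ratio_table(packaged_flux_table("lf_21"), packaged_flux_table("lf_05"))
        t1 = t1.set_index(["type", "id"])
        assert t1.loc[("NET", "MCT"), "ratio"] == pytest.approx(0.89, abs=0.005)
        assert t1.loc[("NET", "PDH"), "ratio"] == pytest.approx(0.30, abs=0.005)
        t2 = flux_ratio_table(packaged_flux_table("lf_dmso"), packaged_flux_table("lf_bay"))
        t2 = t2.set_index(["type", "id"])
        assert t2.loc[("NET", "HK"), "ratio"] == pytest.approx(1.44, abs=0.005)
        t3 = flux_ratio_table(packaged_flux_table("pasmc_21"), packaged_flux_table("pasmc_05"))
        t3 = t3.set_index(["type", "id"])
        assert t3.loc[("NET", "GLNR"), "ratio"] == pytest.approx(2.29, abs=0.005)

    def test_near_zero_reference_ratio_omitted(self):
        a = pd.DataFrame([{"type": "NET", "id": "X", "flux": 1e-8, "lb": 0, "ub": 1e-7}])
        b = pd.DataFrame([{"type": "NET", "id": "X", "flux": 5.0, "lb": 4, "ub": 6}])
        out = flux_ratio_table(a, b)
        assert np.isnan(out.iloc[0]["ratio"])

    def test_non_overlap_flag(self):
        a = pd.DataFrame([{"type": "NET", "id": "X", "flux": 5.0, "lb": 4.0, "ub": 6.0}])
        b = pd.DataFrame([{"type": "NET", "id": "X", "flux": 10.0, "lb": 9.0, "ub": 11.0}])
        assert flux_ratio_table(a, b).iloc[0]["non_overlapping"]

    def test_growth_normalization_scales_inversely(self):
        table = packaged_flux_table("lf_21")
        unit = growth_normalized_fluxes(table, 1.0)
        assert np.allclose(unit["flux"], table["flux"], equal_nan=True)
        half = growth_normalized_fluxes(table, 0.5)
        assert np.allclose(half["flux"], 2 * table["flux"], equal_nan=True)
        with pytest.raises(ValueError):
            growth_normalized_fluxes(table, 0.0)

    def test_raw_decrease_can_be_normalized_increase(self):
        a = pd.DataFrame([{"type": "NET", "id": "HK", "flux": 514.0}])
        b = pd.DataFrame([{"type": "NET", "id": "HK", "flux": 441.0}])
        raw = flux_ratio_table(a, b).iloc[0]["ratio"]
        na = growth_normalized_fluxes(a, 0.0238)
        nb = growth_normalized_fluxes(b, 0.0168)
        norm = flux_ratio_table(na, nb).iloc[0]["ratio"]
        assert raw < 1.0 < norm


class TestCalibration:
    def test_ssr_at_truth_is_chi2_distributed(self, toy_net):
        """SSR evaluated at the generating parameters over repeated noise
        draws follows the chi-square law with one dof per residual."""
        from scipy import stats

        from scipy import stats

        ssrs = []
        n_meas = None
        for seed in range(200):
            ms = toy_measurements(toy_net, seed=seed)
            model = SteadyStateModel(toy_net, ms)
            n_meas = model.n_meas
            theta_true = model.basis.from_fluxmap(TOY_TRUE)
            ssrs.append(model.ssr(theta_true))
        stat, p = stats.kstest(ssrs, "chi2", args=(n_meas,))
        assert p > 0.01
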