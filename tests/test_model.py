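"""Tests for the three-compartment disposition model and simulator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import teicopk as tk
from teicopk.model import DegenerateDispositionError, _check_distinct, rate_matrix

from conftest import random_params


def ode_profile(p, events, times, rtol=1e-10, y0=None):
    """Independent oracle: stiff ODE integration of the mammillary system.

    Integrates piecewise between infusion edges so the solver never steps
    across a discontinuity in the input rate.
    """
    m = rate_matrix(p)
    times = np.asarray(times, dtype=float)
    t_end = float(times.max())
    edges = {0.0, t_end}
    for e in events:
        edges |= {e.time, e.time + e.duration}
    edges = sorted(t for t in edges if t <= t_end)
    y = np.zeros(3) if y0 is None else np.asarray(y0, dtype=float)
    out = np.empty_like(times)
    for a, b in zip(edges, edges[1:] + [t_end]):
        if b <= a:
            continue
        rate = sum(e.rate for e in events if e.time <= a < e.time + e.duration)

        def rhs(t, yv, rate=rate):
            dy = m @ yv
            dy[0] += rate
            return dy

        mask = (times > a) & (times <= b)
        t_eval = np.unique(np.concatenate([times[mask], [b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, method="LSODA",
                        rtol=rtol, atol=1e-13)
        for t, col in zip(sol.t, sol.y.T):
            hits = np.isclose(times, t, rtol=0, atol=1e-12) & mask
            out[hits] = col[0] / p.V1
        y = sol.y[:, -1]
    out[times <= 0.0] = (y0[0] / p.V1) if y0 is not None else 0.0
    return out


class TestApplyCovariates:
    def test_reference_covariates_give_table_typicals(self, model):
        p = tk.apply_covariates(model, 105.27, 67.85)
        assert p.CL == pytest.approx(0.693)
        assert p.V3 == pytest.approx(69.8)
        assert (p.V1, p.Q2, p.V2, p.Q3) == (3.96, 4.45, 8.24, 1.76)

    def test_zero_exponent_removes_egfr_effect(self, model):
        from dataclasses import replace

        flat = replace(model, theta2_CL_exp=0.0)
        for egfr in (50.0, 105.27, 200.0):
            assert tk.apply_covariates(flat, egfr, 67.85).CL == pytest.approx(0.693)

    def test_doubled_egfr_power_law(self, model):
        p = tk.apply_covariates(model, 2 * 105.27, 67.85)
        assert p.CL == pytest.approx(1.1941029773608558, rel=1e-12)

    @pytest.mark.parametrize("egfr,weight", [(0.0, 70.0), (-5.0, 70.0), (100.0, 0.0)])
    def test_nonpositive_covariates_rejected(self, model, egfr, weight):
        with pytest.raises(ValueError):
            tk.apply_covariates(model, egfr, weight)


class TestDisposition:
    def test_one_compartment_collapse(self):
        p = tk.IndividualParams(CL=1.0, V1=10.0, Q2=0.0, V2=1.0, Q3=0.0, V3=1.0)
        d = tk.disposition_of(p)
        assert d.lambdas == pytest.approx([0.1])
        assert d.coeffs == pytest.approx([0.1])

    def test_coefficients_sum_to_inverse_central_volume(self, typical):
        rng = np.random.default_rng(7)
        for p in [typical] + [random_params(rng) for _ in range(20)]:
            d = tk.disposition_of(p)
            assert d.coeffs.sum() == pytest.approx(1.0 / p.V1, rel=1e-9)

    def test_rates_match_characteristic_polynomial_roots(self, typical):
        # independent oracle: roots of the cubic in the micro constants
        p = typical
        k10, k12 = p.CL / p.V1, p.Q2 / p.V1
        k21, k13, k31 = p.Q2 / p.V2, p.Q3 / p.V1, p.Q3 / p.V3
        a2 = k10 + k12 + k21 + k13 + k31
        a1 = k10 * k21 + k10 * k31 + k12 * k31 + k13 * k21 + k21 * k31
        a0 = k10 * k21 * k31
        roots = np.sort(np.roots([1.0, -a2, a1, -a0]))[::-1]
        assert tk.disposition_of(p).lambdas == pytest.approx(roots, rel=1e-10)

    def test_unit_bolus_matches_ode_oracle(self, typical):
        d = tk.disposition_of(typical)
        times = np.linspace(0.05, 500.0, 120)
        analytic = (d.coeffs[None, :] * np.exp(-np.outer(times, d.lambdas))).sum(axis=1)
        # unit bolus as an initial condition in the central compartment
        numeric = ode_profile(typical, [], times, rtol=1e-11, y0=[1.0, 0.0, 0.0])
        assert np.max(np.abs(analytic / numeric - 1.0)) < 1e-6

    def test_degenerate_rates_raise(self):
        with pytest.raises(DegenerateDispositionError):
            _check_distinct(np.array([0.5, 0.5 * (1 + 1e-12), 2.0]))


class TestHalfLives:
    def test_one_compartment_value(self):
        p = tk.IndividualParams(CL=0.693, V1=10.0, Q2=0.0, V2=1.0, Q3=0.0, V3=1.0)
        assert tk.half_lives(p) == pytest.approx([np.log(2) * 10 / 0.693])

    def test_sorted_ascending_and_ln2_over_lambda(self, typical):
        th = tk.half_lives(typical)
        assert np.all(np.diff(th) > 0)
        lam = tk.disposition_of(typical).lambdas
        assert th == pytest.approx(np.sort(np.log(2) / lam))


class TestSimulateProfile:
    def test_zero_before_first_dose(self, typical):
        reg = [tk.DoseEvent(10.0, 400.0, 0.5)]
        prof = tk.simulate_profile(typical, reg, [0.0, 5.0, 9.99])
        assert np.all(prof.conc == 0.0)

    def test_one_compartment_infusion_closed_form(self):
        p = tk.IndividualParams(CL=2.0, V1=10.0, Q2=0.0, V2=1.0, Q3=0.0, V3=1.0)
        r0 = 400.0  # mg/h
        t = 0.25
        expected = (r0 / p.CL) * (1.0 - np.exp(-p.CL * t / p.V1))
        prof = tk.simulate_profile(p, [tk.DoseEvent(0.0, r0 * 0.5, 0.5)], [t])
        assert prof.conc[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_ode_oracle_at_study_times(self, typical):
        ev = [tk.DoseEvent(0.0, 200.0, 0.5)]
        times = [0.55, 0.75, 4.0, 8.0, 72.0, 192.0]
        analytic = tk.simulate_profile(typical, ev, times).conc
        numeric = ode_profile(typical, ev, times, rtol=1e-10)
        assert analytic == pytest.approx(numeric, rel=1e-6)

    def test_random_parameter_sets_match_ode(self):
        rng = np.random.default_rng(42)
        times = np.linspace(0.1, 500.0, 40)
        ev = [tk.DoseEvent(0.0, 400.0, 0.5)]
        worst = 0.0
        for _ in range(15):
            p = random_params(rng)
            analytic = tk.simulate_profile(p, ev, times).conc
            numeric = ode_profile(p, ev, times)
            worst = max(worst, np.max(np.abs(analytic / numeric - 1.0)))
        assert worst < 1e-6

    def test_dose_linearity(self, typical):
        times = [1.0, 10.0, 100.0]
        base = tk.simulate_profile(typical, [tk.DoseEvent(0.0, 100.0, 0.5)], times).conc
        tripled = tk.simulate_profile(
            typical, [tk.DoseEvent(0.0, 300.0, 0.5)], times
        ).conc
        assert tripled == pytest.approx(3.0 * base, rel=1e-12)

    def test_superposition_of_shifted_doses(self, typical):
        times = np.linspace(0.0, 200.0, 97)
        multi = [tk.DoseEvent(0.0, 400.0, 0.5), tk.DoseEvent(12.0, 250.0, 0.5)]
        combined = tk.simulate_profile(typical, multi, times).conc
        separate = sum(
            tk.simulate_profile(typical, [e], times).conc for e in multi
        )
        assert combined == pytest.approx(separate, rel=1e-9, abs=1e-15)

    def test_negative_times_rejected(self, typical):
        with pytest.raises(ValueError):
            tk.simulate_profile(typical, [tk.DoseEvent(0.0, 100.0, 0.5)], [-1.0])

    def test_two_compartment_collapse(self, typical):
        # Q3=0 must reproduce the analytic two-compartment infusion response
        from dataclasses import replace

        p2 = replace(typical, Q3=0.0)
        d = tk.disposition_of(p2)
        assert d.lambdas.size == 2
        ev = [tk.DoseEvent(0.0, 200.0, 0.5)]
        times = [0.25, 1.0, 8.0, 48.0]
        numeric = ode_profile(p2, ev, times)
        analytic = tk.simulate_profile(p2, ev, times).conc
        assert analytic == pytest.approx(numeric, rel=1e-6)


class TestIntegralsAndVss:
    def test_single_dose_auc_inf_equals_dose_over_cl(self, typical):
        reg = tk.Regimen(ld_dose=200.0, md_dose=0.0, ld_count=1, md_count=0,
                         per_kg=False)
        auc = tk.auc_interval(typical, reg, 0.0, 1e6)
        assert auc == pytest.approx(200.0 / typical.CL, rel=1e-6)

    def test_vss_is_sum_of_volumes(self, typical):
        assert tk.steady_state_volume(typical) == pytest.approx(82.0)
        p = tk.IndividualParams(CL=1.0, V1=1.0, Q2=1.0, V2=1.0, Q3=1.0, V3=1.0)
        assert tk.steady_state_volume(p) == 3.0

    def test_vss_equals_mrt_times_cl_moment_identity(self, typical):
        d = tk.disposition_of(typical)
        mrt = (d.coeffs / d.lambdas**2).sum() / (d.coeffs / d.lambdas).sum()
        assert tk.steady_state_volume(typical) == pytest.approx(
            mrt * typical.CL, rel=1e-9
        )


class TestModelConfig:
    def test_packaged_default_is_published_parameter_set(self, model):
        assert model.theta1_CL == 0.693
        assert model.iiv_cv["Q2"] == 0.327
        assert model.prop_error_cv == 0.0633

    def test_load_model_roundtrip_and_unknown_keys(self, tmp_path, model):
        import json
        from dataclasses import asdict

        path = tmp_path / "m.json"
        path.write_text(json.dumps(asdict(model)))
        assert tk.load_model(path) == model
        bad = tmp_path / "bad.yaml"
        bad.write_text("theta1_CL: 0.7\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            tk.load_model(bad)
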