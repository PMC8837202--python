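"""Catch-slip Bell model and binding isotherm fits."""

import numpy as np
import pandas as pd
import pytest

from forcejump import (
    RSA4_BELL,
    BellParams,
    catch_slip_lifetime,
    catch_slip_rate,
    critical_force,
    fit_binding_isotherm,
    fit_catch_slip,
)
from forcejump.models import DegenerateBranchError, UnidentifiableKDError

KBT = 4.09


def _groups(forces, taus, sems=None):
    return pd.DataFrame(
        {
            "F_Load_pN": forces,
            "mean_tau_s": taus,
            "sem_tau_s": sems if sems is not None else np.zeros(len(forces)),
        }
    )


class TestCatchSlipLaw:
    def test_zero_force_lifetime(self):
        p = BellParams(kc0=2.0, xc=-1.5, ks0=0.5, xs=3.0)
        assert catch_slip_lifetime(0.0, p) == pytest.approx(1.0 / 2.5)
        assert catch_slip_rate(0.0, p) == pytest.approx(2.5)

    def test_printed_rsa4_parameters_give_chevron(self):
        f = np.linspace(0.0, 12.0, 500)
        tau = catch_slip_lifetime(f, RSA4_BELL)
        imax = int(np.argmax(tau))
        assert 0 < imax < len(f) - 1  # rises then falls
        assert np.all(np.diff(tau[: imax + 1]) > 0)
        assert np.all(np.diff(tau[imax:]) < 0)

    def test_lifetime_maximal_at_critical_force(self):
        p = BellParams(kc0=5.3, xc=-2.0, ks0=0.01, xs=4.1)
        f_star = critical_force(p)
        grid = np.arange(0.0, 20.0, 0.001)
        tau = catch_slip_lifetime(grid, p)
        assert abs(grid[int(np.argmax(tau))] - f_star) < 0.01

    def test_invalid_signs_rejected(self):
        with pytest.raises(ValueError):
            BellParams(kc0=1.0, xc=1.0, ks0=1.0, xs=2.0)
        with pytest.raises(ValueError):
            BellParams(kc0=-1.0, xc=-1.0, ks0=1.0, xs=2.0)


class TestCriticalForce:
    def test_symmetric_closed_form(self):
        # xc = -xs, kc0 = r*ks0 reduces to F* = kBT*ln(r)/(2*xs)
        r, xs = 100.0, 3.0
        p = BellParams(kc0=r * 0.01, xc=-xs, ks0=0.01, xs=xs)
        assert critical_force(p) == pytest.approx(KBT * np.log(r) / (2 * xs))

    def test_closed_form_equals_grid_argmax_random_params(self, rng):
        grid = np.arange(0.0, 20.0, 0.001)
        n_checked = 0
        while n_checked < 100:
            p = BellParams(
                kc0=float(10 ** rng.uniform(-1, 1.7)),
                xc=float(-rng.uniform(0.5, 8.0)),
                ks0=float(10 ** rng.uniform(-3, 0)),
                xs=float(rng.uniform(0.5, 8.0)),
            )
            try:
                f_star = critical_force(p)
            except ValueError:
                continue  # no interior maximum for this draw
            if not 0.05 < f_star < 19.0:
                continue  # maximum not interior to the grid
            tau = catch_slip_lifetime(grid, p)
            assert abs(grid[int(np.argmax(tau))] - f_star) < 0.01
            n_checked += 1

    def test_no_interior_maximum_is_failure(self):
        p = BellParams(kc0=1e-6, xc=-1e-3, ks0=10.0, xs=5.0)
        with pytest.raises(ValueError):
            critical_force(p)


class TestCatchSlipFit:
    def test_noiseless_self_consistency(self):
        truth = BellParams(kc0=5.3, xc=-2.0, ks0=0.01, xs=4.1)
        f = np.arange(1.0, 13.0)
        fit = fit_catch_slip(_groups(f, catch_slip_lifetime(f, truth)))
        assert fit.params.kc0 == pytest.approx(truth.kc0, rel=1e-4)
        assert fit.params.xc == pytest.approx(truth.xc, rel=1e-4)
        assert fit.params.ks0 == pytest.approx(truth.ks0, rel=1e-4)
        assert fit.params.xs == pytest.approx(truth.xs, rel=1e-4)
        assert fit.F_crit == pytest.approx(critical_force(truth), rel=1e-4)

    def test_monotone_decreasing_flags_catch_branch(self):
        f = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        with pytest.raises(DegenerateBranchError) as err:
            fit_catch_slip(_groups(f, np.exp(-f)))
        assert err.value.branch == "catch"

    def test_monotone_increasing_flags_slip_branch(self):
        f = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        with pytest.raises(DegenerateBranchError) as err:
            fit_catch_slip(_groups(f, np.exp(0.2 * f)))
        assert err.value.branch == "slip"

    def test_needs_four_force_levels(self):
        with pytest.raises(ValueError):
            fit_catch_slip(_groups([1.0, 2.0, 3.0], [0.3, 0.5, 0.3]))

    def test_lifetime_scaling_equivariance(self):
        truth = BellParams(kc0=5.3, xc=-2.0, ks0=0.01, xs=4.1)
        f = np.arange(1.0, 13.0)
        tau = catch_slip_lifetime(f, truth)
        base = fit_catch_slip(_groups(f, tau))
        c = 3.7
        scaled = fit_catch_slip(_groups(f, c * tau))
        assert scaled.params.kc0 == pytest.approx(base.params.kc0 / c, rel=1e-3)
        assert scaled.params.ks0 == pytest.approx(base.params.ks0 / c, rel=1e-3)
        assert scaled.params.xc == pytest.approx(base.params.xc, rel=1e-3)
        assert scaled.params.xs == pytest.approx(base.params.xs, rel=1e-3)
        assert scaled.F_crit == pytest.approx(base.F_crit, rel=1e-3)

    def test_ci_coverage_on_synthetic_refits(self, rng):
        # linearized 95% CIs should cover the truth in >= 85% of refits at
        # assay-like sample sizes (10 force levels, ~30 events per group)
        truth = RSA4_BELL
        forces = np.array(
            [1.37, 1.89, 2.65, 3.40, 4.00, 5.01, 5.44, 6.71, 6.95, 8.47]
        )
        tau_true = catch_slip_lifetime(forces, truth)
        starts = [(5.0, -2.0, 0.01, 4.0), (1.0, -1.0, 0.1, 2.0), (20.0, -4.0, 0.001, 6.0)]
        n_rep, cov_xc, cov_xs = 200, 0, 0
        for _ in range(n_rep):
            means, sems = [], []
            for t in tau_true:
                draws = rng.exponential(t, 30)
                means.append(draws.mean())
                sems.append(draws.std(ddof=1) / np.sqrt(30))
            fit = fit_catch_slip(_groups(forces, means, sems), starts=starts)
            if np.isfinite(fit.ci95["xc"]):
                cov_xc += abs(fit.params.xc - truth.xc) <= fit.ci95["xc"]
            if np.isfinite(fit.ci95["xs"]):
                cov_xs += abs(fit.params.xs - truth.xs) <= fit.ci95["xs"]
        assert cov_xc / n_rep >= 0.85
        assert cov_xs / n_rep >= 0.85


class TestIsotherm:
    def test_noiseless_recovery(self):
        s = 40.0 / 2 ** np.arange(16)
        y = 20.0 * s / (5.0 + s)
        fit = fit_binding_isotherm(s, y)
        assert fit.KD == pytest.approx(5.0, rel=1e-6)
        assert fit.Ymax == pytest.approx(20.0, rel=1e-6)

    def test_half_maximum_identity(self):
        s = 40.0 / 2 ** np.arange(16)
        y = 7.0 * s / (3.0 + s)
        fit = fit_binding_isotherm(s, y)
        y_at_kd = fit.Ymax * fit.KD / (fit.KD + fit.KD)
        assert y_at_kd == pytest.approx(fit.Ymax / 2)

    def test_linear_titration_unidentifiable(self):
        s = 40.0 / 2 ** np.arange(16)
        with pytest.raises(UnidentifiableKDError):
            fit_binding_isotherm(s, 0.01 * s)

    def test_needs_decade_span(self):
        with pytest.raises(ValueError):
            fit_binding_isotherm([1.0, 1.5, 2.0, 2.5, 3.0], [1, 2, 3, 4, 5])
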