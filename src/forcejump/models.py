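"""Catch-slip Bell kinetics and the single-site binding isotherm.

The two-pathway (catch-slip) Bell model describes force-dependent bond
dissociation as two parallel escape routes, one suppressed and one
accelerated by load:

    1 / taubar(F) = kc0 * exp(F * xc / kBT) + ks0 * exp(F * xs / kBT)

with zero-force rates kc0, ks0 > 0 and distance parameters xc < 0 (catch)
and xs > 0 (slip).  The mean bond lifetime taubar rises with force while
the catch pathway dominates and falls once the slip pathway takes over;
the crossover defines the critical force

    F* = kBT * ln(-kc0*xc / (ks0*xs)) / (xs - xc),

the closed-form argmax of taubar(F).  Fitting is weighted nonlinear least
squares of taubar against mean lifetimes per force group, with multi-start
initialization and sign constraints that pin the pathway identities.

The module also fits the single-site binding isotherm used for solution
titrations, Y = Ymax * [S] / (KD + [S]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

from .mechanics import DEFAULT_KBT


class DegenerateBranchError(ValueError):
    """Lifetime data lack a rising or falling branch; one pathway is
    unidentifiable."""

    def __init__(self, branch: str):
        super().__init__(
            f"{branch} pathway unidentifiable: lifetimes are monotone "
            f"{'decreasing' if branch == 'catch' else 'increasing'} in force"
        )
        self.branch = branch


class UnidentifiableKDError(ValueError):
    """Titration shows no curvature; KD cannot be estimated."""


@dataclass(frozen=True)
class BellParams:
    """Catch-slip Bell parameters.

    kc0, ks0 are zero-force rates (1/s); xc (negative) and xs (positive)
    are the distance parameters (nm) of the catch and slip pathways.
    """

    kc0: float
    xc: float
    ks0: float
    xs: float
    kBT: float = DEFAULT_KBT

    def __post_init__(self) -> None:
        if self.kc0 <= 0 or self.ks0 <= 0:
            raise ValueError("kc0 and ks0 must be > 0")
        if not (self.xc < 0 < self.xs):
            raise ValueError("pathway signs require xc < 0 < xs")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0")


@dataclass(frozen=True)
class BellFit:
    """Result of a catch-slip fit: parameters, 95% CIs and diagnostics."""

    params: BellParams
    ci95: dict[str, float]  # half-widths, 1.96 * stderr where available
    F_crit: float  # pN
    n_groups: int
    redchi: float
    success: bool


@dataclass(frozen=True)
class IsothermFit:
    """Single-site isotherm fit: KD (same units as [S]) and Ymax."""

    KD: float
    Ymax: float
    ci95: dict[str, float]
    n_points: int
    success: bool


def catch_slip_rate(F, params: BellParams):
    """Off-rate 1/taubar at force F (pN); scalar or array."""
    f = np.asarray(F, dtype=float)
    r = params.kc0 * np.exp(f * params.xc / params.kBT) + params.ks0 * np.exp(
        f * params.xs / params.kBT
    )
    return float(r) if np.ndim(F) == 0 else r


def catch_slip_lifetime(F, params: BellParams):
    """Mean bond lifetime taubar(F) in seconds; scalar or array."""
    r = catch_slip_rate(F, params)
    return 1.0 / r


def critical_force(params: BellParams) -> float:
    """Closed-form force of maximal lifetime.

    Raises ``ValueError`` when the log argument is non-positive (no
    stationary point) and returns the algebraic root otherwise; a value
    <= 0 means the maximum is not interior to the physical force range.
    """
    arg = -params.kc0 * params.xc / (params.ks0 * params.xs)
    if arg <= 0:
        raise ValueError("no interior lifetime maximum for these parameters")
    f_star = params.kBT * math.log(arg) / (params.xs - params.xc)
    if f_star <= 0:
        raise ValueError(
            "no interior lifetime maximum at positive force (slip-dominated)"
        )
    return f_star


def _default_starts() -> list[tuple[float, float, float, float]]:
    """Deterministic multi-start grid (kc0, xc, ks0, xs) spanning the
    physically plausible decades; avoids the catch/slip label-swap
    minimum because signs are constrained per start."""
    starts = []
    for kc0 in (0.3, 3.0, 30.0):
        for xc in (-4.0, -1.0):
            for ks0 in (1e-3, 0.1):
                for xs in (1.5, 5.0):
                    starts.append((kc0, xc, ks0, xs))
    return starts


def fit_catch_slip(
    groups: pd.DataFrame,
    kBT: float = DEFAULT_KBT,
    force_column: str = "F_Load_pN",
    weights: str = "sem",
    starts: Optional[list[tuple[float, float, float, float]]] = None,
) -> BellFit:
    """Weighted NLS of the catch-slip lifetime law to group means.

    Parameters
    ----------
    groups : DataFrame
        Needs ``force_column``, ``mean_tau_s`` and (for SEM weighting)
        ``sem_tau_s``.  Typically the output of
        :func:`forcejump.kinetics.groups_to_frame` with both bridge
        constructs pooled on the F_Load axis.
    weights : {"sem", "unit"}
        ``"sem"`` uses 1/SEM^2 weights with unit weight for single-event
        groups (SEM = 0); ``"unit"`` fits unweighted.

    Raises
    ------
    DegenerateBranchError
        If the mean lifetimes are monotone in force, so that one pathway
        has no leverage on the data.
    """
    f = groups[force_column].to_numpy(dtype=float)
    tau = groups["mean_tau_s"].to_numpy(dtype=float)
    if len(np.unique(f)) < 4:
        raise ValueError("need >= 4 distinct force levels to fit four parameters")
    order = np.argsort(f)
    tau_sorted = tau[order]
    imax = int(np.argmax(tau_sorted))
    if imax == 0:
        raise DegenerateBranchError("catch")
    if imax == len(tau_sorted) - 1:
        raise DegenerateBranchError("slip")

    if weights == "sem":
        sem = groups["sem_tau_s"].to_numpy(dtype=float)
        sigma = np.where(sem > 0, sem, 1.0)
    elif weights == "unit":
        sigma = np.ones_like(tau)
    else:
        raise ValueError("weights must be 'sem' or 'unit'")

    def residual(p):
        model = 1.0 / (
            p["kc0"] * np.exp(f * p["xc"] / kBT)
            + p["ks0"] * np.exp(f * p["xs"] / kBT)
        )
        return (model - tau) / sigma

    best = None
    for kc0, xc, ks0, xs in starts if starts is not None else _default_starts():
        p = lmfit.Parameters()
        p.add("kc0", value=kc0, min=1e-8, max=1e5)
        p.add("xc", value=xc, min=-20.0, max=-1e-4)
        p.add("ks0", value=ks0, min=1e-10, max=1e5)
        p.add("xs", value=xs, min=1e-4, max=20.0)
        try:
            res = lmfit.minimize(
                residual, p, method="leastsq", xtol=1e-12, ftol=1e-12
            )
        except Exception:  # pragma: no cover - pathological start
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:  # pragma: no cover
        raise RuntimeError("catch-slip fit failed from every start")

    vals = {k: float(best.params[k].value) for k in ("kc0", "xc", "ks0", "xs")}
    bell = BellParams(kBT=kBT, **vals)
    ci95 = {}
    for k in vals:
        se = best.params[k].stderr
        ci95[k] = 1.96 * float(se) if se is not None else float("nan")
    return BellFit(
        params=bell,
        ci95=ci95,
        F_crit=critical_force(bell),
        n_groups=int(len(f)),
        redchi=float(best.redchi),
        success=bool(best.success),
    )


def fit_binding_isotherm(
    concentration, response, conc_unit: str = "uM"
) -> IsothermFit:
    """Fit Y = Ymax*[S]/(KD + [S]) to a titration.

    Needs at least five concentrations spanning a decade.  A titration
    with no curvature (response effectively linear in [S], KD driven far
    beyond the measured range) raises :class:`UnidentifiableKDError`.
    """
    s = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if s.size != y.size:
        raise ValueError("concentration and response lengths differ")
    pos = s[s > 0]
    if pos.size < 5 or pos.max() / pos.min() < 10.0:
        raise ValueError("need >= 5 concentrations spanning at least one decade")

    ymax0 = float(y[np.argmax(s)])
    half = 0.5 * ymax0
    kd0 = float(np.interp(half, np.sort(y), s[np.argsort(y)])) if ymax0 != 0 else 1.0
    kd0 = min(max(abs(kd0), pos.min()), pos.max())

    p = lmfit.Parameters()
    p.add("KD", value=kd0, min=1e-9, max=1e9)
    p.add("Ymax", value=ymax0 if ymax0 != 0 else 1.0)

    def residual(pars):
        return pars["Ymax"] * s / (pars["KD"] + s) - y

    res = lmfit.minimize(residual, p, method="leastsq", xtol=1e-12, ftol=1e-12)
    kd = float(res.params["KD"].value)
    if kd > 50.0 * pos.max():
        raise UnidentifiableKDError(
            "no curvature over the titrated range: KD unidentifiable"
        )
    ci95 = {}
    for k in ("KD", "Ymax"):
        se = res.params[k].stderr
        ci95[k] = 1.96 * float(se) if se is not None else float("nan")
    return IsothermFit(
        KD=kd,
        Ymax=float(res.params["Ymax"].value),
        ci95=ci95,
        n_points=int(s.size),
        success=bool(res.success),
    )


#: Printed catch-slip parameters for the MIDAS-Rsa4 bond (rounded).
RSA4_BELL = BellParams(kc0=5.3, xc=-2.0, ks0=0.01, xs=4.1)

#: Printed catch-slip parameters for the MIDAS-Ytm1 bond (rounded).
YTM1_BELL = BellParams(kc0=15.2, xc=-4.8, ks0=0.04, xs=3.2)
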