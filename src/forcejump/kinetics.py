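"""Lifetime aggregation and survival analysis.

Bond lifetimes pooled at a common plateau force are summarized as survival
probabilities, S(t) = 1 - ECDF(t), fitted with a single exponential
S = A*exp(b*t), and reduced to mean lifetimes (the inverse of the mean is
the off-rate).  Events from different molecules at the same nominal force
are pooled.  For semilog plotting the final survival point is moved from 0
to 0.01 — a display convention only, never part of any fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

from .mechanics import TetherGeometry, solve_bound_state

#: survival value substituted for 0 on the plotting copy of a curve
PLOT_FLOOR = 0.01


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival probability at the observed lifetimes."""

    times: np.ndarray  # sorted unique lifetimes, s
    survival: np.ndarray  # S(t) = P(T > t) at each time
    n: int  # number of lifetimes

    def plotting_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Copy with S = 0 lifted to the 0.01 semilog floor (display only)."""
        s = self.survival.copy()
        s[s == 0.0] = PLOT_FLOOR
        return self.times.copy(), s


@dataclass(frozen=True)
class ExponentialFit:
    """Single-exponential fit S = A*exp(b*t) to a survival curve."""

    A: float
    b: float  # 1/s, negative for decaying data
    residuals: np.ndarray
    n_points: int
    n_events: int
    runs_pvalue: float  # Wald-Wolfowitz runs test on residual signs
    converged: bool

    @property
    def rate(self) -> float:
        """Off-rate implied by the fit, -b (1/s)."""
        return -self.b

    @property
    def mean_tau(self) -> float:
        return -1.0 / self.b

    @property
    def ks_stat(self) -> float:
        """Scaled worst residual, max|S - fit| * sqrt(n_events).

        The preferred single-vs-multi-exponential diagnostic: survival
        residuals are strongly autocorrelated (the ECDF is a cumulative
        process), so the sign-runs p-value is small even for a correct
        model, whereas this Kolmogorov-style statistic stays below ~1
        for adequate single-exponential fits and grows to several units
        for mixed populations.
        """
        return float(np.max(np.abs(self.residuals)) * np.sqrt(self.n_events))


@dataclass
class LifetimeGroup:
    """Pooled lifetimes at one (construct, F_Tot) condition."""

    construct: int
    F_Tot: float  # pN
    F_Load: float  # pN, via the mechanical circuit
    lifetimes: np.ndarray  # s
    n_molecules: int
    single_event: bool = False

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        if self.lifetimes.size < 1:
            raise ValueError("a lifetime group needs at least one event")
        self.single_event = self.lifetimes.size == 1

    @property
    def n_events(self) -> int:
        return int(self.lifetimes.size)

    @property
    def mean_tau(self) -> float:
        return float(self.lifetimes.mean())

    @property
    def sem_tau(self) -> float:
        # single-event groups are kept, flagged, with SEM reported as 0
        if self.single_event:
            return 0.0
        return float(self.lifetimes.std(ddof=1) / np.sqrt(self.n_events))

    @property
    def off_rate(self) -> float:
        return 1.0 / self.mean_tau


def survival_curve(lifetimes) -> SurvivalCurve:
    """Survival probability 1 - ECDF evaluated at each observed lifetime."""
    t = np.asarray(lifetimes, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one lifetime")
    times = np.unique(t)
    # S(t_i) = fraction strictly greater than t_i
    counts_le = np.searchsorted(np.sort(t), times, side="right")
    survival = 1.0 - counts_le / t.size
    return SurvivalCurve(times=times, survival=survival, n=int(t.size))


def _runs_pvalue(signs: np.ndarray) -> float:
    """Wald-Wolfowitz runs test (normal approximation), two-sided.

    Few runs signal systematic residual structure, e.g. a survival curve
    that a single exponential cannot describe.
    """
    s = signs[signs != 0]
    n_pos = int((s > 0).sum())
    n_neg = int((s < 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 1.0
    runs = 1 + int((np.diff(s) != 0).sum())
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def fit_exponential_survival(curve: SurvivalCurve) -> ExponentialFit:
    """Nonlinear least squares of S = A*exp(b*t) on the unadjusted curve.

    Fits the survival points at the observed lifetimes only, unweighted,
    with free amplitude.  The plotting floor is never applied here.
    """
    if curve.times.size < 3:
        raise ValueError("need at least 3 distinct lifetimes to fit")
    t, s = curve.times, curve.survival
    mean_t = float(np.average(t, weights=np.ones_like(t)))
    p0 = (1.0, -1.0 / max(mean_t, 1e-12))
    try:
        popt, _ = curve_fit(
            lambda x, A, b: A * np.exp(b * x), t, s, p0=p0, maxfev=10000
        )
        converged = True
    except RuntimeError:
        return ExponentialFit(
            A=np.nan, b=np.nan, residuals=np.full_like(t, np.nan),
            n_points=t.size, n_events=curve.n, runs_pvalue=np.nan, converged=False,
        )
    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = s - a_hat * np.exp(b_hat * t)
    return ExponentialFit(
        A=a_hat,
        b=b_hat,
        residuals=resid,
        n_points=int(t.size),
        n_events=curve.n,
        runs_pvalue=_runs_pvalue(np.sign(resid)),
        converged=converged,
    )


def group_and_summarize(
    events: pd.DataFrame, geom_by_construct: Optional[dict[int, TetherGeometry]] = None
) -> list[LifetimeGroup]:
    """Pool events by (construct, F_Tot) and summarize each group.

    F_Load per group comes from the event table when present, otherwise
    from the mechanical circuit via ``geom_by_construct``.  The two bridge
    constructs are kept as separate groups; plotting or fitting against
    F_Load pools them on a common force axis, as the assay analysis does.
    """
    if events.empty:
        raise ValueError("no events to group")
    groups: list[LifetimeGroup] = []
    for (construct, f_tot), sub in events.groupby(["construct", "F_Tot_pN"]):
        if "F_Load_pN" in sub.columns and sub["F_Load_pN"].notna().all():
            f_load = float(sub["F_Load_pN"].iloc[0])
        elif geom_by_construct is not None:
            geom = geom_by_construct[int(construct)]
            f_load = solve_bound_state(float(f_tot), geom).F_Load
        else:
            raise ValueError("events lack F_Load_pN and no geometry supplied")
        groups.append(
            LifetimeGroup(
                construct=int(construct),
                F_Tot=float(f_tot),
                F_Load=f_load,
                lifetimes=sub["tau_s"].to_numpy(),
                n_molecules=int(sub["molecule_id"].nunique()),
            )
        )
    groups.sort(key=lambda g: (g.construct, g.F_Tot))
    return groups


def groups_to_frame(groups: list[LifetimeGroup]) -> pd.DataFrame:
    """Summary table with the on-disk CSV column layout."""
    return pd.DataFrame(
        [
            {
                "construct": g.construct,
                "F_Tot_pN": g.F_Tot,
                "F_Load_pN": g.F_Load,
                "n_events": g.n_events,
                "n_molecules": g.n_molecules,
                "mean_tau_s": g.mean_tau,
                "sem_tau_s": g.sem_tau,
                "off_rate_per_s": g.off_rate,
                "single_event": g.single_event,
            }
            for g in groups
        ]
    )
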