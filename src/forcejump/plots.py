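"""Optional diagnostic plots (never an analysis surface).

Semilog survival curves use the 0.01 floor for zero survival points, the
same display convention as the assay figures; chevron plots show mean
lifetime against protein load with the fitted catch-slip curve.
"""

from __future__ import annotations

import numpy as np

from .kinetics import SurvivalCurve
from .mechanics import TetherGeometry, f_load_curve
from .models import BellParams, catch_slip_lifetime


def plot_survival(curves: dict[str, SurvivalCurve], ax=None):
    """Semilog survival curves, one per label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        t, s = curve.plotting_points()
        ax.semilogy(t, s, "o-", label=label, markersize=4)
    ax.set_xlabel("bond lifetime (s)")
    ax.set_ylabel("survival probability")
    ax.legend()
    return ax


def plot_chevron(groups_frame, bell: BellParams | None = None, ax=None):
    """Mean lifetime vs protein load, optionally with the model curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for construct, sub in groups_frame.groupby("construct"):
        ax.errorbar(
            sub["F_Load_pN"], sub["mean_tau_s"], yerr=sub["sem_tau_s"],
            fmt="o", capsize=3, label=f"{construct} nt bridge",
        )
    if bell is not None:
        f = np.linspace(0.0, float(groups_frame["F_Load_pN"].max()) * 1.1, 300)
        ax.plot(f, catch_slip_lifetime(f, bell), "k-", label="catch-slip fit")
    ax.set_xlabel("force on proteins, F_Load (pN)")
    ax.set_ylabel("mean bond lifetime (s)")
    ax.legend()
    return ax


def plot_delta_x(events_frame, geoms: dict[int, TetherGeometry], ax=None):
    """Measured rupture steps against the circuit-model prediction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(2.0, 14.0, 120)
    for construct, geom in geoms.items():
        sub = events_frame[events_frame["construct"] == construct]
        ax.plot(sub["F_Tot_pN"], sub["delta_x_nm"], ".", alpha=0.4,
                label=f"{construct} nt events")
        model = f_load_curve(grid, geom)
        ax.plot(model["F_Tot_pN"], model["delta_x_nm"], "k-")
    ax.set_xlabel("total force, F_Tot (pN)")
    ax.set_ylabel("Δx (nm)")
    ax.legend()
    return ax
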