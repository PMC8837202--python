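"""Worm-like-chain elasticity and the two-spring tether circuit.

In the force-jump assay a single-stranded DNA *bridge* (55 or 70 nt of
unpaired sequence) runs in parallel with a *loading* path made of two 12-nt
unpaired oligonucleotide segments plus the bound protein pair, which is
treated as an inextensible rod of length ``L_prot``.  Because the proteins
sit on the loading path, the bridge starts pre-stretched relative to the
loading strand by ``L_prot``.  The total trap force ``F_Tot`` is therefore
partitioned between the two springs:

    bound:    F_Tot = F_Bridge(x + L_prot) + F_Load(x)
    unbound:  F_Tot = F_Bridge(x + L_prot)

where ``x`` is the extension of the ssDNA portion of the loading strand and
each spring follows the worm-like chain (WLC) interpolation formula

    F * Lp / kBT = 1/4 * (1 - x/Lc)^-2 - 1/4 + x/Lc.

On dissociation the whole force shifts to the bridge, which stretches
further; the resulting position step Δx is what the trap reads out.  This
module solves both states, predicts Δx(F_Tot), and maps plateau forces to
the load actually carried by the protein pair (F_Load), which is the force
axis on which catch-bond kinetics are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: Thermal energy in pN*nm at 23 C (296 K), the assay temperature.
DEFAULT_KBT = 4.09

#: ssDNA contour length per nucleotide, nm.
DEFAULT_NM_PER_NT = 0.59

#: ssDNA persistence length, nm.
DEFAULT_PERSISTENCE_LENGTH = 1.0

#: Inextensible length of the bound protein pair, nm.
DEFAULT_L_PROT = 8.0

_X_FRAC_MAX = 0.999  # largest fractional extension the solvers will bracket


class MechanicsDomainError(ValueError):
    """Requested state lies outside the physical domain of the circuit."""


@dataclass(frozen=True)
class WLCParams:
    """Parameters of one worm-like-chain spring.

    Parameters
    ----------
    persistence_length : float
        Persistence length Lp in nm (1 nm for ssDNA here).
    contour_length : float
        Contour length Lc in nm.
    kBT : float
        Thermal energy in pN*nm.
    """

    persistence_length: float
    contour_length: float
    kBT: float = DEFAULT_KBT

    def __post_init__(self) -> None:
        for name in ("persistence_length", "contour_length", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"WLCParams.{name} must be > 0")


@dataclass(frozen=True)
class TetherGeometry:
    """Geometry and constants of the two-spring force-jump tether."""

    bridge_nt: int = 55
    loading_nt: int = 24
    nm_per_nt: float = DEFAULT_NM_PER_NT
    L_prot: float = DEFAULT_L_PROT
    persistence_length: float = DEFAULT_PERSISTENCE_LENGTH
    kBT: float = DEFAULT_KBT

    def __post_init__(self) -> None:
        if self.bridge_nt <= 0 or self.loading_nt <= 0:
            raise ValueError("strand lengths must be positive nucleotide counts")
        if self.nm_per_nt <= 0 or self.persistence_length <= 0 or self.kBT <= 0:
            raise ValueError("nm_per_nt, persistence_length and kBT must be > 0")
        if self.L_prot < 0:
            raise ValueError("L_prot must be >= 0")
        if self.bridge_contour <= self.L_prot:
            raise ValueError(
                "bridge contour length must exceed L_prot for the circuit to close"
            )

    @property
    def bridge_contour(self) -> float:
        return self.bridge_nt * self.nm_per_nt

    @property
    def loading_contour(self) -> float:
        return self.loading_nt * self.nm_per_nt

    @property
    def bridge(self) -> WLCParams:
        return WLCParams(self.persistence_length, self.bridge_contour, self.kBT)

    @property
    def loading(self) -> WLCParams:
        return WLCParams(self.persistence_length, self.loading_contour, self.kBT)


@dataclass(frozen=True)
class ForcePartition:
    """Solved mechanical state of the tether at one total force.

    ``x`` is the extension of the ssDNA part of the loading strand (nm);
    negative values mean the loading path is slack.  ``delta_x`` is the
    predicted rupture step at this total force (0 for unbound solutions and
    for slack bound states, where bond rupture moves nothing).
    """

    F_Tot: float
    F_Load: float
    F_Bridge: float
    x: float
    delta_x: float
    bound: bool


def wlc_force(extension, params: WLCParams):
    """WLC interpolation force at a given extension.

    Negative extensions are treated as slack and return zero force (an
    entropic strand cannot push).  Extensions at or beyond the contour
    length raise :class:`MechanicsDomainError` (the force diverges).
    Accepts scalars or arrays.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x >= params.contour_length):
        raise MechanicsDomainError(
            f"extension >= contour length ({params.contour_length} nm): force diverges"
        )
    t = np.clip(x, 0.0, None) / params.contour_length
    f = (params.kBT / params.persistence_length) * (
        0.25 / (1.0 - t) ** 2 - 0.25 + t
    )
    return float(f) if np.ndim(extension) == 0 else f


def wlc_extension(force: float, params: WLCParams, xtol: float = 1e-12) -> float:
    """Numerically invert :func:`wlc_force`.

    Returns the unique extension in ``[0, Lc)`` carrying the given tension.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    if force == 0:
        return 0.0
    lc = params.contour_length
    hi = lc * (1.0 - 1e-12)
    if wlc_force(hi, params) < force:  # pragma: no cover - astronomically stiff
        raise MechanicsDomainError("force beyond representable WLC range")
    return float(brentq(lambda x: wlc_force(x, params) - force, 0.0, hi, xtol=xtol))


def _bound_total_force(x: float, geom: TetherGeometry) -> float:
    """Total force on the tether at loading-strand extension x, proteins bound."""
    return wlc_force(x, geom.loading) + wlc_force(x + geom.L_prot, geom.bridge)


def solve_bound_state(
    F_Tot: float, geom: TetherGeometry, xtol: float = 1e-9
) -> ForcePartition:
    """Partition a total force over the bound (two-spring) tether.

    Solves ``F_Load(x) + F_Bridge(x + L_prot) = F_Tot`` for the
    loading-strand extension ``x`` by bracketed root finding; the summed
    force-extension curve is strictly increasing, so the root is unique.
    If even at ``x = 0`` the pre-stretched bridge alone carries more than
    ``F_Tot``, the loading strand is slack: the bound state degenerates to
    the unbound geometry with ``F_Load = 0``.
    """
    if F_Tot < 0:
        raise ValueError("F_Tot must be >= 0")
    if F_Tot <= wlc_force(geom.L_prot, geom.bridge):
        # loading path slack: bridge carries everything, proteins feel nothing
        x = wlc_extension(F_Tot, geom.bridge) - geom.L_prot
        return ForcePartition(F_Tot, 0.0, F_Tot, x, 0.0, bound=True)
    x_hi = min(
        _X_FRAC_MAX * geom.loading_contour,
        geom.bridge_contour - geom.L_prot - 1e-9 * geom.bridge_contour,
    )
    if _bound_total_force(x_hi, geom) < F_Tot:
        raise MechanicsDomainError(
            f"F_Tot={F_Tot} pN not reachable below fractional extension "
            f"{_X_FRAC_MAX} for this geometry"
        )
    x = float(
        brentq(lambda v: _bound_total_force(v, geom) - F_Tot, 0.0, x_hi, xtol=xtol)
    )
    f_load = wlc_force(x, geom.loading)
    x_unbound = wlc_extension(F_Tot, geom.bridge) - geom.L_prot
    delta_x = max(x_unbound - x, 0.0)
    return ForcePartition(F_Tot, f_load, F_Tot - f_load, x, delta_x, bound=True)


def solve_unbound_state(F_Tot: float, geom: TetherGeometry) -> ForcePartition:
    """State after rupture: the bridge alone carries the full trap force."""
    if F_Tot < 0:
        raise ValueError("F_Tot must be >= 0")
    x = wlc_extension(F_Tot, geom.bridge) - geom.L_prot
    return ForcePartition(F_Tot, 0.0, F_Tot, x, 0.0, bound=False)


def predict_delta_x(F_Tot: float, geom: TetherGeometry) -> float:
    """Predicted rupture step Δx = x_unbound - x_bound at constant F_Tot."""
    if F_Tot <= 0:
        raise ValueError("F_Tot must be > 0")
    return solve_bound_state(F_Tot, geom).delta_x


def f_load_curve(F_Tot_grid, geom: TetherGeometry) -> pd.DataFrame:
    """Tabulate the circuit model over a grid of total forces.

    Returns a DataFrame with columns ``F_Tot_pN``, ``F_Load_pN``,
    ``F_Bridge_pN`` and ``delta_x_nm``; used to map plateau forces to
    protein loads when pooling events, and as a QC/plotting table.
    """
    grid = np.asarray(F_Tot_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("F_Tot_grid must be a non-empty 1-D array")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("F_Tot_grid must be positive and strictly increasing")
    rows = [solve_bound_state(f, geom) for f in grid]
    return pd.DataFrame(
        {
            "F_Tot_pN": grid,
            "F_Load_pN": [r.F_Load for r in rows],
            "F_Bridge_pN": [r.F_Bridge for r in rows],
            "delta_x_nm": [r.delta_x for r in rows],
        }
    )
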