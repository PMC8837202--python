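"""Synthetic force-jump sessions and titrations with known ground truth.

The simulator emulates the statistical structure of the force-jump assay:
constant-force cycles alternating a 0.5 pN low plateau (binding permitted,
collapsed to a single Bernoulli outcome at jump time) and a 4-12 pN high
plateau held for at least 5 s at 200 Hz.  If the proteins are bound at the
jump, they experience the load F_Load given by the mechanical circuit, the
bond survives an exponentially distributed time whose mean follows the
catch-slip law, and rupture steps the position by the circuit-model Δx.
Gaussian position noise, optional per-molecule linear drift, and a
single-pole low-pass mimicking the instrument response (~7.5 ms) are
applied on top.  Every high plateau carries a ground-truth record, so the
entire detection/fitting pipeline can be validated event by event without
any recorded data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .detection import PlateauSpec, TraceRecord
from .mechanics import TetherGeometry, solve_bound_state, wlc_extension
from .models import BellParams, catch_slip_lifetime

#: minimum plateau dwell of the assay, s ("held for at least 5 s")
MIN_PLATEAU_S = 5.0


@dataclass(frozen=True)
class GroundTruthRecord:
    """What really happened on one high-force plateau."""

    plateau_id: int
    bound_at_jump: bool
    tau: float  # s; nan if never bound
    delta_x: float  # nm; 0 if never bound
    F_Load: float  # pN
    F_Tot: float  # pN
    censored: bool  # bond outlived the plateau (no step in record)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated session set.

    Defaults mirror the assay: 200 Hz sampling, 0.5 pN low force, high
    forces {4, 6, 8, 10, 12} pN, 5 s plateaus, ~7.5 ms instrument
    response.  ``noise_sd`` defaults to 1 nm, a typical point-to-point
    position noise for a dual-trap instrument at 200 Hz, which puts the
    smallest analyzed rupture step (~3.4 nm, 55-nt bridge at 4 pN) above
    3 eSD and mid-range steps at 5-9 eSD; ``p_bind`` (fraction of jumps
    showing a bound intermediate) is a free choice of 0.3.  ``fixed_tau``
    overrides the exponential lifetime draw for noiseless round-trip
    checks.
    """

    bell: BellParams
    geom: TetherGeometry = TetherGeometry()
    sampling_rate: float = 200.0
    low_force: float = 0.5
    high_forces: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0)
    plateau_s: float = 5.0
    n_molecules: int = 4
    cycles_per_molecule: int = 25
    p_bind: float = 0.3
    noise_sd: float = 1.0  # nm
    drift_sd_nm_per_s: float = 0.5  # per-molecule drift rate spread
    response_time_s: float = 0.0075
    fixed_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.plateau_s < MIN_PLATEAU_S:
            raise ValueError(
                f"plateau_s must be >= {MIN_PLATEAU_S} s (assay minimum dwell)"
            )
        if not 0.0 <= self.p_bind <= 1.0:
            raise ValueError("p_bind must lie in [0, 1]")
        if self.sampling_rate <= 0 or self.low_force < 0:
            raise ValueError("sampling_rate must be > 0 and low_force >= 0")
        if min(self.high_forces) <= self.low_force:
            raise ValueError("high forces must exceed the low force")
        if self.noise_sd < 0 or self.drift_sd_nm_per_s < 0 or self.response_time_s < 0:
            raise ValueError("noise, drift and response time must be >= 0")


def _geometry_for(config: SimulationConfig, construct: int) -> TetherGeometry:
    return dataclasses.replace(config.geom, bridge_nt=construct)


def _single_pole_lowpass(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exponential smoother y[n] = y[n-1] + a*(x[n]-y[n-1]), a = dt/(tau+dt)."""
    if tau <= 0:
        return x
    a = dt / (tau + dt)
    y, _ = lfilter([a], [1.0, a - 1.0], x, zi=[(1.0 - a) * x[0]])
    return y


def simulate_session(
    config: SimulationConfig,
    construct: int,
    molecule_id: str,
    rng: np.random.Generator,
    synthesize: bool = True,
) -> TraceRecord:
    """Simulate one molecule's force-jump session.

    Cycles step round-robin through ``config.high_forces``.  With
    ``synthesize=False`` only the plateau schedule and ground-truth log
    are generated (no waveform), which is cheap enough for large-n
    statistical checks.
    """
    geom = _geometry_for(config, construct)
    dt = 1.0 / config.sampling_rate
    n_pl = int(round(config.plateau_s * config.sampling_rate))

    # per-force mechanics and kinetics, computed once
    levels: dict[float, tuple[float, float, float]] = {}
    for f_tot in config.high_forces:
        part = solve_bound_state(f_tot, geom)
        pos_bound = part.x + geom.L_prot  # bridge-side extension, nm
        levels[f_tot] = (part.F_Load, part.delta_x, pos_bound)
    pos_low = wlc_extension(config.low_force, geom.bridge)

    n_cycles = config.cycles_per_molecule
    n_total = n_cycles * 2 * n_pl
    schedule: list[PlateauSpec] = []
    truth: list[GroundTruthRecord] = []
    clean = np.empty(n_total) if synthesize else None
    force = np.empty(n_total) if synthesize else None

    pid = 0
    cursor = 0
    for cycle in range(n_cycles):
        f_tot = config.high_forces[cycle % len(config.high_forces)]
        f_load, delta_x, pos_bound = levels[f_tot]

        lo = PlateauSpec(pid, cursor, cursor + n_pl, "low", config.low_force)
        schedule.append(lo)
        if synthesize:
            clean[lo.start : lo.end] = pos_low
            force[lo.start : lo.end] = config.low_force
        pid += 1
        cursor += n_pl

        bound = bool(rng.random() < config.p_bind)
        if bound:
            tau = (
                config.fixed_tau
                if config.fixed_tau is not None
                else float(rng.exponential(catch_slip_lifetime(f_load, config.bell)))
            )
            k = int(np.ceil(tau / dt))  # samples with t < tau stay bound
            censored = k >= n_pl
        else:
            tau, k, censored = float("nan"), 0, False

        hi = PlateauSpec(pid, cursor, cursor + n_pl, "high", f_tot)
        schedule.append(hi)
        if synthesize:
            seg = force[hi.start : hi.end]
            seg[:] = f_tot
            pos = clean[hi.start : hi.end]
            if bound:
                kk = min(k, n_pl)
                pos[:kk] = pos_bound
                pos[kk:] = pos_bound + delta_x
            else:
                pos[:] = pos_bound + delta_x  # unbound level from the start
        truth.append(
            GroundTruthRecord(
                plateau_id=pid,
                bound_at_jump=bound,
                tau=tau,
                delta_x=delta_x if bound else 0.0,
                F_Load=f_load,
                F_Tot=f_tot,
                censored=censored,
            )
        )
        pid += 1
        cursor += n_pl

    t = np.arange(n_total) * dt
    if synthesize:
        # the force jump itself is sub-sample (~20,000 pN/s), and plateaus
        # are delimited where the force has settled, so the instrument
        # response is applied per plateau: rupture steps are smoothed but
        # the inter-plateau jump does not bleed into the analysis window
        position = clean.copy()
        for p in schedule:
            position[p.start : p.end] = _single_pole_lowpass(
                clean[p.start : p.end], dt, config.response_time_s
            )
        if config.drift_sd_nm_per_s > 0:
            drift_rate = float(rng.normal(0.0, config.drift_sd_nm_per_s))
            position = position + drift_rate * t
        if config.noise_sd > 0:
            position = position + rng.normal(0.0, config.noise_sd, n_total)
    else:
        position = np.zeros(0)
        force = np.zeros(0)
        t = np.zeros(0)

    return TraceRecord(
        time=t,
        position=position,
        force=force,
        schedule=schedule,
        construct=construct,
        molecule_id=molecule_id,
        sampling_rate=config.sampling_rate,
        ground_truth=truth,
    )


def simulate_corpus(
    config: SimulationConfig,
    seed: int,
    constructs: tuple[int, ...] = (55, 70),
    label: str = "sim",
    synthesize: bool = True,
) -> list[TraceRecord]:
    """Simulate ``n_molecules`` sessions per bridge construct, reproducibly."""
    rng = np.random.default_rng(seed)
    traces = []
    for construct in constructs:
        for m in range(config.n_molecules):
            traces.append(
                simulate_session(
                    config,
                    construct,
                    molecule_id=f"{label}_{construct}nt_m{m:02d}",
                    rng=rng,
                    synthesize=synthesize,
                )
            )
    return traces


def simulate_mst(
    KD: float,
    Ymax: float,
    noise_fraction: float,
    rng: np.random.Generator,
    n_points: int = 16,
    top_uM: float = 40.0,
) -> pd.DataFrame:
    """Simulate an MST titration: 1:2 serial dilutions from the top
    concentration (80 uM stock mixed 1:1 with the 50 nM labeled partner
    gives 40 uM final), with Gaussian noise as a fraction of Ymax."""
    if KD <= 0:
        raise ValueError("KD must be > 0")
    conc = top_uM / 2.0 ** np.arange(n_points)
    y = Ymax * conc / (KD + conc)
    if noise_fraction > 0:
        y = y + rng.normal(0.0, noise_fraction * abs(Ymax), n_points)
    return pd.DataFrame({"conc_uM": conc, "dfnorm": y})


def make_fixture_suite(outdir, seed: int) -> dict:
    """Write a small deterministic corpus exercising every pipeline stage.

    Produces negative-control sessions (p_bind = 0), catch-bond sessions
    with the Rsa4-like and Ytm1-like printed parameters as ground truth,
    and an MST titration table, plus a manifest with per-file SHA-256
    hashes.  Sized so the full simulate -> detect -> fit pipeline runs in
    well under two minutes on one CPU.
    """
    from pathlib import Path

    from . import io
    from .models import RSA4_BELL, YTM1_BELL

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    negative = SimulationConfig(
        bell=RSA4_BELL, p_bind=0.0, n_molecules=2, cycles_per_molecule=50
    )
    rsa4 = SimulationConfig(
        bell=RSA4_BELL, n_molecules=5, cycles_per_molecule=30
    )
    ytm1 = SimulationConfig(
        bell=YTM1_BELL, n_molecules=5, cycles_per_molecule=30
    )
    written = {}
    for name, cfg, sd in (
        ("negative", negative, seeds[0]),
        ("rsa4_like", rsa4, seeds[1]),
        ("ytm1_like", ytm1, seeds[2]),
    ):
        sub = outdir / name
        for trace in simulate_corpus(cfg, seed=sd, label=name):
            io.write_trace(trace, sub)
        written[name] = str(sub)

    mst_dir = outdir / "mst"
    mst_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seeds[3])
    table = simulate_mst(KD=6.9, Ymax=20.0, noise_fraction=0.05, rng=rng)
    table.to_csv(mst_dir / "rsa4_mst.csv", index=False)
    written["mst"] = str(mst_dir)

    manifest = io.write_manifest(outdir)
    written["manifest"] = str(manifest)
    return written
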