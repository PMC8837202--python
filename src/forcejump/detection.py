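"""Event extraction from force-jump traces.

Each high-force plateau is screened for a single dissociation step: the
position record is centered on the mean of its first five samples, an
effective noise scale (eSD, the median of 10-point boxcar standard
deviations) is estimated, and the samples are decoded with a two-state
hidden Markov model.  The intermediate (proteins bound) and final
(proteins unbound) levels are Gaussian emitters centered at 0 and +4 eSD
with standard deviation 1 eSD, and the transition matrix only permits the
bound -> unbound move, so the Viterbi path is exactly a single-changepoint
segmentation.  Accepted events carry a bond lifetime tau (time from the
force jump to the decoded changepoint), a step size delta_x (difference of
level means over equal pre/post windows), and the protein load F_Load
assigned through the mechanical circuit model.

Automated screens replace the manual curation of recorded data: events
shorter than four samples, events whose post-rupture samples still drift,
and events whose level change is not an essentially instantaneous step are
rejected, with reasons tallied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .mechanics import TetherGeometry, solve_bound_state


class EventRejected(Exception):
    """A candidate event failed one of the acceptance screens."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class PlateauSpec:
    """One constant-force plateau inside a trace."""

    plateau_id: int
    start: int  # inclusive sample index
    end: int  # exclusive sample index
    level: str  # "low" | "high"
    F_Tot: float  # pN


@dataclass
class TraceRecord:
    """One molecule's force-jump session (recorded or simulated)."""

    time: np.ndarray  # s
    position: np.ndarray  # nm
    force: np.ndarray  # pN
    schedule: list[PlateauSpec]
    construct: int  # bridge length, nt
    molecule_id: str
    sampling_rate: float = 200.0
    ground_truth: Optional[list] = None  # GroundTruthRecord list for simulations

    def __post_init__(self) -> None:
        n = len(self.position)
        if not (len(self.time) == len(self.force) == n):
            raise ValueError("time, position and force must have equal length")
        if n > 0:  # schedule-only records (no waveform) skip the bounds check
            for p in self.schedule:
                if not (0 <= p.start < p.end <= n):
                    raise ValueError(f"plateau {p.plateau_id} indices outside trace")


@dataclass(frozen=True)
class NoiseEstimate:
    """Effective noise scale of a plateau."""

    eSD: float  # nm
    boxcar_width: int = 10


@dataclass(frozen=True)
class StatePath:
    """Decoded state sequence: 0 = intermediate/bound, 1 = final/unbound."""

    states: np.ndarray
    changepoint: Optional[int]  # index of the first unbound sample, or None


@dataclass(frozen=True)
class BindingEvent:
    """One accepted dissociation event."""

    molecule_id: str
    construct: int
    plateau_id: int
    F_Tot: float  # pN
    F_Load: float  # pN, from the mechanical circuit model
    tau: float  # s
    delta_x: float  # nm
    n_pre_samples: int
    flags: str = ""


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds of the event detector.

    All defaults mirror the assay analysis: 10-sample boxcar for eSD, a
    per-sample bound->unbound transition probability of 1e-3 (a log penalty
    of about -6.9 that sets detection sensitivity but not changepoint
    location for well-separated levels), emitter separation of 4 eSD, and a
    four-sample minimum event length.  The drift and instantaneity screens
    are reproducible proxies for manual trace curation.
    """

    boxcar_width: int = 10
    p_trans: float = 1e-3
    emitter_separation: float = 4.0  # in eSD units
    min_pre_samples: int = 4
    min_post_samples: int = 1
    drift_slope_esd_per_s: float = 2.0  # post-rupture slope screen
    truncate_halfwidth_s: float = 0.5  # window kept around the jump on drift
    max_transition_span: int = 5  # mid-band smoothed samples near the step
    step_vs_ramp_min_chi2: float = 25.0  # min SSE gain of step over line, in eSD^2
    esd_floor: float = 1e-9  # nm; keeps noiseless synthetic traces decodable


def center_plateau(segment: np.ndarray) -> np.ndarray:
    """Shift a plateau so the mean of its first five samples is zero."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < 5:
        raise EventRejected("plateau shorter than 5 samples")
    return seg - seg[:5].mean()


def estimate_noise(segment: np.ndarray, boxcar_width: int = 10) -> NoiseEstimate:
    """Median of sliding-window sample standard deviations (the eSD)."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < boxcar_width:
        raise EventRejected(f"plateau shorter than boxcar width {boxcar_width}")
    windows = sliding_window_view(seg, boxcar_width)
    sds = windows.std(axis=1, ddof=1)
    return NoiseEstimate(eSD=float(np.median(sds)), boxcar_width=boxcar_width)


def viterbi_decode(
    segment: np.ndarray,
    noise: NoiseEstimate,
    p_trans: float = 1e-3,
    emitter_separation: float = 4.0,
) -> StatePath:
    """Maximum-likelihood state path of the one-way two-state Gaussian HMM.

    State 0 emits N(0, eSD^2), state 1 emits N(sep*eSD, eSD^2); the chain
    starts in state 0 and state 1 is absorbing, so any decoded path has at
    most one transition.  Returns the index of the first state-1 sample as
    the changepoint.
    """
    if noise.eSD <= 0:
        raise EventRejected("degenerate emission: eSD must be > 0")
    if not 0.0 < p_trans < 1.0:
        raise ValueError("p_trans must lie strictly between 0 and 1")
    z = np.asarray(segment, dtype=float) / noise.eSD
    e0 = (-0.5 * z**2).tolist()
    e1 = (-0.5 * (z - emitter_separation) ** 2).tolist()
    n = len(e0)
    log_stay = math.log1p(-p_trans)
    log_go = math.log(p_trans)

    # dynamic program over the two states; the absorbing state keeps the
    # index where its best path left state 0
    d0 = e0[0]
    d1 = -math.inf
    cp = -1
    for t in range(1, n):
        cand = d0 + log_go
        if cand > d1:
            d1 = cand
            cp = t
        d1 += e1[t]
        d0 += log_stay + e0[t]

    if d1 > d0:
        states = np.zeros(n, dtype=np.uint8)
        states[cp:] = 1
        return StatePath(states=states, changepoint=cp)
    return StatePath(states=np.zeros(n, dtype=np.uint8), changepoint=None)


def extract_event(
    segment: np.ndarray,
    path: StatePath,
    sampling_rate: float,
    min_pre_samples: int = 4,
    min_post_samples: int = 1,
) -> tuple[float, float, int]:
    """Lifetime and step size of a decoded changepoint.

    The bond lifetime is the duration preceding the state change; delta_x
    is the difference in means of an equal number of samples (the binding
    duration, clipped to availability) before and after the changepoint.
    Returns ``(tau, delta_x, n_pre)`` or raises :class:`EventRejected`.
    """
    if path.changepoint is None:
        raise EventRejected("no state change decoded")
    cp = path.changepoint
    seg = np.asarray(segment, dtype=float)
    n_pre = cp
    n_post_avail = seg.size - cp
    if n_pre < min_pre_samples:
        raise EventRejected("event shorter than minimum sample count")
    if n_post_avail < min_post_samples:
        raise EventRejected("too few post-rupture samples to estimate delta_x")
    n_use = min(n_pre, n_post_avail)
    delta_x = float(seg[cp : cp + n_use].mean() - seg[:cp].mean())
    tau = cp / sampling_rate
    return tau, delta_x, n_pre


def _post_slope(segment: np.ndarray, cp: int, sampling_rate: float) -> float:
    """Least-squares slope (nm/s) of the post-changepoint samples."""
    post = np.asarray(segment[cp:], dtype=float)
    if post.size < 3:
        return 0.0
    t = np.arange(post.size) / sampling_rate
    return float(np.polyfit(t, post, 1)[0])


def truncate_for_drift(
    segment: np.ndarray,
    changepoint: int,
    noise: NoiseEstimate,
    sampling_rate: float,
    drift_slope_esd_per_s: float = 2.0,
    truncate_halfwidth_s: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Clip a drifting plateau to a window around its provisional jump.

    If the linear slope of the post-changepoint samples exceeds the screen
    threshold (in eSD per second), return the sub-segment of configurable
    half-width centered on the changepoint together with its start offset;
    otherwise return the segment unchanged with offset 0.  The window is
    centered on the changepoint, so truncation never removes it.
    """
    seg = np.asarray(segment, dtype=float)
    slope = _post_slope(seg, changepoint, sampling_rate)
    if abs(slope) <= drift_slope_esd_per_s * noise.eSD:
        return seg, 0
    half = max(int(round(truncate_halfwidth_s * sampling_rate)), 10)
    start = max(changepoint - half, 0)
    end = min(changepoint + half, seg.size)
    return seg[start:end], start


def _transition_span(
    segment: np.ndarray, cp: int, n_use: int, window: int = 10
) -> int:
    """Samples near the changepoint lying between the two levels.

    Median-smooths the trace (width 5, suppressing single-sample noise
    excursions) and counts, within ``cp +/- window``, the samples whose
    smoothed value falls in the middle band (35-65%) between the pre and
    post level means.  An instantaneous step blurred only by the
    instrument response occupies ~2 such samples; a ramp masquerading as
    a step fills the window.
    """
    from scipy.ndimage import median_filter

    seg = np.asarray(segment, dtype=float)
    pre_mean = seg[:cp].mean()
    post_mean = seg[cp : cp + n_use].mean()
    delta = post_mean - pre_mean
    if delta == 0:
        return 0
    lo = pre_mean + 0.35 * delta
    hi = pre_mean + 0.65 * delta
    if lo > hi:
        lo, hi = hi, lo
    a = max(cp - window, 0)
    b = min(cp + window, seg.size)
    pad = 2  # median width 5 needs context beyond the window
    local = median_filter(
        seg[max(a - pad, 0) : min(b + pad, seg.size)], size=5, mode="nearest"
    )
    lo_i = a - max(a - pad, 0)
    smoothed = local[lo_i : lo_i + (b - a)]
    return int(np.sum((smoothed > lo) & (smoothed < hi)))


def _best_step_cp(segment: np.ndarray) -> tuple[int, float]:
    """Drift-immune step scan: best changepoint of a line+step regression.

    For every candidate changepoint, computes the SSE gain of adding a
    step indicator to a linear trend, ``y = a + b*t + c*1[t >= cp]``, in
    closed form via prefix sums (the indicator is scored against the
    residual of the line fit, with its own projection removed).  Returns
    the argmax candidate and its gain.  Used as the provisional-jump
    finder when drift cancels the step over the full plateau and the
    one-way decoder cannot fire.
    """
    y = np.asarray(segment, dtype=float)
    n = y.size
    t = np.arange(n, dtype=float)
    slope, icept = np.polyfit(t, y, 1)
    e = y - (icept + slope * t)  # residual, orthogonal to [1, t]

    # suffix statistics for every cp: m = #post, St = sum of post t,
    # Stt fixed; Gram of [1, t] inverted once
    suf_e = np.cumsum(e[::-1])[::-1]
    suf_t = np.cumsum(t[::-1])[::-1]
    m = n - np.arange(n, dtype=float)
    s1, st, stt = float(n), t.sum(), float(np.dot(t, t))
    det = s1 * stt - st * st
    # b' G^-1 b with b = [m, St]
    quad = (m * m * stt - 2.0 * m * suf_t * st + suf_t * suf_t * s1) / det
    denom = m - quad
    cps = np.arange(4, n - 1)  # leave room for pre/post samples
    gain = np.full(n, -np.inf)
    valid = denom[cps] > 1e-9
    gain[cps[valid]] = suf_e[cps[valid]] ** 2 / denom[cps[valid]]
    cp = int(np.argmax(gain))
    return cp, float(gain[cp])


def _step_improvement(segment: np.ndarray, cp: int) -> float:
    """SSE gain of adding a step term at ``cp`` to a linear trend.

    Fits ``y = a + b*t`` and ``y = a + b*t + c*1[t >= cp]`` by least
    squares and returns ``SSE_line - SSE_step``.  A genuine rupture gains
    on the order of ``n_pre * delta_x^2``; a slow drift whose tail the
    decoder mistook for a final level gains only noise-scale (chi^2 with
    one degree of freedom), because the line already explains the ramp.
    """
    seg = np.asarray(segment, dtype=float)
    n = seg.size
    t = np.arange(n, dtype=float)
    step = (t >= cp).astype(float)
    x_line = np.column_stack([np.ones(n), t])
    x_full = np.column_stack([np.ones(n), t, step])
    _, res_line, _, _ = np.linalg.lstsq(x_line, seg, rcond=None)
    _, res_full, _, _ = np.linalg.lstsq(x_full, seg, rcond=None)
    sse_line = float(res_line[0]) if res_line.size else 0.0
    sse_full = float(res_full[0]) if res_full.size else 0.0
    return sse_line - sse_full


def detect_events(
    trace: TraceRecord,
    geom: TetherGeometry,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[list[BindingEvent], dict[str, int]]:
    """Run the full per-plateau detection pass over one trace.

    Scans every high-force plateau, decodes it, applies all acceptance
    screens, and assigns F_Load from the mechanical circuit.  Plateaus that
    end with the system still bound (no changepoint) are discarded, not
    censored.  Returns the accepted events and a tally of outcomes keyed by
    reason.
    """
    if geom.bridge_nt != trace.construct:
        raise ValueError(
            f"geometry bridge_nt={geom.bridge_nt} does not match trace "
            f"construct={trace.construct}"
        )
    events: list[BindingEvent] = []
    tally: dict[str, int] = {}
    f_load_cache: dict[float, float] = {}

    def count(reason: str) -> None:
        tally[reason] = tally.get(reason, 0) + 1

    for plateau in trace.schedule:
        if plateau.level != "high":
            continue
        raw = trace.position[plateau.start : plateau.end]
        try:
            event = _detect_one(raw, trace.sampling_rate, config)
        except EventRejected as err:
            count(err.reason)
            continue
        tau, delta_x, n_pre, flags = event
        f_tot = plateau.F_Tot
        if f_tot not in f_load_cache:
            f_load_cache[f_tot] = solve_bound_state(f_tot, geom).F_Load
        events.append(
            BindingEvent(
                molecule_id=trace.molecule_id,
                construct=trace.construct,
                plateau_id=plateau.plateau_id,
                F_Tot=f_tot,
                F_Load=f_load_cache[f_tot],
                tau=tau,
                delta_x=delta_x,
                n_pre_samples=n_pre,
                flags=flags,
            )
        )
        count("accepted")
    return events, tally


def _detect_one(
    raw: np.ndarray, sampling_rate: float, config: DetectionConfig
) -> tuple[float, float, int, str]:
    """Decode one high-force plateau; raises EventRejected on any screen."""
    seg = center_plateau(raw)
    noise = estimate_noise(seg, config.boxcar_width)
    if noise.eSD < config.esd_floor:
        noise = NoiseEstimate(config.esd_floor, config.boxcar_width)
    path = viterbi_decode(seg, noise, config.p_trans, config.emitter_separation)
    flags = ""
    cp_full = cp_local = None
    work, offset = seg, 0

    if path.changepoint is not None:
        work, offset = truncate_for_drift(
            seg,
            path.changepoint,
            noise,
            sampling_rate,
            config.drift_slope_esd_per_s,
            config.truncate_halfwidth_s,
        )
        if offset > 0 or work.size != seg.size:
            flags = "truncated"
            work = center_plateau(work)
            noise_t = estimate_noise(work, config.boxcar_width)
            if noise_t.eSD < config.esd_floor:
                noise_t = NoiseEstimate(config.esd_floor, config.boxcar_width)
            path_t = viterbi_decode(
                work, noise_t, config.p_trans, config.emitter_separation
            )
            if path_t.changepoint is not None:
                cp_local = path_t.changepoint
                cp_full = offset + cp_local
                noise = noise_t
            # else: provisional jump was drift-induced; fall through to the
            # drift-immune scan below
        else:
            cp_local = cp_full = path.changepoint

    if cp_full is None:
        # strong drift can cancel the step over a full plateau (the one-way
        # decoder never fires) or mislead the provisional changepoint; look
        # for the jump with the drift-immune line+step scan, truncate the
        # original record around it, and redecode (drift within the short
        # window is small)
        cp_scan, gain = _best_step_cp(seg)
        if gain < max(config.step_vs_ramp_min_chi2, 1.0) * noise.eSD**2:
            raise EventRejected("no state change decoded")
        half = max(int(round(config.truncate_halfwidth_s * sampling_rate)), 10)
        start = max(cp_scan - half, 0)
        work, offset = seg[start : min(cp_scan + half, seg.size)], start
        flags = "detrended"
        work = center_plateau(work)
        noise_t = estimate_noise(work, config.boxcar_width)
        if noise_t.eSD < config.esd_floor:
            noise_t = NoiseEstimate(config.esd_floor, config.boxcar_width)
        path_t = viterbi_decode(
            work, noise_t, config.p_trans, config.emitter_separation
        )
        if path_t.changepoint is None:
            raise EventRejected("drift: no step within truncated window")
        cp_local = path_t.changepoint
        cp_full = offset + cp_local
        noise = noise_t

    # lifetime always counts from the force jump, even after truncation
    n_pre_full = cp_full
    if n_pre_full < config.min_pre_samples:
        raise EventRejected("event shorter than minimum sample count")
    _, delta_x, n_pre_local = extract_event(
        work, StatePath(np.zeros(0, np.uint8), cp_local), sampling_rate,
        min_pre_samples=1, min_post_samples=config.min_post_samples,
    )
    tau = n_pre_full / sampling_rate

    n_use = min(n_pre_local, work.size - cp_local)
    if _transition_span(work, cp_local, n_use) > config.max_transition_span:
        raise EventRejected("gradual transition (not an instantaneous step)")
    if config.step_vs_ramp_min_chi2 > 0:
        gain = _step_improvement(work, cp_local)
        if gain < config.step_vs_ramp_min_chi2 * noise.eSD**2:
            raise EventRejected("drift-like: step adds no power over a linear trend")
    slope = _post_slope(work, cp_local, sampling_rate)
    if abs(slope) > config.drift_slope_esd_per_s * noise.eSD:
        raise EventRejected("residual post-rupture drift")
    return tau, delta_x, n_pre_full, flags


def events_to_frame(events: list[BindingEvent]):
    """Tabulate accepted events with the on-disk CSV column layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "molecule_id": e.molecule_id,
                "construct": e.construct,
                "plateau_id": e.plateau_id,
                "F_Tot_pN": e.F_Tot,
                "F_Load_pN": e.F_Load,
                "tau_s": e.tau,
                "delta_x_nm": e.delta_x,
                "n_pre_samples": e.n_pre_samples,
                "flags": e.flags,
            }
            for e in events
        ],
        columns=[
            "molecule_id",
            "construct",
            "plateau_id",
            "F_Tot_pN",
            "F_Load_pN",
            "tau_s",
            "delta_x_nm",
            "n_pre_samples",
            "flags",
        ],
    )
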