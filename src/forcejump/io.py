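"""On-disk formats: TSV traces with JSON sidecars, CSV events/groups,
JSON reports.

A trace is stored as a tab-separated table (``time_s``, ``position_nm``,
``force_pN``, ``plateau_id``) next to a ``.json`` sidecar holding the
molecule id, construct, sampling rate, the plateau schedule, and - for
simulated data - the ground-truth event log.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import PlateauSpec, TraceRecord

EVENT_COLUMNS = [
    "molecule_id",
    "construct",
    "plateau_id",
    "F_Tot_pN",
    "F_Load_pN",
    "tau_s",
    "delta_x_nm",
    "n_pre_samples",
    "flags",
]


def write_trace(trace: TraceRecord, outdir) -> Path:
    """Write one session as ``<molecule_id>.tsv`` + ``.json`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / f"{trace.molecule_id}.tsv"

    plateau_of = np.empty(len(trace.position), dtype=int)
    for p in trace.schedule:
        plateau_of[p.start : p.end] = p.plateau_id
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "position_nm": trace.position,
            "force_pN": trace.force,
            "plateau_id": plateau_of,
        }
    )
    df.to_csv(tsv, sep="\t", index=False, float_format="%.5f")

    sidecar = {
        "molecule_id": trace.molecule_id,
        "construct": trace.construct,
        "sampling_rate_hz": trace.sampling_rate,
        "schedule": [
            {
                "plateau_id": p.plateau_id,
                "start": p.start,
                "end": p.end,
                "level": p.level,
                "F_Tot_pN": p.F_Tot,
            }
            for p in trace.schedule
        ],
    }
    if trace.ground_truth is not None:
        sidecar["ground_truth"] = [
            {
                "plateau_id": g.plateau_id,
                "bound_at_jump": g.bound_at_jump,
                "tau_s": None if np.isnan(g.tau) else g.tau,
                "delta_x_nm": g.delta_x,
                "F_Load_pN": g.F_Load,
                "F_Tot_pN": g.F_Tot,
                "censored": g.censored,
            }
            for g in trace.ground_truth
        ]
    tsv.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_trace(tsv_path) -> TraceRecord:
    """Read a trace TSV and its JSON sidecar back into a TraceRecord."""
    from .simulate import GroundTruthRecord  # deferred: io <-> simulate

    tsv_path = Path(tsv_path)
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    df = pd.read_csv(tsv_path, sep="\t")
    schedule = [
        PlateauSpec(
            plateau_id=int(s["plateau_id"]),
            start=int(s["start"]),
            end=int(s["end"]),
            level=s["level"],
            F_Tot=float(s["F_Tot_pN"]),
        )
        for s in meta["schedule"]
    ]
    truth = None
    if "ground_truth" in meta:
        truth = [
            GroundTruthRecord(
                plateau_id=int(g["plateau_id"]),
                bound_at_jump=bool(g["bound_at_jump"]),
                tau=float("nan") if g["tau_s"] is None else float(g["tau_s"]),
                delta_x=float(g["delta_x_nm"]),
                F_Load=float(g["F_Load_pN"]),
                F_Tot=float(g["F_Tot_pN"]),
                censored=bool(g["censored"]),
            )
            for g in meta["ground_truth"]
        ]
    return TraceRecord(
        time=df["time_s"].to_numpy(),
        position=df["position_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        schedule=schedule,
        construct=int(meta["construct"]),
        molecule_id=meta["molecule_id"],
        sampling_rate=float(meta["sampling_rate_hz"]),
        ground_truth=truth,
    )


def list_traces(directory) -> list[Path]:
    """All trace TSVs in a directory, sorted for deterministic iteration."""
    return sorted(Path(directory).glob("*.tsv"))


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.reindex(columns=EVENT_COLUMNS).to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(directory) -> Path:
    """List every data file in a corpus directory with its SHA-256."""
    directory = Path(directory)
    entries = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(directory))] = {
                "sha256": sha256_file(p),
                "bytes": p.stat().st_size,
            }
    out = directory / "manifest.json"
    out.write_text(json.dumps(entries, indent=1))
    return out
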