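"""Orchestration of simulate -> detect -> summarize -> fit.

Each stage consumes only the declared files of the previous stage; the
final report carries the config hash, software version and seed so a run
is reproducible from its report alone (timestamps are isolated in a
single field).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .detection import detect_events, events_to_frame
from .kinetics import group_and_summarize, groups_to_frame
from .models import (
    DegenerateBranchError,
    UnidentifiableKDError,
    fit_binding_isotherm,
    fit_catch_slip,
)
from .simulate import make_fixture_suite

log = logging.getLogger("forcejump")

__version__ = "0.1.0"


def run_simulate(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Write the deterministic fixture corpus and its manifest."""
    seed = config.seed if seed is None else seed
    written = make_fixture_suite(outdir, seed)
    log.info("simulate: corpus written under %s", outdir)
    return written


def run_detect(config: PipelineConfig, indir, out_csv) -> pd.DataFrame:
    """Detect events in every trace under ``indir`` and write the CSV."""
    det = config.detection.detection_config()
    all_events = []
    tally: dict[str, int] = {}
    paths = io.list_traces(indir)
    if not paths:
        raise FileNotFoundError(f"no trace TSVs under {indir}")
    for path in paths:
        trace = io.read_trace(path)
        geom = config.geometry.geometry(trace.construct)
        events, t = detect_events(trace, geom, det)
        all_events.extend(events)
        for k, v in t.items():
            tally[k] = tally.get(k, 0) + v
    frame = events_to_frame(all_events)
    io.write_events(frame, out_csv)
    log.info(
        "detect: %d traces, %d events accepted, rejections: %s",
        len(paths),
        len(frame),
        {k: v for k, v in sorted(tally.items()) if k != "accepted"},
    )
    frame.attrs["tally"] = tally
    return frame


def run_fit(
    config: PipelineConfig,
    events_csv,
    out_json,
    mst_csv=None,
    seed: int | None = None,
) -> dict:
    """Group events, fit the catch-slip Bell model (and isotherm), report."""
    events = io.read_events(events_csv)
    report: dict = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed if seed is None else seed,
        "timestamps": {"completed_unix": time.time()},
        "n_events": int(len(events)),
        "inputs": {"events_csv": str(events_csv), "events_sha256": io.sha256_file(events_csv)},
    }
    if events.empty:
        report["groups"] = []
        report["bell_fit"] = {"skipped": "no events"}
        io.write_report(report, out_json)
        return report

    groups = group_and_summarize(events)
    gframe = groups_to_frame(groups)
    report["groups"] = gframe.to_dict(orient="records")

    force_col = "F_Load_pN" if config.grouping.axis == "F_Load" else "F_Tot_pN"
    fit_input = gframe if config.grouping.pool_constructs else gframe[
        gframe["construct"] == gframe["construct"].iloc[0]
    ]
    n_levels = fit_input[force_col].nunique()
    if n_levels < config.fit.min_force_levels:
        report["bell_fit"] = {
            "skipped": f"only {n_levels} force levels (< {config.fit.min_force_levels})"
        }
    else:
        try:
            fit = fit_catch_slip(
                fit_input,
                kBT=config.fit.kBT,
                force_column=force_col,
                weights=config.fit.weighting,
            )
            report["bell_fit"] = {
                "kc0_per_s": fit.params.kc0,
                "xc_nm": fit.params.xc,
                "ks0_per_s": fit.params.ks0,
                "xs_nm": fit.params.xs,
                "kBT_pN_nm": fit.params.kBT,
                "ci95": fit.ci95,
                "F_crit_pN": fit.F_crit,
                "n_groups": fit.n_groups,
                "redchi": fit.redchi,
            }
        except DegenerateBranchError as err:
            report["bell_fit"] = {"skipped": str(err)}

    if mst_csv is not None:
        mst = pd.read_csv(mst_csv)
        try:
            iso = fit_binding_isotherm(mst["conc_uM"], mst["dfnorm"])
            report["isotherm_fit"] = {
                "KD_uM": iso.KD,
                "Ymax": iso.Ymax,
                "ci95": iso.ci95,
                "n_points": iso.n_points,
            }
        except UnidentifiableKDError as err:
            report["isotherm_fit"] = {"skipped": str(err)}

    io.write_report(report, out_json)
    log.info("fit: report written to %s", out_json)
    return report


def run_all(config: PipelineConfig, workdir, seed: int | None = None) -> dict:
    """simulate -> detect -> fit on the Rsa4-like corpus, end to end."""
    workdir = Path(workdir)
    run_simulate(config, workdir / "corpus", seed=seed)
    events = run_detect(
        config, workdir / "corpus" / "rsa4_like", workdir / "events.csv"
    )
    report = run_fit(
        config,
        workdir / "events.csv",
        workdir / "report.json",
        mst_csv=workdir / "corpus" / "mst" / "rsa4_mst.csv",
        seed=seed,
    )
    report["n_detected_events"] = int(len(events))
    return report
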