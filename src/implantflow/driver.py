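"""Run orchestration: single scenarios and contact-angle sweeps.

A sweep runs one simulation per contact angle (the 5-degree run is the
ratio reference), then assembles the stage-average tables, ratio tables
and rate correlations, and writes per-run CSV/VTK/PNG artefacts.
Identical configurations produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import sys
import time
from pathlib import Path

import pandas as pd

from . import metrics
from .config import RunConfig
from .export import export_fields, write_series_csv
from .solver import run_simulation


def run_one(config: RunConfig, progress: bool = False):
    """Run a single scenario; returns ``(snapshots, series)`` and writes
    the configured artefacts under ``outdir``."""
    mesh = config.mesh()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    snapshots, series = run_simulation(mesh, config.props, config.bc,
                                       config.solver, progress=progress)
    if config.export_csv:
        write_series_csv(series, outdir / "infiltration.csv")
    fmt = {(True, True): "both", (True, False): "vtk",
           (False, True): "png"}.get((config.export_vtk, config.export_png))
    if fmt:
        export_fields(snapshots, outdir / "fields", fmt, mesh, config.props)
    return snapshots, series


def run_sweep(config: RunConfig, angles, progress: bool = False) -> dict:
    """One simulation per contact angle plus the combined analysis.

    Returns a report dict with per-angle series, the stage/ratio tables,
    the rate correlations and the hydrophilicity trend checks.  A failed
    run is recorded and the sweep continues (``report['failed']``).
    """
    angles = list(dict.fromkeys(float(a) for a in angles))  # dedupe, keep order
    if not angles:
        raise ValueError("at least one contact angle is required")
    outroot = Path(config.outdir)
    outroot.mkdir(parents=True, exist_ok=True)

    series_by_angle: dict[float, pd.DataFrame] = {}
    failed: dict[float, str] = {}
    for angle in angles:
        sub = dataclasses.replace(
            config,
            bc=dataclasses.replace(config.bc, contact_angle=angle),
            outdir=str(outroot / f"cais_{angle:g}"),
        )
        t0 = time.perf_counter()
        if progress:
            print(f"[sweep] contact angle {angle:g} deg ...", flush=True)
        try:
            _, series = run_one(sub, progress=progress)
            series_by_angle[angle] = series
            if progress:
                print(f"[sweep]   done in {time.perf_counter() - t0:.1f} s",
                      flush=True)
        except Exception as exc:           # noqa: BLE001 - record and continue
            failed[angle] = f"{type(exc).__name__}: {exc}"
            print(f"[sweep] contact angle {angle:g} deg FAILED: {exc}",
                  file=sys.stderr, flush=True)

    report: dict = {"angles": angles, "series": series_by_angle, "failed": failed}
    if not series_by_angle:
        return report

    summaries = {a: metrics.stage_summary(s) for a, s in series_by_angle.items()}
    report["summaries"] = summaries

    means = pd.DataFrame([
        {
            "contact_angle_deg": a,
            "fib_mean_mg": metrics.run_mean(s, "m_fib_interfacial_mg"),
            "plasma_mean_mg": metrics.run_mean(s, "m_plasma_interfacial_mg"),
            "fib_rate_pct": metrics.run_mean(s, "rate_fib_pct"),
            "plasma_rate_pct": metrics.run_mean(s, "rate_plasma_pct"),
        }
        for a, s in sorted(series_by_angle.items())
    ])
    report["means"] = means

    reference = 5.0 if 5.0 in summaries else min(summaries)
    report["reference_angle"] = reference
    report["ratio_table"] = metrics.ratio_table(summaries, reference=reference)

    correlations = {}
    for a, s in series_by_angle.items():
        try:
            correlations[a] = metrics.rate_correlation(s)
        except ValueError:
            correlations[a] = None
    report["correlations"] = correlations

    # hydrophilicity trend: infiltration decreases from 5 to 70 to 100 deg
    trend = {}
    for col in ("fib_mean_mg", "plasma_mean_mg"):
        vals = means.set_index("contact_angle_deg")[col]
        checks = []
        for lo, hi in ((5.0, 70.0), (70.0, 100.0)):
            if lo in vals.index and hi in vals.index:
                checks.append(bool(vals[lo] > vals[hi]))
        trend[col] = all(checks) if checks else None
    report["trend_ok"] = trend

    # persist the combined tables
    means.to_csv(outroot / "means.csv", index=False, float_format="%.6g")
    report["ratio_table"].to_csv(outroot / "stage_ratios.csv", index=False,
                                 float_format="%.6g")
    corr_rows = [
        {"contact_angle_deg": a, "R": c.R, "p_value": c.p_value, "n": c.n}
        for a, c in sorted(correlations.items()) if c is not None
    ]
    pd.DataFrame(corr_rows).to_csv(outroot / "rate_correlations.csv",
                                   index=False, float_format="%.6g")
    return report
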