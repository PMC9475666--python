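"""End-to-end per-deployment and cohort analysis.

``analyze_deployment`` chains detection, engulfment and energetics for one
trace; ``analyze_cohort`` pools deployments, aggregates per individual and
fits the log-log scaling regressions; ``run_pipeline`` drives everything
from a RunConfig and writes the output bundle (tables + resolved config +
MANIFEST) to disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from lungeforge import engulfment as eng
from lungeforge import energetics as en
from lungeforge import scaling
from lungeforge.io import RunConfig, write_morphometrics, write_tag_trace
from lungeforge.kinematics import (
    TagTrace,
    detect_lunges,
    sample_middle_lunges,
    segment_dives,
)
from lungeforge.morphometry import WhaleMorphometrics, complete_morphometrics

__all__ = ["analyze_deployment", "analyze_cohort", "run_pipeline", "DeploymentResult"]

log = logging.getLogger(__name__)


@dataclass
class DeploymentResult:
    lunges: pd.DataFrame
    engulfment: pd.DataFrame
    energetics: pd.DataFrame
    morphometrics: WhaleMorphometrics
    n_detected: int = 0
    n_sampled: int = 0


_LUNGE_FIELDS = (
    "T_fluke", "T_accel", "T_max", "T_MO", "T_MC", "T_min",
    "U_fluke", "U_accel", "U_max", "U_MO", "U_MC", "U_min",
    "depth_at_MO", "dive_id", "position_in_dive", "distance_decel",
    "T_gyr1", "T_gyr2", "T_gyr3",
)


def analyze_deployment(
    trace: TagTrace,
    morph: WhaleMorphometrics,
    config: RunConfig | None = None,
    sample: bool = True,
) -> DeploymentResult:
    """Detect, sample and fully analyze the lunges of one deployment."""
    cfg = config or RunConfig()
    morph = complete_morphometrics(morph, cfg.allometry)
    events = detect_lunges(trace, cfg.thresholds, individual_id=morph.individual_id)
    chosen = sample_middle_lunges(events, cfg.n_sample, cfg.seed) if sample else events
    if sample and not chosen:
        chosen = events          # fall back to everything when no middle lunges
    dives = segment_dives(trace, cfg.thresholds.dive_depth)
    by_dive: dict[int, list] = {}
    for ev in events:
        by_dive.setdefault(ev.dive_id, []).append(ev)

    lunge_rows, eng_rows, en_rows = [], [], []
    for idx, ev in enumerate(chosen):
        row = {f: getattr(ev, f) for f in _LUNGE_FIELDS}
        row.update(individual_id=morph.individual_id, species=morph.species,
                   lunge_index=idx, dT_accel=ev.dT_accel,
                   dT_adjust=ev.dT_adjust, dT_decel=ev.dT_decel,
                   dT_finOs=ev.dT_finOs)
        lunge_rows.append(row)

        res = eng.compute_engulfment(
            trace.t, trace.speed, ev,
            A_jaw=morph.A_jaw, W_bz=morph.W_bz, L_rbh=morph.L_rbh,
            M_kg=morph.M_kg, rho=cfg.energetics.rho,
            max_gape_deg=cfg.max_gape_deg, vpos_end=cfg.vpos_end,
        )
        eng_rows.append({
            "individual_id": morph.individual_id, "lunge_index": idx,
            "V_pos": res.V_pos, "V_ant": res.V_ant, "V_total": res.V_total,
            "M_W": res.M_W, "D_engulf": res.D_engulf,
            "force_residual": res.force_residual,
            "normalized_residual": res.normalized_residual,
            "rho": res.rho, "T_MG": res.T_MG,
        })

        le = en.compute_lunge_energetics(ev, res, morph, cfg.energetics)
        ln_dive = max(1, len(by_dive.get(ev.dive_id, [ev])))
        if ev.dive_id >= 0 and ev.dive_id < len(dives):
            dT_dive = dives[ev.dive_id][1] - dives[ev.dive_id][0]
        else:
            dT_dive = ln_dive * (ev.dT_accel + ev.dT_decel)
        lunge_dur = ev.dT_accel + ev.dT_decel
        dT_dive = max(dT_dive, ln_dive * lunge_dur)
        ln_day = cfg.energetics.ln_day.get(morph.species, 150)
        ts = en.timescale_efficiency(
            le, ln_dive=ln_dive, dT_dive=dT_dive, ln_day=ln_day,
            lunge_duration=lunge_dur, params=cfg.energetics, M_kg=morph.M_kg,
        )
        en_rows.append({
            "individual_id": morph.individual_id, "species": morph.species,
            "lunge_index": idx,
            "W_flukes": le.W_flukes, "W_parasite": le.W_parasite,
            "W_VGB": le.W_VGB, "E_accel": le.E_accel, "E_decel": le.E_decel,
            "cet_cost": le.cet_cost, "E_cost": le.E_cost, "E_gain": le.E_gain,
            "FE": le.FE, "Re_MO": le.Re_MO, "U_mom": le.U_mom,
            "FE_dive": ts.FE_dive, "FE_day": ts.FE_day,
            "ln_dive": ts.ln_dive, "ln_day": ts.ln_day, "dT_dive": ts.dT_dive,
            "U_MO": ev.U_MO, "L_body": morph.L_body, "M_kg": morph.M_kg,
        })
    log.info("deployment %s: %d detected, %d analyzed",
             morph.individual_id, len(events), len(chosen))
    return DeploymentResult(
        lunges=pd.DataFrame(lunge_rows),
        engulfment=pd.DataFrame(eng_rows),
        energetics=pd.DataFrame(en_rows),
        morphometrics=morph,
        n_detected=len(events),
        n_sampled=len(chosen),
    )


def aggregate_individuals(energetics: pd.DataFrame) -> pd.DataFrame:
    """Per-individual means (with se) of the energetic outputs."""
    def se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    grouped = energetics.groupby(["individual_id", "species"], as_index=False)
    agg = grouped.agg(
        n_lunges=("lunge_index", "count"),
        L_body=("L_body", "first"),
        M_kg=("M_kg", "first"),
        U_MO_mean=("U_MO", "mean"),
        E_cost_mean=("E_cost", "mean"), E_cost_se=("E_cost", se),
        E_gain_mean=("E_gain", "mean"), E_gain_se=("E_gain", se),
        FE_mean=("FE", "mean"), FE_se=("FE", se),
        FE_dive_mean=("FE_dive", "mean"),
        FE_day_mean=("FE_day", "mean"),
        U_mom_mean=("U_mom", "mean"),
    )
    return agg


def cohort_regressions(per_individual: pd.DataFrame,
                       energetics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Log-log OLS fits of the cohort outputs against length and speed.

    Length regressions pool individuals across species; speed regressions
    are fitted within species at the lunge level (across species the speed
    effect is confounded with body mass).
    """
    fits = []
    df = per_individual
    if len(df) >= 3:
        for y_name, col in (("E_cost", "E_cost_mean"),
                            ("E_gain", "E_gain_mean"),
                            ("FE_lunge", "FE_mean"),
                            ("FE_dive", "FE_dive_mean"),
                            ("FE_day", "FE_day_mean")):
            fits.append(scaling.loglog_ols(
                df["L_body"], df[col], x_name="L_body", y_name=y_name,
                group="pooled"))
    if energetics is not None:
        for species, sub in energetics.groupby("species"):
            if len(sub) < 3:
                continue
            for y_name in ("E_cost", "E_gain", "FE"):
                fits.append(scaling.loglog_ols(
                    sub["U_MO"], sub[y_name], x_name="U_MO", y_name=y_name,
                    group=str(species)))
    return scaling.regression_report(fits)


def analyze_cohort(deployments, config: RunConfig | None = None) -> dict:
    """Run every deployment and pool the results.

    ``deployments`` yields (TagTrace, WhaleMorphometrics) pairs or
    SyntheticDeployment objects.
    """
    cfg = config or RunConfig()
    results = []
    for dep in deployments:
        if hasattr(dep, "trace"):
            trace, morph = dep.trace, dep.morphometrics
        else:
            trace, morph = dep
        results.append(analyze_deployment(trace, morph, cfg))
    bundle = {
        "lunges": pd.concat([r.lunges for r in results], ignore_index=True),
        "engulfment": pd.concat([r.engulfment for r in results], ignore_index=True),
        "energetics": pd.concat([r.energetics for r in results], ignore_index=True),
        "results": results,
    }
    bundle["per_individual"] = aggregate_individuals(bundle["energetics"])
    bundle["regressions"] = cohort_regressions(bundle["per_individual"],
                                               bundle["energetics"])
    return bundle


def run_pipeline(
    deployments,
    outdir,
    config: RunConfig | None = None,
) -> dict:
    """Analyze a cohort and write the full output bundle to ``outdir``.

    On a stage failure the partial outputs are retained and the MANIFEST
    records the completion state; the exception is re-raised.
    """
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "stages": [], "seed": cfg.seed}
    cfg.to_yaml(outdir / "run_config.yaml")
    try:
        bundle = analyze_cohort(deployments, cfg)
        for name in ("lunges", "engulfment", "energetics", "per_individual",
                     "regressions"):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
            manifest["stages"].append(name)
        manifest["n_lunges"] = int(len(bundle["lunges"]))
        manifest["complete"] = True
        return bundle
    finally:
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def export_deployment(dep, outdir) -> None:
    """Write a synthetic deployment (trace, morphometrics, truth) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tag_trace(dep.trace, outdir / "trace.csv")
    write_morphometrics([dep.morphometrics], outdir / "morphometrics.csv")
    truth = [
        {f: getattr(ev, f) for f in _LUNGE_FIELDS}
        for ev in dep.truth
    ]
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"seed": dep.seed, "species": dep.profile.species,
                   "events": truth}, fh, indent=2)
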