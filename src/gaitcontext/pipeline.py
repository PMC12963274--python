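"""End-to-end orchestration: simulate/load -> segment -> contextualize ->
aggregate -> modes -> statistics, with a reproducibility manifest.

Every stage writes plain CSV (plus GeoJSON for the map and JSON for ground
truth and the manifest) into the run's output directory, so any stage can be
re-examined or re-run in isolation. The manifest records the package
version, the full configuration (every analysis constant in force), the
seed, and per-stage row counts; a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bouts import bouts_to_frame, segment_participant_days
from .config import GAIT_CLASS_LABELS, RunConfig
from .context import infer_participant_context
from .dmo import aggregate_daily, aggregate_participant
from .modes import mode_count_table, modes_by_threshold
from .stats import (
    fisher_exact,
    glm_interaction,
    glm_within_cohort,
    ordinal_backward_elimination,
)
from .synthetic import generate_cohort

__all__ = ["run_pipeline", "make_report"]

log = logging.getLogger("gaitcontext")

#: DMOs entered into the indoor/outdoor GLM comparisons
DEFAULT_GLM_OUTCOMES = (
    "steps",
    "walking_min",
    "n_bouts",
    "mean_bout_duration_s",
    "max_bout_duration_s",
    "walking_speed_mps__gt10",
    "stride_length_m__gt10",
    "stride_duration_s__gt10",
    "cadence_spm__gt10",
)

#: clinical candidates for the ordinal mode-count model
ORDINAL_CANDIDATES = (
    "updrs2", "updrs3", "ledd_mg", "n_meds", "fogq",
    "pd_duration_y", "llfdi", "mass_kg", "height_m",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(cfg: RunConfig):
    from .synthetic import CohortData, GroundTruth

    strides = pd.read_csv(cfg.strides_csv)
    gps = pd.read_csv(cfg.gps_csv)
    with open(cfg.map_geojson) as fh:
        landuse = json.load(fh)
    clinical = (
        pd.read_csv(cfg.clinical_csv) if cfg.clinical_csv else pd.DataFrame()
    )
    return CohortData(
        strides=strides, gps=gps, landuse=landuse, clinical=clinical,
        truth=GroundTruth(),
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    In simulation mode the cohort seed is taken from ``cfg.seed`` so a
    single integer reproduces the whole run.
    """
    cfg.validate()
    # one integer reproduces the whole run: the seed fans out to every stage
    cfg.modes.seed = cfg.seed
    cfg.stats.seed = cfg.seed
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    counts: dict[str, int] = {}

    # --- stage: inputs -----------------------------------------------------
    try:
        if cfg.cohort is not None:
            cfg.cohort.seed = cfg.seed
            data = generate_cohort(cfg.cohort)
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(data.truth.to_dict(), fh, indent=1)
        else:
            data = _load_inputs(cfg)
    except Exception as e:  # noqa: BLE001 — abort with stage context
        raise PipelineError("inputs", str(e)) from e
    data.strides.to_csv(out / "strides.csv", index=False)
    data.gps.to_csv(out / "gps.csv", index=False)
    with open(out / "map.geojson", "w") as fh:
        json.dump(data.landuse, fh)
    if len(data.clinical):
        data.clinical.to_csv(out / "clinical.csv", index=False)
    counts["strides"] = len(data.strides)
    counts["gps_fixes"] = len(data.gps)

    # --- stage: bout segmentation ------------------------------------------
    try:
        bouts, rejections = segment_participant_days(data.strides, cfg.bouts)
    except Exception as e:
        raise PipelineError("bout_segmentation", str(e)) from e
    rejections.to_csv(out / "stride_rejections.csv", index=False)
    counts["bouts"] = len(bouts)
    log.info("segmented %d bouts (%d strides rejected)", len(bouts), len(rejections))

    # --- stage: context inference ------------------------------------------
    try:
        by_pid: dict[str, list] = {}
        for b in bouts:
            by_pid.setdefault(b.participant_id, []).append(b)
        for pid, pid_bouts in by_pid.items():
            fixes = data.gps[data.gps["participant_id"] == pid]
            infer_participant_context(pid_bouts, fixes, data.landuse, cfg.context)
    except Exception as e:
        raise PipelineError("context_inference", str(e)) from e
    bout_frame = bouts_to_frame(bouts)
    bout_frame.to_csv(out / "bouts.csv", index=False)
    bout_frame[["bout_id", "p_indoor", "context", "evidence_coverage"]].to_csv(
        out / "bout_context.csv", index=False
    )
    counts["bouts_indoor"] = int((bout_frame["context"] == "indoor").sum())
    counts["bouts_outdoor"] = int((bout_frame["context"] == "outdoor").sum())
    counts["bouts_unknown"] = int((bout_frame["context"] == "unknown").sum())

    # --- stage: DMO aggregation --------------------------------------------
    try:
        days = (
            data.strides.groupby("participant_id")["day"]
            .agg(lambda s: sorted(s.unique()))
            .to_dict()
        )
        daily = aggregate_daily(bouts, days=days)
        participant = aggregate_participant(daily, min_days=cfg.min_days)
    except Exception as e:
        raise PipelineError("dmo_aggregation", str(e)) from e
    daily.to_csv(out / "dmo_daily.csv", index=False)
    participant.to_csv(out / "dmo_participant.csv", index=False)
    counts["dmo_daily_rows"] = len(daily)
    counts["participants"] = participant["participant_id"].nunique() if len(participant) else 0

    # --- stage: walking-speed modes ----------------------------------------
    if cfg.run_modes:
        try:
            estimates, modes_log = modes_by_threshold(bouts, cfg.modes)
            cohorts = (
                dict(zip(data.clinical["participant_id"], data.clinical["cohort"]))
                if len(data.clinical)
                else {}
            )
            table = mode_count_table(estimates, cohorts)
        except Exception as e:
            raise PipelineError("speed_modes", str(e)) from e
        mode_rows = []
        bic_rows = []
        for (pid, label), est in estimates.items():
            mode_rows.append(
                {
                    "participant_id": pid,
                    "duration_class": label,
                    "selected_k": est.k,
                    "family": est.fit.family,
                    "bic": est.fit.bic,
                    "means": ";".join(f"{m:.4f}" for m in est.fit.means),
                    "sds": ";".join(f"{s:.4f}" for s in est.fit.sds),
                    "weights": ";".join(f"{w:.4f}" for w in est.fit.weights),
                }
            )
            bic_rows.append(
                est.bic_table.assign(participant_id=pid, duration_class=label)
            )
        pd.DataFrame(mode_rows).to_csv(out / "modes.csv", index=False)
        if bic_rows:
            pd.concat(bic_rows, ignore_index=True).to_csv(
                out / "bic_table.csv", index=False
            )
        modes_log.to_csv(out / "modes_log.csv", index=False)
        table.to_csv(out / "mode_table.csv", index=False)
        counts["mode_estimates"] = len(estimates)

    # --- stage: statistics --------------------------------------------------
    if cfg.run_stats and len(data.clinical):
        try:
            results = _run_stats(participant, data.clinical, cfg, out)
        except Exception as e:
            raise PipelineError("inference_stats", str(e)) from e
        results.to_csv(out / "results.csv", index=False)
        counts["stat_results"] = len(results)

    manifest = {
        "package": "gaitcontext",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _run_stats(
    participant: pd.DataFrame, clinical: pd.DataFrame, cfg: RunConfig, out: Path
) -> pd.DataFrame:
    rows = []
    cohorts = sorted(clinical["cohort"].unique())
    for outcome in DEFAULT_GLM_OUTCOMES:
        if outcome not in participant.columns:
            continue
        for cohort in cohorts:
            try:
                res = glm_within_cohort(participant, clinical, cohort, outcome,
                                        cfg.stats)
                rows.append(res.summary())
            except Exception as e:  # noqa: BLE001 — stats are per-outcome
                log.warning("within-cohort GLM failed (%s, %s): %s",
                            cohort, outcome, e)
        if len(cohorts) == 2:
            try:
                res = glm_interaction(participant, clinical, outcome, cfg.stats)
                rows.append(res.summary())
            except Exception as e:  # noqa: BLE001
                log.warning("interaction GLM failed (%s): %s", outcome, e)

    # ordinal clinical model on the mode counts, if modes ran
    modes_path = out / "modes.csv"
    trace_lines = []
    if modes_path.exists():
        modes = pd.read_csv(modes_path)
        pwp = clinical[clinical["cohort"] == "pwp"]
        for label in GAIT_CLASS_LABELS:
            sub = modes[modes["duration_class"] == label][
                ["participant_id", "selected_k"]
            ].merge(pwp, on="participant_id")
            candidates = [
                c for c in ORDINAL_CANDIDATES
                if c in sub.columns and sub[c].notna().all() and sub[c].nunique() > 1
            ]
            if len(sub) < 10 or sub["selected_k"].nunique() < 2 or not candidates:
                continue
            try:
                res = ordinal_backward_elimination(
                    sub, "selected_k", candidates, cfg.stats,
                    adjusters=("age_y",),
                )
                rows.append(res.summary().assign(duration_class=label))
                trace_lines.append(f"== duration class {label} ==")
                for t in res.elimination_trace:
                    trace_lines.append(
                        f"step {t['step']}: dropped {t['dropped']} (p={t['p']:.4f})"
                    )
                trace_lines.append(
                    f"retained: {res.diagnostics['retained']}  "
                    f"Nagelkerke R2={res.diagnostics['nagelkerke_r2']:.3f}"
                )
            except Exception as e:  # noqa: BLE001
                log.warning("ordinal model failed (%s): %s", label, e)
    if trace_lines:
        (out / "elimination_trace.txt").write_text("\n".join(trace_lines) + "\n")
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# report


def make_report(out_dir: str | Path, density_grid: int = 200) -> Path:
    """Summary exports from a finished run.

    Writes: ``report_boxplot_data.csv`` (participant-level DMOs by stratum,
    the data behind indoor/outdoor boxplots), ``report_mode_table.csv``
    (mode-count distribution per cohort and duration class with counts,
    percentages, and the modal cell flagged), and ``report_ridge.csv``
    (per-participant speed density on a common grid, the data behind a
    ridge-density figure).
    """
    out = Path(out_dir)
    for required in ("dmo_participant.csv", "bouts.csv"):
        if not (out / required).exists():
            raise PipelineError("report", f"missing stage output {required}")
    participant = pd.read_csv(out / "dmo_participant.csv")
    box = participant[participant["stratum"].isin(["indoor", "outdoor"])].copy()
    strata_present = sorted(box.loc[box["n_bouts"] > 0, "stratum"].unique())
    box.attrs["strata_present"] = strata_present
    box.to_csv(out / "report_boxplot_data.csv", index=False)

    mode_path = out / "mode_table.csv"
    if mode_path.exists():
        table = pd.read_csv(mode_path)
        k_cols = [c for c in table.columns if c.startswith("K=")]
        rows = []
        for _, row in table.iterrows():
            total = int(row[k_cols].sum())
            modal = max(k_cols, key=lambda c: row[c]) if total else ""
            rec = {"cohort": row["cohort"], "duration_class": row["duration_class"],
                   "n": total, "modal_k": modal}
            for c in k_cols:
                rec[c] = int(row[c])
                rec[f"{c}_pct"] = 100.0 * row[c] / total if total else 0.0
            rows.append(rec)
        pd.DataFrame(rows).to_csv(out / "report_mode_table.csv", index=False)

    strides_path = out / "strides.csv"
    if strides_path.exists():
        strides = pd.read_csv(strides_path)
        strides["speed_mps"] = (
            strides["stride_length_m"] / strides["stride_duration_s"]
        )
        grid = np.linspace(0.0, 2.0, density_grid)
        ridge_rows = []
        for pid, grp in strides.groupby("participant_id"):
            v = grp["speed_mps"].to_numpy()
            if v.size < 10:
                continue
            # Gaussian KDE with Silverman bandwidth
            bw = 0.9 * min(v.std(), np.subtract(*np.percentile(v, [75, 25])) / 1.34)
            bw = max(bw * v.size ** (-0.2), 1e-3)
            dens = np.exp(
                -0.5 * ((grid[:, None] - v[None, :]) / bw) ** 2
            ).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
            ridge_rows.append(
                pd.DataFrame(
                    {"participant_id": pid, "speed_mps": grid, "density": dens}
                )
            )
        if ridge_rows:
            pd.concat(ridge_rows, ignore_index=True).to_csv(
                out / "report_ridge.csv", index=False
            )
    return out
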