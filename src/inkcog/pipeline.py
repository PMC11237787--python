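"""End-to-end orchestration: simulate -> score -> extract -> stats ->
classify -> render, from one configuration.

Every stage writes its tabular outputs as CSV (the shapes mirror the
analysis' published tables: a tasks x features p-value grid, a selected
-variable coefficient table, a per-task performance table and the
cross-task averages) plus ROC and pseudocolor PNGs.  A manifest listing
every emitted file with its SHA-256 hash is written last; identical
(config, seed) runs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    DiagnosticPerformance,
    StepwiseLogisticModel,
    classify_metrics,
    task_average_performance,
)
from .errors import ConfigError
from .features import APPLICABLE_SLOTS, feature_table, slot_name
from .ink import TASK_IDS, write_sessions, write_subjects
from .render import render_pseudocolor
from .scoring import score_annotation
from .simulate import EffectConfig, PRESETS, generate_cohort
from .stats import compare_feature, significant_features

log = logging.getLogger("inkcog.pipeline")

DRAWING_TASKS = ("T1", "T2", "T5", "T6")  # the four drawing models
DRAG_TASKS = ("T7", "T8")  # the two home dragging models


@dataclass
class RunConfig:
    out_dir: str | Path = "inkcog_run"
    preset: str = "default"
    effect: EffectConfig | None = None  # overrides preset when given
    seed: int = 0
    n_hc: int = 99
    n_mci: int = 108
    alpha: float = 0.05
    entry_p: float = 0.05
    removal_p: float = 0.10
    threshold: float = 0.5
    tasks: tuple[str, ...] = TASK_IDS
    render_samples: bool = True

    def resolve_effect(self) -> EffectConfig:
        if self.effect is not None:
            return self.effect
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}", ["preset"])
        return PRESETS[self.preset](seed=self.seed, n_hc=self.n_hc, n_mci=self.n_mci)

    def check(self) -> None:
        bad = [
            name
            for name in ("alpha", "entry_p", "removal_p", "threshold")
            if not 0 < getattr(self, name) < 1
        ]
        bad += [t for t in self.tasks if t not in TASK_IDS]
        if bad:
            raise ConfigError("invalid run configuration", bad)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def score_table(sessions) -> pd.DataFrame:
    rows = []
    for s in sessions:
        rep = score_annotation(s.annotation, s.task_id)
        row = {
            "subject_id": s.subject_id,
            "task_id": s.task_id,
            "rubric": rep.rubric,
            "total": rep.total,
        }
        for name, sub in rep.per_component:
            row[f"sub_{name}"] = sub
        rows.append(row)
    return pd.DataFrame(rows)


def stats_tables(
    features: pd.DataFrame, alpha: float, tasks=TASK_IDS
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """(tasks x f01..f17 p grid, long comparison table, significant ids per task)."""
    grid_rows = []
    long_rows = []
    sig: dict[str, list[str]] = {}
    for task in tasks:
        sub = features[features.task_id == task]
        hc = sub[sub.group == "HC"]
        mci = sub[sub.group == "MCI"]
        grid: dict[str, object] = {"task_id": task}
        comps = []
        for slot in sorted(APPLICABLE_SLOTS[task]):
            col = f"f{slot:02d}"
            comp = compare_feature(
                hc[col].to_numpy(), mci[col].to_numpy(), alpha=alpha, feature_id=col
            )
            comps.append(comp)
            grid[col] = comp.p_value
            long_rows.append(
                {
                    "task_id": task,
                    "feature": col,
                    "feature_name": slot_name(task, slot),
                    "n_hc": comp.n_hc,
                    "n_mci": comp.n_mci,
                    "test_used": comp.test_used,
                    "statistic": comp.statistic,
                    "p_value": comp.p_value,
                    "hl_estimate": comp.hl.estimate,
                    "hl_ci_low": comp.hl.ci_low,
                    "hl_ci_high": comp.hl.ci_high,
                    "significant": comp.significant,
                }
            )
        sig[task] = significant_features(comps, alpha=alpha)
        grid_rows.append(grid)
    cols = ["task_id"] + [f"f{i:02d}" for i in range(1, 18)]
    grid_df = pd.DataFrame(grid_rows)
    for c in cols:
        if c not in grid_df.columns:
            grid_df[c] = np.nan
    return grid_df[cols], pd.DataFrame(long_rows), sig


def fit_task_models(
    features: pd.DataFrame,
    entry_p: float,
    removal_p: float,
    threshold: float,
    tasks=TASK_IDS,
) -> tuple[dict[str, StepwiseLogisticModel], dict[str, DiagnosticPerformance], pd.DataFrame]:
    """Stepwise model + in-sample performance per task, plus the pooled
    coefficient table."""
    models: dict[str, StepwiseLogisticModel] = {}
    perfs: dict[str, DiagnosticPerformance] = {}
    coef_rows = []
    for task in tasks:
        sub = features[features.task_id == task]
        cols = {f"f{s:02d}": slot_name(task, s) for s in sorted(APPLICABLE_SLOTS[task])}
        X = sub[list(cols)].rename(columns=cols)
        y = sub["group"].to_numpy()
        model = StepwiseLogisticModel(
            entry_p=entry_p, removal_p=removal_p, threshold=threshold
        ).fit(X, y)
        models[task] = model
        prob = model.predict_proba(X)[:, 1]
        perfs[task] = classify_metrics(prob, y, threshold=threshold, label=task)
        for _, r in model.params_table_.iterrows():
            coef_rows.append(
                {
                    "task_id": task,
                    "variable": r["feature"],
                    "beta": r["beta"],
                    "or": r["or"],
                    "or_ci_low": r["or_ci_low"],
                    "or_ci_high": r["or_ci_high"],
                    "p": r["p"],
                }
            )
    coef_df = pd.DataFrame(
        coef_rows,
        columns=["task_id", "variable", "beta", "or", "or_ci_low", "or_ci_high", "p"],
    )
    return models, perfs, coef_df


def performance_table(perfs: dict[str, DiagnosticPerformance]) -> pd.DataFrame:
    rows = []
    for task, p in perfs.items():
        rows.append(
            {
                "task_id": task,
                "accuracy": round(p.accuracy, 3),
                "sensitivity": round(p.sensitivity, 3),
                "specificity": round(p.specificity, 3),
                "auc": round(p.auc, 3),
                "auc_ci_low": round(p.auc_ci[0], 3),
                "auc_ci_high": round(p.auc_ci[1], 3),
            }
        )
    return pd.DataFrame(rows)


def averages_table(perfs: dict[str, DiagnosticPerformance]) -> pd.DataFrame:
    rows = []
    for name, group in (("drawing_average", DRAWING_TASKS), ("dragging_average", DRAG_TASKS)):
        avail = [t for t in group if t in perfs]
        if not avail:
            continue
        sens, spec = task_average_performance(perfs, avail)
        rows.append({"set": name, "tasks": "+".join(avail), "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def _save_roc(perf: DiagnosticPerformance, task: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    fpr = [p[0] for p in perf.roc]
    tpr = [p[1] for p in perf.roc]
    ax.plot(fpr, tpr, color="#31688e", lw=2, label=f"AUC = {perf.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{task} (in-sample)")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the artifact manifest."""
    config.check()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effect = config.resolve_effect()
    stage = "simulate"
    files: list[Path] = []
    try:
        log.info("simulate: %d HC + %d MCI subjects, seed %d",
                 effect.n_hc, effect.n_mci, effect.seed)
        bundle = generate_cohort(effect)
        sessions = [s for s in bundle.sessions if s.task_id in config.tasks]
        write_sessions(sessions, out / "sessions.jsonl")
        write_subjects(bundle.subjects, out / "cohort.csv")
        files += [out / "sessions.jsonl", out / "cohort.csv"]

        stage = "score"
        scores = score_table(sessions)
        scores.to_csv(out / "scores.csv", index=False)
        files.append(out / "scores.csv")
        log.info("score: %d sessions scored", len(scores))

        stage = "extract"
        groups = {s.subject_id: s.group for s in bundle.subjects}
        feats = feature_table(sessions, groups=groups)
        feats.to_csv(out / "features.csv", index=False)
        files.append(out / "features.csv")
        log.info("extract: feature table %s", feats.shape)

        stage = "stats"
        grid, long_df, sig = stats_tables(feats, config.alpha, tasks=config.tasks)
        grid.to_csv(out / "stats_pvalues.csv", index=False)
        long_df.to_csv(out / "stats_comparisons.csv", index=False)
        files += [out / "stats_pvalues.csv", out / "stats_comparisons.csv"]
        log.info("stats: significant features per task: %s",
                 {t: len(v) for t, v in sig.items()})

        stage = "classify"
        models, perfs, coef_df = fit_task_models(
            feats, config.entry_p, config.removal_p, config.threshold,
            tasks=config.tasks,
        )
        coef_df.to_csv(out / "model_coefficients.csv", index=False)
        perf_df = performance_table(perfs)
        perf_df.to_csv(out / "task_performance.csv", index=False)
        avg_df = averages_table(perfs)
        avg_df.to_csv(out / "task_averages.csv", index=False)
        files += [
            out / "model_coefficients.csv",
            out / "task_performance.csv",
            out / "task_averages.csv",
        ]
        for task, perf in perfs.items():
            roc_path = out / f"roc_{task}.png"
            _save_roc(perf, task, roc_path)
            files.append(roc_path)
        log.info("classify: per-task AUC %s",
                 {t: round(p.auc, 3) for t, p in perfs.items()})

        stage = "render"
        if config.render_samples and sessions:
            first_subject = sessions[0].subject_id
            for s in sessions:
                if s.subject_id != first_subject:
                    continue
                img = render_pseudocolor(s)
                p = out / f"strokes_{s.subject_id}_{s.task_id}.png"
                img.save(p)
                files.append(p)
    except Exception as err:
        partial = {
            "failed_stage": stage,
            "error": str(err),
            "files": {str(p.relative_to(out)): _sha256(p) for p in files if p.exists()},
        }
        (out / "manifest.json").write_text(json.dumps(partial, indent=2))
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "alpha": config.alpha,
        "entry_p": config.entry_p,
        "removal_p": config.removal_p,
        "threshold": config.threshold,
        "tasks": list(config.tasks),
        "n_hc": effect.n_hc,
        "n_mci": effect.n_mci,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("pipeline complete: %d artifacts in %s", len(files), out)
    return manifest
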