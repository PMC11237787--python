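"""Synthetic cohort generator for the drawing/dragging analysis.

The generator produces two groups of subjects (HC and MCI) with one
session per task T1-T8 each, encoding the qualitative group contrasts
the analysis is designed to detect: the MCI group takes longer to move
the hand between strokes (longer in-air/unpainted times), draws and
drags more slowly (longer on-surface times), lifts the pen more within
components, and earns lower rubric scores.

Timing model
------------
All timing draws are log-normal (times are positive and right-skewed,
which is also why the downstream statistics default to the Mann-Whitney
branch): thinking time before the first stroke, per-stroke on-surface
duration, and per-transition in-air gap, each parameterized by median
(ms) and log-scale sigma.  Each task is a fixed ordered list of
component *runs* (clock: circle, number, pointer; figure tasks: the 9
components; drag clock: number, pointer).  A run emits one stroke
unless an internal lift occurs (probability ``internal_lift_prob``), in
which case the run's stroke count is ``2 + Poisson(max(0, mean - 2))``
— a shifted Poisson with minimum 1 overall.

Scores are not emitted directly: the generator draws structured
annotations (component error flags) whose rubric totals respond to
``score_shift``, so the scoring operations are exercised end to end.
``score_shift`` is expressed in rubric points (negative = worse); for
the 9-component figure rubric a shift of s maps to a per-flag failure
probability increase of \|s\|/18, since d/dp E[component weight] ~= -2.

Geometry is schematic (polylines around per-component template
anchors): the feature catalog is time/count based, so trajectory
realism is irrelevant and not attempted.

Reproducibility: one global seed; subject *i* uses the independent
substream ``default_rng([seed, i])``, so cohorts are reproducible under
parallel generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .ink import (
    CLOCK_LABELS,
    DRAG_LABELS,
    DrawingSession,
    PenEvent,
    Stroke,
    Subject,
    task_family,
)
from .scoring import (
    ClockAnnotation,
    ComponentAnnotation,
    DigitAnnotation,
    DragClockAnnotation,
    FigureAnnotation,
    SRCFT_COMPONENTS,
)

#: Tablet raster the sessions are laid out on (landscape 2160 x 1620).
CANVAS_W, CANVAS_H = 2160, 1620


@dataclass
class GroupEffect:
    """Per-group generative parameters (times in ms, medians of log-normals)."""

    thinking_median_ms: float = 1500.0
    thinking_sigma: float = 0.5
    stroke_duration_median_ms: float = 800.0
    stroke_duration_sigma: float = 0.45
    inter_stroke_air_median_ms: float = 500.0
    inter_stroke_air_sigma: float = 0.55
    strokes_per_component_mean: float = 3.0
    internal_lift_prob: float = 0.12
    score_shift: float = 0.0  # rubric points, <= 0 means worse scores

    def check(self, prefix: str) -> list[str]:
        bad = []
        for name in (
            "thinking_median_ms",
            "stroke_duration_median_ms",
            "inter_stroke_air_median_ms",
        ):
            if getattr(self, name) <= 0:
                bad.append(f"{prefix}.{name}")
        for name in ("thinking_sigma", "stroke_duration_sigma", "inter_stroke_air_sigma"):
            if getattr(self, name) < 0:
                bad.append(f"{prefix}.{name}")
        if self.strokes_per_component_mean < 1:
            bad.append(f"{prefix}.strokes_per_component_mean")
        if not 0.0 <= self.internal_lift_prob <= 1.0:
            bad.append(f"{prefix}.internal_lift_prob")
        return bad


@dataclass
class EffectConfig:
    """Cohort-level configuration: group effects, sizes and seed."""

    hc: GroupEffect = field(default_factory=GroupEffect)
    mci: GroupEffect = field(default_factory=GroupEffect)
    n_hc: int = 99
    n_mci: int = 108
    seed: int = 0

    def check(self) -> list[str]:
        bad = self.hc.check("hc") + self.mci.check("mci")
        if self.n_hc < 2:
            bad.append("n_hc")
        if self.n_mci < 2:
            bad.append("n_mci")
        return bad

    def for_group(self, group: str) -> GroupEffect:
        return self.mci if group == "MCI" else self.hc


def default_config(seed: int = 0, n_hc: int = 99, n_mci: int = 108) -> EffectConfig:
    """Moderate group contrasts: the study-like condition."""
    hc = GroupEffect()
    mci = replace(
        hc,
        thinking_median_ms=hc.thinking_median_ms * 1.15,
        stroke_duration_median_ms=hc.stroke_duration_median_ms * 1.15,
        inter_stroke_air_median_ms=hc.inter_stroke_air_median_ms * 1.35,
        strokes_per_component_mean=3.5,
        internal_lift_prob=0.18,
        score_shift=-1.0,
    )
    return EffectConfig(hc=hc, mci=mci, n_hc=n_hc, n_mci=n_mci, seed=seed)


def strong_config(seed: int = 0, n_hc: int = 100, n_mci: int = 100) -> EffectConfig:
    """Strong preset: MCI in-air median doubled, scores shifted by -2."""
    hc = GroupEffect()
    mci = replace(
        hc,
        thinking_median_ms=hc.thinking_median_ms * 1.5,
        stroke_duration_median_ms=hc.stroke_duration_median_ms * 1.5,
        inter_stroke_air_median_ms=hc.inter_stroke_air_median_ms * 2.0,
        strokes_per_component_mean=4.0,
        internal_lift_prob=0.3,
        score_shift=-2.0,
    )
    return EffectConfig(hc=hc, mci=mci, n_hc=n_hc, n_mci=n_mci, seed=seed)


def null_config(seed: int = 0, n_hc: int = 50, n_mci: int = 50) -> EffectConfig:
    """Both groups identical: for type-I calibration experiments."""
    return EffectConfig(
        hc=GroupEffect(), mci=GroupEffect(), n_hc=n_hc, n_mci=n_mci, seed=seed
    )


PRESETS = {"default": default_config, "strong": strong_config, "null": null_config}


@dataclass
class CohortBundle:
    subjects: list[Subject]
    sessions: list[DrawingSession]
    truth: EffectConfig


# ---------------------------------------------------------------------------
# Subjects — demographic marginals per group (means/SDs of the matched
# cohort: ~70-71 y old, ~6 y education, ~6 h sleep, ~5.5 y device use,
# ~58% women, ~90% right-handed, ~50% exercisers; MCI defined by
# MoCA < 26 with CDR 0.5, HC by MoCA >= 26 with CDR 0).

_DEMOGRAPHICS = {
    "MCI": dict(
        age=(71.34, 4.48),
        education=(6.21, 3.28),
        sleep=(5.93, 1.20),
        device=(5.52, 2.54),
        moca=(24.09, 1.13),
        mmse=(25.31, 1.13),
        p_woman=0.592,
        p_left=0.102,
        p_exercise=0.481,
        cdr=0.5,
    ),
    "HC": dict(
        age=(70.11, 4.00),
        education=(6.81, 2.89),
        sleep=(6.28, 1.06),
        device=(5.87, 2.52),
        moca=(27.04, 1.21),
        mmse=(28.00, 0.92),
        p_woman=0.576,
        p_left=0.071,
        p_exercise=0.515,
        cdr=0.0,
    ),
}


def generate_subject(
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S0000",
    demographics_model: dict | None = None,
) -> Subject:
    """Draw one subject near the group's demographic marginals."""
    if group not in ("HC", "MCI"):
        raise ConfigError(f"group must be HC or MCI, got {group!r}", ["group"])
    m = demographics_model or _DEMOGRAPHICS[group]

    def norm(key, lo=None, hi=None):
        mu, sd = m[key]
        x = rng.normal(mu, sd)
        if lo is not None:
            x = max(lo, x)
        if hi is not None:
            x = min(hi, x)
        return x

    moca_lo, moca_hi = (0, 25) if group == "MCI" else (26, 30)
    moca = int(round(norm("moca", moca_lo, moca_hi)))
    mmse = int(round(norm("mmse", 0, 30)))
    return Subject(
        subject_id=subject_id,
        group=group,
        age=round(norm("age", 65.0), 1),
        gender="woman" if rng.random() < m["p_woman"] else "man",
        hand_preference="left" if rng.random() < m["p_left"] else "right",
        education_years=round(norm("education", 0.0), 1),
        sleep_hours=round(norm("sleep", 1.0), 1),
        exercise_habit="yes" if rng.random() < m["p_exercise"] else "no",
        device_years=round(norm("device", 0.0), 1),
        moca=moca,
        mmse=mmse,
        cdr=m["cdr"],
    )


# ---------------------------------------------------------------------------
# Sessions

#: Ordered component runs per task family.
_RUNS = {
    "clock": list(CLOCK_LABELS),
    "figure": list(SRCFT_COMPONENTS),
    "drag": list(DRAG_LABELS),
}

#: Schematic template anchors (fractions of the canvas) per label.
_ANCHORS: dict[str, tuple[float, float]] = {
    "circle": (0.5, 0.5),
    "number": (0.5, 0.35),
    "pointer": (0.5, 0.55),
    "global_1": (0.45, 0.45),
    "global_2": (0.45, 0.3),
    "global_3": (0.3, 0.45),
    "global_4": (0.6, 0.45),
    "global_5": (0.45, 0.6),
    "local_1": (0.25, 0.25),
    "local_2": (0.7, 0.3),
    "local_3": (0.3, 0.7),
    "local_4": (0.7, 0.7),
}


def _lognormal_ms(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(median * math.exp(sigma * rng.standard_normal()))))


def _run_stroke_count(eff: GroupEffect, rng: np.random.Generator) -> int:
    if rng.random() >= eff.internal_lift_prob:
        return 1
    lam = max(0.0, eff.strokes_per_component_mean - 2.0)
    return 2 + int(rng.poisson(lam))


def _stroke_events(
    rng: np.random.Generator,
    t0: int,
    duration: int,
    label: str,
    source: str,
    n_moves: int = 3,
) -> list[PenEvent]:
    ax, ay = _ANCHORS[label]
    cx = ax * CANVAS_W + rng.normal(0, 40)
    cy = ay * CANVAS_H + rng.normal(0, 40)
    # schematic polyline: short random walk around the anchor
    n_pts = n_moves + 2
    xs = cx + np.cumsum(rng.normal(0, 25, n_pts))
    ys = cy + np.cumsum(rng.normal(0, 25, n_pts))
    xs = np.clip(xs, 0, CANVAS_W - 1)
    ys = np.clip(ys, 0, CANVAS_H - 1)
    ts = t0 + np.round(np.linspace(0, duration, n_pts)).astype(int)
    ts[-1] = t0 + duration  # exact endpoint despite rounding
    events = []
    for k in range(n_pts):
        phase = "down" if k == 0 else ("up" if k == n_pts - 1 else "move")
        events.append(
            PenEvent(t=int(ts[k]), x=round(float(xs[k]), 1), y=round(float(ys[k]), 1),
                     phase=phase, source=source)
        )
    return events


def _generate_annotation(task_id: str, eff: GroupEffect, rng: np.random.Generator):
    """Draw a structured annotation whose rubric total tracks score_shift."""
    shift = max(0.0, -eff.score_shift)
    family = task_family(task_id)
    if family == "figure":
        # |shift|/18 per flag: d E[weight]/d p_fail ~= -2 over 9 components
        p_fail = min(0.95, 0.04 + shift / 18.0)
        comps = {}
        for c in SRCFT_COMPONENTS:
            comps[c] = ComponentAnnotation(
                accurately_drawn=rng.random() >= p_fail,
                correctly_located=rng.random() >= p_fail,
                identifiable=rng.random() < 0.85,
            )
        return FigureAnnotation(components=comps)
    if family == "drag":
        p_fail = min(0.95, 0.05 + shift * 0.15)
        return DragClockAnnotation(
            numbers_position_ok=rng.random() >= p_fail,
            numbers_order_ok=rng.random() >= p_fail,
            pointers_ok=rng.random() >= p_fail,
        )
    # clock family: error propensities scale with the shift
    p_pos = min(0.9, 0.03 + shift * 0.06)
    p_miss = min(0.5, 0.01 + shift * 0.02)
    p_ord = min(0.5, 0.01 + shift * 0.03)
    p_major = min(0.8, 0.02 + shift * 0.08)
    p_minor = min(0.8, 0.05 + shift * 0.10)
    digits = []
    for _ in range(12):
        present = rng.random() >= p_miss
        digits.append(
            DigitAnnotation(
                present=present,
                in_order=(not present) or rng.random() >= p_ord,
                position_ok=(not present) or rng.random() >= p_pos,
            )
        )
    u = rng.random()
    hands = "major_error" if u < p_major else ("minor_error" if u < p_major + p_minor else "correct")
    return ClockAnnotation(
        contour_acceptable=rng.random() >= min(0.8, 0.02 + shift * 0.04),
        numbers=digits,
        hands_indicate_11_10=hands,
        clock_recognizable=rng.random() >= min(0.5, 0.002 + shift * 0.01),
    )


def generate_session(
    subject: Subject,
    task_id: str,
    config: EffectConfig,
    rng: np.random.Generator,
) -> DrawingSession:
    """Generate one legal, annotated session for (subject, task)."""
    eff = config.for_group(subject.group)
    family = task_family(task_id)
    source = "drag" if family == "drag" else "stylus"
    events: list[PenEvent] = []
    strokes: list[Stroke] = []
    t = _lognormal_ms(rng, eff.thinking_median_ms, eff.thinking_sigma)
    first = True
    for label in _RUNS[family]:
        for _ in range(_run_stroke_count(eff, rng)):
            if not first:
                t += _lognormal_ms(
                    rng, eff.inter_stroke_air_median_ms, eff.inter_stroke_air_sigma
                )
            first = False
            duration = _lognormal_ms(
                rng, eff.stroke_duration_median_ms, eff.stroke_duration_sigma
            )
            ev = _stroke_events(rng, t, duration, label, source)
            span = (len(events), len(events) + len(ev) - 1)
            events.extend(ev)
            strokes.append(
                Stroke(events=ev, component=label, index=len(strokes), span=span)
            )
            t += duration
    session_end = t + int(rng.integers(200, 800))
    return DrawingSession(
        subject_id=subject.subject_id,
        task_id=task_id,
        events=events,
        strokes=strokes,
        annotation=_generate_annotation(task_id, eff, rng),
        session_end_ms=session_end,
    )


def generate_cohort(config: EffectConfig) -> CohortBundle:
    """Generate the full cohort: subjects plus one session per task each."""
    bad = config.check()
    if bad:
        raise ConfigError("invalid effect configuration", bad)
    subjects: list[Subject] = []
    sessions: list[DrawingSession] = []
    groups = ["HC"] * config.n_hc + ["MCI"] * config.n_mci
    for i, group in enumerate(groups):
        rng = np.random.default_rng([config.seed, i])
        subject = generate_subject(group, rng, subject_id=f"S{i:04d}")
        subjects.append(subject)
        for task_id in ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8"):
            sessions.append(generate_session(subject, task_id, config, rng))
    return CohortBundle(subjects=subjects, sessions=sessions, truth=config)
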