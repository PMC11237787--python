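"""The 17 hand-motor-function features and their per-task applicability.

The feature catalog has four quantitative categories — time, stroke,
frequency and score — computed per component class of a session:

* **time**: thinking time before the first stroke; painting (on-surface)
  time per component class; unpainted (in-air) time per class.  Each
  in-air gap between consecutive strokes is charged to the *upcoming*
  stroke's component: unpainted time reflects planning before drawing
  that element (the hand "switching from one stroke to the next").  The
  gap before the very first stroke is thinking time, never unpainted
  time.
* **stroke**: total strokes per class, and pen-up strokes — internal
  lifts, i.e. in-air transitions whose flanking strokes carry the same
  component label.
* **frequency**: strokes per second of on-surface time for the class
  (not per elapsed time, which would conflate frequency with the
  unpainted-time features).
* **score**: the rubric total from :mod:`inkcog.scoring`.

Slots are numbered 1-17.  Cells that do not apply to a task (e.g. no
pointer in the figure tasks) are *missing*, never 0, and are excluded
from downstream statistics rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ApplicabilityError, FeatureUndefinedError
from .ink import DrawingSession, Stroke, task_family, task_labels
from .scoring import SRCFT_COMPONENTS, SRCFT_GLOBAL, SRCFT_LOCAL, ScoreReport, score_annotation

N_SLOTS = 17

#: slot -> feature name, per task family.  Names follow the catalog's
#: per-task wording (drag tasks reuse the time slots for drag times).
SLOT_NAMES: dict[str, dict[int, str]] = {
    "clock": {
        1: "thinking_time_first_stroke",
        2: "circle_paint_time",
        3: "number_paint_time",
        4: "pointer_paint_time",
        5: "circle_unpainted_time",
        6: "number_unpainted_time",
        7: "pointer_unpainted_time",
        8: "circle_total_stroke",
        9: "number_total_stroke",
        10: "pointer_total_stroke",
        11: "circle_penup_stroke",
        12: "number_penup_stroke",
        13: "pointer_penup_stroke",
        14: "circle_paint_freq",
        15: "number_paint_freq",
        16: "pointer_paint_freq",
        17: "score",
    },
    "figure": {
        1: "thinking_time_first_stroke",
        3: "figure_paint_time",
        6: "figure_unpainted_time",
        9: "figure_total_stroke",
        12: "figure_penup_stroke",
        15: "figure_paint_freq",
        17: "score",
    },
    "drag": {
        1: "thinking_time_first_stroke",
        2: "number_drag_time",
        4: "pointer_drag_time",
        14: "hand_drag_freq",
        17: "score",
    },
    "pointline": {
        1: "thinking_time_first_stroke",
        5: "global_drawing_time",
        7: "local_drawing_time",
        16: "figure_draw_freq",
        17: "score",
    },
}

#: Applicability matrix: task -> applicable slot numbers (the non-"not
#: applicable" cells of the catalog).
APPLICABLE_SLOTS: dict[str, frozenset[int]] = {
    "T1": frozenset(range(1, 18)),
    "T2": frozenset(range(1, 18)),
    "T3": frozenset(range(1, 18)),
    "T4": frozenset(range(1, 18)),
    "T5": frozenset({1, 3, 6, 9, 12, 15, 17}),
    "T6": frozenset({1, 3, 6, 9, 12, 15, 17}),
    "T7": frozenset({1, 2, 4, 14, 17}),
    "T8": frozenset({1, 5, 7, 16, 17}),
}


def _feature_family(task_id: str) -> str:
    """Naming family for a task (T8 has its own column wording)."""
    if task_id == "T8":
        return "pointline"
    return task_family(task_id)


def slot_name(task_id: str, slot: int) -> str:
    names = SLOT_NAMES[_feature_family(task_id)]
    if slot not in names:
        raise ApplicabilityError(f"slot {slot} is not applicable to task {task_id}")
    return names[slot]


@dataclass
class FeatureVector:
    """Applicable slot values for one session; missing slots are inapplicable."""

    subject_id: str
    task_id: str
    values: dict[int, float] = field(default_factory=dict)

    def name(self, slot: int) -> str:
        return slot_name(self.task_id, slot)

    def as_row(self) -> dict[str, float]:
        """Flat row keyed ``f01``..``f17``; inapplicable slots absent."""
        return {f"f{slot:02d}": v for slot, v in sorted(self.values.items())}


# ---------------------------------------------------------------------------
# Component-class helpers.  A *class* is a set of component labels; e.g.
# the whole-figure class is the union of the 9 components.


def _class_set(session_task: str, component_class: str) -> frozenset[str]:
    """Resolve a class name to its label set for the task."""
    labels = set(task_labels(session_task))
    composites = {
        "figure": set(SRCFT_COMPONENTS),
        "global": set(SRCFT_GLOBAL),
        "local": set(SRCFT_LOCAL),
        "hand": {"number", "pointer"},  # all draggable elements of T7
    }
    if component_class in composites:
        cls = composites[component_class]
        if not cls & labels:
            raise ApplicabilityError(
                f"class {component_class!r} is not applicable to task {session_task}"
            )
        return frozenset(cls & labels)
    if component_class not in labels:
        raise ApplicabilityError(
            f"class {component_class!r} is not applicable to task {session_task} "
            f"(allowed: {sorted(labels)} or composite classes)"
        )
    return frozenset({component_class})


def thinking_time_first_stroke(session: DrawingSession) -> int:
    """Time from session start to the first pen-down, in ms."""
    if not session.strokes:
        raise FeatureUndefinedError(
            f"thinking time undefined: session {session.subject_id}/{session.task_id} "
            "has no strokes"
        )
    return session.strokes[0].start_t


def component_paint_time(session: DrawingSession, component_class: str) -> int:
    """Total on-surface (painting/drag) time of the class, in ms."""
    cls = _class_set(session.task_id, component_class)
    return sum(s.duration_ms for s in session.strokes if s.component in cls)


def component_unpainted_time(session: DrawingSession, component_class: str) -> int:
    """Total in-air time charged to the class, in ms.

    The gap before stroke *i* (i >= 1) is charged to stroke *i*'s
    component; the gap before stroke 0 is thinking time.
    """
    cls = _class_set(session.task_id, component_class)
    total = 0
    for prev, cur in zip(session.strokes, session.strokes[1:]):
        if cur.component in cls:
            total += cur.start_t - prev.end_t
    return total


def component_stroke_counts(
    session: DrawingSession, component_class: str
) -> tuple[int, int]:
    """(total strokes of the class, pen-up strokes).

    A pen-up stroke is an internal lift: an in-air transition whose
    flanking strokes carry the *same* label, that label being in the
    class.
    """
    cls = _class_set(session.task_id, component_class)
    total = sum(1 for s in session.strokes if s.component in cls)
    penup = sum(
        1
        for prev, cur in zip(session.strokes, session.strokes[1:])
        if prev.component == cur.component and cur.component in cls
    )
    return total, penup


def painting_frequency(session: DrawingSession, component_class: str) -> float:
    """Strokes of the class per second of its on-surface time."""
    paint_ms = component_paint_time(session, component_class)
    if paint_ms <= 0:
        raise FeatureUndefinedError(
            f"painting frequency undefined for class {component_class!r}: "
            "zero paint time"
        )
    total, _ = component_stroke_counts(session, component_class)
    return total / (paint_ms / 1000.0)


#: slot -> (kind, class) recipes per family; kind selects the computation.
_RECIPES: dict[str, dict[int, tuple[str, str | None]]] = {
    "clock": {
        1: ("thinking", None),
        2: ("paint", "circle"),
        3: ("paint", "number"),
        4: ("paint", "pointer"),
        5: ("unpainted", "circle"),
        6: ("unpainted", "number"),
        7: ("unpainted", "pointer"),
        8: ("total", "circle"),
        9: ("total", "number"),
        10: ("total", "pointer"),
        11: ("penup", "circle"),
        12: ("penup", "number"),
        13: ("penup", "pointer"),
        14: ("freq", "circle"),
        15: ("freq", "number"),
        16: ("freq", "pointer"),
        17: ("score", None),
    },
    "figure": {
        1: ("thinking", None),
        3: ("paint", "figure"),
        6: ("unpainted", "figure"),
        9: ("total", "figure"),
        12: ("penup", "figure"),
        15: ("freq", "figure"),
        17: ("score", None),
    },
    "drag": {
        1: ("thinking", None),
        2: ("paint", "number"),
        4: ("paint", "pointer"),
        14: ("freq", "hand"),
        17: ("score", None),
    },
    "pointline": {
        1: ("thinking", None),
        5: ("paint", "global"),
        7: ("paint", "local"),
        16: ("freq", "figure"),
        17: ("score", None),
    },
}


def extract_features(
    session: DrawingSession, score_report: ScoreReport | None = None
) -> FeatureVector:
    """Fill every applicable slot of the catalog for one session.

    ``score_report`` defaults to scoring the session's own annotation.
    Sub-operation errors propagate, naming the slot.
    """
    if score_report is None:
        if session.annotation is None:
            raise FeatureUndefinedError(
                f"session {session.subject_id}/{session.task_id} has no annotation "
                "and no score report was supplied"
            )
        score_report = score_annotation(session.annotation, session.task_id)
    family = _feature_family(session.task_id)
    recipes = _RECIPES[family]
    values: dict[int, float] = {}
    for slot in sorted(APPLICABLE_SLOTS[session.task_id]):
        kind, cls = recipes[slot]
        try:
            if kind == "thinking":
                values[slot] = float(thinking_time_first_stroke(session))
            elif kind == "paint":
                values[slot] = float(component_paint_time(session, cls))
            elif kind == "unpainted":
                values[slot] = float(component_unpainted_time(session, cls))
            elif kind == "total":
                values[slot] = float(component_stroke_counts(session, cls)[0])
            elif kind == "penup":
                values[slot] = float(component_stroke_counts(session, cls)[1])
            elif kind == "freq":
                values[slot] = painting_frequency(session, cls)
            elif kind == "score":
                values[slot] = float(score_report.total)
        except FeatureUndefinedError as err:
            raise FeatureUndefinedError(
                f"slot {slot} ({slot_name(session.task_id, slot)}): {err}"
            ) from err
    return FeatureVector(subject_id=session.subject_id, task_id=session.task_id, values=values)


def feature_table(
    sessions: Iterable[DrawingSession],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per (subject, task); columns subject_id, task_id, group, f01..f17.

    Inapplicable slots are NaN (empty cells on disk).
    """
    rows = []
    for s in sessions:
        fv = extract_features(s)
        row: dict[str, object] = {"subject_id": s.subject_id, "task_id": s.task_id}
        if groups is not None:
            row["group"] = groups.get(s.subject_id)
        row.update(fv.as_row())
        rows.append(row)
    # stable full column set even if some tasks are absent
    cols = ["subject_id", "task_id"] + (["group"] if groups is not None else [])
    cols += [f"f{i:02d}" for i in range(1, N_SLOTS + 1)]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = math.nan
    return df[cols]


class SessionFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer from drawing sessions to the numeric feature table.

    ``transform`` accepts a sequence of :class:`DrawingSession` and
    returns a DataFrame with one row per session and the applicable
    ``f01``..``f17`` columns for ``task_id`` (others dropped).  Stateless;
    ``fit`` only validates parameters, so the transformer composes with
    sklearn pipelines and feature selection downstream.
    """

    def __init__(self, task_id: str | None = None):
        self.task_id = task_id

    def fit(self, X: Sequence[DrawingSession], y=None):  # noqa: N803 (sklearn API)
        if self.task_id is not None and self.task_id not in APPLICABLE_SLOTS:
            raise ApplicabilityError(f"unknown task_id {self.task_id!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[DrawingSession]) -> pd.DataFrame:
        sessions = [s for s in X if self.task_id is None or s.task_id == self.task_id]
        df = feature_table(sessions)
        if self.task_id is not None:
            keep = [f"f{i:02d}" for i in sorted(APPLICABLE_SLOTS[self.task_id])]
            df = df[["subject_id", "task_id"] + keep]
        return df

    def get_feature_names_out(self, input_features=None):
        if self.task_id is None:
            return [f"f{i:02d}" for i in range(1, N_SLOTS + 1)]
        return [f"f{i:02d}" for i in sorted(APPLICABLE_SLOTS[self.task_id])]
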