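"""Data model, validation and file IO for digitized drawing/dragging sessions.

A session is a timestamped stream of pen (or drag) events on a tablet,
segmented into strokes.  A *stroke* is a maximal ``down -> move* -> up``
run; ``move`` events between an ``up`` and the next ``down`` are in-air
travel and belong to no stroke.  Strokes carry a component label (clock
circle / numbers / pointers, or one of the 9 figure components) supplied
by the generator or a human annotator — no geometric recognition is
attempted.

Times are integer milliseconds since session start; coordinates are
device pixels with a top-left origin (y grows downward), matching touch
digitizer conventions.  The on-disk format is JSON Lines, one session
object per line (UTF-8, LF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import MalformedStreamError, SessionParseError
from .scoring import (
    Annotation,
    ClockAnnotation,
    ComponentAnnotation,
    DigitAnnotation,
    DragClockAnnotation,
    FigureAnnotation,
    SRCFT_COMPONENTS,
)

PHASES = ("down", "move", "up")
SOURCES = ("stylus", "drag")

#: Component label sets per task family.
CLOCK_LABELS = ("circle", "number", "pointer")
DRAG_LABELS = ("number", "pointer")

#: Task registry: T1-T4 are clock-drawing variants (single task plus the
#: three dual tasks), T5/T6 figure copy and delayed recall, T7 the
#: drag-and-drop clock, T8 the point-and-line figure.
TASK_IDS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")

_TASK_FAMILY = {
    "T1": "clock",
    "T2": "clock",
    "T3": "clock",
    "T4": "clock",
    "T5": "figure",
    "T6": "figure",
    "T7": "drag",
    "T8": "figure",
}

_FAMILY_LABELS = {
    "clock": CLOCK_LABELS,
    "figure": SRCFT_COMPONENTS,
    "drag": DRAG_LABELS,
}

TASK_NAMES = {
    "T1": "dCDT single task",
    "T2": "dCDT dual task (series 1)",
    "T3": "dCDT dual task (animal names)",
    "T4": "dCDT dual task (series 3)",
    "T5": "sRCFT raw copy",
    "T6": "sRCFT delayed recall",
    "T7": "clock drag and drop",
    "T8": "sRCFT point and line",
}


def task_family(task_id: str) -> str:
    if task_id not in _TASK_FAMILY:
        raise SessionParseError(f"unknown task_id {task_id!r}; expected one of {TASK_IDS}")
    return _TASK_FAMILY[task_id]


def task_labels(task_id: str) -> tuple[str, ...]:
    """Permitted component labels for a task."""
    return _FAMILY_LABELS[task_family(task_id)]


@dataclass(frozen=True)
class PenEvent:
    t: int
    x: float
    y: float
    phase: str  # down | move | up
    source: str = "stylus"  # stylus | drag


@dataclass
class Stroke:
    """One down..up run; ``span`` indexes the session event list (inclusive)."""

    events: list[PenEvent]
    component: str | None
    index: int
    span: tuple[int, int]

    @property
    def start_t(self) -> int:
        return self.events[0].t

    @property
    def end_t(self) -> int:
        return self.events[-1].t

    @property
    def duration_ms(self) -> int:
        return self.end_t - self.start_t


@dataclass
class DrawingSession:
    subject_id: str
    task_id: str
    events: list[PenEvent]
    strokes: list[Stroke]
    annotation: Annotation | None
    session_end_ms: int


@dataclass
class Subject:
    subject_id: str
    group: str  # HC | MCI
    age: float
    gender: str  # man | woman
    hand_preference: str  # left | right
    education_years: float
    sleep_hours: float
    exercise_habit: str  # yes | no
    device_years: float
    moca: int
    mmse: int
    cdr: float


def segment_strokes(events: Sequence[PenEvent]) -> list[Stroke]:
    """Segment a legal event stream into strokes.

    Each stroke is a maximal down..up run; events between an ``up`` and
    the next ``down`` (in-air moves) belong to no stroke.  Raises
    :class:`MalformedStreamError` naming the offending event index when
    the phase grammar is violated (unmatched down/up, move before the
    first down, decreasing time).
    """
    strokes: list[Stroke] = []
    open_start: int | None = None
    prev_t: int | None = None
    for i, ev in enumerate(events):
        if ev.phase not in PHASES:
            raise MalformedStreamError(f"event {i}: unknown phase {ev.phase!r}")
        if ev.t < 0:
            raise MalformedStreamError(f"event {i}: negative time {ev.t}")
        if prev_t is not None and ev.t < prev_t:
            raise MalformedStreamError(f"event {i}: time decreases ({ev.t} < {prev_t})")
        prev_t = ev.t
        if ev.phase == "down":
            if open_start is not None:
                raise MalformedStreamError(f"event {i}: down while pen already down")
            open_start = i
        elif ev.phase == "up":
            if open_start is None:
                raise MalformedStreamError(f"event {i}: up without a matching down")
            strokes.append(
                Stroke(
                    events=list(events[open_start : i + 1]),
                    component=None,
                    index=len(strokes),
                    span=(open_start, i),
                )
            )
            open_start = None
        # moves are legal both on-surface (inside a stroke) and in-air,
        # except before the very first down:
        elif open_start is None and not strokes:
            raise MalformedStreamError(f"event {i}: move before the first down")
    if open_start is not None:
        raise MalformedStreamError(f"event {open_start}: down without a matching up")
    return strokes


def validate_session(session: DrawingSession) -> list[str]:
    """Return all invariant violations (empty list = well-formed).

    Total function: never raises; malformed streams are reported as
    violations.
    """
    v: list[str] = []
    if session.task_id not in TASK_IDS:
        v.append(f"task_id: {session.task_id!r} not in {TASK_IDS}")
        return v  # labels/annotation cannot be checked without a task
    try:
        segmented = segment_strokes(session.events)
    except MalformedStreamError as err:
        v.append(f"events: {err}")
        segmented = None

    for i, ev in enumerate(session.events):
        if ev.source not in SOURCES:
            v.append(f"events[{i}].source: {ev.source!r} not in {SOURCES}")
            break

    if segmented is not None:
        if len(segmented) != len(session.strokes):
            v.append(
                f"strokes: {len(session.strokes)} recorded but stream segments "
                f"into {len(segmented)}"
            )
        else:
            for got, ref in zip(session.strokes, segmented):
                if got.span != ref.span:
                    v.append(f"strokes[{ref.index}].span: {got.span} != {ref.span}")

    labels = task_labels(session.task_id)
    for s in session.strokes:
        if s.component is not None and s.component not in labels:
            v.append(
                f"strokes[{s.index}].component: {s.component!r} not permitted "
                f"for {session.task_id} (allowed: {labels})"
            )
    for j, s in enumerate(session.strokes):
        if s.index != j:
            v.append(f"strokes[{j}].index: {s.index} != {j}")
            break

    if session.events and session.session_end_ms < session.events[-1].t:
        v.append(
            f"session_end_ms: {session.session_end_ms} < last event t "
            f"{session.events[-1].t}"
        )

    family = _TASK_FAMILY[session.task_id]
    ann = session.annotation
    if ann is not None:
        if getattr(ann, "family", None) != family:
            v.append(
                f"annotation: family {getattr(ann, 'family', None)!r} does not "
                f"match task family {family!r}"
            )
        else:
            try:
                ann.check()
            except Exception as err:  # AnnotationError
                v.append(f"annotation: {err}")
    return v


# ---------------------------------------------------------------------------
# JSON-Lines serialization


def _annotation_to_dict(ann: Annotation | None) -> dict | None:
    if ann is None:
        return None
    if isinstance(ann, ClockAnnotation):
        return {
            "family": "clock",
            "contour_acceptable": ann.contour_acceptable,
            "numbers": [asdict(d) for d in ann.numbers],
            "hands_indicate_11_10": ann.hands_indicate_11_10,
            "clock_recognizable": ann.clock_recognizable,
        }
    if isinstance(ann, FigureAnnotation):
        return {
            "family": "figure",
            "components": {k: asdict(c) for k, c in ann.components.items()},
        }
    if isinstance(ann, DragClockAnnotation):
        return {
            "family": "drag",
            "numbers_position_ok": ann.numbers_position_ok,
            "numbers_order_ok": ann.numbers_order_ok,
            "pointers_ok": ann.pointers_ok,
        }
    raise TypeError(f"unknown annotation type {type(ann).__name__}")


def _annotation_from_dict(d: dict | None) -> Annotation | None:
    if d is None:
        return None
    family = d.get("family")
    if family == "clock":
        return ClockAnnotation(
            contour_acceptable=bool(d["contour_acceptable"]),
            numbers=[DigitAnnotation(**n) for n in d["numbers"]],
            hands_indicate_11_10=d["hands_indicate_11_10"],
            clock_recognizable=bool(d["clock_recognizable"]),
        )
    if family == "figure":
        return FigureAnnotation(
            components={k: ComponentAnnotation(**c) for k, c in d["components"].items()}
        )
    if family == "drag":
        return DragClockAnnotation(
            numbers_position_ok=bool(d["numbers_position_ok"]),
            numbers_order_ok=bool(d["numbers_order_ok"]),
            pointers_ok=bool(d["pointers_ok"]),
        )
    raise ValueError(f"unknown annotation family {family!r}")


def session_to_dict(session: DrawingSession) -> dict:
    return {
        "subject_id": session.subject_id,
        "task_id": session.task_id,
        "session_end_ms": session.session_end_ms,
        "events": [
            {"t": e.t, "x": e.x, "y": e.y, "phase": e.phase, "source": e.source}
            for e in session.events
        ],
        "strokes": [
            {"component": s.component, "event_span": list(s.span)}
            for s in session.strokes
        ],
        "annotation": _annotation_to_dict(session.annotation),
    }


def session_from_dict(d: dict) -> DrawingSession:
    events = [
        PenEvent(
            t=int(e["t"]),
            x=float(e["x"]),
            y=float(e["y"]),
            phase=e["phase"],
            source=e.get("source", "stylus"),
        )
        for e in d["events"]
    ]
    strokes = []
    for k, s in enumerate(d.get("strokes", [])):
        i, j = s["event_span"]
        strokes.append(
            Stroke(
                events=events[i : j + 1],
                component=s.get("component"),
                index=k,
                span=(int(i), int(j)),
            )
        )
    return DrawingSession(
        subject_id=str(d["subject_id"]),
        task_id=str(d["task_id"]),
        events=events,
        strokes=strokes,
        annotation=_annotation_from_dict(d.get("annotation")),
        session_end_ms=int(d["session_end_ms"]),
    )


def write_sessions(sessions: Iterable[DrawingSession], path: str | Path) -> None:
    """Write sessions as JSON Lines (UTF-8, LF)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in sessions:
            fh.write(json.dumps(session_to_dict(s), separators=(",", ":")) + "\n")


def read_sessions(path: str | Path) -> list[DrawingSession]:
    """Read a JSON-Lines session file, rejecting invalid records.

    Raises :class:`SessionParseError` with the 1-based line number on a
    schema or invariant violation.
    """
    sessions = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as err:
                raise SessionParseError(f"invalid JSON: {err}", line=lineno) from err
            try:
                session = session_from_dict(record)
            except (KeyError, ValueError, TypeError, IndexError) as err:
                raise SessionParseError(f"bad record: {err}", line=lineno) from err
            violations = validate_session(session)
            if violations:
                raise SessionParseError(
                    "invalid session: " + "; ".join(violations), line=lineno
                )
            sessions.append(session)
    return sessions


# ---------------------------------------------------------------------------
# Cohort (subject) CSV

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "hand_preference",
    "education_years",
    "sleep_hours",
    "exercise_habit",
    "device_years",
    "moca",
    "mmse",
    "cdr",
]


def write_subjects(subjects: Iterable[Subject], path: str | Path) -> None:
    df = pd.DataFrame([asdict(s) for s in subjects], columns=SUBJECT_COLUMNS)
    df.to_csv(path, index=False)


def read_subjects(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SessionParseError(f"cohort file missing columns: {missing}")
    return [
        Subject(
            subject_id=str(r.subject_id),
            group=str(r.group),
            age=float(r.age),
            gender=str(r.gender),
            hand_preference=str(r.hand_preference),
            education_years=float(r.education_years),
            sleep_hours=float(r.sleep_hours),
            exercise_habit=str(r.exercise_habit),
            device_years=float(r.device_years),
            moca=int(r.moca),
            mmse=int(r.mmse),
            cdr=float(r.cdr),
        )
        for r in df.itertuples()
    ]
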