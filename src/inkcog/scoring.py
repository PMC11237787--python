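"""Deterministic rubric scorers for the drawing and dragging tasks.

Three rubrics are implemented, all operating on structured annotations
rather than raw ink (automatic geometric scoring of clock drawings is a
non-goal; annotations come from the synthetic generator or a human rater):

* **Schulman clock score** (tasks T1-T4): ordinal 1 (perfect clock) to
  6 (no identifiable clock).  The published criteria are a severity
  ladder; the exact tier boundaries used here are collected in one
  place (:func:`score_clock_schulman`) so they can be revised easily.
* **Simplified Rey-Osterrieth figure score** (tasks T5, T6, T8): each of
  the 9 components is weighted 2 (accurately drawn and correctly
  located), 1 (exactly one of the two), 0.5 (neither, but identifiable)
  or 0; total range 0-18 in steps of 0.5.  The point-and-line task T8
  uses the identical rule.
* **Drag-clock score** (task T7): one point each for numbers position,
  numbers order and pointer indication; range 0-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnnotationError

# The 9 figure components: 5 global, 4 local.
SRCFT_GLOBAL = ("global_1", "global_2", "global_3", "global_4", "global_5")
SRCFT_LOCAL = ("local_1", "local_2", "local_3", "local_4")
SRCFT_COMPONENTS = SRCFT_GLOBAL + SRCFT_LOCAL

HAND_STATES = ("correct", "minor_error", "major_error")


@dataclass
class DigitAnnotation:
    """Rater judgement for one clock digit (1..12)."""

    present: bool = True
    in_order: bool = True
    position_ok: bool = True


@dataclass
class ClockAnnotation:
    """Structured annotation of a drawn clock (tasks T1-T4)."""

    contour_acceptable: bool = True
    numbers: list[DigitAnnotation] = field(
        default_factory=lambda: [DigitAnnotation() for _ in range(12)]
    )
    hands_indicate_11_10: str = "correct"
    clock_recognizable: bool = True

    family = "clock"

    def check(self) -> None:
        if len(self.numbers) != 12:
            raise AnnotationError(
                f"clock annotation needs 12 digit entries, got {len(self.numbers)}"
            )
        if self.hands_indicate_11_10 not in HAND_STATES:
            raise AnnotationError(
                f"hands_indicate_11_10 must be one of {HAND_STATES}, "
                f"got {self.hands_indicate_11_10!r}"
            )


@dataclass
class ComponentAnnotation:
    """Rater judgement for one figure component."""

    accurately_drawn: bool = True
    correctly_located: bool = True
    identifiable: bool = True


@dataclass
class FigureAnnotation:
    """Structured annotation of a simplified Rey figure (T5, T6, T8)."""

    components: dict[str, ComponentAnnotation] = field(
        default_factory=lambda: {c: ComponentAnnotation() for c in SRCFT_COMPONENTS}
    )

    family = "figure"

    def check(self) -> None:
        missing = [c for c in SRCFT_COMPONENTS if c not in self.components]
        if missing:
            raise AnnotationError(f"missing figure component entries: {missing}")


@dataclass
class DragClockAnnotation:
    """Structured annotation of the clock drag-and-drop result (T7)."""

    numbers_position_ok: bool = True
    numbers_order_ok: bool = True
    pointers_ok: bool = True

    family = "drag"

    def check(self) -> None:  # all fields have defaults; nothing can be missing
        return None


Annotation = ClockAnnotation | FigureAnnotation | DragClockAnnotation


@dataclass
class ScoreReport:
    """Rubric output: total plus per-component sub-scores."""

    task_id: str | None
    rubric: str  # "schulman" | "srcft" | "dragclock"
    total: float
    per_component: list[tuple[str, float]] = field(default_factory=list)


def component_weight(entry: ComponentAnnotation) -> float:
    """Weight of one figure component.

    2 if accurately drawn and correctly located; 1 if exactly one of the
    two holds; 0.5 if neither holds but the component is identifiable;
    0 otherwise.  ``identifiable`` is only consulted when both accuracy
    and location fail.
    """
    if entry.accurately_drawn and entry.correctly_located:
        return 2.0
    if entry.accurately_drawn or entry.correctly_located:
        return 1.0
    if entry.identifiable:
        return 0.5
    return 0.0


def score_srcft(annotation: FigureAnnotation, task_id: str | None = None) -> ScoreReport:
    """Score a simplified Rey figure annotation; total in [0, 18] by 0.5."""
    if not isinstance(annotation, FigureAnnotation):
        raise AnnotationError(
            f"figure rubric needs a FigureAnnotation, got {type(annotation).__name__}"
        )
    annotation.check()
    per = [(c, component_weight(annotation.components[c])) for c in SRCFT_COMPONENTS]
    return ScoreReport(
        task_id=task_id,
        rubric="srcft",
        total=sum(w for _, w in per),
        per_component=per,
    )


def _clock_error_counts(annotation: ClockAnnotation) -> tuple[int, int, int]:
    """(missing digits, position faults among present digits, order faults)."""
    missing = sum(1 for d in annotation.numbers if not d.present)
    pos = sum(1 for d in annotation.numbers if d.present and not d.position_ok)
    order = sum(1 for d in annotation.numbers if d.present and not d.in_order)
    return missing, pos, order


#: Schulman severity ladder, evaluated top-down; the first matching tier
#: is the score.  ``layout faults`` = missing digits + misplaced digits.
#:
#: ==== =====================================================================
#: tier condition
#: ==== =====================================================================
#: 6    clock not recognizable
#: 5    severe disorganization: majority of digits missing or misplaced (>= 7)
#: 4    moderate disorganization: any order fault, or > 2 layout faults
#: 3    hands majorly wrong (time misrepresented), layout otherwise intact
#: 2    minor errors: 1-2 layout faults, minor hand error, or bad contour
#: 1    perfect clock
#: ==== =====================================================================
def score_clock_schulman(
    annotation: ClockAnnotation, task_id: str | None = None
) -> ScoreReport:
    """Score a clock annotation on the Schulman 1-6 severity scale."""
    if not isinstance(annotation, ClockAnnotation):
        raise AnnotationError(
            f"clock rubric needs a ClockAnnotation, got {type(annotation).__name__}"
        )
    annotation.check()
    missing, pos, order = _clock_error_counts(annotation)
    layout_faults = missing + pos

    if not annotation.clock_recognizable:
        total = 6
    elif layout_faults >= 7:
        total = 5
    elif order > 0 or layout_faults > 2:
        total = 4
    elif annotation.hands_indicate_11_10 == "major_error":
        total = 3
    elif (
        annotation.hands_indicate_11_10 == "minor_error"
        or layout_faults > 0
        or not annotation.contour_acceptable
    ):
        total = 2
    else:
        total = 1

    per = [
        ("missing_digits", float(missing)),
        ("position_faults", float(pos)),
        ("order_faults", float(order)),
    ]
    return ScoreReport(task_id=task_id, rubric="schulman", total=float(total), per_component=per)


def score_drag_clock(
    annotation: DragClockAnnotation, task_id: str | None = None
) -> ScoreReport:
    """Score the drag-and-drop clock: one point per satisfied criterion."""
    if not isinstance(annotation, DragClockAnnotation):
        raise AnnotationError(
            f"drag rubric needs a DragClockAnnotation, got {type(annotation).__name__}"
        )
    per = [
        ("numbers_position", float(annotation.numbers_position_ok)),
        ("numbers_order", float(annotation.numbers_order_ok)),
        ("pointers", float(annotation.pointers_ok)),
    ]
    return ScoreReport(
        task_id=task_id,
        rubric="dragclock",
        total=sum(w for _, w in per),
        per_component=per,
    )


def score_annotation(annotation: Annotation, task_id: str) -> ScoreReport:
    """Dispatch to the rubric for the task's family."""
    from .ink import task_family  # late import to avoid a cycle

    family = task_family(task_id)
    if family == "clock":
        return score_clock_schulman(annotation, task_id)
    if family == "drag":
        return score_drag_clock(annotation, task_id)
    return score_srcft(annotation, task_id)
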