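"""Shared fixtures: hand-built sessions and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from inkcog.ink import DrawingSession, PenEvent, Stroke
from inkcog.scoring import ClockAnnotation, DragClockAnnotation, FigureAnnotation
from inkcog.simulate import default_config, generate_cohort


def make_events(spans, source="stylus", xy=(100.0, 100.0), moves=1):
    """Events for down..up spans given as (t_down, t_up) pairs, with
    ``moves`` evenly spaced move events inside each stroke."""
    events = []
    for t0, t1 in spans:
        events.append(PenEvent(t=t0, x=xy[0], y=xy[1], phase="down", source=source))
        for k in range(1, moves + 1):
            tm = t0 + (t1 - t0) * k // (moves + 1)
            events.append(
                PenEvent(t=tm, x=xy[0] + 5 * k, y=xy[1] + 5 * k, phase="move", source=source)
            )
        events.append(PenEvent(t=t1, x=xy[0] + 10, y=xy[1] + 10, phase="up", source=source))
    return events


def make_session(task_id, spans, labels, subject_id="S0", annotation=None, end_pad=100):
    """A session with one stroke per (t_down, t_up) span, labelled as given."""
    assert len(spans) == len(labels)
    source = "drag" if task_id == "T7" else "stylus"
    events = []
    strokes = []
    for idx, ((t0, t1), label) in enumerate(zip(spans, labels)):
        ev = make_events([(t0, t1)], source=source)
        span = (len(events), len(events) + len(ev) - 1)
        events.extend(ev)
        strokes.append(Stroke(events=ev, component=label, index=idx, span=span))
    if annotation is None:
        if task_id in ("T1", "T2", "T3", "T4"):
            annotation = ClockAnnotation()
        elif task_id == "T7":
            annotation = DragClockAnnotation()
        else:
            annotation = FigureAnnotation()
    return DrawingSession(
        subject_id=subject_id,
        task_id=task_id,
        events=events,
        strokes=strokes,
        annotation=annotation,
        session_end_ms=(spans[-1][1] + end_pad) if spans else end_pad,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """A 15+15-subject cohort with the default (moderate) contrasts."""
    return generate_cohort(default_config(seed=42, n_hc=15, n_mci=15))
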