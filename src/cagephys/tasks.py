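"""Task rules and correctness labeling for home-cage operant modules.

Each experimental module (place preference, spatial sequence, delayed
response, place avoidance, ...) defines what a *correct* visit or
nosepoke is.  This module replays a validated event stream against a
:class:`TaskDefinition` and labels every visit (and, where the rule is
poke-level, every nosepoke) as correct / incorrect / neutral, or as
outside the active reward windows.

Rules implemented
-----------------
PPL / PPL_REV
    One assigned corner per animal is rewarded; a visit is correct iff it
    goes to that corner inside an active window.  Side-level correctness
    (left door in the daytime session, right door at night, by default)
    is recorded on the nosepokes: only the first correct poke opens the
    door.
SSL / SSL_REV
    The rewarded corner advances clockwise (anti-clockwise for the
    reversal) along 1→2→3→4→1, but only after a visit *with licks* to the
    current rewarded corner — exploratory visits without licks do not
    advance the chain.  Labels are a deterministic replay of this state
    machine.
DRL
    Within a visit the animal must poke the same door a second time after
    a minimum delay; a premature second poke is incorrect and ends
    scoring for that visit.  Pokes on the opposite door have no effect.
    One neutral corner opens its doors with a fixed probability,
    independent of timing.
PAL / PA_EXT
    One punished corner per animal; a visit is correct iff it avoids that
    corner (chance expectation 3/4), and a poke is correct iff it is not
    made in the punished corner.  The two proportions are reported
    separately because animals may keep visiting the punished corner
    while withholding pokes there.

All correctness labels are pure functions of the event stream, the task
definition and (for DRL neutral-corner openings) a seeded random
substream, so replays are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import ExperimentMetadata

__all__ = [
    "CORRECT",
    "INCORRECT",
    "NEUTRAL",
    "OUTSIDE_WINDOW",
    "TASK_KINDS",
    "DEFAULT_ACTIVE_WINDOWS",
    "TaskConfigError",
    "TaskDefinition",
    "in_active_window",
    "label_ppl",
    "label_ssl",
    "label_drl",
    "label_pal",
    "place_error_proportion",
    "correct_visit_sequences",
]

CORRECT = "CORRECT"
INCORRECT = "INCORRECT"
NEUTRAL = "NEUTRAL"
OUTSIDE_WINDOW = "OUTSIDE_WINDOW"

TASK_KINDS = (
    "FA",
    "NP_ADAPT",
    "DS",
    "PPL",
    "PPL_REV",
    "SSL",
    "SSL_REV",
    "DRL",
    "PAL",
    "PA_EXT",
)

#: Default drinking-session windows, wall-clock half-open hours:
#: [11:00, 14:00) and [23:00, 02:00) (the latter wraps midnight).
DEFAULT_ACTIVE_WINDOWS: tuple[tuple[float, float], ...] = ((11.0, 14.0), (23.0, 2.0))

#: Clockwise corner order used by the spatial-sequence chain.
CLOCKWISE_ORDER = (1, 2, 3, 4)


class TaskConfigError(ValueError):
    """The task definition is inconsistent with the event stream."""


@dataclass
class TaskDefinition:
    """Rules of one operant module.

    Parameters
    ----------
    kind
        One of :data:`TASK_KINDS`.
    active_windows
        Wall-clock half-open ``[start_h, end_h)`` intervals during which
        the module rewards; a window with ``end < start`` wraps midnight.
        Empty tuple means always active.
    assignment
        Animal tag -> assigned corner.  For PPL this is the rewarded
        corner, for PAL the punished corner, for SSL the initial chain
        position.
    side_by_window
        For PPL: rewarded door side per active-window index
        (default LEFT in the daytime window, RIGHT in the night window).
    delay_s
        DRL minimum inter-poke delay on the same door, seconds.
    neutral_corner
        DRL corner whose doors open probabilistically.
    open_probability
        DRL neutral-corner door-opening probability.
    door_open_s
        Door-open duration after a correct poke (metadata only).
    """

    kind: str
    active_windows: tuple[tuple[float, float], ...] = DEFAULT_ACTIVE_WINDOWS
    assignment: dict[str, int] = field(default_factory=dict)
    side_by_window: tuple[str, ...] = ("LEFT", "RIGHT")
    delay_s: float = 4.0
    neutral_corner: int | None = None
    open_probability: float = 0.5
    door_open_s: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise TaskConfigError(f"unknown task kind {self.kind!r}")
        if self.kind == "DRL" and self.delay_s <= 0:
            raise TaskConfigError("DRL delay_s must be positive")
        for lo, hi in self.active_windows:
            if not (0 <= lo < 24 and 0 <= hi < 24):
                raise TaskConfigError(f"window bounds must lie in [0, 24): {(lo, hi)}")
        for corner in self.assignment.values():
            if corner not in (1, 2, 3, 4):
                raise TaskConfigError(f"assigned corner outside 1-4: {corner}")


def in_active_window(
    hour: np.ndarray | float, windows: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Vectorized membership of wall-clock hours in half-open windows.

    A window ``(lo, hi)`` with ``hi <= lo`` wraps midnight (e.g. 23–2).
    An empty window list means the module is always active.
    """
    h = np.atleast_1d(np.asarray(hour, dtype=float))
    if not windows:
        return np.ones_like(h, dtype=bool)
    hit = np.zeros_like(h, dtype=bool)
    for lo, hi in windows:
        if hi > lo:
            hit |= (h >= lo) & (h < hi)
        else:  # wraps midnight
            hit |= (h >= lo) | (h < hi)
    return hit


def _window_index(
    hour: np.ndarray, windows: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Index of the window containing each hour, -1 if none."""
    h = np.atleast_1d(np.asarray(hour, dtype=float))
    if not windows:  # always active: everything belongs to window 0
        return np.zeros(h.shape, dtype=int)
    idx = np.full(h.shape, -1, dtype=int)
    for i, (lo, hi) in enumerate(windows):
        if hi > lo:
            inside = (h >= lo) & (h < hi)
        else:
            inside = (h >= lo) | (h < hi)
        idx[inside & (idx < 0)] = i
    return idx


def _require_assignment(visits: pd.DataFrame, task: TaskDefinition) -> None:
    missing = sorted(set(visits["animal_tag"]) - set(task.assignment))
    if missing:
        raise TaskConfigError(f"no corner assignment for animal(s): {missing}")


def label_ppl(
    visits: pd.DataFrame,
    task: TaskDefinition,
    meta: ExperimentMetadata,
    nosepokes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label visits for the place-preference task (and its reversal).

    A visit is CORRECT iff it goes to the animal's assigned corner and
    starts inside an active window; other in-window visits are INCORRECT
    ("place errors"); visits outside the windows are OUTSIDE_WINDOW and
    excluded from trial counts.  Correctness is fixed by the state at
    visit start.

    When ``nosepokes`` is given, side-level poke correctness is added:
    inside the window with index *i* the rewarded door side is
    ``task.side_by_window[i]``, and correct/incorrect poke counts per
    visit are returned (only the first correct poke opens the door, but
    all are counted).
    """
    if task.kind not in ("PPL", "PPL_REV"):
        raise TaskConfigError(f"label_ppl expects PPL/PPL_REV, got {task.kind}")
    _require_assignment(visits, task)

    hours = meta.clock_hour(visits["start_time_s"].to_numpy())
    widx = _window_index(hours, task.active_windows)
    assigned = visits["animal_tag"].map(task.assignment).to_numpy()
    correctness = np.where(
        widx < 0,
        OUTSIDE_WINDOW,
        np.where(visits["corner"].to_numpy() == assigned, CORRECT, INCORRECT),
    )
    out = visits[["visit_id", "animal_tag", "corner", "start_time_s"]].copy()
    out["correctness"] = correctness
    out["window_index"] = widx
    out["correct_nosepoke_count"] = 0
    out["incorrect_nosepoke_count"] = 0

    if nosepokes is not None and len(nosepokes):
        side_ok = {
            vid: task.side_by_window[w]
            for vid, w in zip(out["visit_id"], widx)
            if 0 <= w < len(task.side_by_window)
        }
        pk = nosepokes.merge(
            out[["visit_id", "correctness"]], on="visit_id", how="inner"
        )
        pk["target_side"] = pk["visit_id"].map(side_ok)
        scored = pk["target_side"].notna() & (pk["correctness"] == CORRECT)
        pk_correct = scored & (pk["side"] == pk["target_side"])
        pk_incorrect = (pk["target_side"].notna()) & ~pk_correct
        n_ok = pk.loc[pk_correct].groupby("visit_id").size()
        n_bad = pk.loc[pk_incorrect].groupby("visit_id").size()
        out["correct_nosepoke_count"] = (
            out["visit_id"].map(n_ok).fillna(0).astype(int)
        )
        out["incorrect_nosepoke_count"] = (
            out["visit_id"].map(n_bad).fillna(0).astype(int)
        )
    return out


def place_error_proportion(labeled: pd.DataFrame) -> float:
    """Wrong in-window visits relative to all in-window visits.

    Returns NaN when there are no in-window visits (empty denominator is
    flagged rather than raising, so time-binned curves can carry gaps).
    """
    scored = labeled["correctness"].isin([CORRECT, INCORRECT])
    n = int(scored.sum())
    if n == 0:
        return float("nan")
    return float((labeled.loc[scored, "correctness"] == INCORRECT).sum() / n)


def label_ssl(
    visits: pd.DataFrame,
    task: TaskDefinition,
    meta: ExperimentMetadata,
    visit_classes: pd.Series | None = None,
    nosepokes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replay the spatial-sequence chain and label each visit.

    The rewarded corner advances along the clockwise order 1→2→3→4→1
    (anti-clockwise for SSL_REV) *only* after a visit with licks
    (L-visit) to the current rewarded corner; a correct visit without
    licks leaves the pointer in place.  Visits outside active windows are
    OUTSIDE_WINDOW and do not move the chain.

    Parameters
    ----------
    visit_classes
        Visit class per visit_id (from :func:`cagephys.events.classify_visits`);
        required unless ``nosepokes`` is given, in which case classes are
        derived here.

    Returns
    -------
    (labeled, chain_trace)
        ``labeled`` has one row per visit with ``correctness``;
        ``chain_trace`` records, per animal and visit, the rewarded
        corner before the visit and whether the chain advanced.
    """
    if task.kind not in ("SSL", "SSL_REV"):
        raise TaskConfigError(f"label_ssl expects SSL/SSL_REV, got {task.kind}")
    _require_assignment(visits, task)
    if visit_classes is None:
        if nosepokes is None:
            raise TaskConfigError("label_ssl needs visit_classes or nosepokes")
        from .events import classify_visits

        visit_classes = classify_visits(visits, nosepokes)

    step = 1 if task.kind == "SSL" else -1
    order = {c: i for i, c in enumerate(CLOCKWISE_ORDER)}

    v = visits.sort_values("start_time_s", kind="stable")
    hours = meta.clock_hour(v["start_time_s"].to_numpy())
    inside = in_active_window(hours, task.active_windows)

    pointer = dict(task.assignment)  # animal -> current rewarded corner
    rows = []
    trace = []
    for (vid, tag, corner), ok in zip(
        v[["visit_id", "animal_tag", "corner"]].itertuples(index=False), inside
    ):
        cur = pointer[tag]
        if not ok:
            label, advanced = OUTSIDE_WINDOW, False
        elif corner == cur:
            label = CORRECT
            advanced = visit_classes.loc[vid] == "L_VISIT"
            if advanced:
                pointer[tag] = CLOCKWISE_ORDER[(order[cur] + step) % 4]
        else:
            label, advanced = INCORRECT, False
        rows.append((vid, tag, corner, label))
        trace.append((vid, tag, cur, advanced, pointer[tag]))

    labeled = pd.DataFrame(
        rows, columns=["visit_id", "animal_tag", "corner", "correctness"]
    )
    chain = pd.DataFrame(
        trace,
        columns=["visit_id", "animal_tag", "corner_before", "advanced", "corner_after"],
    )
    return labeled, chain


def label_drl(
    nosepokes: pd.DataFrame,
    visits: pd.DataFrame,
    task: TaskDefinition,
    seed: int = 0,
) -> pd.DataFrame:
    """Label nosepokes for the delayed-response task.

    Within a visit the first poke on a door arms the trial; the next poke
    on the *same* door decides it: delay >= ``task.delay_s`` is CORRECT,
    a premature poke is INCORRECT and scoring for that visit stops.
    Pokes on the opposite door are NEUTRAL and leave the armed door
    untouched.  Pokes in the neutral corner are NEUTRAL; their door
    openings are drawn Bernoulli(``open_probability``) from a dedicated
    seeded substream per animal so replays are reproducible.
    """
    if task.kind != "DRL":
        raise TaskConfigError(f"label_drl expects DRL, got {task.kind}")
    if task.delay_s <= 0:
        raise TaskConfigError("delay_s must be positive")

    corner_of = visits.set_index("visit_id")["corner"]
    animal_of = visits.set_index("visit_id")["animal_tag"]
    rngs: dict[str, np.random.Generator] = {}
    for i, tag in enumerate(sorted(visits["animal_tag"].unique())):
        rngs[tag] = np.random.default_rng(np.random.SeedSequence((seed, i)))

    pk = nosepokes.sort_values(["visit_id", "time_s"], kind="stable")
    labels = []
    opens = []
    armed_side: str | None = None
    armed_time = 0.0
    decided = False
    last_vid = None
    for vid, side, t in pk[["visit_id", "side", "time_s"]].itertuples(index=False):
        if vid != last_vid:
            armed_side, decided, last_vid = None, False, vid
        corner = corner_of.loc[vid]
        if task.neutral_corner is not None and corner == task.neutral_corner:
            opened = bool(rngs[animal_of.loc[vid]].random() < task.open_probability)
            labels.append(NEUTRAL)
            opens.append(opened)
            continue
        if decided:
            labels.append(NEUTRAL)
            opens.append(False)
            continue
        if armed_side is None:
            armed_side, armed_time = side, t
            labels.append(NEUTRAL)
            opens.append(False)
        elif side != armed_side:
            labels.append(NEUTRAL)  # opposite door: no effect
            opens.append(False)
        else:
            ok = (t - armed_time) >= task.delay_s
            labels.append(CORRECT if ok else INCORRECT)
            opens.append(bool(ok))
            decided = True

    out = pk[["visit_id", "side", "time_s"]].copy()
    out["label"] = labels
    out["door_opened"] = opens
    return out.reset_index(drop=True)


def label_pal(
    visits: pd.DataFrame,
    nosepokes: pd.DataFrame,
    task: TaskDefinition,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label visits and pokes for place avoidance (and its extinction).

    A visit is CORRECT iff its corner is not the animal's punished corner
    (random expectation 3/4 under uniform corner choice); a poke is
    correct iff not made in the punished corner.  Visit-level and
    nosepoke-level correct proportions are returned separately per
    animal: animals can keep inspecting the punished corner while
    learning to withhold pokes there.
    """
    if task.kind not in ("PAL", "PA_EXT"):
        raise TaskConfigError(f"label_pal expects PAL/PA_EXT, got {task.kind}")
    _require_assignment(visits, task)

    punished = visits["animal_tag"].map(task.assignment).to_numpy()
    labeled = visits[["visit_id", "animal_tag", "corner", "start_time_s"]].copy()
    labeled["correctness"] = np.where(
        visits["corner"].to_numpy() != punished, CORRECT, INCORRECT
    )

    pk = nosepokes.merge(
        labeled[["visit_id", "animal_tag", "correctness"]], on="visit_id", how="inner"
    )
    # a poke is correct iff its visit avoids the punished corner
    pk["poke_correct"] = pk["correctness"] == CORRECT

    per_animal = []
    for tag, sub in labeled.groupby("animal_tag"):
        vis_prop = float((sub["correctness"] == CORRECT).mean())
        pk_sub = pk[pk["animal_tag"] == tag]
        np_prop = float(pk_sub["poke_correct"].mean()) if len(pk_sub) else float("nan")
        per_animal.append((tag, vis_prop, np_prop))
    props = pd.DataFrame(
        per_animal, columns=["animal_tag", "visit_correct_prop", "np_correct_prop"]
    )
    return labeled, props


def correct_visit_sequences(labeled: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-animal boolean trial sequences for the sequential learning test.

    Trials are the in-window visits only (CORRECT or INCORRECT), in time
    order; OUTSIDE_WINDOW visits carry no reward information and are
    dropped.
    """
    scored = labeled[labeled["correctness"].isin([CORRECT, INCORRECT])]
    if "start_time_s" in scored.columns:
        scored = scored.sort_values("start_time_s", kind="stable")
    return {
        tag: (sub["correctness"] == CORRECT).to_numpy()
        for tag, sub in scored.groupby("animal_tag")
    }
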