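"""Task-rule labeling: place preference, sequence chain, DRL, avoidance."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from cagephys.events import ExperimentMetadata
from cagephys.tasks import (
    CORRECT,
    INCORRECT,
    NEUTRAL,
    OUTSIDE_WINDOW,
    TaskConfigError,
    TaskDefinition,
    correct_visit_sequences,
    in_active_window,
    label_drl,
    label_pal,
    label_ppl,
    label_ssl,
    place_error_proportion,
)

META = ExperimentMetadata(t0_clock=datetime(2020, 1, 6, 0, 0, 0))  # t=0 at midnight


def _visits(rows):
    """rows: (visit_id, tag, corner, start_h)"""
    return pd.DataFrame(
        {
            "visit_id": [r[0] for r in rows],
            "animal_tag": [r[1] for r in rows],
            "corner": [r[2] for r in rows],
            "start_time_s": [r[3] * 3600.0 for r in rows],
            "end_time_s": [r[3] * 3600.0 + 30.0 for r in rows],
            "module_label": ["x"] * len(rows),
        }
    )


def test_active_window_membership_half_open_and_wrapping():
    h = np.array([10.99, 11.0, 13.99, 14.0, 22.5, 23.0, 1.99, 2.0])
    got = in_active_window(h, [(11, 14), (23, 2)])
    assert got.tolist() == [False, True, True, False, False, True, True, False]


class TestPPL:
    def test_place_error_proportion(self):
        # 8 in-window visits, 2 to the assigned corner -> error prop 0.75
        rows = [(i, "m1", 2 if i < 2 else 3, 11.5) for i in range(8)]
        v = _visits(rows)
        # stagger starts to keep visits non-overlapping
        v["start_time_s"] += np.arange(8) * 60.0
        v["end_time_s"] += np.arange(8) * 60.0
        task = TaskDefinition(kind="PPL", assignment={"m1": 2})
        lab = label_ppl(v, task, META)
        assert place_error_proportion(lab) == pytest.approx(0.75)

    def test_outside_window_flagged_and_undefined_proportion(self):
        v = _visits([(1, "m1", 2, 5.0), (2, "m1", 2, 17.0)])
        task = TaskDefinition(kind="PPL", assignment={"m1": 2})
        lab = label_ppl(v, task, META)
        assert (lab["correctness"] == OUTSIDE_WINDOW).all()
        assert np.isnan(place_error_proportion(lab))

    def test_missing_assignment_raises(self):
        v = _visits([(1, "m1", 2, 11.5)])
        task = TaskDefinition(kind="PPL", assignment={})
        with pytest.raises(TaskConfigError, match="m1"):
            label_ppl(v, task, META)

    def test_side_level_poke_counts(self):
        v = _visits([(1, "m1", 2, 11.5), (2, "m1", 2, 23.5)])
        pokes = pd.DataFrame(
            {
                "visit_id": [1, 1, 2],
                "side": ["LEFT", "RIGHT", "LEFT"],
                "time_s": [v.loc[0, "start_time_s"] + 1] * 2
                + [v.loc[1, "start_time_s"] + 1],
                "door_opened": [True, False, False],
                "lick_count": [5, 0, 0],
                "lick_duration_s": [0.5, 0.0, 0.0],
                "contact_time_s": [0.5, 0.1, 0.1],
            }
        )
        task = TaskDefinition(kind="PPL", assignment={"m1": 2})
        lab = label_ppl(v, task, META, nosepokes=pokes).set_index("visit_id")
        # daytime window: LEFT correct; night window: RIGHT correct
        assert lab.loc[1, "correct_nosepoke_count"] == 1
        assert lab.loc[1, "incorrect_nosepoke_count"] == 1
        assert lab.loc[2, "correct_nosepoke_count"] == 0
        assert lab.loc[2, "incorrect_nosepoke_count"] == 1

    def test_simulated_cohort_matches_truth(self, small_cohort):
        cfg, visits, _, meta, truth = small_cohort
        task = TaskDefinition(
            kind="PPL",
            active_windows=cfg.active_windows,
            assignment={t: cfg.rewarded_corner for t in meta.roster},
        )
        lab = label_ppl(visits, task, meta).set_index("visit_id")
        expected = pd.Series(
            {d["visit_id"]: d["correctness"] for d in truth["visits"]}
        )
        assert (lab["correctness"].loc[expected.index] == expected).all()


def _ssl_replay_oracle(stream, start, step):
    """Brute-force replay: (corner, licked) pairs -> labels + pointer."""
    order = [1, 2, 3, 4]
    ptr = start
    labels = []
    for corner, licked in stream:
        if corner == ptr:
            labels.append(CORRECT)
            if licked:
                ptr = order[(order.index(ptr) + step) % 4]
        else:
            labels.append(INCORRECT)
    return labels, ptr


class TestSSL:
    def _run(self, stream, kind="SSL"):
        rows = [(i, "m1", c, 11.0 + i * 0.01) for i, (c, _) in enumerate(stream)]
        v = _visits(rows)
        v["end_time_s"] = v["start_time_s"] + 30.0
        classes = pd.Series(
            ["L_VISIT" if licked else "NP_VISIT" for _, licked in stream],
            index=[r[0] for r in rows],
        )
        task = TaskDefinition(kind=kind, assignment={"m1": 1})
        return label_ssl(v, task, META, visit_classes=classes)

    def test_hand_replay_chain(self):
        # lick-visits to C1 then C2 advance the pointer to C3; the third
        # visit to C3 without licks is correct but does not advance
        stream = [(1, True), (2, True), (3, False)]
        lab, chain = self._run(stream)
        assert lab["correctness"].tolist() == [CORRECT, CORRECT, CORRECT]
        assert chain["corner_after"].iloc[-1] == 3

    def test_fixed_corner_becomes_incorrect(self):
        stream = [(1, True)] * 4
        lab, _ = self._run(stream)
        assert lab["correctness"].tolist() == [CORRECT] + [INCORRECT] * 3

    def test_reversed_chain_mirrors(self):
        stream = [(1, True), (4, True), (3, False)]
        lab, chain = self._run(stream, kind="SSL_REV")
        assert lab["correctness"].tolist() == [CORRECT, CORRECT, CORRECT]
        assert chain["corner_after"].iloc[-1] == 3

    @pytest.mark.parametrize("kind,step", [("SSL", 1), ("SSL_REV", -1)])
    def test_state_machine_equals_bruteforce_oracle(self, kind, step, rng):
        for _ in range(30):
            n = int(rng.integers(1, 50))
            stream = [
                (int(rng.integers(1, 5)), bool(rng.random() < 0.5))
                for _ in range(n)
            ]
            lab, chain = self._run(stream, kind=kind)
            want, ptr = _ssl_replay_oracle(stream, 1, step)
            assert lab["correctness"].tolist() == want
            assert chain["corner_after"].iloc[-1] == ptr


class TestDRL:
    def _run(self, poke_times, sides=None, delay=4.0, corner=2, neutral=None):
        v = _visits([(1, "m1", corner, 11.5)])
        v["end_time_s"] = v["start_time_s"] + 60.0
        n = len(poke_times)
        pokes = pd.DataFrame(
            {
                "visit_id": [1] * n,
                "side": sides or ["LEFT"] * n,
                "time_s": [v.loc[0, "start_time_s"] + t for t in poke_times],
                "door_opened": [False] * n,
                "lick_count": [0] * n,
                "lick_duration_s": [0.0] * n,
                "contact_time_s": [0.1] * n,
            }
        )
        task = TaskDefinition(kind="DRL", delay_s=delay, neutral_corner=neutral)
        return label_drl(pokes, v, task, seed=0)

    def test_delayed_second_poke_correct(self):
        lab = self._run([0.0, 4.1])
        assert lab["label"].tolist() == [NEUTRAL, CORRECT]
        assert bool(lab["door_opened"].iloc[1])

    def test_premature_second_poke_incorrect(self):
        lab = self._run([0.0, 3.9])
        assert lab["label"].tolist() == [NEUTRAL, INCORRECT]

    def test_first_premature_poke_decides(self):
        lab = self._run([0.0, 2.0, 5.0])
        assert lab["label"].tolist() == [NEUTRAL, INCORRECT, NEUTRAL]

    def test_opposite_door_has_no_effect(self):
        lab = self._run([0.0, 1.0, 4.5], sides=["LEFT", "RIGHT", "LEFT"])
        assert lab["label"].tolist() == [NEUTRAL, NEUTRAL, CORRECT]

    def test_neutral_corner_seeded_openings(self):
        lab1 = self._run([0.0, 4.1], corner=3, neutral=3)
        lab2 = self._run([0.0, 4.1], corner=3, neutral=3)
        assert (lab1["label"] == NEUTRAL).all()
        assert lab1["door_opened"].tolist() == lab2["door_opened"].tolist()

    def test_nonpositive_delay_rejected(self):
        with pytest.raises(TaskConfigError):
            TaskDefinition(kind="DRL", delay_s=0.0)


class TestPAL:
    def test_visit_and_poke_proportions(self):
        rows = [(i, "m1", 1 if i < 5 else 2, 0.1 * i) for i in range(20)]
        v = _visits(rows)
        v["end_time_s"] = v["start_time_s"] + 30.0
        pokes = pd.DataFrame(
            {
                "visit_id": [5, 6],
                "side": ["LEFT", "LEFT"],
                "time_s": v.loc[5, "start_time_s"] + np.array([1.0, 361.0]),
                "door_opened": [True, True],
                "lick_count": [3, 3],
                "lick_duration_s": [0.3, 0.3],
                "contact_time_s": [0.3, 0.3],
            }
        )
        task = TaskDefinition(kind="PAL", active_windows=(), assignment={"m1": 1})
        lab, props = label_pal(v, pokes, task)
        assert props.loc[0, "visit_correct_prop"] == pytest.approx(0.75)
        # pokes all made outside the punished corner -> NP correctness 1
        assert props.loc[0, "np_correct_prop"] == pytest.approx(1.0)

    def test_punished_visit_without_pokes_leaves_np_prop_alone(self):
        v = _visits([(1, "m1", 1, 0.0), (2, "m1", 2, 1.0)])
        pokes = pd.DataFrame(
            {
                "visit_id": [2],
                "side": ["LEFT"],
                "time_s": [3601.0],
                "door_opened": [True],
                "lick_count": [2],
                "lick_duration_s": [0.2],
                "contact_time_s": [0.2],
            }
        )
        task = TaskDefinition(kind="PAL", active_windows=(), assignment={"m1": 1})
        lab, props = label_pal(v, pokes, task)
        assert lab.set_index("visit_id").loc[1, "correctness"] == INCORRECT
        assert props.loc[0, "np_correct_prop"] == pytest.approx(1.0)


def test_uniform_agent_long_run_proportions(rng):
    """A uniform-random corner process scores 1/4 correct under place
    preference and 3/4 correct under place avoidance (binomial 3 sigma)."""
    n = 100_000
    corners = rng.integers(1, 5, size=n)
    starts = np.arange(n) * 40.0
    v = pd.DataFrame(
        {
            "visit_id": np.arange(n),
            "animal_tag": "m1",
            "corner": corners,
            "start_time_s": starts,
            "end_time_s": starts + 30.0,
            "module_label": "x",
        }
    )
    empty_pokes = pd.DataFrame(
        {
            "visit_id": [],
            "side": [],
            "time_s": [],
            "door_opened": [],
            "lick_count": [],
            "lick_duration_s": [],
            "contact_time_s": [],
        }
    )
    ppl = TaskDefinition(kind="PPL", active_windows=(), assignment={"m1": 2})
    lab = label_ppl(v, ppl, META)
    p_hat = (lab["correctness"] == CORRECT).mean()
    assert abs(p_hat - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    pal = TaskDefinition(kind="PAL", active_windows=(), assignment={"m1": 2})
    _, props = label_pal(v, empty_pokes, pal)
    assert abs(props.loc[0, "visit_correct_prop"] - 0.75) < 3 * np.sqrt(
        0.75 * 0.25 / n
    )


def test_correct_visit_sequences_drop_outside_window(small_cohort):
    cfg, visits, _, meta, truth = small_cohort
    task = TaskDefinition(
        kind="PPL",
        active_windows=cfg.active_windows,
        assignment={t: cfg.rewarded_corner for t in meta.roster},
    )
    lab = label_ppl(visits, task, meta)
    seqs = correct_visit_sequences(lab)
    for tag, seq in seqs.items():
        assert seq.tolist() == truth["animals"][tag]["trial_outcomes"]
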