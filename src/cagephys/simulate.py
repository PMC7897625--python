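"""Ground-truth-labeled synthetic data for every pipeline stage.

Two generators:

``simulate_cohort``
    A group-housed cage of RFID-tagged agents.  Each animal visits the
    four corners under a nonhomogeneous Poisson process whose rate
    follows a 24-h cosinor, lambda(t) = max(0, M + A cos(2 pi (t -
    phi)/24)) (sampled exactly by thinning), learns a rewarded corner
    inside the drinking-session windows with an exponential-saturation
    success probability p(n) = p0 + (p_max - p0)(1 - exp(-n/tau)), and
    emits nosepokes and negative-binomially distributed lick bouts per
    visit.  A reversal switches the rewarded corner and (by default,
    fully) resets the learned probability.  Every label the analysis
    pipeline must recover — visit class, correctness, trial index,
    sequential-test decision — is recorded in a truth dictionary at
    generation time.

``simulate_sweeps``
    Field-potential slices with a sigmoidal intensity -> slope response,
    a programmable post-TBS potentiation time course (plateau percent,
    optional exponential decay), slice-to-slice gain variability, an
    adjustable linear coupling between sqrt(I/O AUC) and LTP AUC, and
    Gaussian voltage noise.

Both generators are exactly reproducible: a fixed seed yields
byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .events import ExperimentMetadata, write_event_log, write_metadata
from .learning import SPRTConfig, sprt_track
from .tasks import (
    CORRECT,
    INCORRECT,
    OUTSIDE_WINDOW,
    DEFAULT_ACTIVE_WINDOWS,
    in_active_window,
)

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SweepGroupParams",
    "SweepSimConfig",
    "simulate_cohort",
    "simulate_sweeps",
    "write_cohort",
    "write_sweeps",
]


# ---------------------------------------------------------------------------
# cage cohort
# ---------------------------------------------------------------------------


@dataclass
class GroupParams:
    """Behavioral parameters of one genotype/treatment group.

    Defaults are sized to a middle-aged mouse cohort: a visiting rate of
    a few visits per hour peaking in the dark phase, learning that
    saturates within tens of in-window trials, and overdispersed lick
    bouts of a few dozen licks per rewarded visit.
    """

    mesor: float = 3.0  # visits/h
    amplitude: float = 2.0  # visits/h
    acrophase_h: float = 24.0  # peak of activity, wall-clock (midnight)
    tau_trials: float = 30.0  # learning time constant, in-window trials
    p_max: float = 0.85  # asymptotic correct-visit probability
    p0: float = 0.25  # chance level (4 corners)
    licks_mean: float = 30.0  # mean licks per rewarded visit
    licks_dispersion: float = 5.0  # negative-binomial size parameter
    np_visit_fraction: float = 0.6  # P(pokes) for unrewarded visits
    plain_visit_fraction: float = 0.25  # P(no pokes at all) for any visit

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 <= self.p_max <= 1.0):
            raise ValueError("require 0 < p0 <= p_max <= 1")
        if self.mesor < 0 or self.amplitude < 0:
            raise ValueError("rates must be >= 0")
        if self.mesor + self.amplitude <= 0:
            raise ValueError("rate is identically zero: no events to draw")


@dataclass
class CohortConfig:
    """Cohort layout, task schedule reference and seed."""

    groups: dict[str, GroupParams] = field(
        default_factory=lambda: {"wt": GroupParams(), "ko": GroupParams()}
    )
    n_per_group: int = 12
    duration_days: float = 7.0
    t0_clock: datetime = field(default_factory=lambda: datetime(2020, 1, 6, 10, 0, 0))
    active_windows: tuple[tuple[float, float], ...] = DEFAULT_ACTIVE_WINDOWS
    rewarded_corner: int = 2
    reversal_day: float | None = None  # switch to the diagonal corner
    reversal_reset_fraction: float = 1.0  # 1 = full reset of learning
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.duration_days <= 0:
            raise ValueError("need >= 1 animal and positive duration")
        if self.rewarded_corner not in (1, 2, 3, 4):
            raise ValueError("rewarded_corner must be 1-4")
        if not (0.0 <= self.reversal_reset_fraction <= 1.0):
            raise ValueError("reversal_reset_fraction in [0, 1]")


def _thinning_times(
    rng: np.random.Generator,
    duration_h: float,
    t0_hour: float,
    mesor: float,
    amplitude: float,
    acrophase_h: float,
) -> np.ndarray:
    """Event times (hours since start) of the cosinor-rate Poisson process."""
    lam_max = mesor + amplitude
    t = 0.0
    out = []
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= duration_h:
            break
        clock = (t0_hour + t) % 24.0
        lam = max(
            0.0, mesor + amplitude * np.cos(2 * np.pi * (clock - acrophase_h) / 24.0)
        )
        if rng.random() * lam_max < lam:
            out.append(t)
    return np.asarray(out)


def _diagonal(corner: int) -> int:
    return ((corner - 1) + 2) % 4 + 1


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentMetadata, dict]:
    """Generate the visit/nosepoke tables, metadata and ground truth.

    Returns ``(visits, nosepokes, metadata, truth)``.  ``truth`` holds,
    per visit: the class and correctness label the pipeline must
    recover; per animal: the rewarded corner(s), the in-window trial
    outcome sequence, and the sequential-test decision computed on it.
    """
    root = np.random.SeedSequence(config.seed)
    meta_roster: dict[str, str] = {}
    duration_h = config.duration_days * 24.0
    t0_hour = (
        config.t0_clock.hour
        + config.t0_clock.minute / 60.0
        + config.t0_clock.second / 3600.0
    )
    reversal_h = (
        config.reversal_day * 24.0 if config.reversal_day is not None else np.inf
    )

    visit_rows = []
    poke_rows = []
    truth_visits = []
    truth_animals = {}
    vid = 0
    animal_streams = root.spawn(len(config.groups) * config.n_per_group)
    k = 0
    for gname, gp in config.groups.items():
        for j in range(config.n_per_group):
            tag = f"{gname}{j:02d}"
            meta_roster[tag] = gname
            rng = np.random.default_rng(animal_streams[k])
            k += 1

            times_h = _thinning_times(
                rng, duration_h, t0_hour, gp.mesor, gp.amplitude, gp.acrophase_h
            )
            corner_now = config.rewarded_corner
            n_trial = 0.0
            trial_outcomes = []
            prev_end = -1.0
            for i, th in enumerate(times_h):
                gap = (
                    (times_h[i + 1] - th) * 3600.0 if i + 1 < len(times_h) else np.inf
                )
                dur = min(float(rng.lognormal(np.log(20.0), 0.5)), max(gap - 1.0, 2.0))
                start = round(max(th * 3600.0, prev_end + 0.5), 3)
                end = round(start + dur, 3)
                prev_end = end

                if th >= reversal_h and corner_now == config.rewarded_corner:
                    corner_now = _diagonal(config.rewarded_corner)
                    n_trial *= 1.0 - config.reversal_reset_fraction

                clock = (t0_hour + start / 3600.0) % 24.0
                inside = bool(in_active_window(clock, config.active_windows)[0])
                if inside:
                    # 1-based trial index: tau -> 0 gives an immediately
                    # asymptotic (all-correct for p_max = 1) agent
                    n_trial += 1.0
                    p = gp.p0 + (gp.p_max - gp.p0) * (
                        1.0 - np.exp(-n_trial / gp.tau_trials)
                    )
                    correct = bool(rng.random() < p)
                    if correct:
                        corner = corner_now
                    else:
                        others = [c for c in (1, 2, 3, 4) if c != corner_now]
                        corner = int(others[rng.integers(3)])
                    correctness = CORRECT if correct else INCORRECT
                    trial_outcomes.append(correct)
                else:
                    corner = int(rng.integers(1, 5))
                    correctness = OUTSIDE_WINDOW
                    correct = False

                # visit content: plain / pokes without licks / rewarded licks
                rewarded = inside and correct
                if rng.random() < gp.plain_visit_fraction and not rewarded:
                    vclass = "PLAIN_VISIT"
                    n_pokes = 0
                elif rewarded:
                    vclass = "L_VISIT"
                    n_pokes = 1 + int(rng.poisson(1.0))
                elif rng.random() < gp.np_visit_fraction:
                    vclass = "NP_VISIT"
                    n_pokes = 1 + int(rng.poisson(1.0))
                else:
                    vclass = "PLAIN_VISIT"
                    n_pokes = 0

                visit_rows.append((vid, tag, corner, start, end, "PPL"))
                truth_visits.append(
                    {
                        "visit_id": vid,
                        "animal_tag": tag,
                        "visit_class": vclass,
                        "correctness": correctness,
                    }
                )
                if n_pokes:
                    licks_left = 0
                    if vclass == "L_VISIT":
                        m, disp = gp.licks_mean, gp.licks_dispersion
                        licks_left = 1 + int(
                            rng.negative_binomial(disp, disp / (disp + m))
                        )
                    for q in range(n_pokes):
                        pt = min(start + 0.5 + 1.5 * q, end)
                        licks = licks_left if q == n_pokes - 1 else 0
                        poke_rows.append(
                            (
                                vid,
                                "LEFT" if rng.random() < 0.5 else "RIGHT",
                                round(pt, 3),
                                bool(rewarded and q == 0),
                                licks,
                                round(licks * 0.12, 3),
                                round(licks * 0.15, 3),
                            )
                        )
                vid += 1

            outcome = sprt_track(np.asarray(trial_outcomes, dtype=bool), SPRTConfig())
            truth_animals[tag] = {
                "group": gname,
                "rewarded_corner": config.rewarded_corner,
                "rewarded_corner_after_reversal": (
                    _diagonal(config.rewarded_corner)
                    if config.reversal_day is not None
                    else None
                ),
                "trial_outcomes": [bool(x) for x in trial_outcomes],
                "sprt_decision": outcome.decision,
                "trials_to_criterion": outcome.trials_to_criterion,
            }

    visits = pd.DataFrame(
        visit_rows,
        columns=[
            "visit_id",
            "animal_tag",
            "corner",
            "start_time_s",
            "end_time_s",
            "module_label",
        ],
    )
    nosepokes = pd.DataFrame(
        poke_rows,
        columns=[
            "visit_id",
            "side",
            "time_s",
            "door_opened",
            "lick_count",
            "lick_duration_s",
            "contact_time_s",
        ],
    )
    meta = ExperimentMetadata(t0_clock=config.t0_clock, roster=meta_roster)
    truth = {
        "config": {
            "n_per_group": config.n_per_group,
            "duration_days": config.duration_days,
            "rewarded_corner": config.rewarded_corner,
            "reversal_day": config.reversal_day,
            "seed": config.seed,
            "groups": {g: asdict(p) for g, p in config.groups.items()},
        },
        "visits": truth_visits,
        "animals": truth_animals,
    }
    return visits, nosepokes, meta, truth


def write_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Run :func:`simulate_cohort` and write the four artifact files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    visits, nosepokes, meta, truth = simulate_cohort(config)
    write_event_log(visits, nosepokes, out / "visits.csv", out / "nosepokes.csv")
    write_metadata(meta, out / "metadata.json")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# field-potential sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepGroupParams:
    """Electrophysiological parameters of one group of slices."""

    io_max_slope: float = 1.2  # mV/ms at saturation
    io_half_intensity: float = 50.0  # stimulation units
    io_gain: float = 12.0  # sigmoid steepness (intensity units)
    ltp_plateau_pct: float = 150.0  # % of baseline after TBS
    ltp_decay_tau_min: float | None = None  # None = stable plateau
    slice_gain_sd: float = 0.15  # lognormal sd of slice gain
    coupling: float = 0.0  # d(LTP AUC)/d(sqrt I/O AUC)
    noise_sd_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_mV < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass
class SweepSimConfig:
    groups: dict[str, SweepGroupParams] = field(
        default_factory=lambda: {"wt": SweepGroupParams()}
    )
    n_slices_per_group: int = 8
    intensities: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    sample_rate_khz: float = 10.0
    sweep_len_ms: float = 40.0
    stim_time_ms: float = 5.0
    baseline_min: float = 20.0
    post_min: float = 60.0
    sweep_every_min: float = 1.0
    seed: int = 0


def _sigmoid_slope(intensity: float, p: SweepGroupParams, gain_mult: float) -> float:
    return (
        gain_mult
        * p.io_max_slope
        / (1.0 + np.exp(-(intensity - p.io_half_intensity) / p.io_gain))
    )


def _make_sweep(
    t_ms: np.ndarray,
    stim_ms: float,
    slope: float,
    rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    """Flat baseline + biphasic artifact + negative FP with the given onset slope."""
    v = np.zeros_like(t_ms)
    # 0.4-ms biphasic stimulus artifact, inside the 1-ms blank window
    art = (t_ms >= stim_ms) & (t_ms < stim_ms + 0.2)
    v[art] += 1.5
    art2 = (t_ms >= stim_ms + 0.2) & (t_ms < stim_ms + 0.4)
    v[art2] -= 1.5
    # linear onset ramp of the field potential: 1.5 ms to the negative peak
    onset = stim_ms + 2.0
    ramp_ms = 1.5
    amp = slope * ramp_ms
    rampmask = (t_ms >= onset) & (t_ms <= onset + ramp_ms)
    v[rampmask] -= slope * (t_ms[rampmask] - onset)
    # exponential recovery back to baseline
    rec = t_ms > onset + ramp_ms
    v[rec] -= amp * np.exp(-(t_ms[rec] - onset - ramp_ms) / 8.0)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return v


def simulate_sweeps(config: SweepSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the long-format sweep table and per-slice ground truth.

    For each slice: one I/O series over ``config.intensities``, then an
    LTP timeline at the 30%-of-maximum intensity, sampled every
    ``sweep_every_min`` minutes from ``-baseline_min`` to ``post_min``
    with TBS at t = 0.  The LTP AUC is coupled to the slice's
    excitability via ``coupling`` (LTP plateau shifted linearly in the
    slice's sqrt I/O AUC, centered on the group mean).
    """
    root = np.random.SeedSequence((config.seed, 7))
    dt = 1.0 / config.sample_rate_khz
    t_ms = np.round(np.arange(0.0, config.sweep_len_ms + dt / 2, dt), 6)

    rows = []
    truth_slices = {}
    streams = root.spawn(config.n_slices_per_group * len(config.groups))
    k = 0
    for gname, gp in config.groups.items():
        # slice gains drawn first so the coupling can be centered
        gains, rngs = [], []
        for _ in range(config.n_slices_per_group):
            rng = np.random.default_rng(streams[k])
            k += 1
            rngs.append(rng)
            gains.append(float(rng.lognormal(0.0, gp.slice_gain_sd)))
        io_aucs = []
        for g in gains:
            s = np.array([_sigmoid_slope(i, gp, g) for i in config.intensities])
            io_aucs.append(float(np.trapezoid(s, np.asarray(config.intensities))))
        sqrt_mean = float(np.mean(np.sqrt(io_aucs)))

        for j, (g, rng) in enumerate(zip(gains, rngs)):
            sid = f"{gname}_s{j:02d}"
            plateau = gp.ltp_plateau_pct + gp.coupling * (
                np.sqrt(io_aucs[j]) - sqrt_mean
            )
            swid = 0
            # --- I/O series ---
            for inten in config.intensities:
                slope = _sigmoid_slope(inten, gp, g)
                v = _make_sweep(t_ms, config.stim_time_ms, slope, rng, gp.noise_sd_mV)
                rows.append((sid, swid, "io", inten, -config.baseline_min - 1.0, v))
                swid += 1
            # --- LTP timeline at ~30% of max ---
            target = 0.3 * gp.io_max_slope * g
            inten30 = min(
                config.intensities,
                key=lambda i: abs(_sigmoid_slope(i, gp, g) - target),
            )
            base_slope = _sigmoid_slope(inten30, gp, g)
            times = np.arange(
                -config.baseline_min, config.post_min + 1e-9, config.sweep_every_min
            )
            for tm in times:
                if tm < 0:
                    factor = 1.0
                elif gp.ltp_decay_tau_min is None:
                    factor = plateau / 100.0
                else:
                    factor = 1.0 + (plateau / 100.0 - 1.0) * np.exp(
                        -tm / gp.ltp_decay_tau_min
                    )
                v = _make_sweep(
                    t_ms, config.stim_time_ms, base_slope * factor, rng, gp.noise_sd_mV
                )
                rows.append((sid, swid, "ltp", inten30, float(tm), v))
                swid += 1
            truth_slices[sid] = {
                "group": gname,
                "gain": g,
                "io_auc": io_aucs[j],
                "ltp_plateau_pct": float(plateau),
                "baseline_slope": float(base_slope),
                "ltp_intensity": float(inten30),
            }

    frames = []
    for sid, swid, phase, inten, tm, v in rows:
        frames.append(
            pd.DataFrame(
                {
                    "slice_id": sid,
                    "sweep_id": swid,
                    "phase": phase,
                    "stim_intensity": float(inten),
                    "stim_time_ms": config.stim_time_ms,
                    "timestamp_min": tm,
                    "t_ms": t_ms,
                    "v_mV": np.round(v, 6),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "config": {
            "seed": config.seed,
            "groups": {g: asdict(p) for g, p in config.groups.items()},
        },
        "slices": truth_slices,
    }
    return table, truth


def write_sweeps(config: SweepSimConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_sweeps(config)
    table.to_csv(out / "sweeps.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out
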