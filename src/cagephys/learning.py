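"""Sequential learning-criterion statistics (Wald SPRT).

An animal's in-window visits form a Bernoulli trial stream (correct /
incorrect).  Whether the animal has learned is decided sequentially with
Wald's sequential probability ratio test between chance performance
H0: p = p0 (0.25 for a four-corner place task) and criterion performance
H1: p = p1 (0.35 in this design).  The log-likelihood ratio

    llr_n = k * ln(p1/p0) + (n - k) * ln((1-p1)/(1-p0)),

with k successes in n trials, is tracked until it first crosses the Wald
boundaries upper = ln((1-beta)/alpha) or lower = ln(beta/(1-alpha)); the
first crossing classifies the animal as LEARNER or NON_LEARNER, and the
crossing trial is the *trials to criterion*.  Streams that exhaust
``max_trials`` undecided are CENSORED.

With alpha = beta = 0.05 the boundaries are ±ln 19 ≈ ±2.9444, so an
animal that is always correct reaches criterion at trial 9 and one that
is never correct is classified non-learner at trial 21.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEARNER",
    "NON_LEARNER",
    "CENSORED",
    "SPRTConfig",
    "LearningOutcome",
    "sprt_boundaries",
    "sprt_track",
    "sprt_monte_carlo",
    "learner_proportion_curve",
    "cumulative_correct_curve",
]

LEARNER = "LEARNER"
NON_LEARNER = "NON_LEARNER"
CENSORED = "CENSORED"


@dataclass(frozen=True)
class SPRTConfig:
    """Design parameters of the sequential test.

    Defaults are the four-corner place-task design: chance success
    p0 = 0.25, criterion p1 = 0.35, type-1 and type-2 error rates 0.05.
    """

    p0: float = 0.25
    p1: float = 0.35
    alpha: float = 0.05
    beta: float = 0.05
    max_trials: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < self.p1 < 1.0):
            raise ValueError("require 0 < p0 < p1 < 1")
        if not (0.0 < self.alpha < 0.5 and 0.0 < self.beta < 0.5):
            raise ValueError("require 0 < alpha, beta < 0.5")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")

    @property
    def llr_success(self) -> float:
        """Log-likelihood-ratio increment for a correct trial."""
        return math.log(self.p1 / self.p0)

    @property
    def llr_failure(self) -> float:
        """Log-likelihood-ratio increment for an incorrect trial (negative)."""
        return math.log((1.0 - self.p1) / (1.0 - self.p0))


@dataclass
class LearningOutcome:
    """Decision for one animal's trial stream."""

    animal_tag: str
    decision: str
    trials_to_criterion: int | None
    llr_path: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.llr_path)


def sprt_boundaries(config: SPRTConfig) -> tuple[float, float]:
    """Wald decision boundaries on the log-odds scale.

    Returns ``(lower, upper)`` with ``upper = ln((1-beta)/alpha)`` and
    ``lower = ln(beta/(1-alpha))``; symmetric about zero when
    alpha == beta.
    """
    upper = math.log((1.0 - config.beta) / config.alpha)
    lower = math.log(config.beta / (1.0 - config.alpha))
    return lower, upper


def sprt_track(
    outcomes: Sequence[bool] | np.ndarray,
    config: SPRTConfig = SPRTConfig(),
    animal_tag: str = "",
) -> LearningOutcome:
    """Run the sequential test over one ordered outcome stream.

    The first boundary crossing decides; trailing trials beyond the
    decision are not inspected.  An empty stream, or one that neither
    crosses a boundary nor reaches ``max_trials`` trials, is CENSORED.
    ``trials_to_criterion`` is set only for LEARNER decisions.
    """
    lower, upper = sprt_boundaries(config)
    up, down = config.llr_success, config.llr_failure
    x = np.asarray(outcomes, dtype=bool)[: config.max_trials]
    if x.size == 0:
        return LearningOutcome(animal_tag, CENSORED, None, np.empty(0))

    incr = np.where(x, up, down)
    path = np.cumsum(incr)
    crossed = (path >= upper) | (path <= lower)
    if crossed.any():
        stop = int(np.argmax(crossed))
        decision = LEARNER if path[stop] >= upper else NON_LEARNER
        return LearningOutcome(
            animal_tag,
            decision,
            stop + 1 if decision == LEARNER else None,
            path[: stop + 1],
        )
    if x.size >= config.max_trials:
        return LearningOutcome(animal_tag, CENSORED, None, path)
    return LearningOutcome(animal_tag, CENSORED, None, path)


def sprt_monte_carlo(
    p: float,
    n_replicates: int,
    config: SPRTConfig = SPRTConfig(),
    rng: np.random.Generator | None = None,
    block: int = 512,
) -> pd.DataFrame:
    """Simulate i.i.d. Bernoulli(p) agents through the sequential test.

    Trials are generated lazily in blocks so long undecided streams do
    not materialize a replicates x max_trials matrix.  Returns one row
    per replicate with ``decision`` and ``stop_trial`` (the deciding
    trial, or ``max_trials`` for censored streams).
    """
    if rng is None:
        rng = np.random.default_rng()
    lower, upper = sprt_boundaries(config)
    up, down = config.llr_success, config.llr_failure

    llr = np.zeros(n_replicates)
    active = np.arange(n_replicates)
    decision = np.full(n_replicates, CENSORED, dtype=object)
    stop = np.full(n_replicates, config.max_trials, dtype=int)

    done_trials = 0
    while active.size and done_trials < config.max_trials:
        b = min(block, config.max_trials - done_trials)
        steps = np.where(rng.random((active.size, b)) < p, up, down)
        paths = llr[active, None] + np.cumsum(steps, axis=1)
        hit = (paths >= upper) | (paths <= lower)
        any_hit = hit.any(axis=1)
        first = np.where(any_hit, hit.argmax(axis=1), b - 1)
        rows = np.arange(active.size)
        end_llr = paths[rows, first]

        decided = active[any_hit]
        decision[decided] = np.where(
            end_llr[any_hit] >= upper, LEARNER, NON_LEARNER
        )
        stop[decided] = done_trials + first[any_hit] + 1
        llr[active] = paths[rows, b - 1]
        active = active[~any_hit]
        done_trials += b

    return pd.DataFrame({"decision": decision, "stop_trial": stop})


def learner_proportion_curve(
    outcomes_by_animal: Mapping[str, Sequence[bool]] | Iterable[LearningOutcome],
    config: SPRTConfig = SPRTConfig(),
) -> pd.DataFrame:
    """Fraction of the group classified LEARNER by each trial number.

    The curve is the empirical cumulative distribution of trials to
    criterion over the group: a monotone nondecreasing step function in
    [0, 1] evaluated at trials 0..max_trials.  Animals never decided
    LEARNER contribute nothing (curve need not reach 1).
    """
    if isinstance(outcomes_by_animal, Mapping):
        results = [
            sprt_track(seq, config, animal_tag=tag)
            for tag, seq in outcomes_by_animal.items()
        ]
    else:
        results = list(outcomes_by_animal)
    n = len(results)
    if n == 0:
        raise ValueError("need at least one animal")

    trials = np.arange(config.max_trials + 1)
    frac = np.zeros(config.max_trials + 1)
    for r in results:
        if r.decision == LEARNER and r.trials_to_criterion is not None:
            frac[r.trials_to_criterion :] += 1.0
    frac /= n
    return pd.DataFrame({"trial": trials, "fraction_learner": frac})


def cumulative_correct_curve(outcomes: Sequence[bool]) -> np.ndarray:
    """Cumulative number of correct visits versus trial number.

    The slope of this curve against the trial axis visualizes learning
    velocity; the chance line has slope p0.
    """
    return np.cumsum(np.asarray(outcomes, dtype=int))
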