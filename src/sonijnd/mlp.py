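"""The adaptive maximum-likelihood track.

A *track* measures one just-noticeable difference: a fixed standard, one of
the five directions, and a grid of candidate psychometric functions
(*hypotheses*) that share slope and chance level but differ in midpoint.
After every 2AFC trial the log-likelihood of each hypothesis is updated

    L(H_j) = sum_i [ C_i * log H_j(x_i) + W_i * log(1 - H_j(x_i)) ]

with C_i = 1 for a correct answer and W_i = 1 for a wrong one.  The next
stimulus is placed at the sweet point of the currently most likely
hypothesis — the inverse of its psychometric function at the target
proportion correct (80.9% in 2AFC, which minimizes threshold-estimate
variance) — snapped to the stimulus grid.  After the final trial the JND is
read off the winning hypothesis, either as its sweet point (default) or as
its midpoint alpha.

Log-likelihoods are accumulated in natural log; the argmax is invariant to
the base.  Base-10 values are available for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .data_space import Direction, StandardPoint, variable_coordinate
from .psychometrics import PsychometricHypothesis, inverse_psi, psi

#: A responder answers one 2AFC trial: given the stimulus offset (the
#: magnitude by which the variable differs from the standard) it returns
#: True for a correct judgment.  Virtual observers and interactive prompts
#: both satisfy this signature.
Responder = Callable[[float], bool]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class MLPConventions:
    """Standardized parameters of the adaptive procedure.

    Defaults are the proposed conventions for comparable sonification
    evaluations: 2AFC chance level gamma = 0.5, shared slope beta = 100,
    100 hypothesis midpoints spread over alpha in [0.001, 0.1], sweet point
    at 80.9% correct, 12 trials per track, stimulus grid step 0.001, and a
    clearly audible initial offset of 0.07.
    """

    gamma: float = 0.5
    beta: float = 100.0
    alpha_min: float = 0.001
    alpha_max: float = 0.1
    n_hypotheses: int = 100
    p_target: float = 0.809
    n_trials: int = 12
    initial_delta: float = 0.07
    grid_step: float = 0.001

    def __post_init__(self) -> None:
        if self.n_hypotheses < 2:
            raise ValueError(f"need at least 2 hypotheses, got {self.n_hypotheses}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0 < self.alpha_min < self.alpha_max):
            raise ValueError(
                f"need 0 < alpha_min < alpha_max, got {self.alpha_min}, {self.alpha_max}"
            )
        if not (self.gamma < self.p_target < 1.0):
            raise ValueError(
                f"p_target must lie in (gamma, 1) = ({self.gamma}, 1), got {self.p_target}"
            )
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be positive, got {self.n_trials}")
        if self.grid_step <= 0:
            raise ValueError(f"grid_step must be positive, got {self.grid_step}")

    def alpha_grid(self) -> np.ndarray:
        """Hypothesis midpoints, linearly spaced over [alpha_min, alpha_max]."""
        return np.linspace(self.alpha_min, self.alpha_max, self.n_hypotheses)


def init_grid(conventions: MLPConventions) -> list[PsychometricHypothesis]:
    """The hypothesis grid: shared beta and gamma, linearly spaced midpoints."""
    return [
        PsychometricHypothesis(alpha=float(a), beta=conventions.beta, gamma=conventions.gamma)
        for a in conventions.alpha_grid()
    ]


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial: its index, stimulus offset, order, and outcome."""

    n: int                    # 1-based trial index
    delta: float              # stimulus offset, a grid value
    presentation_order: Literal["standard_first", "variable_first"]
    correct: bool


@dataclass
class TrackState:
    """Running state of one adaptive track."""

    standard: StandardPoint
    direction: Direction
    conventions: MLPConventions = field(default_factory=MLPConventions)
    history: list[TrialRecord] = field(default_factory=list)
    log_likelihoods: np.ndarray | None = None  # natural log, one per hypothesis
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.log_likelihoods is None:
            self.log_likelihoods = np.zeros(self.conventions.n_hypotheses)
        self.log_likelihoods = np.asarray(self.log_likelihoods, dtype=float)
        if len(self.log_likelihoods) != self.conventions.n_hypotheses:
            raise ValueError(
                f"log_likelihoods length {len(self.log_likelihoods)} does not match "
                f"n_hypotheses={self.conventions.n_hypotheses}"
            )

    @property
    def complete(self) -> bool:
        return len(self.history) >= self.conventions.n_trials

    def log10_likelihoods(self) -> np.ndarray:
        """The accumulators in base 10, for reporting."""
        return self.log_likelihoods / LN10


def _psi_grid(delta: float, conventions: MLPConventions) -> np.ndarray:
    """psi(delta) under every hypothesis of the grid, vectorized."""
    alphas = conventions.alpha_grid()
    z = conventions.beta * (delta - alphas)
    f = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return conventions.gamma + (1.0 - conventions.gamma) * f


def snap_to_grid(value: float, conventions: MLPConventions) -> float:
    """Round *value* to the nearest stimulus-grid point (half away from zero),
    clamped to [alpha_min, alpha_max]."""
    c = conventions
    k = math.floor(value / c.grid_step + 0.5)
    v = min(max(k * c.grid_step, c.alpha_min), c.alpha_max)
    # return the exact grid element so equality checks against the grid hold
    grid = c.alpha_grid()
    idx = int(np.argmin(np.abs(grid - v)))
    return float(grid[idx])


def update_likelihoods(state: TrackState, trial: TrialRecord) -> TrackState:
    """Fold one trial into the per-hypothesis log-likelihood accumulators.

    Adds log psi(delta) for a correct answer and log(1 - psi(delta)) for a
    wrong one, to every hypothesis.  Mutates and returns *state*.
    """
    p = _psi_grid(trial.delta, state.conventions)
    if trial.correct:
        state.log_likelihoods += np.log(p)
    else:
        state.log_likelihoods += np.log1p(-p)
    state.history.append(trial)
    return state


def best_hypothesis(state: TrackState) -> PsychometricHypothesis:
    """The hypothesis with the highest likelihood; ties go to the smallest alpha."""
    idx = int(np.argmax(state.log_likelihoods))  # first maximum = smallest alpha
    c = state.conventions
    return PsychometricHypothesis(
        alpha=float(c.alpha_grid()[idx]), beta=c.beta, gamma=c.gamma
    )


def sweet_point(state: TrackState, clamp: bool = True) -> float:
    """Inverse of the best hypothesis's psychometric function at p_target."""
    c = state.conventions
    x = inverse_psi(c.p_target, best_hypothesis(state))
    if clamp:
        x = min(max(x, c.alpha_min), c.alpha_max)
    return x


def select_next_stimulus(state: TrackState) -> float:
    """The stimulus offset for the next trial.

    The first trial uses the clearly audible initial offset; afterwards the
    sweet point of the current best hypothesis, snapped to the stimulus grid
    and clamped to its range.
    """
    c = state.conventions
    if not state.history:
        return snap_to_grid(c.initial_delta, c)
    raw = inverse_psi(c.p_target, best_hypothesis(state))
    return snap_to_grid(raw, c)


def jnd_estimate(
    state: TrackState, mode: Literal["sweet_point", "midpoint"] = "sweet_point"
) -> float:
    """Read the JND off a completed track.

    ``sweet_point`` (default): the inverse of the winning hypothesis at
    p_target, clamped to the grid range.  ``midpoint``: the winning
    hypothesis's alpha itself, whose smallest reportable value is alpha_min.
    """
    if not state.complete:
        raise RuntimeError(
            f"track has {len(state.history)} of {state.conventions.n_trials} trials; "
            "JND is read only from a completed track"
        )
    if mode == "sweet_point":
        return sweet_point(state)
    if mode == "midpoint":
        return best_hypothesis(state).alpha
    raise ValueError(f"unknown JND readout mode {mode!r}")


class TrackAborted(RuntimeError):
    """A responder failed mid-track; the partial state is preserved."""

    def __init__(self, state: TrackState, cause: BaseException):
        super().__init__(f"track aborted after {len(state.history)} trials: {cause}")
        self.state = state
        self.cause = cause


def run_track(
    standard: StandardPoint,
    direction: Direction,
    responder: Responder,
    conventions: MLPConventions | None = None,
    seed: int | None = None,
    readout: Literal["sweet_point", "midpoint"] = "sweet_point",
) -> tuple[TrackState, float]:
    """Run one complete adaptive track and return (final state, JND estimate).

    Each trial selects a stimulus, derives the variable coordinate (which
    validates that the offset stays inside the mapping space), randomizes
    the presentation order, asks the responder, and updates the likelihoods.
    """
    c = conventions or MLPConventions()
    rng = np.random.default_rng(seed)
    state = TrackState(standard=standard, direction=direction, conventions=c, seed=seed)
    for n in range(1, c.n_trials + 1):
        delta = select_next_stimulus(state)
        variable_coordinate(standard, direction, delta)  # range check
        order = "standard_first" if rng.integers(2) == 0 else "variable_first"
        try:
            correct = bool(responder(delta))
        except Exception as exc:
            raise TrackAborted(state, exc) from exc
        update_likelihoods(
            state, TrialRecord(n=n, delta=delta, presentation_order=order, correct=correct)
        )
    return state, jnd_estimate(state, mode=readout)
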