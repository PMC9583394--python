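"""A virtual listener for closed-loop simulation.

The virtual observer answers 2AFC trials stochastically from a known
psychometric function, which makes parameter recovery testable without
human subjects: a track run against an observer with true midpoint alpha
should estimate a JND near the observer's sweet point.

The response probability at stimulus offset delta is

    gamma + (1 - gamma - lapse) * logistic(delta; true_alpha, true_beta)

so an attentional lapse lowers the ceiling below 1 while the floor stays at
the chance level.  Answers depend only on the offset, not on which interval
held the variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psychometrics import PsychometricHypothesis, inverse_psi, logistic


@dataclass
class VirtualObserver:
    """A simulated 2AFC listener with a known logistic psychometric function."""

    true_alpha: float = 0.03
    true_beta: float = 100.0
    gamma: float = 0.5
    lapse: float = 0.0
    seed: int | None = None
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.true_beta <= 0:
            raise ValueError(f"true_beta must be positive, got {self.true_beta}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        if self.gamma + self.lapse >= 1.0:
            raise ValueError("gamma + lapse must stay below 1")
        self._rng = np.random.default_rng(self.seed)

    def p_correct(self, delta: float) -> float:
        """The probability of a correct answer at stimulus offset *delta*."""
        return self.gamma + (1.0 - self.gamma - self.lapse) * logistic(
            delta, self.true_alpha, self.true_beta
        )

    def respond(self, delta: float) -> bool:
        """Answer one trial; the draw stream is reproducible under the seed."""
        if delta < 0:
            raise ValueError(f"stimulus offset must be non-negative, got {delta}")
        return bool(self._rng.random() < self.p_correct(delta))

    __call__ = respond

    def true_sweet_point(self, p_target: float = 0.809) -> float:
        """The sweet point of the observer's (lapse-free) psychometric function."""
        hyp = PsychometricHypothesis(self.true_alpha, self.true_beta, self.gamma)
        return inverse_psi(p_target, hyp)

    @classmethod
    def from_dict(cls, params: dict, seed: int | None = None) -> "VirtualObserver":
        """Build an observer from a configuration mapping.

        Recognized keys: true_alpha, true_beta, gamma, lapse, seed (a seed
        passed explicitly overrides one in the mapping).
        """
        allowed = {"true_alpha", "true_beta", "gamma", "lapse", "seed"}
        unknown = set(params) - allowed
        if unknown:
            raise ValueError(f"unknown observer parameters: {sorted(unknown)}")
        kwargs = dict(params)
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)
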