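"""Logistic psychometric functions for 2AFC discrimination.

The probability of a correct answer as a function of stimulus magnitude x is
modeled as

    psi(x; alpha, beta, gamma) = gamma + (1 - gamma) * f(x; alpha, beta)

where f is the logistic sigmoid 1 / (1 + exp(beta * (alpha - x))), alpha its
midpoint and beta its slope.  gamma is the chance level — 0.5 in a
two-alternative forced choice, where a deaf guess is still right half the
time — and forms the floor of psi; the ceiling is 1.  The inverse of psi at
a target proportion correct (the *sweet point*) drives adaptive stimulus
placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def logistic(x, alpha: float, beta: float):
    """The logistic sigmoid 1 / (1 + exp(beta * (alpha - x))).

    Accepts scalar or array ``x``; beta must be positive.  Saturates cleanly
    at 0 and 1 for extreme arguments.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    z = np.multiply(beta, np.subtract(x, alpha, dtype=float))
    # equivalent to scipy.special.expit, but keeps this module dependency-light
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                   np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class PsychometricHypothesis:
    """One candidate psychometric function: midpoint, slope, chance level."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")


def psi(x, hyp: PsychometricHypothesis):
    """Proportion correct at stimulus magnitude ``x`` under hypothesis *hyp*.

    gamma + (1 - gamma) * logistic(x); bounded in [gamma, 1).
    """
    return hyp.gamma + (1.0 - hyp.gamma) * logistic(x, hyp.alpha, hyp.beta)


def inverse_psi(p_target: float, hyp: PsychometricHypothesis) -> float:
    """Stimulus magnitude at which *hyp* predicts proportion correct p_target.

    Closed form: alpha - (1/beta) * ln((1 - gamma) / (p_target - gamma) - 1).
    Defined only on the open interval (gamma, 1).
    """
    if not (hyp.gamma < p_target < 1.0):
        raise ValueError(
            f"p_target={p_target} outside the open interval ({hyp.gamma}, 1) "
            "where the psychometric function is invertible"
        )
    return hyp.alpha - math.log((1.0 - hyp.gamma) / (p_target - hyp.gamma) - 1.0) / hyp.beta
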