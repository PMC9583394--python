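"""Perceptual-resolution, hysteresis, and interference scores.

Each quadrant of the mapping space yields five JNDs: toward and away from
the origin along x and y, and along the positive diagonal.  From these:

* resolution — the two away-from-origin JNDs; 1/JND is the number of
  distinguishable steps of that dimension (1000 at the grid floor of 0.001,
  10 at the ceiling of 0.1);
* hysteresis — h = 0.5 * log10(JND(-d) / JND(+d)) per dimension, in
  [-1, 1]; positive h means larger steps are needed to be audible when
  approaching the origin;
* interference — with JND_min/JND_max the smaller/larger of the two
  away-from-origin JNDs, T = 0.5 * log10(JND_max / JND_min) in [0, 1] and
  delta = 0.5 * log10(JND_diag / JND_min) in [-1, 1]; the qualitative class
  Q is positive (delta < 0), none (delta = 0), usual (0 < delta <= T), or
  negative (delta > T).

Log-ratios are computed as differences of log10 so the extreme grid values
give exactly ±1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_space import Quadrant


def _check_positive(**jnds: float) -> None:
    for name, v in jnds.items():
        if not (v > 0) or math.isnan(v):
            raise ValueError(f"JND {name}={v} must be strictly positive")


@dataclass(frozen=True)
class QuadrantJNDs:
    """The five JNDs measured at one standard."""

    quadrant: Quadrant
    plus_x: float
    minus_x: float
    plus_y: float
    minus_y: float
    diagonal: float

    def __post_init__(self) -> None:
        _check_positive(
            plus_x=self.plus_x, minus_x=self.minus_x,
            plus_y=self.plus_y, minus_y=self.minus_y, diagonal=self.diagonal,
        )


@dataclass(frozen=True)
class ResolutionScores:
    """Away-from-origin JNDs of one quadrant and their step counts (1/JND)."""

    jnd_plus_x: float
    jnd_plus_y: float
    steps_x: float
    steps_y: float


def steps(jnd: float) -> float:
    """Number of distinguishable steps along a unit dimension: 1/JND."""
    _check_positive(jnd=jnd)
    return 1.0 / jnd


def resolution(q: QuadrantJNDs) -> ResolutionScores:
    """Perceptual resolution of both dimensions in one quadrant."""
    return ResolutionScores(
        jnd_plus_x=q.plus_x,
        jnd_plus_y=q.plus_y,
        steps_x=steps(q.plus_x),
        steps_y=steps(q.plus_y),
    )


def _half_log10_ratio(num: float, den: float) -> float:
    return 0.5 * (math.log10(num) - math.log10(den))


def hysteresis(jnd_minus: float, jnd_plus: float) -> float:
    """h = 0.5 * log10(JND(-d) / JND(+d)).

    Zero when both JNDs agree; +1/-1 at the extreme grid ratio 0.1/0.001.
    Positive values mean the resolution toward the origin is lower than
    away from it.
    """
    _check_positive(jnd_minus=jnd_minus, jnd_plus=jnd_plus)
    return _half_log10_ratio(jnd_minus, jnd_plus)


class InterferenceClass(str, Enum):
    POSITIVE = "positive interference"
    NONE = "no interference"
    USUAL = "usual interference"
    NEGATIVE = "negative interference"


@dataclass(frozen=True)
class InterferenceScores:
    T: float
    delta: float
    Q: InterferenceClass
    jnd_min: float
    jnd_max: float


def interference(
    jnd_plus_x: float, jnd_plus_y: float, jnd_diagonal: float, epsilon: float = 0.0
) -> InterferenceScores:
    """Perceptual interference between the two dimensions.

    *epsilon* widens the measure-zero "no interference" band (|delta| <=
    epsilon) for floating-point or measurement tolerance; the default 0
    applies the literal four-case rule.
    """
    _check_positive(
        jnd_plus_x=jnd_plus_x, jnd_plus_y=jnd_plus_y, jnd_diagonal=jnd_diagonal
    )
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    jnd_min = min(jnd_plus_x, jnd_plus_y)
    jnd_max = max(jnd_plus_x, jnd_plus_y)
    T = _half_log10_ratio(jnd_max, jnd_min)
    delta = _half_log10_ratio(jnd_diagonal, jnd_min)
    if delta < -epsilon:
        Q = InterferenceClass.POSITIVE
    elif abs(delta) <= epsilon or delta == 0.0:
        Q = InterferenceClass.NONE
    elif delta <= T:
        Q = InterferenceClass.USUAL
    else:
        Q = InterferenceClass.NEGATIVE
    return InterferenceScores(T=T, delta=delta, Q=Q, jnd_min=jnd_min, jnd_max=jnd_max)


def interference_for(q: QuadrantJNDs, epsilon: float = 0.0) -> InterferenceScores:
    return interference(q.plus_x, q.plus_y, q.diagonal, epsilon=epsilon)


@dataclass(frozen=True)
class LinearityResult:
    """Spread of the away-from-origin JND across the ticks of one axis polarity."""

    axis: str
    polarity: int
    jnds: tuple[float, ...]
    ratio: float
    tolerance: float
    passed: bool


def linearity_check(
    jnds: Sequence[float], tolerance: float = 1.5, axis: str = "x", polarity: int = 1
) -> LinearityResult:
    """Design-stage linearity verdict for one axis polarity.

    A perceptually linear mapping has equal JNDs at every tick mark; the
    check passes iff max(JND)/min(JND) <= tolerance.  Needs at least two
    ticks.
    """
    if len(jnds) < 2:
        raise ValueError(f"linearity needs JNDs from at least 2 ticks, got {len(jnds)}")
    _check_positive(**{f"tick_{i}": v for i, v in enumerate(jnds)})
    if tolerance < 1:
        raise ValueError(f"tolerance must be >= 1, got {tolerance}")
    ratio = max(jnds) / min(jnds)
    return LinearityResult(
        axis=axis, polarity=polarity, jnds=tuple(float(v) for v in jnds),
        ratio=ratio, tolerance=tolerance, passed=ratio <= tolerance,
    )


_QUADRANT_ORDER = (Quadrant.I, Quadrant.II, Quadrant.III, Quadrant.IV)


def _frame_to_markdown(frame: pd.DataFrame) -> str:
    def fmt(v) -> str:
        if isinstance(v, float):
            return f"{v:.5g}"
        return str(v)

    header = [""] + [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    for idx, row in frame.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [fmt(v) for v in row]) + " |")
    return "\n".join(lines)


@dataclass
class ScoreReport:
    """The three standardized report tables plus run metadata.

    ``resolution`` and ``hysteresis`` have rows x/y and one column per
    measured quadrant; ``interference`` has one row per quadrant and
    columns delta/Q (T, JND_min, JND_max carried alongside).
    """

    resolution: pd.DataFrame
    hysteresis: pd.DataFrame
    interference: pd.DataFrame
    readout_mode: str = "sweet_point"
    epsilon: float = 0.0
    metadata: dict = field(default_factory=dict)
    missing_quadrants: tuple[str, ...] = ()

    def to_markdown(self) -> str:
        parts = [
            "## Perceptual resolution (JND per dimension and quadrant)",
            _frame_to_markdown(self.resolution),
            "",
            "## Hysteresis h per dimension and quadrant",
            _frame_to_markdown(self.hysteresis),
            "",
            "## Perceptual interference per quadrant",
            _frame_to_markdown(self.interference),
            "",
            f"readout mode: {self.readout_mode}; epsilon: {self.epsilon}",
        ]
        if self.missing_quadrants:
            parts.append(f"missing quadrants: {', '.join(self.missing_quadrants)}")
        return "\n".join(parts) + "\n"

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in (
            ("resolution", self.resolution),
            ("hysteresis", self.hysteresis),
            ("interference", self.interference),
        ):
            p = out_dir / f"{name}.csv"
            frame.to_csv(p)
            paths.append(p)
        return paths

    def to_dict(self) -> dict:
        def split(frame: pd.DataFrame) -> dict:
            # full-precision split layout (DataFrame.to_json truncates floats)
            return {
                "index": list(frame.index),
                "columns": list(frame.columns),
                "data": [list(row) for _, row in frame.iterrows()],
            }

        return {
            "resolution": split(self.resolution),
            "hysteresis": split(self.hysteresis),
            "interference": split(self.interference),
            "readout_mode": self.readout_mode,
            "epsilon": self.epsilon,
            "metadata": self.metadata,
            "missing_quadrants": list(self.missing_quadrants),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreReport":
        def frame(key: str) -> pd.DataFrame:
            part = d[key]
            return pd.DataFrame(
                part["data"], index=part["index"], columns=part["columns"]
            )
        return cls(
            resolution=frame("resolution"),
            hysteresis=frame("hysteresis"),
            interference=frame("interference"),
            readout_mode=d["readout_mode"],
            epsilon=d["epsilon"],
            metadata=d.get("metadata", {}),
            missing_quadrants=tuple(d.get("missing_quadrants", ())),
        )


def build_report(
    quadrant_jnds: Iterable[QuadrantJNDs],
    epsilon: float = 0.0,
    readout_mode: str = "sweet_point",
    expected_quadrants: Sequence[Quadrant] | None = None,
    metadata: Mapping | None = None,
) -> ScoreReport:
    """Assemble the three report tables from per-quadrant JND sets.

    Quadrants expected (per the configuration mask) but absent from
    *quadrant_jnds* are listed in ``missing_quadrants`` and excluded from
    the tables — never imputed.
    """
    by_q = {q.quadrant: q for q in quadrant_jnds}
    expected = tuple(expected_quadrants) if expected_quadrants is not None else tuple(by_q)
    present = [q for q in _QUADRANT_ORDER if q in by_q and q in expected]
    missing = tuple(q.name for q in expected if q not in by_q)
    cols = [q.name for q in present]

    res = pd.DataFrame(
        {q.name: [by_q[q].plus_x, by_q[q].plus_y] for q in present}, index=["x", "y"]
    ).reindex(columns=cols)
    hyst = pd.DataFrame(
        {
            q.name: [
                hysteresis(by_q[q].minus_x, by_q[q].plus_x),
                hysteresis(by_q[q].minus_y, by_q[q].plus_y),
            ]
            for q in present
        },
        index=["x", "y"],
    ).reindex(columns=cols)
    rows = {}
    for q in present:
        s = interference_for(by_q[q], epsilon=epsilon)
        rows[f"S_{q.name}"] = [s.delta, s.Q.value, s.T, s.jnd_min, s.jnd_max]
    interf = pd.DataFrame.from_dict(
        rows, orient="index", columns=["delta", "Q", "T", "JND_min", "JND_max"]
    )
    return ScoreReport(
        resolution=res,
        hysteresis=hyst,
        interference=interf,
        readout_mode=readout_mode,
        epsilon=epsilon,
        metadata=dict(metadata or {}),
        missing_quadrants=missing,
    )
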