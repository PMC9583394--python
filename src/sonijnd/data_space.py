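"""The normalized two-dimensional mapping space.

A two-dimensional sonification is evaluated on an abstract data space with
two Cartesian dimensions, each normalized to [-1, 1].  The space splits into
four quadrants (roman I-IV); in the center of each quadrant sits a *standard*
at (±0.5, ±0.5), the fixed reference coordinate of every 2AFC trial in that
quadrant.  Comparison stimuli (*variables*) are offset from the standard
along one of five directions: away from / toward the coordinate origin in x,
the same in y, or along the positive diagonal (both absolute values grow
equally).

Raw application data (a temperature, a concentration, ...) enters the space
through a piecewise linear transfer function anchored at a target value and
hard-clamped at configurable lower/upper bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence


class Quadrant(Enum):
    """Quadrants of the mapping space, with their component signs."""

    I = (1, 1)
    II = (-1, 1)
    III = (-1, -1)
    IV = (1, -1)

    @property
    def sign_x(self) -> int:
        return self.value[0]

    @property
    def sign_y(self) -> int:
        return self.value[1]

    @classmethod
    def from_name(cls, name: str) -> "Quadrant":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown quadrant {name!r}; expected one of I, II, III, IV")


class Direction(Enum):
    """The five tested motions from a standard.

    ``plus`` means increasing the *absolute* value of the component (moving
    away from the coordinate origin), ``minus`` decreasing it.  The diagonal
    increases both absolute values equally.
    """

    PLUS_X = "plus_x"
    MINUS_X = "minus_x"
    PLUS_Y = "plus_y"
    MINUS_Y = "minus_y"
    DIAGONAL = "diagonal"

    @classmethod
    def from_name(cls, name: str) -> "Direction":
        try:
            return cls(name.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown direction {name!r}; expected one of "
                + ", ".join(d.value for d in cls)
            )


ALL_DIRECTIONS: tuple[Direction, ...] = tuple(Direction)


@dataclass(frozen=True)
class MappingCoordinate:
    """A point (x, y) in the normalized [-1, 1]^2 mapping space."""

    x: float
    y: float

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y)):
            if not (-1.0 <= v <= 1.0) or math.isnan(v):
                raise ValueError(f"coordinate {name}={v} outside the normalized range [-1, 1]")

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class StandardPoint:
    """A reference coordinate against which variables are judged.

    In the full evaluation experiment the standard is the center of a
    quadrant, (±0.5, ±0.5).  In the light (design-stage) experiment the
    standards are tick marks on one of the axes; ``axis``/``polarity`` then
    record which axis polarity the tick samples.
    """

    coordinate: MappingCoordinate
    quadrant: Quadrant | None = None
    axis: str | None = None        # "x" or "y" (light mode)
    polarity: int | None = None    # +1 or -1 (light mode)

    def __post_init__(self) -> None:
        if self.quadrant is not None:
            q = self.quadrant
            expected = (q.sign_x * 0.5, q.sign_y * 0.5)
            if self.coordinate.as_tuple() != expected:
                raise ValueError(
                    f"standard of quadrant {q.name} must lie at {expected}, "
                    f"got {self.coordinate.as_tuple()}"
                )
        if self.axis is not None and self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if self.polarity is not None and self.polarity not in (1, -1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity!r}")

    @property
    def label(self) -> str:
        if self.quadrant is not None:
            return f"S_{self.quadrant.name}"
        return f"{self.axis}{'+' if self.polarity == 1 else '-'}@{abs(getattr(self.coordinate, self.axis or 'x')):g}"


def quadrant_standard(quadrant: Quadrant) -> StandardPoint:
    """The standard of *quadrant*: (sign_x * 0.5, sign_y * 0.5)."""
    return StandardPoint(
        coordinate=MappingCoordinate(quadrant.sign_x * 0.5, quadrant.sign_y * 0.5),
        quadrant=quadrant,
    )


@dataclass(frozen=True)
class NormalizationSpec:
    """Anchors of the piecewise linear transfer from raw units to [-1, 1].

    ``target`` maps to 0, ``upper_bound`` to +1, ``lower_bound`` to -1;
    values beyond the bounds clamp.
    """

    target: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if not (self.lower_bound < self.target < self.upper_bound):
            raise ValueError(
                "normalization requires lower_bound < target < upper_bound, got "
                f"{self.lower_bound} / {self.target} / {self.upper_bound}"
            )


def normalize_value(raw: float, spec: NormalizationSpec) -> float:
    """Map a raw sensor/application value into [-1, 1].

    Piecewise linear: 0 at the target, +1 at (and above) the upper bound,
    -1 at (and below) the lower bound; linear in between, with separate
    slopes above and below the target.
    """
    if raw >= spec.upper_bound:
        return 1.0
    if raw <= spec.lower_bound:
        return -1.0
    if raw > spec.target:
        return (raw - spec.target) / (spec.upper_bound - spec.target)
    return (raw - spec.target) / (spec.target - spec.lower_bound)


def _shift_abs(component: float, delta: float) -> float:
    """Change |component| by *delta*, keeping its sign (sign(0) treated as +)."""
    sign = -1.0 if component < 0 else 1.0
    return sign * (abs(component) + delta)


def variable_coordinate(
    standard: StandardPoint, direction: Direction, alpha: float
) -> MappingCoordinate:
    """The variable stimulus coordinate at offset *alpha* from *standard*.

    ``plus`` directions move the component away from the origin by alpha,
    ``minus`` toward it; the diagonal moves both components away by alpha.
    Raises ValueError if the result would leave [-1, 1]^2.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    x, y = standard.coordinate.as_tuple()
    if direction is Direction.PLUS_X:
        x = _shift_abs(x, alpha)
    elif direction is Direction.MINUS_X:
        x = _shift_abs(x, -alpha)
    elif direction is Direction.PLUS_Y:
        y = _shift_abs(y, alpha)
    elif direction is Direction.MINUS_Y:
        y = _shift_abs(y, -alpha)
    elif direction is Direction.DIAGONAL:
        x = _shift_abs(x, alpha)
        y = _shift_abs(y, alpha)
    else:  # pragma: no cover - exhaustive over the enum
        raise ValueError(f"unknown direction {direction!r}")
    try:
        return MappingCoordinate(x, y)
    except ValueError:
        raise ValueError(
            f"offset alpha={alpha} along {direction.value} pushes the variable "
            f"to ({x}, {y}), outside [-1, 1]^2"
        ) from None


def light_standards(
    tick_spacing: float = 0.1,
    quadrants: Iterable[Quadrant] | None = None,
    alpha_max: float = 0.1,
) -> list[StandardPoint]:
    """Axis tick-mark standards for the light (design-stage) experiment.

    Returns standards at (k*tick_spacing, 0) and (0, k*tick_spacing) for all
    nonzero integers k with |k*tick_spacing| <= 1 - alpha_max, so that the
    full offset grid up to alpha_max stays inside the space.  Each standard
    is tagged with the axis and polarity it samples.  *quadrants* restricts
    the axis polarities to those touched by the given quadrant mask (e.g.,
    a quadrant-I-only space yields only positive-x and positive-y ticks).
    """
    if not (0 < tick_spacing < 1):
        raise ValueError(f"tick_spacing must lie in (0, 1), got {tick_spacing}")
    mask = tuple(quadrants) if quadrants is not None else tuple(Quadrant)
    if not mask:
        raise ValueError("quadrant mask must not be empty")
    polarities: dict[str, set[int]] = {"x": set(), "y": set()}
    for q in mask:
        polarities["x"].add(q.sign_x)
        polarities["y"].add(q.sign_y)

    k_max = int(math.floor((1.0 - alpha_max) / tick_spacing + 1e-9))
    out: list[StandardPoint] = []
    for axis in ("x", "y"):
        for pol in sorted(polarities[axis], reverse=True):
            for k in range(1, k_max + 1):
                v = round(pol * k * tick_spacing, 12)
                coord = MappingCoordinate(v, 0.0) if axis == "x" else MappingCoordinate(0.0, v)
                out.append(StandardPoint(coordinate=coord, axis=axis, polarity=pol))
    return out


def parse_quadrant_mask(names: Sequence[str]) -> tuple[Quadrant, ...]:
    """Parse a configuration quadrant mask like ``["I", "II"]``."""
    mask = tuple(Quadrant.from_name(n) for n in names)
    if len(set(mask)) != len(mask):
        raise ValueError(f"duplicate quadrants in mask {list(names)!r}")
    return mask
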