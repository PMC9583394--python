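"""Orchestration of a full or light evaluation session.

A *full* session measures five JNDs (±x, ±y, diagonal) at the standard of
every quadrant in the configured mask — 20 adaptive tracks of 12 trials
each under the default conventions.  A *light* session is the design-stage
variant: one away-from-origin track per axis tick mark and polarity, whose
JNDs feed the perceptual-linearity check.

Tracks run in a seeded random order.  In simulated mode every source of
randomness (track order, per-trial presentation order, the virtual
observer's draws) derives from the session seed, so a session replayed
from its configuration reproduces every trial and serializes to
byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import yaml

from .data_space import (
    Direction,
    NormalizationSpec,
    Quadrant,
    StandardPoint,
    light_standards,
    parse_quadrant_mask,
    quadrant_standard,
)
from .mlp import MLPConventions, Responder, jnd_estimate, run_track
from .observer import VirtualObserver
from .scoring import (
    LinearityResult,
    QuadrantJNDs,
    ScoreReport,
    build_report,
    linearity_check,
)

FULL_DIRECTIONS = (
    Direction.PLUS_X,
    Direction.MINUS_X,
    Direction.PLUS_Y,
    Direction.MINUS_Y,
    Direction.DIAGONAL,
)


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to run (or exactly replay) one session."""

    mode: Literal["full", "light"] = "full"
    quadrants: tuple[Quadrant, ...] = tuple(Quadrant)
    conventions: MLPConventions = field(default_factory=MLPConventions)
    tick_spacing: float = 0.1
    readout_mode: Literal["sweet_point", "midpoint"] = "sweet_point"
    epsilon: float = 0.0
    linearity_tolerance: float = 1.5
    observer: dict | None = None   # simulated responder parameters; None => interactive
    normalization: dict[str, NormalizationSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "light"):
            raise ValueError(f"mode must be 'full' or 'light', got {self.mode!r}")
        if not self.quadrants:
            raise ValueError("quadrant mask must not be empty")

    @property
    def simulated(self) -> bool:
        return self.observer is not None

    def track_plan(self) -> list[tuple[StandardPoint, Direction]]:
        """All (standard, direction) tracks of this session, in canonical order."""
        if self.mode == "full":
            return [
                (quadrant_standard(q), d) for q in self.quadrants for d in FULL_DIRECTIONS
            ]
        plan = []
        for std in light_standards(
            self.tick_spacing, self.quadrants, self.conventions.alpha_max
        ):
            d = Direction.PLUS_X if std.axis == "x" else Direction.PLUS_Y
            plan.append((std, d))
        return plan

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "quadrants" in d:
            d["quadrants"] = parse_quadrant_mask(d["quadrants"])
        if "conventions" in d and isinstance(d["conventions"], dict):
            d["conventions"] = MLPConventions(**d["conventions"])
        if "normalization" in d and d["normalization"]:
            d["normalization"] = {
                var: NormalizationSpec(
                    target=s["target"], lower_bound=s["min"], upper_bound=s["max"]
                )
                for var, s in d["normalization"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        c = self.conventions
        return {
            "mode": self.mode,
            "quadrants": [q.name for q in self.quadrants],
            "conventions": {
                "gamma": c.gamma, "beta": c.beta,
                "alpha_min": c.alpha_min, "alpha_max": c.alpha_max,
                "n_hypotheses": c.n_hypotheses, "p_target": c.p_target,
                "n_trials": c.n_trials, "initial_delta": c.initial_delta,
                "grid_step": c.grid_step,
            },
            "tick_spacing": self.tick_spacing,
            "readout_mode": self.readout_mode,
            "epsilon": self.epsilon,
            "linearity_tolerance": self.linearity_tolerance,
            "observer": self.observer,
            "normalization": {
                var: {"target": s.target, "min": s.lower_bound, "max": s.upper_bound}
                for var, s in self.normalization.items()
            },
            "seed": self.seed,
        }


@dataclass
class TrackLog:
    """Serialized outcome of one track."""

    standard_label: str
    quadrant: str | None
    axis: str | None
    polarity: int | None
    coordinate: tuple[float, float]
    direction: str
    seed: int
    trials: list[dict]
    jnd_sweet_point: float
    jnd_midpoint: float

    def to_dict(self) -> dict:
        return {
            "standard": self.standard_label,
            "quadrant": self.quadrant,
            "axis": self.axis,
            "polarity": self.polarity,
            "coordinate": list(self.coordinate),
            "direction": self.direction,
            "seed": self.seed,
            "trials": self.trials,
            "jnd_sweet_point": self.jnd_sweet_point,
            "jnd_midpoint": self.jnd_midpoint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrackLog":
        return cls(
            standard_label=d["standard"],
            quadrant=d.get("quadrant"),
            axis=d.get("axis"),
            polarity=d.get("polarity"),
            coordinate=tuple(d["coordinate"]),
            direction=d["direction"],
            seed=d["seed"],
            trials=d["trials"],
            jnd_sweet_point=d["jnd_sweet_point"],
            jnd_midpoint=d["jnd_midpoint"],
        )


@dataclass
class SessionLog:
    """Configuration snapshot plus the ordered per-track logs of one session."""

    config: dict
    tracks: list[TrackLog]
    timestamp: str | None = None  # set for interactive sessions only

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "timestamp": self.timestamp,
            "tracks": [t.to_dict() for t in self.tracks],
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SessionLog":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            config=d["config"],
            tracks=[TrackLog.from_dict(t) for t in d["tracks"]],
            timestamp=d.get("timestamp"),
        )

    def to_jsonl(self, path: str | Path) -> Path:
        """One JSON line per trial, with its track context."""
        path = Path(path)
        with open(path, "w") as fh:
            for t in self.tracks:
                for trial in t.trials:
                    fh.write(json.dumps({
                        "standard": t.standard_label,
                        "direction": t.direction,
                        **trial,
                    }) + "\n")
        return path

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        rows = []
        for t in self.tracks:
            for trial in t.trials:
                rows.append({"standard": t.standard_label, "direction": t.direction, **trial})
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def _track_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_session(
    config: SessionConfig,
    responder_factory: Callable[[StandardPoint, Direction], Responder] | None = None,
) -> SessionLog:
    """Execute every track of the session in a seeded random order.

    In simulated mode (``config.observer`` set) each track gets a fresh
    virtual observer whose seed derives from the session seed.  For
    interactive use, pass a *responder_factory* that builds the prompt/
    playback responder for each track.
    """
    if responder_factory is None and not config.simulated:
        raise ValueError(
            "config has no observer parameters and no responder_factory was "
            "given; supply one of the two"
        )
    rng = np.random.default_rng(config.seed)
    plan = config.track_plan()
    order = rng.permutation(len(plan))
    tracks: list[TrackLog] = []
    for i in order:
        standard, direction = plan[int(i)]
        track_seed = _track_seed(rng)
        if responder_factory is not None:
            responder = responder_factory(standard, direction)
        else:
            responder = VirtualObserver.from_dict(
                config.observer or {}, seed=_track_seed(rng)
            )
        state, _ = run_track(
            standard, direction, responder,
            conventions=config.conventions, seed=track_seed,
        )
        tracks.append(
            TrackLog(
                standard_label=standard.label,
                quadrant=standard.quadrant.name if standard.quadrant else None,
                axis=standard.axis,
                polarity=standard.polarity,
                coordinate=standard.coordinate.as_tuple(),
                direction=direction.value,
                seed=track_seed,
                trials=[
                    {
                        "n": tr.n,
                        "delta": tr.delta,
                        "order": tr.presentation_order,
                        "correct": tr.correct,
                    }
                    for tr in state.history
                ],
                jnd_sweet_point=jnd_estimate(state, "sweet_point"),
                jnd_midpoint=jnd_estimate(state, "midpoint"),
            )
        )
    timestamp = (
        None if config.simulated else datetime.now(timezone.utc).isoformat()
    )
    return SessionLog(config=config.to_dict(), tracks=tracks, timestamp=timestamp)


def _jnd_from_log(t: TrackLog, readout_mode: str) -> float:
    return t.jnd_sweet_point if readout_mode == "sweet_point" else t.jnd_midpoint


def score_session(
    log: SessionLog,
) -> ScoreReport | dict[str, LinearityResult]:
    """Turn a completed session log into the standardized scores.

    Full mode: the three report tables.  Light mode: one linearity verdict
    per axis polarity.  Raises with an explicit listing of missing tracks
    if the log is incomplete for its mode.
    """
    if not log.tracks:
        raise ValueError("empty session log: no tracks to score")
    config = SessionConfig.from_dict(log.config)
    readout = config.readout_mode

    if config.mode == "full":
        by_key = {(t.quadrant, t.direction): t for t in log.tracks}
        missing = [
            f"{q.name}/{d.value}"
            for q in config.quadrants
            for d in FULL_DIRECTIONS
            if (q.name, d.value) not in by_key
        ]
        if missing:
            raise ValueError(f"incomplete session log; missing tracks: {', '.join(missing)}")
        quadrant_jnds = [
            QuadrantJNDs(
                quadrant=q,
                plus_x=_jnd_from_log(by_key[(q.name, "plus_x")], readout),
                minus_x=_jnd_from_log(by_key[(q.name, "minus_x")], readout),
                plus_y=_jnd_from_log(by_key[(q.name, "plus_y")], readout),
                minus_y=_jnd_from_log(by_key[(q.name, "minus_y")], readout),
                diagonal=_jnd_from_log(by_key[(q.name, "diagonal")], readout),
            )
            for q in config.quadrants
        ]
        return build_report(
            quadrant_jnds,
            epsilon=config.epsilon,
            readout_mode=readout,
            expected_quadrants=config.quadrants,
            metadata={"seed": config.seed, "mode": config.mode},
        )

    # light mode: group away-from-origin JNDs per axis polarity, ordered by tick
    groups: dict[tuple[str, int], list[tuple[float, float]]] = {}
    expected = {
        (s.axis, s.polarity)
        for s in light_standards(config.tick_spacing, config.quadrants,
                                 config.conventions.alpha_max)
    }
    for t in log.tracks:
        if t.axis is None or t.polarity is None:
            raise ValueError(f"track {t.standard_label} is not a light-mode track")
        tick = t.coordinate[0] if t.axis == "x" else t.coordinate[1]
        groups.setdefault((t.axis, t.polarity), []).append(
            (abs(tick), _jnd_from_log(t, readout))
        )
    missing_polarities = sorted(
        f"{axis}{'+' if pol == 1 else '-'}" for axis, pol in expected - set(groups)
    )
    if missing_polarities:
        raise ValueError(
            f"incomplete light session; missing axis polarities: {', '.join(missing_polarities)}"
        )
    results: dict[str, LinearityResult] = {}
    for (axis, pol), pairs in sorted(groups.items()):
        pairs.sort()
        results[f"{axis}{'+' if pol == 1 else '-'}"] = linearity_check(
            [j for _, j in pairs],
            tolerance=config.linearity_tolerance,
            axis=axis,
            polarity=pol,
        )
    return results
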