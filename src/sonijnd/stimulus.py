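"""Stimulus grids and audio rendering for 2AFC trials.

The experiment presents *pairs* of sounds: the standard and a variable
offset from it by alpha.  Discrete test sounds must not leak cues that the
continuous sonification would not produce, so every rendered sound is
peak-normalized together with its partner, given a short raised-cosine
onset ramp against clicks, and a long gradual offset fade so listeners
cannot compare the two sounds by the phase of a modulator at the note end.
Sounds last 3-5 s (default 4 s) and are separated by a silent pause of
equal length.

The sonifier under test is supplied by the caller as a deterministic
function from a mapping coordinate to a sample buffer; any modulators must
start at a fixed phase so standard and variable begin at the same point of
the modulation cycle.  A simple reference sonifier (log-frequency carrier
in x, amplitude-modulation rate in y) is included for tests and demos.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Protocol

import numpy as np

from .data_space import Direction, MappingCoordinate, StandardPoint, variable_coordinate
from .mlp import MLPConventions


@dataclass(frozen=True)
class StimulusSpec:
    """Timing and format of one rendered test sound.

    The pause between the two sounds of a pair equals the sound duration.
    Ramps: a short onset (default 50 ms) and a long, gradual offset
    (default 500 ms); both raised-cosine, both shorter than half the sound.
    """

    duration: float = 4.0
    pause: float | None = None
    onset_ramp: float = 0.05
    offset_ramp: float = 0.5
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if not (3.0 <= self.duration <= 5.0):
            raise ValueError(f"duration must lie in [3, 5] s, got {self.duration}")
        if self.pause is not None and self.pause != self.duration:
            raise ValueError(
                f"the pause must equal the sound duration ({self.duration} s), got {self.pause}"
            )
        for name, r in (("onset_ramp", self.onset_ramp), ("offset_ramp", self.offset_ramp)):
            if not (0 < r < self.duration / 2):
                raise ValueError(f"{name}={r} must lie in (0, duration/2)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def pause_duration(self) -> float:
        return self.duration if self.pause is None else self.pause

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


class Sonifier(Protocol):
    """The sonification under test: coordinate -> mono sample buffer.

    Must be deterministic (identical inputs yield identical buffers) and
    start any modulators at a fixed phase.
    """

    def __call__(
        self, coordinate: MappingCoordinate, duration: float, sample_rate: int
    ) -> np.ndarray: ...


def reference_sonifier(
    coordinate: MappingCoordinate, duration: float, sample_rate: int
) -> np.ndarray:
    """A minimal two-dimensional sonifier for tests and demonstrations.

    x maps linearly to the logarithm of the carrier frequency (440 Hz at the
    origin, one octave per unit), y to the rate of a sinusoidal amplitude
    modulation (4 Hz at the origin, ±3 Hz per unit).  Carrier and modulator
    both start at phase zero, so paired sounds begin at the same point of
    the modulation cycle.
    """
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    f_carrier = 440.0 * 2.0 ** coordinate.x
    am_rate = 4.0 + 3.0 * coordinate.y
    depth = 0.8
    am = 1.0 - depth * 0.5 * (1.0 - np.cos(2.0 * np.pi * am_rate * t))
    return np.sin(2.0 * np.pi * f_carrier * t) * am


def variable_grid(
    standard: StandardPoint,
    direction: Direction,
    conventions: MLPConventions | None = None,
) -> list[MappingCoordinate]:
    """All pre-renderable variable coordinates of one track.

    One coordinate per hypothesis-grid offset (100 under the default
    conventions, alpha = 0.001 ... 0.1), ordered by alpha.  Raises if any
    offset would leave the mapping space, naming the offending alpha.
    """
    c = conventions or MLPConventions()
    return [
        variable_coordinate(standard, direction, float(alpha)) for alpha in c.alpha_grid()
    ]


def _raised_cosine_ramps(n: int, spec: StimulusSpec) -> np.ndarray:
    env = np.ones(n)
    n_on = int(round(spec.onset_ramp * spec.sample_rate))
    n_off = int(round(spec.offset_ramp * spec.sample_rate))
    if n_on > 0:
        env[:n_on] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_on) / n_on))
    if n_off > 0:
        env[n - n_off:] = 0.5 * (1.0 + np.cos(np.pi * (np.arange(n_off) + 1) / n_off))
    return env


@dataclass(frozen=True)
class RenderedPair:
    """Two processed buffers of one 2AFC trial plus their presentation order."""

    first: np.ndarray
    second: np.ndarray
    order: Literal["standard_first", "variable_first"]
    spec: StimulusSpec

    def sequence(self) -> np.ndarray:
        """first sound, silent pause of equal length, second sound."""
        pause = np.zeros(int(round(self.spec.pause_duration * self.spec.sample_rate)))
        return np.concatenate([self.first, pause, self.second])


def render_pair(
    standard: MappingCoordinate,
    variable: MappingCoordinate,
    sonifier: Sonifier,
    spec: StimulusSpec | None = None,
    order: Literal["standard_first", "variable_first"] = "standard_first",
) -> RenderedPair:
    """Render a standard/variable pair with shared normalization and ramps.

    Both buffers are scaled by one common factor (0.9 over the joint peak),
    then onset- and offset-ramped, so relative level differences between the
    two sounds survive but neither clips and neither clicks.
    """
    s = spec or StimulusSpec()
    bufs = []
    for coord in (standard, variable):
        buf = np.asarray(sonifier(coord, s.duration, s.sample_rate), dtype=float)
        if buf.ndim != 1 or len(buf) != s.n_samples:
            raise ValueError(
                f"sonifier violated its contract: expected {s.n_samples} mono samples "
                f"at {s.sample_rate} Hz, got shape {buf.shape}"
            )
        bufs.append(buf)
    peak = max(float(np.max(np.abs(b))) for b in bufs)
    scale = 0.9 / peak if peak > 0 else 1.0
    env = _raised_cosine_ramps(s.n_samples, s)
    std_buf, var_buf = (b * scale * env for b in bufs)
    if order == "standard_first":
        first, second = std_buf, var_buf
    elif order == "variable_first":
        first, second = var_buf, std_buf
    else:
        raise ValueError(f"unknown presentation order {order!r}")
    return RenderedPair(first=first, second=second, order=order, spec=s)


@dataclass(frozen=True)
class DemoStimulus:
    label: str
    coordinate: MappingCoordinate
    offset: float
    samples: np.ndarray


def demo_stimuli(
    sonifier: Sonifier,
    spec: StimulusSpec | None = None,
    reference: MappingCoordinate = MappingCoordinate(0.6, 0.6),
    personal_jnd: float = 0.01,
) -> list[DemoStimulus]:
    """The pre-experiment demonstration set.

    Four labeled sounds anchored at the reference coordinate: the reference
    itself, a probably inaudible difference (offset 0.001), a probably
    clearly audible difference (offset 0.1), and a difference at the
    conductor's personal JND — all offsets along +x, configurable.
    """
    s = spec or StimulusSpec()
    entries = [
        ("reference", 0.0),
        ("probably inaudible difference", 0.001),
        ("probably clearly audible difference", 0.1),
        ("personal JND", personal_jnd),
    ]
    env = _raised_cosine_ramps(s.n_samples, s)
    out = []
    for label, offset in entries:
        coord = MappingCoordinate(reference.x + offset, reference.y)
        buf = np.asarray(sonifier(coord, s.duration, s.sample_rate), dtype=float)
        peak = float(np.max(np.abs(buf)))
        out.append(
            DemoStimulus(label, coord, offset, buf * (0.9 / peak if peak > 0 else 1.0) * env)
        )
    return out


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int = 44100) -> Path:
    """Write a mono float buffer in [-1, 1] as uncompressed 16-bit PCM WAV."""
    path = Path(path)
    pcm = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    data = (pcm * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(sample_rate)
        w.writeframes(data.tobytes())
    return path


def stimulus_filename(standard: StandardPoint, direction: Direction, alpha: float) -> str:
    """Canonical WAV name ``<quadrant>_<direction>_<alpha>.wav`` for a grid file."""
    tag = standard.quadrant.name if standard.quadrant is not None else standard.label
    return f"{tag}_{direction.value}_{alpha:.3f}.wav"


def render_grid_to_wavs(
    standard: StandardPoint,
    direction: Direction,
    sonifier: Sonifier,
    out_dir: str | Path,
    conventions: MLPConventions | None = None,
    spec: StimulusSpec | None = None,
) -> list[Path]:
    """Pre-render the full variable grid of one track to WAV files."""
    c = conventions or MLPConventions()
    s = spec or StimulusSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    env = _raised_cosine_ramps(s.n_samples, s)
    paths = []
    for alpha, coord in zip(c.alpha_grid(), variable_grid(standard, direction, c)):
        buf = np.asarray(sonifier(coord, s.duration, s.sample_rate), dtype=float)
        peak = float(np.max(np.abs(buf)))
        processed = buf * (0.9 / peak if peak > 0 else 1.0) * env
        paths.append(
            write_wav(out_dir / stimulus_filename(standard, direction, float(alpha)),
                      processed, s.sample_rate)
        )
    return paths
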