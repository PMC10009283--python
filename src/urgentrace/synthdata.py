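"""Synthetic session generation and saccade-onset detection.

Emulates the structure of a monkey psychophysics dataset for the urgent
color-matching task with varying salience: randomly interleaved trial
types, gaps on a 25-250 ms grid, ~100-trial target-color blocks, choice
stimuli at mixed orientations and eccentricities, and a 450 ms response
deadline.  Reaction times and outcomes come from the race-to-threshold
simulator, so a generated dataset is internally consistent with the
model that produced it.

Also provides a synthetic 1 kHz eye-position trace whose speed first
exceeds the 50 deg/s saccade-detection threshold exactly at a requested
reaction time, and the matching velocity-threshold onset detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import TRIAL_TYPES, TrialDesign, simulate_trials
from .params import ModelParams

__all__ = [
    "SessionDesign",
    "generate_dataset",
    "EyeTrace",
    "generate_eye_trace",
    "detect_saccade_onset",
]

#: Beta(a, b) shape scaled to [5, 20] deg; calibrated so the eccentricity
#: distribution has median ~11 deg and 90% range close to 7-18 deg.
_ECC_BETA = (1.5, 2.0)
_ECC_RANGE = (5.0, 20.0)

#: Orientation mixture: near-horizontal / near-vertical / near-diagonal.
_ORIENTATIONS = ("horizontal", "vertical", "diagonal")
_ORIENT_BASE_ANGLES = {
    "horizontal": (0.0, 180.0),
    "vertical": (90.0, 270.0),
    "diagonal": (45.0, 135.0, 225.0, 315.0),
}


@dataclass(frozen=True)
class SessionDesign:
    """Layout of one synthetic experimental session."""

    n_trials: int = 800
    proportions: dict = field(
        default_factory=lambda: {t: 1.0 / 3.0 for t in TRIAL_TYPES}
    )
    gaps: Sequence[float] = tuple(range(25, 251, 25))
    block_length: int = 100
    orientation_weights: tuple = (0.33, 0.15, 0.52)
    ecc_beta: tuple = _ECC_BETA
    ecc_range: tuple = _ECC_RANGE
    rt_deadline: float = 450.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if any(g < 25 or g > 250 for g in self.gaps):
            raise ValueError("gaps must lie within [25, 250] ms")
        if abs(sum(self.orientation_weights) - 1.0) > 1e-9:
            raise ValueError("orientation weights must sum to 1")

    def trial_design(self) -> TrialDesign:
        return TrialDesign(proportions=dict(self.proportions), gaps=tuple(self.gaps))


def _sample_eccentricity(design: SessionDesign, n: int, rng: np.random.Generator):
    a, b = design.ecc_beta
    lo, hi = design.ecc_range
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def _sample_angles(design: SessionDesign, n: int, rng: np.random.Generator):
    cat = rng.choice(_ORIENTATIONS, size=n, p=np.asarray(design.orientation_weights))
    angles = np.empty(n)
    for name in _ORIENTATIONS:
        mask = cat == name
        base = np.asarray(_ORIENT_BASE_ANGLES[name])
        picks = base[rng.integers(0, len(base), size=int(mask.sum()))]
        angles[mask] = picks + rng.uniform(-10.0, 10.0, size=int(mask.sum()))
    return np.mod(angles, 360.0), cat


def _color_blocks(n: int, block_length: int, rng: np.random.Generator):
    """Alternating red/green target blocks of roughly ``block_length``."""
    colors = []
    current = rng.choice(["red", "green"])
    while len(colors) < n:
        span = max(1, int(round(rng.normal(block_length, block_length / 10.0))))
        colors.extend([current] * span)
        current = "green" if current == "red" else "red"
    return np.asarray(colors[:n])


def generate_dataset(
    params: ModelParams,
    design: SessionDesign | Sequence[SessionDesign],
    n_sessions: int = 1,
    rng: np.random.Generator | int | None = None,
    monkey_id: str = "S1",
) -> pd.DataFrame:
    """Generate a multi-session trial table in the canonical schema.

    ``design`` may be a single :class:`SessionDesign` (reused for every
    session) or one design per session.  Trial outcomes come from the
    race-to-threshold simulator under ``params``.
    """
    rng = np.random.default_rng(rng)
    if isinstance(design, SessionDesign):
        designs = [design] * n_sessions
    else:
        designs = list(design)
        if len(designs) != n_sessions:
            raise ValueError(
                f"got {len(designs)} designs for {n_sessions} sessions"
            )

    sessions = []
    for s_idx, d in enumerate(designs):
        deadline_params = params.replace(rt_deadline=d.rt_deadline)
        table = simulate_trials(deadline_params, d.trial_design(), d.n_trials, rng)
        n = len(table)
        angles, _ = _sample_angles(d, n, rng)
        table.insert(0, "monkey_id", monkey_id)
        table.insert(1, "session_id", s_idx + 1)
        table["target_color"] = _color_blocks(n, d.block_length, rng)
        table["target_angle_deg"] = angles
        table["eccentricity_deg"] = _sample_eccentricity(d, n, rng)
        sessions.append(table)
    return pd.concat(sessions, ignore_index=True)


@dataclass
class EyeTrace:
    """1 kHz eye-position trace with derived speed.

    ``speed[k]`` is the magnitude of the position step into sample ``k``
    times the sampling rate (deg/s); ``speed[0] = 0``.
    """

    time: np.ndarray   # ms
    x: np.ndarray      # deg
    y: np.ndarray      # deg

    @property
    def speed(self) -> np.ndarray:
        dt_s = np.diff(self.time) / 1000.0
        step = np.hypot(np.diff(self.x), np.diff(self.y))
        return np.concatenate([[0.0], step / dt_s])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.time, "x_deg": self.x, "y_deg": self.y})


_DETECT_THRESHOLD = 50.0  # deg/s


def generate_eye_trace(
    rt_ms: float,
    amplitude_deg: float,
    rng: np.random.Generator | int | None = None,
    direction_deg: float = 0.0,
    noise_sd: float = 0.003,
    tail_ms: float = 80.0,
) -> EyeTrace:
    """Synthetic fixation-then-saccade trace sampled at 1 kHz.

    The saccade has a raised-sine velocity pulse (duration from a
    main-sequence-like rule, ~2.2 ms/deg + 21 ms) placed so that, absent
    noise, the derived speed first exceeds 50 deg/s exactly at the sample
    at ``rt_ms``.  Gaussian positional noise of SD ``noise_sd`` deg is
    added throughout.
    """
    if rt_ms < 0:
        raise ValueError(f"rt_ms must be >= 0, got {rt_ms}")
    if amplitude_deg <= 0:
        raise ValueError(f"amplitude_deg must be positive, got {amplitude_deg}")
    rng = np.random.default_rng(rng)

    dur = max(20.0, 2.2 * amplitude_deg + 21.0)
    vpeak = 2000.0 * amplitude_deg / dur  # deg/s; integral of pulse = amplitude
    if vpeak <= _DETECT_THRESHOLD * 1.05:
        raise ValueError(
            f"amplitude {amplitude_deg} deg too small: peak velocity "
            f"{vpeak:.1f} deg/s cannot clear the {_DETECT_THRESHOLD} deg/s "
            "detection threshold"
        )
    # time after pulse onset at which the pulse reaches the threshold
    t50 = (dur / np.pi) * np.arcsin(np.sqrt(_DETECT_THRESHOLD / vpeak))
    onset = rt_ms - t50 - 0.5  # crossing lands between samples rt-1 and rt

    n = int(np.ceil(rt_ms + dur + tail_ms)) + 1
    t = np.arange(n, dtype=float)
    phase = np.clip((t - onset) / dur, 0.0, 1.0)
    v = vpeak * np.sin(np.pi * phase) ** 2  # deg/s
    along = np.concatenate([[0.0], np.cumsum((v[1:] + 0.0) / 1000.0)])

    theta = np.deg2rad(direction_deg)
    x = along * np.cos(theta) + rng.normal(0.0, noise_sd, size=n)
    y = along * np.sin(theta) + rng.normal(0.0, noise_sd, size=n)
    return EyeTrace(time=t, x=x, y=y)


def detect_saccade_onset(
    trace: EyeTrace, threshold: float = _DETECT_THRESHOLD
) -> float | None:
    """Saccade onset: time of the first sample with speed strictly above
    ``threshold`` (deg/s); None if the speed never exceeds it."""
    dts = np.diff(trace.time)
    if len(dts) == 0 or not np.allclose(dts, dts[0]):
        raise ValueError("eye trace must be uniformly sampled")
    above = np.flatnonzero(trace.speed > threshold)
    if len(above) == 0:
        return None
    return float(trace.time[above[0]])
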