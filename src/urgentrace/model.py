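"""Accelerated race-to-threshold simulator for urgent saccadic choices.

Two motor plans, one per choice location, ramp linearly toward a fixed
threshold; the first to cross triggers the saccade.  The race starts after
an afferent go delay with build-up rates drawn from a correlated bivariate
Gaussian.  The color cue appears ``gap`` ms after the go signal and reaches
the circuit one afferent delay later, opening the exogenous response
interval (ERI):

* symmetric trials — both rates are attenuated by ``g_eri`` for the whole
  (short) ERI; salience favors neither plan;
* congruent / incongruent trials — both rates are attenuated for the first
  ``delta_eri`` ms, after which the plan toward the *salient* stimulus
  accelerates at ``a_ex`` while the other plan stays attenuated.

After the ERI the cue content is resolved and the ERI rate modulation,
being transient, ends: the plan toward the color-defined target runs at its
intrinsic rate plus an endogenous acceleration ``a_end`` while the
distracter plan decelerates at ``d_end``.  With probability ``lapse`` the
endogenous terms are never applied, as if the cue colors were never
resolved, and both plans continue at their intrinsic rates.  Position
changes accrued during the ERI always persist.

All updates are explicit Euler steps ``x(t + dt) = x(t) + b(t) dt`` on a
global time grid ``t = k * dt``; a step's rates are those in force at the
step's start, and a crossing detected at the end of a step is stamped at
``t + dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "TRIAL_TYPES",
    "TrialSpec",
    "TrialResult",
    "TrialDesign",
    "sample_initial_rates",
    "simulate_trial",
    "simulate_trials",
]

TRIAL_TYPES = ("congruent", "symmetric", "incongruent")
_SIDES = ("left", "right")


def _opposite(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition: type, gap, and target side."""

    trial_type: str
    gap: float
    target_side: str = "left"

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.target_side not in _SIDES:
            raise ValueError(f"target_side must be left/right, got {self.target_side!r}")
        if self.gap < 0:
            raise ValueError(f"gap must be >= 0, got {self.gap}")

    @property
    def salient_side(self) -> str:
        """Side of the larger stimulus: target (congruent), its opposite
        (incongruent), or ``"none"`` (symmetric)."""
        if self.trial_type == "congruent":
            return self.target_side
        if self.trial_type == "incongruent":
            return _opposite(self.target_side)
        return "none"


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    spec: TrialSpec
    choice_side: str | None
    rt: float
    pt: float
    correct: bool
    captured_during_eri: bool
    valid: bool
    is_lapse: bool
    trajectory: pd.DataFrame | None = None


@dataclass(frozen=True)
class TrialDesign:
    """Mixture of trial conditions for a simulated session.

    ``proportions`` maps trial types to probabilities; gaps are drawn
    uniformly (or per ``gap_probs``) from ``gaps``; the target appears on
    the left with probability ``p_left``.
    """

    proportions: dict = field(
        default_factory=lambda: {t: 1.0 / 3.0 for t in TRIAL_TYPES}
    )
    gaps: Sequence[float] = tuple(range(25, 251, 25))
    gap_probs: Sequence[float] | None = None
    p_left: float = 0.5

    def __post_init__(self) -> None:
        if not self.proportions:
            raise ValueError("design has no trial types")
        bad = set(self.proportions) - set(TRIAL_TYPES)
        if bad:
            raise ValueError(f"unknown trial type(s) in design: {sorted(bad)}")
        total = sum(self.proportions.values())
        if total <= 0:
            raise ValueError("trial-type proportions must sum to a positive value")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"trial-type proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        if len(self.gaps) == 0:
            raise ValueError("design has no gap values")
        if not 0.0 <= self.p_left <= 1.0:
            raise ValueError(f"p_left must be in [0, 1], got {self.p_left}")

    def sample_specs(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw ``n`` randomly interleaved trial specifications."""
        types = [t for t in TRIAL_TYPES if self.proportions.get(t, 0.0) > 0]
        probs = np.array([self.proportions[t] for t in types], dtype=float)
        probs /= probs.sum()
        ttype = rng.choice(types, size=n, p=probs)
        gaps = rng.choice(np.asarray(self.gaps, dtype=float), size=n,
                          p=None if self.gap_probs is None else self.gap_probs)
        left = rng.random(n) < self.p_left
        return pd.DataFrame(
            {
                "trial_type": ttype,
                "gap_ms": gaps,
                "target_side": np.where(left, "left", "right"),
            }
        )


def sample_initial_rates(
    params: ModelParams, rng: np.random.Generator, size: int | None = None
):
    """Draw initial build-up rate pairs (b0_left, b0_right).

    The pair follows a bivariate Gaussian with common mean ``mu_b``, common
    SD ``sigma_b``, and correlation ``rho_b``.  Returns two scalars when
    ``size`` is None, else two arrays of length ``size``.
    """
    n = 1 if size is None else int(size)
    z = rng.standard_normal((2, n))
    b0_left = params.mu_b + params.sigma_b * z[0]
    rho = params.rho_b
    b0_right = params.mu_b + params.sigma_b * (
        rho * z[0] + np.sqrt(max(0.0, 1.0 - rho * rho)) * z[1]
    )
    if size is None:
        return float(b0_left[0]), float(b0_right[0])
    return b0_left, b0_right


def _sample_trial_inputs(
    params: ModelParams,
    trial_type: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Sample every stochastic quantity for a batch of trials.

    Draw order is fixed (rates, go delay, cue delay, ERI duration, lapse,
    tie-break) so that runs are reproducible given a seed.
    """
    n = len(trial_type)
    b0_left, b0_right = sample_initial_rates(params, rng, size=n)
    t_go = np.clip(rng.normal(params.aff_mean, params.aff_sd, size=n), 0.0, None)
    ta = np.clip(rng.normal(params.aff_mean, params.aff_sd, size=n), 0.0, None)
    is_sym = trial_type == "symmetric"
    z = rng.standard_normal(n)
    eri = np.where(
        is_sym,
        np.clip(params.eri_sym_mean + params.eri_sym_sd * z, 0.0, None),
        np.clip(params.mu_eri + params.sigma_eri * z, params.delta_eri, None),
    )
    is_lapse = rng.random(n) < params.lapse
    tie_u = rng.random(n)
    return {
        "b0_left": b0_left,
        "b0_right": b0_right,
        "t_go": t_go,
        "ta": ta,
        "eri": eri,
        "is_lapse": is_lapse,
        "tie_u": tie_u,
    }


def _integrate(
    params: ModelParams,
    gap: np.ndarray,
    target_left: np.ndarray,
    salient_left: np.ndarray,
    has_salient: np.ndarray,
    inputs: dict,
    record: bool = False,
):
    """Vectorised Euler integration of the race for a batch of trials.

    Returns (t_cross, choice_left, captured, crossed[, trajectory]);
    ``t_cross`` is NaN for races that never reach threshold by ``t_max``.
    """
    dt = params.dt
    thr = params.threshold
    g = params.g_eri
    n = len(gap)

    b0_left = inputs["b0_left"]
    b0_right = inputs["b0_right"]
    t_go = inputs["t_go"]
    t_cue = gap + inputs["ta"]
    is_lapse = inputs["is_lapse"]
    tie_u = inputs["tie_u"]

    # phase boundaries: halt then (asymmetric only) exogenous acceleration
    t_halt_end = np.where(has_salient, t_cue + params.delta_eri, t_cue + inputs["eri"])
    t_eri_end = t_cue + inputs["eri"]

    att_left = g * b0_left
    att_right = g * b0_right

    x_left = np.zeros(n)
    x_right = np.zeros(n)
    exo = np.zeros(n)       # accumulated exogenous rate boost (salient side)
    end_a = np.zeros(n)     # accumulated endogenous acceleration (target side)
    end_d = np.zeros(n)     # accumulated endogenous deceleration (distracter)

    active = np.ones(n, dtype=bool)
    t_cross = np.full(n, np.nan)
    choice_left = np.zeros(n, dtype=bool)
    captured = np.zeros(n, dtype=bool)

    traj = [] if record else None
    n_steps = int(np.ceil(params.t_max / dt))

    for k in range(n_steps):
        t = k * dt
        started = t >= t_go
        pre = started & (t < t_cue)
        in_halt = (t >= t_cue) & (t < t_halt_end)
        in_accel = has_salient & (t >= t_halt_end) & (t < t_eri_end)
        post = t >= t_eri_end

        exo_left = np.where(salient_left, exo, 0.0)
        exo_right = np.where(salient_left, 0.0, exo)
        end_left = np.where(target_left, end_a, end_d)
        end_right = np.where(target_left, end_d, end_a)

        eri_left = att_left + exo_left    # end-of-ERI rate, left plan
        eri_right = att_right + exo_right

        # ERI modulation is transient: after the ERI every plan runs at its
        # intrinsic rate, plus the endogenous terms unless the trial lapses.
        post_left = b0_left + np.where(is_lapse, 0.0, end_left)
        post_right = b0_right + np.where(is_lapse, 0.0, end_right)

        b_left = np.where(pre, b0_left, att_left)
        b_left = np.where(in_accel, eri_left, b_left)
        b_left = np.where(post, post_left, b_left)
        b_right = np.where(pre, b0_right, att_right)
        b_right = np.where(in_accel, eri_right, b_right)
        b_right = np.where(post, post_right, b_right)

        upd = active & started
        x_left = np.where(upd, x_left + b_left * dt, x_left)
        x_right = np.where(upd, x_right + b_right * dt, x_right)

        # rate accumulators advance after the position update
        exo = exo + params.a_ex * dt * (in_accel & active)
        endo_on = post & active & ~is_lapse
        end_a = end_a + params.a_end * dt * endo_on
        end_d = end_d + params.d_end * dt * endo_on

        cross_left = upd & (x_left >= thr)
        cross_right = upd & (x_right >= thr)
        new = cross_left | cross_right
        if new.any():
            tie = cross_left & cross_right
            choice_left[new] = (cross_left & ~tie)[new] | (tie & (tie_u < 0.5))[new]
            t_cross[new] = t + dt
            captured[new] = (in_halt | in_accel)[new]
            active &= ~new
        if record:
            traj.append((t + dt, x_left.copy(), x_right.copy()))
        if not active.any():
            break

    crossed = ~np.isnan(t_cross)
    if record:
        tdf = pd.DataFrame(
            {
                "t_ms": [r[0] for r in traj],
                "x_left": [float(r[1][0]) for r in traj],
                "x_right": [float(r[2][0]) for r in traj],
            }
        )
        return t_cross, choice_left, captured, crossed, tdf
    return t_cross, choice_left, captured, crossed


def simulate_trial(
    params: ModelParams,
    spec: TrialSpec,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> TrialResult:
    """Simulate a single trial; optionally record the activity traces."""
    ttype = np.array([spec.trial_type])
    inputs = _sample_trial_inputs(params, ttype, rng)
    gap = np.array([float(spec.gap)])
    target_left = np.array([spec.target_side == "left"])
    salient_left = np.array([spec.salient_side == "left"])
    has_salient = np.array([spec.trial_type != "symmetric"])

    out = _integrate(params, gap, target_left, salient_left, has_salient,
                     inputs, record=record_trajectory)
    if record_trajectory:
        t_cross, choice_left, captured, crossed, traj = out
    else:
        t_cross, choice_left, captured, crossed = out
        traj = None

    if crossed[0]:
        rt = float(t_cross[0] + params.eff_delay)
        choice = "left" if choice_left[0] else "right"
        valid = rt < params.rt_deadline
    else:
        rt = float("nan")
        choice = None
        valid = False
    pt = rt - spec.gap
    return TrialResult(
        spec=spec,
        choice_side=choice,
        rt=rt,
        pt=pt,
        correct=bool(choice == spec.target_side),
        captured_during_eri=bool(captured[0]),
        valid=bool(valid),
        is_lapse=bool(inputs["is_lapse"][0]),
        trajectory=traj,
    )


def simulate_trials(
    params: ModelParams,
    design: TrialDesign,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` trials under a design; returns a trial table.

    The returned DataFrame has one row per trial with columns
    ``trial_index, trial_type, target_side, salient_side, gap_ms, rt_ms,
    pt_ms, choice_side, correct, captured_during_eri, valid``.  Trials
    that never reach threshold by ``t_max`` have NaN ``rt_ms`` and are
    flagged invalid; trials slower than ``rt_deadline`` are likewise
    invalid, mirroring the task's response deadline.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(rng)
    specs = design.sample_specs(n, rng)

    ttype = specs["trial_type"].to_numpy()
    gap = specs["gap_ms"].to_numpy(dtype=float)
    target_left = specs["target_side"].to_numpy() == "left"
    has_salient = ttype != "symmetric"
    salient_left = np.where(ttype == "congruent", target_left, ~target_left)
    salient_left &= has_salient

    inputs = _sample_trial_inputs(params, ttype, rng)
    t_cross, choice_left, captured, crossed = _integrate(
        params, gap, target_left, salient_left, has_salient, inputs
    )

    rt = np.where(crossed, t_cross + params.eff_delay, np.nan)
    choice = np.where(choice_left, "left", "right").astype(object)
    choice[~crossed] = None
    correct = crossed & (choice_left == target_left)
    valid = crossed & (rt < params.rt_deadline)

    salient_side = np.where(
        has_salient, np.where(salient_left, "left", "right"), "none"
    )
    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "trial_type": ttype,
            "target_side": specs["target_side"].to_numpy(),
            "salient_side": salient_side,
            "gap_ms": gap,
            "rt_ms": rt,
            "pt_ms": rt - gap,
            "choice_side": choice,
            "correct": correct,
            "captured_during_eri": captured,
            "valid": valid,
        }
    )
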