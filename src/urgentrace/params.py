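"""Model parameters for the accelerated race-to-threshold simulator.

The model describes an urgent two-alternative saccadic choice: two motor
plans ramp toward a fixed trigger threshold, and cue information arriving
mid-race modulates their build-up rates, first exogenously (salience-driven,
during a brief exogenous response interval, ERI) and then endogenously
(rule-driven). :class:`ModelParams` collects every tunable quantity.

Activity is expressed in arbitrary "activity units"; the model is scale
free, so only the ratios of rates and accelerations to the threshold
matter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ModelParams", "DEFAULT_PARAMS", "load_params", "save_params"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the race-to-threshold model.

    Attributes
    ----------
    mu_b, sigma_b : float
        Mean and SD of the initial build-up rates (activity units / ms).
        The two plans' initial rates are drawn from a bivariate Gaussian
        with these marginals and correlation ``rho_b``.
    rho_b : float
        Correlation coefficient of the two initial rates, in [-1, 1].
    threshold : float
        Fixed saccade-triggering threshold (activity units).
    dt : float
        Euler integration step (ms).
    aff_mean, aff_sd : float
        Gaussian afferent delay (ms): latency for the go signal to start
        the race, and for the cue to reach the circuit after it appears.
    mu_eri, sigma_eri : float
        Gaussian duration of the exogenous response interval on
        asymmetric-salience (congruent / incongruent) trials (ms).
    eri_sym_mean, eri_sym_sd : float
        Gaussian ERI duration on symmetric trials (ms).  Symmetric cues
        produce a shorter, purely pausing ERI.
    delta_eri : float
        Initial portion of the asymmetric ERI (ms) during which both
        plans halt before the salient plan starts accelerating.
    g_eri : float
        Attenuation gain in [0, 1] applied to the build-up rates during
        the ERI halt (0 = full stop, 1 = no slowdown).
    a_ex : float
        Exogenous acceleration of the salient plan's build-up rate
        (activity units / ms^2).
    a_end, d_end : float
        Endogenous acceleration of the target plan (> 0) and
        deceleration of the distracter plan (< 0) after cue resolution
        (activity units / ms^2).
    lapse : float
        Probability that the cue content is never applied endogenously;
        on a lapse the post-ERI plans keep their intrinsic build-up
        rates, so the outcome is decided by the initial race.
    eff_delay : float
        Fixed efferent delay between threshold crossing and saccade
        onset (ms).
    rt_deadline : float
        Maximum allowed reaction time (ms); slower trials are invalid.
    t_max : float
        Simulation cap (ms); races that never cross by then are invalid.
    """

    mu_b: float = 4.8
    sigma_b: float = 1.0
    rho_b: float = -0.6
    threshold: float = 1000.0
    dt: float = 1.0
    aff_mean: float = 60.0
    aff_sd: float = 8.0
    mu_eri: float = 25.0
    sigma_eri: float = 4.0
    eri_sym_mean: float = 19.0
    eri_sym_sd: float = 3.0
    delta_eri: float = 18.0
    g_eri: float = 0.35
    a_ex: float = 4.5
    a_end: float = 0.08
    d_end: float = -0.25
    lapse: float = 0.02
    eff_delay: float = 20.0
    rt_deadline: float = 450.0
    t_max: float = 1000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` if any invariant is violated."""
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if not -1.0 <= self.rho_b <= 1.0:
            raise ValueError(f"rho_b must be in [-1, 1], got {self.rho_b}")
        if not 0.0 <= self.g_eri <= 1.0:
            raise ValueError(f"g_eri must be in [0, 1], got {self.g_eri}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")
        if self.a_end < 0:
            raise ValueError(f"a_end must be >= 0, got {self.a_end}")
        if self.d_end > 0:
            raise ValueError(f"d_end must be <= 0, got {self.d_end}")
        for name in ("aff_mean", "mu_eri", "eri_sym_mean", "delta_eri",
                     "eff_delay", "rt_deadline", "t_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("sigma_b", "aff_sd", "sigma_eri", "eri_sym_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.delta_eri > self.mu_eri:
            raise ValueError(
                f"delta_eri ({self.delta_eri}) must not exceed mu_eri ({self.mu_eri})"
            )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known - {"seed"}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items() if k in known})


#: Default calibrated parameter set.  Chosen so that the simulated
#: behaviour reproduces the qualitative phenomenology of the urgent
#: color-matching task with varying salience: chance performance at short
#: processing times, exogenous capture within the 75-125 ms PT window
#: (above chance for salient targets, below chance for salient
#: distracters), an endogenously driven asymptote near 1 - lapse/2, and
#: mean reaction times in the 250-300 ms range.  A calibration, not a
#: ground-truth estimate.
DEFAULT_PARAMS = ModelParams()


def load_params(path: str | Path) -> tuple[ModelParams, int | None]:
    """Read a flat key:value YAML config; returns (params, seed or None)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    seed = raw.pop("seed", None)
    return ModelParams.from_dict(raw), seed


def save_params(params: ModelParams, path: str | Path, seed: int | None = None) -> None:
    """Write parameters (plus an optional seed) as flat YAML."""
    d = params.to_dict()
    if seed is not None:
        d["seed"] = int(seed)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
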