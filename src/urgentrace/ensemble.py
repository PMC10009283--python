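"""Parameter-sensitivity ensembles.

Confidence bands for the model's summary statistics are obtained by
re-running the simulation many times with all parameters jittered
independently: run ``i`` uses ``p = p_base * (1 + rel_sd * eps)`` with
``eps ~ N(0, 1)`` per parameter, so each parameter has an SD equal to
``rel_sd`` times its magnitude across runs.  Each run simulates a full
session mix, and 2.5th/97.5th percentiles across runs give the 95% bands.

Reproducibility: the master seed is turned into per-run child seeds with
``numpy.random.SeedSequence.spawn``, so the same master seed yields a
bit-identical ensemble regardless of how runs are ordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TRIAL_TYPES, TrialDesign, simulate_trials
from .params import ModelParams
from .tachometrics import capture_range_accuracy, rise_point, tachometric_curve

__all__ = ["randomize_params", "run_ensemble", "percentile_ci", "EnsembleResult"]


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval (2.5th-97.5th for level 0.95) over finite values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)

log = logging.getLogger(__name__)

#: Parameters jittered across runs: every rate, duration, gain and
#: probability.  dt, threshold, rt_deadline and t_max are structural
#: (jittering the threshold is equivalent to rescaling all rates).
RANDOMIZED_FIELDS = (
    "mu_b", "sigma_b", "rho_b",
    "aff_mean", "aff_sd",
    "mu_eri", "sigma_eri", "eri_sym_mean", "eri_sym_sd", "delta_eri",
    "g_eri", "a_ex", "a_end", "d_end",
    "lapse", "eff_delay",
)

_UNIT_INTERVAL = {"lapse", "g_eri"}
_FLOOR_ZERO = {
    "sigma_b", "aff_mean", "aff_sd", "mu_eri", "sigma_eri",
    "eri_sym_mean", "eri_sym_sd", "delta_eri", "eff_delay", "a_end",
}


def randomize_params(
    base: ModelParams, rng: np.random.Generator, rel_sd: float = 0.05
) -> ModelParams:
    """Jitter every non-structural parameter multiplicatively.

    Each parameter becomes ``p * (1 + rel_sd * eps)`` with independent
    standard-normal ``eps``; probabilities and gains are clipped to
    [0, 1], durations and SDs floored at 0, correlations clipped to
    [-1, 1], and ``d_end`` capped at 0.
    """
    if rel_sd < 0:
        raise ValueError(f"rel_sd must be >= 0, got {rel_sd}")
    changes = {}
    for name in RANDOMIZED_FIELDS:
        value = getattr(base, name) * (1.0 + rel_sd * rng.standard_normal())
        if name in _UNIT_INTERVAL:
            value = min(max(value, 0.0), 1.0)
        elif name in _FLOOR_ZERO:
            value = max(value, 0.0)
        elif name == "rho_b":
            value = min(max(value, -1.0), 1.0)
        elif name == "d_end":
            value = min(value, 0.0)
        changes[name] = value
    # keep the halt portion inside the mean ERI duration
    changes["delta_eri"] = min(changes["delta_eri"], changes["mu_eri"])
    return base.replace(**changes)


@dataclass
class EnsembleResult:
    """Per-run statistics and percentile CIs across randomized runs."""

    runs: pd.DataFrame          # one row per (run, trial_type)
    ci: pd.DataFrame            # one row per (trial_type, statistic)
    base: ModelParams
    rel_sd: float
    n_runs: int
    n_trials_per_run: int
    seed: int | None
    n_undefined: dict
    tables: list | None = None      # per-run trial tables when kept
    run_params: list | None = None  # per-run randomized parameter sets


def run_ensemble(
    base: ModelParams,
    n_runs: int = 500,
    n_trials: int = 40_000,
    design: TrialDesign | None = None,
    seed: int | None = None,
    rel_sd: float = 0.05,
    level: float = 0.95,
    keep_tables: bool = False,
) -> EnsembleResult:
    """Run ``n_runs`` simulations with independently jittered parameters.

    For every run and trial type, computes the capture-range accuracy
    (percent correct, 75 <= PT <= 125 ms) and the rise point of the
    tachometric curve.  Percentile CIs (2.5th-97.5th for ``level`` 0.95)
    are taken across runs; runs where a statistic is undefined are
    excluded from that statistic's percentiles and counted.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    if design is None:
        design = TrialDesign()
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_runs)

    rows = []
    tables = [] if keep_tables else None
    run_params = [] if keep_tables else None
    for run_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = randomize_params(base, rng, rel_sd=rel_sd)
        table = simulate_trials(params, design, n_trials, rng)
        if keep_tables:
            tables.append(table)
            run_params.append(params)
        for ttype in TRIAL_TYPES:
            if design.proportions.get(ttype, 0.0) == 0:
                continue
            sub = table[table["trial_type"] == ttype]
            acc, _ = capture_range_accuracy(sub)
            try:
                rp = rise_point(tachometric_curve(sub))
            except ValueError:
                rp = float("nan")
            rows.append(
                {
                    "run": run_idx,
                    "trial_type": ttype,
                    "capture_accuracy": acc,
                    "rise_point": rp,
                }
            )
    runs = pd.DataFrame(rows)

    ci_rows = []
    n_undefined = {}
    for ttype, grp in runs.groupby("trial_type"):
        for stat in ("capture_accuracy", "rise_point"):
            vals = grp[stat].to_numpy(dtype=float)
            good = vals[np.isfinite(vals)]
            n_undef = len(vals) - len(good)
            n_undefined[(ttype, stat)] = n_undef
            if n_undef:
                log.warning(
                    "%d/%d runs had undefined %s for %s trials",
                    n_undef, len(vals), stat, ttype,
                )
            if len(good) == 0:
                lo = med = hi = float("nan")
            else:
                lo, hi = percentile_ci(good, level)
                med = float(np.percentile(good, 50))
            ci_rows.append(
                {
                    "trial_type": ttype,
                    "statistic": stat,
                    "ci_low": lo,
                    "median": med,
                    "ci_high": hi,
                    "n_defined": len(good),
                }
            )
    ci = pd.DataFrame(ci_rows)
    return EnsembleResult(
        runs=runs,
        ci=ci,
        base=base,
        rel_sd=rel_sd,
        n_runs=n_runs,
        n_trials_per_run=n_trials,
        seed=seed,
        n_undefined=n_undefined,
        tables=tables,
        run_params=run_params,
    )
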