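"""Independent reference implementations used only as test oracles.

These deliberately re-derive the model's update rules and the statistics
step by step in plain Python, sharing no code with the package.
"""

from __future__ import annotations

import math


def oracle_trajectory(params, gap, target_side, salient_side, inputs):
    """Scalar step-by-step Euler integration of one trial's race.

    ``inputs`` carries the pre-sampled stochastic quantities (b0_left,
    b0_right, t_go, ta, eri, is_lapse, tie_u) so that the comparison with
    the vectorised simulator is exact, not statistical.

    Returns (times, xs_left, xs_right, t_cross, choice_side, captured).
    """
    dt = params.dt
    b0 = {"left": inputs["b0_left"], "right": inputs["b0_right"]}
    t_go = inputs["t_go"]
    t_cue = gap + inputs["ta"]
    has_salient = salient_side in ("left", "right")
    if has_salient:
        t_halt_end = t_cue + params.delta_eri
    else:
        t_halt_end = t_cue + inputs["eri"]
    t_eri_end = t_cue + inputs["eri"]

    x = {"left": 0.0, "right": 0.0}
    exo = 0.0
    end_a = 0.0
    end_d = 0.0
    times, xs_l, xs_r = [], [], []
    n_steps = int(math.ceil(params.t_max / dt))

    for k in range(n_steps):
        t = k * dt
        rates = {}
        for side in ("left", "right"):
            if t < t_go:
                rates[side] = 0.0  # race not started; x stays 0
            elif t < t_cue:
                rates[side] = b0[side]
            elif t < t_halt_end:
                rates[side] = params.g_eri * b0[side]
            elif has_salient and t < t_eri_end:
                boost = exo if side == salient_side else 0.0
                rates[side] = params.g_eri * b0[side] + boost
            else:
                if inputs["is_lapse"]:
                    rates[side] = b0[side]
                else:
                    endo = end_a if side == target_side else end_d
                    rates[side] = b0[side] + endo
        if t >= t_go:
            x["left"] += rates["left"] * dt
            x["right"] += rates["right"] * dt
        if has_salient and t_halt_end <= t < t_eri_end:
            exo += params.a_ex * dt
        if t >= t_eri_end and not inputs["is_lapse"]:
            end_a += params.a_end * dt
            end_d += params.d_end * dt

        times.append(t + dt)
        xs_l.append(x["left"])
        xs_r.append(x["right"])

        cl = x["left"] >= params.threshold
        cr = x["right"] >= params.threshold
        if cl or cr:
            if cl and cr:
                choice = "left" if inputs["tie_u"] < 0.5 else "right"
            else:
                choice = "left" if cl else "right"
            captured = t_cue <= t < t_eri_end
            return times, xs_l, xs_r, t + dt, choice, captured
    return times, xs_l, xs_r, None, None, False


def oracle_clopper_pearson(k, n, level=0.95):
    """Clopper-Pearson interval straight from beta quantiles."""
    from scipy import stats

    alpha = 1.0 - level
    low = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    high = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(low), float(high)


def oracle_sliding_bins(pts, corrects, centers, width):
    """Exhaustive enumeration of sliding-bin counts and percentages."""
    out = []
    half = width / 2.0
    for c in centers:
        in_bin = [(p, ok) for p, ok in zip(pts, corrects)
                  if c - half <= p < c + half]
        n = len(in_bin)
        k = sum(1 for _, ok in in_bin if ok)
        out.append((n, 100.0 * k / n if n else float("nan")))
    return out
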