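"""Response kinetics: plateau-then-single-phase decay fits, rise half-times,
areas under the curve, and the one-sided extra sum-of-squares F test for
nested model comparison.

The decay model is piecewise: a constant elevated plateau up to a free
changepoint t0, then exponential relaxation toward an asymptote at rate K
expressed per minute. The asymptote is free (bounded below by 0) by
default, or can be fixed to a known pre-stimulation baseline — slow decays
under realistic noise are unidentifiable with a free asymptote. The
changepoint makes the objective non-smooth in t0, so fitting profiles the
conditionally linear parameters in closed form on a (t0, K) grid and
refines the winner with bounded scalar optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

_N_MIN_POINTS = 8
_K_GRID = np.concatenate([[0.0], np.geomspace(1e-3, 30.0, 48)])


@dataclass
class DecayFit:
    """Result of a plateau-then-single-phase-decay least-squares fit.

    `plateau` and `baseline` (the decay asymptote) are in trace units
    (F/F0); `t0` is the decay onset in seconds; `K` is per minute.
    """

    plateau: float
    t0: float
    K: float
    baseline: float
    RSS: float
    n: int
    converged: bool
    message: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.plateau)
        decay = t > self.t0
        out[decay] = self.baseline + (self.plateau - self.baseline) * np.exp(
            -self.K * (t[decay] - self.t0) / 60.0
        )
        return out


@dataclass
class RiseTimeResult:
    """Rise half-time of a stimulus response."""

    T_half: float  # s after stimulation
    peak_value: float
    peak_time: float  # s, absolute
    method: str = "first-crossing, linear interpolation"


@dataclass
class FTestResult:
    """One-sided extra sum-of-squares F test between two trace groups."""

    F: float
    df_num: int
    df_den: int
    p: float
    RSS_shared: float
    RSS_separate: float


def _trace_arrays(trace) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(trace, "time") and hasattr(trace, "values"):
        return np.asarray(trace.time, float), np.asarray(trace.values, float)
    t, y = trace
    return np.asarray(t, float), np.asarray(y, float)


class _Split:
    """Pre/decay split of the post-stimulation points at a candidate t0."""

    __slots__ = ("t_decay", "y_decay", "n_pre", "sum_y_pre", "sum_y2_pre")

    def __init__(self, t: np.ndarray, y: np.ndarray, t0: float):
        decay = t > t0
        self.t_decay = (t[decay] - t0) / 60.0
        self.y_decay = y[decay]
        y_pre = y[~decay]
        self.n_pre = y_pre.size
        self.sum_y_pre = float(y_pre.sum())
        self.sum_y2_pre = float(np.dot(y_pre, y_pre))


def _profile_rss(split: _Split, K: np.ndarray, baseline_fixed: float | None):
    """RSS minimized over the linear parameters for fixed t0 and an array
    of K values.

    Free-asymptote mode solves the 2x2 normal equations of columns
    a = [1 | exp(-K tau)] and b = [0 | 1 - exp(-K tau)], with the
    asymptote clipped at 0 (plateau-only refit when the bound is hit).
    Fixed-asymptote mode shifts the decay targets and fits the plateau
    alone.
    """
    K = np.atleast_1d(np.asarray(K, float))
    E = np.exp(-K[:, None] * split.t_decay[None, :])
    one_m = 1.0 - E
    S_aa = split.n_pre + np.einsum("ij,ij->i", E, E)
    if baseline_fixed is not None:
        b0 = float(baseline_fixed)
        r_d = split.y_decay[None, :] - b0 * one_m
        S_ay = split.sum_y_pre + np.einsum("ij,ij->i", E, r_d)
        plateau = S_ay / S_aa
        sum_r2 = split.sum_y2_pre + np.einsum("ij,ij->i", r_d, r_d)
        rss = sum_r2 - plateau * S_ay
        baseline = np.full_like(plateau, b0)
        return np.maximum(rss, 0.0), plateau, baseline
    sum_y2 = split.sum_y2_pre + float(np.dot(split.y_decay, split.y_decay))
    S_ab = np.einsum("ij,ij->i", E, one_m)
    S_bb = np.einsum("ij,ij->i", one_m, one_m)
    S_ay = split.sum_y_pre + E @ split.y_decay
    S_by = one_m @ split.y_decay
    det = S_aa * S_bb - S_ab * S_ab
    ok = det > 1e-12 * np.maximum(S_aa * S_bb, 1e-300)
    safe_det = np.where(ok, det, 1.0)
    plateau = np.where(ok, (S_bb * S_ay - S_ab * S_by) / safe_det, S_ay / S_aa)
    baseline = np.where(ok, (S_aa * S_by - S_ab * S_ay) / safe_det, plateau)
    # enforce asymptote >= 0: refit plateau alone where the bound is hit
    neg = baseline < 0.0
    plateau = np.where(neg, S_ay / S_aa, plateau)
    baseline = np.where(neg, 0.0, baseline)
    rss = sum_y2 - plateau * S_ay - baseline * S_by
    return np.maximum(rss, 0.0), plateau, baseline


def _fit_for_t0(
    t: np.ndarray,
    y: np.ndarray,
    t0: float,
    baseline_fixed: float | None,
    refine_k: bool,
):
    """Best (RSS, plateau, baseline, K) at a fixed changepoint; `refine_k`
    adds a bounded Brent polish of K between its best grid neighbours."""
    split = _Split(t, y, t0)
    if split.t_decay.size < 2:
        rss, plat, base = _profile_rss(split, np.array([0.0]), baseline_fixed)
        return float(rss[0]), float(plat[0]), float(base[0]), 0.0

    rss, plat, base = _profile_rss(split, _K_GRID, baseline_fixed)
    j = int(np.argmin(rss))
    best = (float(rss[j]), float(plat[j]), float(base[j]), float(_K_GRID[j]))
    if not refine_k:
        return best

    k_lo = float(_K_GRID[max(j - 1, 0)])
    k_hi = float(_K_GRID[min(j + 1, len(_K_GRID) - 1)])
    if k_hi <= k_lo:
        return best
    res = optimize.minimize_scalar(
        lambda k: float(_profile_rss(split, np.array([k]), baseline_fixed)[0][0]),
        bounds=(k_lo, k_hi), method="bounded", options={"xatol": 1e-10},
    )
    r, p, b = _profile_rss(split, np.array([float(res.x)]), baseline_fixed)
    if r[0] < best[0]:
        return float(r[0]), float(p[0]), float(b[0]), float(res.x)
    return best


def fit_plateau_decay(
    trace,
    stim_time: float = 0.0,
    t0_stride: int = 1,
    baseline_fixed: float | None = None,
) -> DecayFit:
    """Fit the plateau-then-single-phase-decay model to the post-stimulation
    part of a trace.

    Grid search over changepoint candidates at (strided) sample times with
    closed-form profiling of the linear parameters and a 1-D search in K,
    then bounded continuous refinement of t0 between the best candidate's
    neighbours. `baseline_fixed` pins the decay asymptote (recommended
    when the pre-stimulation baseline is known; a free asymptote leaves
    slow decays unidentifiable under noise). Non-convergence or
    unidentifiable decays are flagged on the returned fit, not raised.
    """
    t, y = _trace_arrays(trace)
    post = t >= stim_time
    t_post, y_post = t[post], y[post]
    if t_post.size < _N_MIN_POINTS:
        raise ValueError(
            f"need >= {_N_MIN_POINTS} post-stimulation points, got {t_post.size}"
        )

    scale = float(np.max(np.abs(y_post))) or 1.0
    if np.ptp(y_post) <= 1e-12 * scale:
        mean = float(np.mean(y_post))
        return DecayFit(
            plateau=mean, t0=float(t_post[0]), K=0.0,
            baseline=mean if baseline_fixed is None else float(baseline_fixed),
            RSS=float(np.sum((y_post - mean) ** 2)), n=t_post.size,
            converged=False, message="flat trace: decay rate unidentifiable",
        )

    candidates = t_post[: max(t_post.size - 2, 1) : max(int(t0_stride), 1)]
    coarse = []
    for t0 in candidates:
        rss, _, _, _ = _fit_for_t0(t_post, y_post, float(t0), baseline_fixed, False)
        coarse.append((rss, float(t0)))
    coarse.sort()
    # K-refine the leading candidates: the coarse K grid can rank nearby
    # changepoints incorrectly when the true K falls between grid points
    best = None
    for _, t0 in coarse[:5]:
        rss, plat, base, k = _fit_for_t0(t_post, y_post, t0, baseline_fixed, True)
        if best is None or rss < best[0]:
            best = (rss, plat, base, k, t0)
    rss_b, plat_b, base_b, k_b, t0_b = best

    # continuous refinement of the changepoint between neighbouring samples;
    # RSS(t0) is smooth between sample times but kinked at them, so each
    # adjacent kink-free interval is searched separately
    uniq = np.unique(t_post)
    dt = float(np.median(np.diff(uniq))) if uniq.size > 1 else 0.0
    if dt > 0:
        dt = dt * max(int(t0_stride), 1)
        for lo, hi in ((t0_b - dt, t0_b), (t0_b, t0_b + dt)):
            res = optimize.minimize_scalar(
                lambda v: _fit_for_t0(t_post, y_post, float(v), baseline_fixed, True)[0],
                bounds=(lo, hi), method="bounded", options={"xatol": 1e-9},
            )
            rss_r, plat_r, base_r, k_r = _fit_for_t0(
                t_post, y_post, float(res.x), baseline_fixed, True
            )
            if rss_r < rss_b:
                rss_b, plat_b, base_b, k_b, t0_b = rss_r, plat_r, base_r, k_r, float(res.x)

    flat_rss = float(np.sum((y_post - np.mean(y_post)) ** 2))
    identifiable = abs(plat_b - base_b) > 1e-9 * scale and rss_b < flat_rss * (1 - 1e-12)
    return DecayFit(
        plateau=float(plat_b), t0=float(t0_b), K=float(k_b), baseline=float(base_b),
        RSS=float(rss_b), n=int(t_post.size), converged=bool(identifiable),
        message="" if identifiable else "decay amplitude ~0: rate unidentifiable",
    )


def t_half_rise(trace, stim_time: float = 0.0, baseline: float | None = None) -> RiseTimeResult:
    """Time after stimulation to half-maximal response.

    Peak is the post-stimulation maximum; the half level is
    baseline + (peak - baseline)/2 with the baseline taken from
    pre-stimulation samples (or supplied). The first crossing is located
    with linear interpolation between samples; a trace that never
    crosses (no response) raises.
    """
    t, y = _trace_arrays(trace)
    pre = t < stim_time
    if baseline is None:
        baseline = float(np.mean(y[pre])) if np.any(pre) else float(y[0])
    post = t >= stim_time
    if not np.any(post):
        raise ValueError("trace does not span the stimulation time")
    t_post, y_post = t[post], y[post]
    i_peak = int(np.argmax(y_post))
    peak = float(y_post[i_peak])
    if peak <= baseline:
        raise ValueError("no response: post-stimulation peak does not exceed baseline")
    half = baseline + (peak - baseline) / 2.0

    above = np.flatnonzero(y >= half)
    above = above[t[above] >= stim_time]
    if above.size == 0:
        raise ValueError("trace never reaches the half-maximal level after stimulation")
    i = int(above[0])
    if i == 0 or y[i - 1] >= half:
        t_cross = t[i]
    else:
        frac = (half - y[i - 1]) / (y[i] - y[i - 1])
        t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
    return RiseTimeResult(
        T_half=float(max(t_cross - stim_time, 0.0)),
        peak_value=peak,
        peak_time=float(t_post[i_peak]),
    )


def auc(trace, window: tuple[float, float], baseline_ref: float = 0.0) -> float:
    """Trapezoidal integral of (value - baseline_ref) over a time window (s)."""
    t, y = _trace_arrays(trace)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError(f"empty integration window [{w0}, {w1}]")
    if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
        raise ValueError("window extends beyond the trace span")
    sel = (t >= w0) & (t <= w1)
    if np.sum(sel) < 2:
        raise ValueError("window selects fewer than 2 samples")
    return float(np.trapezoid(y[sel] - baseline_ref, t[sel]))


def _pool(traces, stim_time: float) -> tuple[np.ndarray, np.ndarray]:
    ts, ys = [], []
    for tr in traces:
        t, y = _trace_arrays(tr)
        post = t >= stim_time
        ts.append(t[post])
        ys.append(y[post])
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


def extra_ss_f_test(
    traces_A: Sequence,
    traces_B: Sequence,
    stim_time: float = 0.0,
    t0_stride: int = 1,
    baseline_fixed: float | None = None,
) -> FTestResult:
    """One-sided extra sum-of-squares F test: do groups A and B share one
    plateau-decay parameter set, or do they need separate ones?

    RSS_shared comes from a single fit to the pooled points; RSS_separate
    from independent fits. F = ((RSS_sh - RSS_sep)/(df_sh - df_sep)) /
    (RSS_sep/df_sep), with the upper-tail F probability as p.
    """
    tA, yA = _pool(traces_A, stim_time)
    tB, yB = _pool(traces_B, stim_time)
    n_params = 3 if baseline_fixed is not None else 4  # plateau, t0, K (, baseline)
    n_total = tA.size + tB.size
    df_sep = n_total - 2 * n_params
    df_shared = n_total - n_params
    if df_sep <= 0:
        raise ValueError("not enough points for separate fits (df_den <= 0)")

    kw = dict(stim_time=stim_time, t0_stride=t0_stride, baseline_fixed=baseline_fixed)
    fit_A = fit_plateau_decay((tA, yA), **kw)
    fit_B = fit_plateau_decay((tB, yB), **kw)
    t_all = np.concatenate([tA, tB])
    y_all = np.concatenate([yA, yB])
    order = np.argsort(t_all, kind="stable")
    fit_sh = fit_plateau_decay((t_all[order], y_all[order]), **kw)

    rss_sep = fit_A.RSS + fit_B.RSS
    rss_sh = max(fit_sh.RSS, rss_sep)  # shared model is nested: RSS_sh >= RSS_sep
    df_num = df_shared - df_sep
    if rss_sep <= 0:
        f_stat = 0.0 if rss_sh <= rss_sep else np.inf
    else:
        f_stat = ((rss_sh - rss_sep) / df_num) / (rss_sep / df_sep)
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, df_num, df_sep)) if np.isfinite(f_stat) else 0.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return FTestResult(
        F=f_stat, df_num=int(df_num), df_den=int(df_sep), p=p,
        RSS_shared=float(rss_sh), RSS_separate=float(rss_sep),
    )
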