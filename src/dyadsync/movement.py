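"""Dyadic movement synchrony from 3D hand velocities.

The synchrony statistic is the cosine of the angle between the two
participants' instantaneous 3D velocity vectors (CVV):

    C_ij(t) = <v_i(t), v_j(t)> / (|v_i(t)| |v_j(t)|)

CVV = 1 for identical movement direction, -1 for mirror movement, 0 for
orthogonal (unaligned) movement.  |CVV| is thresholded on a time x lag grid
to detect synchronized episodes, at lag 0 and at lags up to +/-750 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    CVV_THRESHOLD,
    FISHER_CLIP,
    LAG0_BOUNDARY_MS,
    LAG_STEP_MS,
    MAX_LAG_MS,
    OUTLIER_SD,
    STILLNESS_EPS,
    SYNC_WINDOW_S,
    VELOCITY_SMOOTH_MS,
)
from .design import MotionTrace


@dataclass
class VelocitySeries:
    """3D instantaneous velocity of one participant (units/s)."""

    participant_id: str
    fs: float
    v: np.ndarray  # (n, 3)
    smoothed: bool = False
    smoothing_window_ms: float | None = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 2 or self.v.shape[1] != 3:
            raise ValueError("v must be (n, 3)")
        if self.smoothed and not (self.smoothing_window_ms or 0) > 0:
            raise ValueError("smoothed series must record a positive window")

    @property
    def n(self) -> int:
        return self.v.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


def compute_velocity(trace: MotionTrace) -> VelocitySeries:
    """First difference of positions scaled to units/s; length n-1."""
    if trace.n < 2:
        raise ValueError("need at least 2 position samples")
    v = np.diff(trace.pos, axis=0) * trace.fs
    return VelocitySeries(trace.participant_id, trace.fs, v)


def gaussian_smooth(
    vel: VelocitySeries, window_ms: float = VELOCITY_SMOOTH_MS
) -> VelocitySeries:
    """Jitter removal: per-axis convolution with a Gaussian kernel of full
    width ``window_ms`` (sigma = window/4, truncated at +/-2 sigma), kernel
    renormalized at the edges so constants pass through unchanged."""
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    sigma = (window_ms / 1000.0) * vel.fs / 4.0
    half = max(1, int(np.ceil(2.0 * sigma)))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()

    out = np.empty_like(vel.v)
    norm = np.convolve(np.ones(vel.n), kernel, mode="same")
    for ax in range(3):
        out[:, ax] = np.convolve(vel.v[:, ax], kernel, mode="same") / norm
    return VelocitySeries(
        vel.participant_id, vel.fs, out, smoothed=True,
        smoothing_window_ms=window_ms,
    )


def cvv(vi: np.ndarray, vj: np.ndarray, eps: float = STILLNESS_EPS) -> np.ndarray:
    """Cosine of the angle between 3D velocity vectors.

    Accepts single vectors (3,) or stacks (n, 3); returns a scalar or (n,)
    array in [-1, 1].  When either vector's magnitude is below ``eps``
    (stillness) the cosine is defined as 0: no direction, no alignment
    evidence.
    """
    vi = np.asarray(vi, dtype=float)
    vj = np.asarray(vj, dtype=float)
    scalar = vi.ndim == 1
    vi = np.atleast_2d(vi)
    vj = np.atleast_2d(vj)
    ni = np.linalg.norm(vi, axis=1)
    nj = np.linalg.norm(vj, axis=1)
    still = (ni < eps) | (nj < eps)
    denom = np.where(still, 1.0, ni * nj)
    c = np.einsum("ij,ij->i", vi, vj) / denom
    c = np.where(still, 0.0, np.clip(c, -1.0, 1.0))
    return float(c[0]) if scalar else c


@dataclass
class SyncMap:
    """|CVV| surface over (time, lag) with its thresholded sync mask.

    Lag sign convention: positive lag means participant j's movement trails
    participant i's (j at time t+lag is compared with i at time t).
    """

    dyad_id: str
    condition: str
    lags_ms: np.ndarray       # symmetric grid about 0
    times_s: np.ndarray       # centers of fully valid windows
    C: np.ndarray             # (n_times, n_lags), windowed |CVV| in [0, 1]
    threshold: float = CVV_THRESHOLD
    window_s: float = SYNC_WINDOW_S

    @property
    def sync_mask(self) -> np.ndarray:
        return self.C > self.threshold


@dataclass
class SyncSummary:
    dyad_id: str
    condition: str
    group: str
    total_sync: float
    lag0_sync: float
    lagged_sync: float
    fisher_z_mean_cvv: float


def _shift_interp(v: np.ndarray, fs: float, shift_s: float, t_query: np.ndarray) -> np.ndarray:
    """Sample a uniformly-sampled 3D series at times t_query + shift_s by
    linear interpolation (sub-sample lags at a 50 Hz grid)."""
    t_src = np.arange(v.shape[0]) / fs
    tq = t_query + shift_s
    out = np.empty((tq.size, 3))
    for ax in range(3):
        out[:, ax] = np.interp(tq, t_src, v[:, ax])
    return out


def lagged_sync_map(
    vi: VelocitySeries,
    vj: VelocitySeries,
    *,
    dyad_id: str = "",
    condition: str = "",
    max_lag_ms: float = MAX_LAG_MS,
    step_ms: float = LAG_STEP_MS,
    window_s: float = SYNC_WINDOW_S,
    threshold: float = CVV_THRESHOLD,
) -> SyncMap:
    """Windowed |CVV| for every lag on the +/-max_lag grid.

    For each lag tau, participant j's velocity is aligned at t + tau
    (linear interpolation handles sub-sample lags), the per-sample signed
    CVV with participant i at t is computed, a centered moving average of
    ``window_s`` is applied, and the absolute value of the windowed mean is
    taken.  A window of consistently aligned movement scores near 1 and a
    window of consistent mirror movement near |-1| = 1, while unaligned
    movement averages toward 0 — so chance-level alignment stays well below
    the detection threshold.  Only fully valid (all-lag, full-window) time
    points are kept, so C contains no partially-windowed estimates.
    """
    if vi.fs != vj.fs:
        raise ValueError("mismatched sampling rates")
    fs = vi.fs
    max_lag_s = max_lag_ms / 1000.0
    n_steps = int(round(max_lag_ms / step_ms))
    lags_ms = np.arange(-n_steps, n_steps + 1) * step_ms

    w = int(round(window_s * fs))
    # time support on i's grid where t + tau stays inside j for every tau
    t_i = vi.t
    lo = max_lag_s
    hi = min(t_i[-1], (vj.n - 1) / fs - max_lag_s)
    valid = (t_i >= lo - 1e-12) & (t_i <= hi + 1e-12)
    t_valid = t_i[valid]
    if t_valid.size < w:
        raise ValueError(
            "traces too short: need at least window_s + 2*max_lag of overlap"
        )
    vi_valid = vi.v[valid]

    kernel = np.ones(w) / w
    n_out = t_valid.size - w + 1
    C = np.empty((n_out, lags_ms.size))
    for k, lag_ms in enumerate(lags_ms):
        vj_shift = _shift_interp(vj.v, fs, lag_ms / 1000.0, t_valid)
        c_signed = cvv(vi_valid, vj_shift)
        C[:, k] = np.abs(np.convolve(c_signed, kernel, mode="valid"))
    # centers of the valid windows
    times = t_valid[: n_out] + (w - 1) / (2.0 * fs)
    return SyncMap(
        dyad_id=dyad_id,
        condition=condition,
        lags_ms=lags_ms,
        times_s=times,
        C=np.clip(C, 0.0, 1.0),
        threshold=threshold,
        window_s=window_s,
    )


def fisher_z(r: float | np.ndarray, clip: float = FISHER_CLIP) -> float | np.ndarray:
    """arctanh variance-stabilizing transform, clipped away from +/-1."""
    return np.arctanh(np.clip(r, -clip, clip))


def total_sync(
    smap: SyncMap,
    group: str = "real",
    lag0_boundary_ms: float = LAG0_BOUNDARY_MS,
) -> SyncSummary:
    """Proportions of block time spent in synchrony.

    lag0_sync: sync mask true at lag 0.  lagged_sync: mask true at any lag
    with |lag| > 30 ms.  total_sync: either regime (per-time-point OR).
    """
    if smap.C.size == 0:
        raise ValueError("empty sync map")
    mask = smap.sync_mask
    lag0_col = int(np.argmin(np.abs(smap.lags_ms)))
    at_lag0 = mask[:, lag0_col]
    lagged_cols = np.abs(smap.lags_ms) > lag0_boundary_ms
    at_lagged = mask[:, lagged_cols].any(axis=1)
    return SyncSummary(
        dyad_id=smap.dyad_id,
        condition=smap.condition,
        group=group,
        total_sync=float(np.mean(at_lag0 | at_lagged)),
        lag0_sync=float(np.mean(at_lag0)),
        lagged_sync=float(np.mean(at_lagged)),
        fisher_z_mean_cvv=float(fisher_z(np.mean(smap.C))),
    )


def dyad_sync_summary(
    trace_i: MotionTrace,
    trace_j: MotionTrace,
    *,
    dyad_id: str = "",
    group: str = "real",
    smooth_ms: float = VELOCITY_SMOOTH_MS,
    **map_kwargs,
) -> SyncSummary:
    """Convenience pipeline: positions -> smoothed velocities -> sync map ->
    summary, for one condition block of one (real or pseudo) dyad."""
    vi = gaussian_smooth(compute_velocity(trace_i), smooth_ms)
    vj = gaussian_smooth(compute_velocity(trace_j), smooth_ms)
    smap = lagged_sync_map(
        vi, vj, dyad_id=dyad_id, condition=trace_i.condition, **map_kwargs
    )
    return total_sync(smap, group=group)


def exclude_outliers(values, k: float = OUTLIER_SD):
    """Single-pass mean +/- k*SD exclusion on summary values.

    Returns (kept_values, report) where report records the removed indices
    and the removed fraction.  The mean and SD are computed once on the full
    set; no iterative re-trimming.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    mu = values.mean()
    sd = values.std(ddof=0)
    if sd == 0:
        keep = np.ones(values.size, dtype=bool)
    else:
        keep = np.abs(values - mu) <= k * sd
    removed = np.flatnonzero(~keep)
    report = {
        "removed_indices": removed.tolist(),
        "removed_fraction": float(removed.size / values.size),
        "mean": float(mu),
        "sd": float(sd),
        "k": float(k),
    }
    return values[keep], report


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded permutation of range(n) with no fixed points."""
    if n < 2:
        raise ValueError("need at least 2 items")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def make_pseudo_dyads(dyads: list[tuple], seed: int) -> list[tuple]:
    """Reshuffle participants across dyads into condition-matched null pairs.

    ``dyads`` is a list of ``(dyad_id, member_a, member_b)`` tuples, where the
    member objects are whatever per-participant payload the caller uses
    (motion traces, hemoglobin series, ...).  Each pseudo dyad pairs member A
    of dyad i with member B of a *different* dyad sigma(i) (sigma a seeded
    derangement), so no pseudo pair shares a real dyad and the count of
    pseudo dyads equals the count of real dyads.
    """
    if len(dyads) < 2:
        raise ValueError("pseudo-dyad construction needs at least 2 real dyads")
    rng = np.random.default_rng(seed)
    perm = _derangement(len(dyads), rng)
    out = []
    for i, j in enumerate(perm):
        a_id, a_member, _ = dyads[i]
        b_id, _, b_member = dyads[j]
        out.append((f"pseudo_{a_id}_{b_id}", a_member, b_member))
    return out
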