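"""Morlet wavelet transform coherence (WTC) and ROI-pair coupling.

Squared coherence between two series x, y at time t and scale s:

    R2(t,s) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

with W the analytic-Morlet continuous wavelet transform (omega0 = 6) and S
a smoothing operator composed of a Gaussian in time (sigma = s) followed by
a boxcar over 0.6 octave along the scale axis.  Without smoothing R2 is
identically 1 for any pair, so the smoothing operator is what makes
coherence informative.

Scale-frequency mapping is pinned as f = omega0 / (2 pi s); edge effects are
tracked through the e-folding time sqrt(2)*s (cone of influence), and cells
beyond it never enter band averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .constants import (
    BAND_HI_HZ,
    BAND_LO_HZ,
    FISHER_CLIP,
    MORLET_OMEGA0,
    ROI_LABELS,
    VOICES_PER_OCTAVE,
)
from .design import ChannelLayout, ConditionBlock, ExperimentDesign
from .movement import fisher_z, make_pseudo_dyads
from .preprocess import HemoSeries


def morlet_scales(
    fs: float,
    f_min: float = 0.01,
    f_max: float = 0.5,
    voices: int = VOICES_PER_OCTAVE,
    omega0: float = MORLET_OMEGA0,
) -> np.ndarray:
    """Log-spaced scale grid covering [f_min, f_max], ``voices`` per octave."""
    s_min = omega0 / (2 * np.pi * f_max)
    n_oct = np.log2(f_max / f_min)
    n = int(np.ceil(n_oct * voices)) + 1
    return s_min * 2.0 ** (np.arange(n) / voices)


def scale_to_freq(scales: np.ndarray, omega0: float = MORLET_OMEGA0) -> np.ndarray:
    return omega0 / (2 * np.pi * np.asarray(scales))


def cwt_morlet(
    x: np.ndarray,
    fs: float,
    scales: np.ndarray,
    omega0: float = MORLET_OMEGA0,
) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet mother wavelet.

    FFT implementation with zero padding to the next power of two; returns
    the (n_scales, n_times) complex coefficient matrix.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("input contains NaN/inf")
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    n = x.size
    dt = 1.0 / fs
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xh = np.fft.fft(x - x.mean(), n_pad)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, dt)
    w = np.empty((scales.size, n), dtype=complex)
    pos = omega > 0
    for k, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = (
            np.sqrt(2 * np.pi * s / dt)
            * np.pi**-0.25
            * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        )
        w[k] = np.fft.ifft(xh * psi_hat)[:n]
    return w


def _smooth_time(w: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Gaussian smoothing along time, sigma = s, per scale row; kernel
    renormalized at the edges.  FFT implementation: rows are zero-padded
    past the widest kernel so the circular product acts as a linear
    convolution, and the zero-padding tail is divided out by the smoothed
    indicator (edge renormalization)."""
    from scipy.fft import fft, ifft, next_fast_len

    n = w.shape[1]
    pad = int(np.ceil(4 * scales.max() / dt))
    nfft = next_fast_len(n + pad)
    omega = 2 * np.pi * np.fft.fftfreq(nfft, dt)
    gain = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    sm = ifft(fft(w, nfft, axis=1) * gain, axis=1)[:, :n]
    norm = ifft(fft(np.ones(n), nfft)[None, :] * gain, axis=1)[:, :n].real
    out = sm / norm
    return out if np.iscomplexobj(w) else out.real


def _smooth_scale(w: np.ndarray, voices: int, decorrelation_oct: float = 0.6) -> np.ndarray:
    """Boxcar smoothing over ~0.6 octave along the scale axis."""
    width = max(1, int(round(decorrelation_oct * voices)))
    if width == 1:
        return w.copy()
    kern = np.ones(width) / width
    out = np.empty_like(w)
    norm = np.convolve(np.ones(w.shape[0]), kern, mode="same")
    for j in range(w.shape[1]):
        out[:, j] = np.convolve(w[:, j], kern, mode="same") / norm
    return out


def _smooth(w: np.ndarray, scales: np.ndarray, dt: float, voices: int) -> np.ndarray:
    sm = _smooth_time(w, scales, dt)
    if np.iscomplexobj(sm):
        return _smooth_scale(sm.real, voices) + 1j * _smooth_scale(sm.imag, voices)
    return _smooth_scale(sm, voices)


def coi_max_scale(n: int, fs: float) -> np.ndarray:
    """Largest edge-safe scale per time sample: distance to the nearer edge
    divided by the e-folding time sqrt(2)*s."""
    t = np.arange(n) / fs
    dist = np.minimum(t, t[-1] - t)
    return dist / np.sqrt(2.0)


@dataclass
class WTCResult:
    """Time x frequency squared-coherence surface with COI bookkeeping."""

    freqs: np.ndarray        # Hz, descending with scale index
    times: np.ndarray        # s
    R2: np.ndarray           # (n_times, n_freqs) in [0, 1]
    coi_freq: np.ndarray     # per-time minimum edge-safe frequency (Hz)
    scales: np.ndarray
    fs: float

    def valid_mask(self) -> np.ndarray:
        """(n_times, n_freqs) True where the cell is inside the COI."""
        return self.freqs[None, :] >= self.coi_freq[:, None]


def wtc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    scales: np.ndarray | None = None,
    omega0: float = MORLET_OMEGA0,
    voices: int = VOICES_PER_OCTAVE,
    smoothing: bool = True,
) -> WTCResult:
    """Wavelet transform coherence of two equal-length series.

    ``smoothing=False`` exists only to demonstrate that without the
    smoothing operator R2 is identically 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance series")
    if scales is None:
        scales = morlet_scales(fs)
    wx, sxx = _cwt_auto(x, fs, scales, omega0, voices, smoothing)
    wy, syy = _cwt_auto(y, fs, scales, omega0, voices, smoothing)
    return _wtc_from_cached(
        (wx, sxx), (wy, syy), fs, scales, omega0, voices, smoothing
    )


def _cwt_auto(x, fs, scales, omega0=MORLET_OMEGA0, voices=VOICES_PER_OCTAVE,
              smoothing=True):
    """Per-series half of the coherence computation: the CWT and its
    smoothed autospectrum (reusable across channel pairs)."""
    w = cwt_morlet(x, fs, scales, omega0)
    inv_s = (1.0 / np.asarray(scales))[:, None]
    auto = np.abs(w) ** 2 * inv_s
    if smoothing:
        auto = _smooth(auto, np.asarray(scales), 1.0 / fs, voices)
    return w, auto


def _wtc_from_cached(xc, yc, fs, scales, omega0=MORLET_OMEGA0,
                     voices=VOICES_PER_OCTAVE, smoothing=True) -> WTCResult:
    wx, sxx = xc
    wy, syy = yc
    scales = np.asarray(scales, float)
    inv_s = (1.0 / scales)[:, None]
    sxy = wx * np.conj(wy) * inv_s
    if smoothing:
        sxy = _smooth(sxy, scales, 1.0 / fs, voices)
    r2 = np.clip((np.abs(sxy) ** 2 / (sxx * syy)).real, 0.0, 1.0)

    n = wx.shape[1]
    freqs = scale_to_freq(scales, omega0)
    coi_s = coi_max_scale(n, fs)
    with np.errstate(divide="ignore"):
        coi_freq = np.where(
            coi_s > 0, omega0 / (2 * np.pi * np.maximum(coi_s, 1e-300)), np.inf
        )
    return WTCResult(
        freqs=freqs,
        times=np.arange(n) / fs,
        R2=r2.T,
        coi_freq=coi_freq,
        scales=scales,
        fs=fs,
    )


def band_average(
    res: WTCResult,
    f_lo: float = BAND_LO_HZ,
    f_hi: float = BAND_HI_HZ,
    time_mask: np.ndarray | None = None,
) -> dict:
    """Mean R2 over band cells inside the COI, plus its Fisher z.

    The z convention is arctanh(sqrt(mean R2)) — coherence is a squared
    quantity, so its square root is the correlation-scale value the
    variance-stabilizing transform expects.  Also reports the effective
    band floor: the lowest frequency that actually contributed COI-valid
    cells (at short recordings this sits above ``f_lo``).
    """
    in_band = (res.freqs >= f_lo) & (res.freqs <= f_hi)
    if not np.any(in_band):
        raise ValueError("band does not intersect the scale grid")
    valid = res.valid_mask() & in_band[None, :]
    if time_mask is not None:
        valid &= np.asarray(time_mask, bool)[:, None]
    if not np.any(valid):
        raise ValueError("no COI-valid cells in band")
    mean_r2 = float(res.R2[valid].mean())
    contributing = np.any(valid, axis=0)
    return {
        "band_mean_r2": mean_r2,
        "band_mean_z": float(fisher_z(np.sqrt(np.clip(mean_r2, 0.0, FISHER_CLIP)))),
        "effective_band_floor_hz": float(res.freqs[contributing].min()),
        "n_cells": int(valid.sum()),
    }


# ------------------------------------------------------------ ROI coupling

@dataclass
class CouplingRecord:
    """One (unit, ROI pair, condition) coupling value for the stats stage."""

    scope: str               # between | within
    unit_id: str             # dyad id (between) or participant id (within)
    roi_pair: str            # e.g. "L.IFG-L.IFG"
    condition: str
    group: str               # real | pseudo
    wtc_z: float
    band_mean_r2: float
    n_channel_pairs: int
    effective_band_floor_hz: float


def roi_pair_label(r1: str, r2: str) -> str:
    a, b = sorted([r1, r2], key=ROI_LABELS.index)
    return f"{a}-{b}"


def _block_time_mask(times: np.ndarray, block: ConditionBlock) -> np.ndarray:
    return (times >= block.start_s) & (times < block.stop_s)


def _pair_band_z(xc, yc, fs, blocks, scales, f_lo, f_hi):
    """WTC from cached per-channel transforms; band averages per block."""
    res = _wtc_from_cached(xc, yc, fs, scales)
    out = {}
    for block in blocks:
        mask = _block_time_mask(res.times, block)
        try:
            out[block.condition] = band_average(res, f_lo, f_hi, time_mask=mask)
        except ValueError:
            out[block.condition] = None
    return out


def roi_pair_coupling(
    hemo_a: HemoSeries,
    layout_a: ChannelLayout,
    hemo_b: HemoSeries | None = None,
    layout_b: ChannelLayout | None = None,
    *,
    scope: str = "between",
    blocks: tuple[ConditionBlock, ...] | None = None,
    unit_id: str = "",
    group: str = "real",
    f_lo: float = BAND_LO_HZ,
    f_hi: float = BAND_HI_HZ,
    scales: np.ndarray | None = None,
    homologous_only: bool = False,
) -> list[CouplingRecord]:
    """Aggregate channel-pair WTC into ROI-pair coupling records.

    between scope: every ok-channel pair spanning participant A's ROI r1 and
    participant B's ROI r2 (both orientations for r1 != r2, or homologous
    channel pairs only with ``homologous_only``).  within scope: ok-channel
    pairs spanning two *different* ROIs of one participant — a channel is
    never paired with itself.  WTC is computed once on the full recording;
    cells are assigned to condition blocks by time before band averaging,
    and channel-pair Fisher-z values are averaged per (ROI pair, condition).
    """
    if scope not in ("between", "within"):
        raise ValueError("scope must be 'between' or 'within'")
    if blocks is None:
        blocks = (ConditionBlock("FM", 0.0, hemo_a.hbo.shape[1] / hemo_a.fs),)
    if scales is None:
        scales = morlet_scales(hemo_a.fs)

    def ok_by_roi(hemo, layout):
        out = {}
        ok = set(hemo.ok_indices())
        for i, ch in enumerate(hemo.channel_ids):
            if i not in ok:
                continue
            roi = layout[ch].roi
            if roi in ROI_LABELS:
                out.setdefault(roi, []).append(i)
        return out

    rois_a = ok_by_roi(hemo_a, layout_a)
    if scope == "between":
        if hemo_b is None or layout_b is None:
            raise ValueError("between scope needs both participants")
        rois_b = ok_by_roi(hemo_b, layout_b)
        roi_pairs = list(combinations_with_replacement(ROI_LABELS, 2))
    else:
        hemo_b, layout_b, rois_b = hemo_a, layout_a, rois_a
        roi_pairs = list(combinations_with_replacement(ROI_LABELS, 2))
        roi_pairs = [(a, b) for a, b in roi_pairs if a != b]

    records = []
    cwt_cache: dict = {}
    for r1, r2 in roi_pairs:
        pairs = []
        if scope == "between":
            for i in rois_a.get(r1, []):
                for j in rois_b.get(r2, []):
                    pairs.append((i, j))
            if r1 != r2:
                for i in rois_a.get(r2, []):
                    for j in rois_b.get(r1, []):
                        pairs.append((i, j))
            if homologous_only:
                pairs = [
                    (i, j) for i, j in pairs
                    if hemo_a.channel_ids[i] == hemo_b.channel_ids[j]
                ]
        else:
            for i in rois_a.get(r1, []):
                for j in rois_b.get(r2, []):
                    if i != j:
                        pairs.append((i, j))
        if not pairs:
            warnings.warn(
                f"ROI pair {r1}-{r2}: no usable channel pairs, record dropped"
            )
            continue

        per_cond: dict[str, list[dict]] = {}
        for i, j in pairs:
            key_a, key_b = (id(hemo_a), i), (id(hemo_b), j)
            for key, hemo, idx in ((key_a, hemo_a, i), (key_b, hemo_b, j)):
                if key not in cwt_cache:
                    cwt_cache[key] = _cwt_auto(hemo.hbo[idx], hemo.fs, scales)
            stats = _pair_band_z(
                cwt_cache[key_a], cwt_cache[key_b], hemo_a.fs, blocks,
                scales, f_lo, f_hi,
            )
            for cond, st in stats.items():
                if st is not None:
                    per_cond.setdefault(cond, []).append(st)
        for cond, sts in per_cond.items():
            zs = [s["band_mean_z"] for s in sts]
            records.append(
                CouplingRecord(
                    scope=scope,
                    unit_id=unit_id,
                    roi_pair=roi_pair_label(r1, r2),
                    condition=cond,
                    group=group,
                    wtc_z=float(np.mean(zs)),
                    band_mean_r2=float(np.mean([s["band_mean_r2"] for s in sts])),
                    n_channel_pairs=len(sts),
                    effective_band_floor_hz=float(
                        np.max([s["effective_band_floor_hz"] for s in sts])
                    ),
                )
            )
    return records


def pseudo_coupling(
    dyads: list[tuple[str, tuple[HemoSeries, ChannelLayout], tuple[HemoSeries, ChannelLayout]]],
    seed: int,
    *,
    blocks: tuple[ConditionBlock, ...] | None = None,
    **kwargs,
) -> list[CouplingRecord]:
    """Between-brain coupling for condition-matched pseudo pairings.

    ``dyads`` holds (dyad_id, (hemoA, layoutA), (hemoB, layoutB)) per real
    dyad; the same seeded derangement used for behavioral pseudo dyads
    re-pairs the recordings.
    """
    records = []
    for pid, (hemo_a, lay_a), (hemo_b, lay_b) in make_pseudo_dyads(dyads, seed):
        records += roi_pair_coupling(
            hemo_a, lay_a, hemo_b, lay_b,
            scope="between", blocks=blocks, unit_id=pid, group="pseudo",
            **kwargs,
        )
    return records


def records_to_frame(records: list[CouplingRecord]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])
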