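"""Synthetic dyadic recordings with known ground-truth coupling.

Movement: each participant's 3D hand velocity is an Ornstein-Uhlenbeck
process (smooth, non-repetitive, unpredictable — rhythmic sinusoids would
trivially inflate the cosine synchrony statistic).  Coupling strength kappa
mixes a delayed copy of partner A's velocity into partner B's, in velocity
space, because the synchrony statistic is a velocity statistic.

fNIRS: per-channel hemodynamic signals are band-limited (0.015-0.15 Hz)
Gaussian processes with a tunable shared component between selected channel
pairs, plus physiological oscillations (cardiac ~1.2 Hz, respiration
~0.25 Hz, Mayer waves ~0.1 Hz), an optional spatially-global scalp process,
and spike artifacts.  Concentrations are converted to two-wavelength
intensities by inverting the same modified Beer-Lambert operator the
preprocessing stage applies, so the pipeline can recover them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .constants import (
    BAND_HI_HZ,
    BAND_LO_HZ,
    DPF,
    EXTINCTION,
    MOTION_FS,
    NIRS_FS,
    OPTODE_SEPARATION_CM,
    ROI_LABELS,
    WAVELENGTHS,
)
from .design import (
    Channel,
    ChannelLayout,
    ConditionBlock,
    ExperimentDesign,
    MotionTrace,
    RawNIRS,
)


@dataclass
class MotionSimConfig:
    """Parameters of the coupled-velocity movement simulator."""

    fs: float = MOTION_FS
    duration_s: float = 120.0
    coupling: float = 0.0        # kappa in [0, 1]
    lag_ms: float = 0.0          # B trails A by this much; |lag| <= 750
    tau_s: float = 0.25          # OU time constant (movement smoothness)
    speed_scale: float = 1.0     # stationary velocity SD, units/s
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if abs(self.lag_ms) > 750.0:
            raise ValueError("|lag_ms| must be <= 750")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


def _ou_velocity(n: int, fs: float, tau: float, scale: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary 3D OU process, exact discretization."""
    dt = 1.0 / fs
    a = np.exp(-dt / tau)
    sig = scale * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal((n, 3))
    v = np.empty((n, 3))
    v[0] = scale * rng.standard_normal(3)
    for k in range(1, n):
        v[k] = a * v[k - 1] + sig * eps[k]
    return v


def simulate_dyad_motion(cfg: MotionSimConfig) -> tuple[MotionTrace, MotionTrace]:
    """Coupled pair of 3D movement traces.

    B's velocity = kappa * (A's velocity delayed by lag_ms)
                 + (1 - kappa) * independent OU process.
    Both velocity fields are integrated to positions.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    pad = int(np.ceil(abs(cfg.lag_ms) / 1000.0 * cfg.fs)) + 2

    vA_full = _ou_velocity(n + 2 * pad, cfg.fs, cfg.tau_s, cfg.speed_scale, rng)
    vB_ind = _ou_velocity(n, cfg.fs, cfg.tau_s, cfg.speed_scale, rng)

    t_full = np.arange(n + 2 * pad) / cfg.fs
    t_out = np.arange(n) / cfg.fs + pad / cfg.fs
    vA = np.column_stack(
        [np.interp(t_out, t_full, vA_full[:, ax]) for ax in range(3)]
    )
    # B at t copies A at t - lag  (B trails A for positive lag)
    t_lagged = t_out - cfg.lag_ms / 1000.0
    vA_delayed = np.column_stack(
        [np.interp(t_lagged, t_full, vA_full[:, ax]) for ax in range(3)]
    )
    vB = cfg.coupling * vA_delayed + (1.0 - cfg.coupling) * vB_ind

    dt = 1.0 / cfg.fs
    posA = np.vstack([np.zeros(3), np.cumsum(vA, axis=0) * dt])
    posB = np.vstack([np.zeros(3), np.cumsum(vB, axis=0) * dt])
    return (
        MotionTrace("A", "FM", cfg.fs, posA),
        MotionTrace("B", "FM", cfg.fs, posB),
    )


# ------------------------------------------------------------------- fNIRS

@dataclass
class NIRSSimConfig:
    """Parameters of the dual-brain fNIRS simulator.

    Amplitudes are in uM of oxyhemoglobin change; the band-limited
    functional signal has unit SD.
    """

    fs: float = NIRS_FS
    duration_s: float = 120.0
    band: tuple[float, float] = (BAND_LO_HZ, BAND_HI_HZ)
    cardiac_hz: float = 1.2
    cardiac_amp: float = 0.3
    resp_hz: float = 0.25
    resp_amp: float = 0.15
    mayer_hz: float = 0.1
    mayer_amp: float = 0.15
    scalp_amp: float = 0.0       # g, global scalp component amplitude
    spike_rate_per_min: float = 0.0
    spike_amp: float = 5.0
    hbr_ratio: float = -0.3      # HHb tracks HbO with this factor
    dpf: dict = field(default_factory=lambda: dict(DPF))
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("fs and duration must be positive")
        for a in (self.cardiac_amp, self.resp_amp, self.mayer_amp,
                  self.scalp_amp, self.spike_amp):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")


def band_limited_noise(n: int, fs: float, f_lo: float, f_hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian process with support restricted to [f_lo, f_hi],
    synthesized in the frequency domain (random phases, flat in-band)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("band contains no Fourier bins at this length")
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spikes(n: int, fs: float, rate_per_min: float, amp: float,
            rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    n_spk = rng.poisson(rate_per_min * (n / fs) / 60.0)
    t = np.arange(n) / fs
    for _ in range(n_spk):
        t0 = rng.uniform(0, n / fs)
        sign = rng.choice([-1.0, 1.0])
        out += sign * amp * np.exp(-np.abs(t - t0) / 0.2)
    return out


def concentration_to_intensity(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    separation_cm: np.ndarray,
    dpf: dict = DPF,
    extinction: np.ndarray = EXTINCTION,
    wavelengths: tuple = WAVELENGTHS,
    baseline: float = 1.0,
) -> np.ndarray:
    """Invert the modified Beer-Lambert law: (ch, t) concentrations in uM
    -> (ch, wl, t) detector intensities around ``baseline``."""
    conc_mm = np.stack([hbo_um, hbr_um], axis=1) / 1000.0  # (ch, 2, t)
    n_ch = conc_mm.shape[0]
    od = np.einsum("wc,nct->nwt", extinction, conc_mm)
    dpf_vec = np.array([dpf[wl] for wl in wavelengths])
    od *= separation_cm.reshape(n_ch, 1, 1) * dpf_vec.reshape(1, -1, 1)
    return baseline * 10.0 ** (-od)


def simulate_dyad_nirs(
    cfg: NIRSSimConfig,
    layout: ChannelLayout,
    pair_plan: dict[tuple[str, str], float] | None = None,
) -> tuple[RawNIRS, RawNIRS, dict]:
    """Two participants' raw intensity recordings with planned coupling.

    ``pair_plan`` maps (channel_of_A, channel_of_B) -> rho in [0, 1]: the
    fraction of in-band variance those two channels share.  Channels not in
    the plan carry fully independent in-band signal.  Returns (rawA, rawB,
    truth) where ``truth`` holds the ground-truth concentration series and
    shared/global components for parameter-recovery tests.
    """
    pair_plan = dict(pair_plan or {})
    ids = layout.channel_ids
    for (ca, cb), rho in pair_plan.items():
        if ca not in ids or cb not in ids:
            raise KeyError(f"pair plan references unknown channel ({ca}, {cb})")
        if not 0.0 <= rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")

    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    f_lo, f_hi = cfg.band

    shared = {
        pair: band_limited_noise(n, cfg.fs, f_lo, f_hi, rng)
        for pair in pair_plan
    }
    # channel -> (shared series, rho); first plan entry wins per channel
    plan_a: dict[str, tuple[np.ndarray, float]] = {}
    plan_b: dict[str, tuple[np.ndarray, float]] = {}
    for (ca, cb), rho in pair_plan.items():
        plan_a.setdefault(ca, (shared[(ca, cb)], rho))
        plan_b.setdefault(cb, (shared[(ca, cb)], rho))

    truth = {"shared": shared, "hbo": {}, "scalp": {}}
    raws = []
    for side, plan in (("A", plan_a), ("B", plan_b)):
        scalp = band_limited_noise(n, cfg.fs, f_lo, f_hi, rng)
        truth["scalp"][side] = scalp
        cardiac_ph, resp_ph, mayer_ph = rng.uniform(0, 2 * np.pi, 3)
        hbo = np.empty((len(ids), n))
        for i, ch in enumerate(ids):
            series, rho = plan.get(ch, (None, 0.0))
            func = np.sqrt(1.0 - rho) * band_limited_noise(n, cfg.fs, f_lo, f_hi, rng)
            if series is not None:
                func = func + np.sqrt(rho) * series
            physio = (
                cfg.cardiac_amp * np.sin(2 * np.pi * cfg.cardiac_hz * t + cardiac_ph)
                + cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_hz * t + resp_ph)
                + cfg.mayer_amp * np.sin(2 * np.pi * cfg.mayer_hz * t + mayer_ph)
            )
            hbo[i] = (
                func
                + physio
                + cfg.scalp_amp * scalp
                + _spikes(n, cfg.fs, cfg.spike_rate_per_min, cfg.spike_amp, rng)
            )
        hbr = cfg.hbr_ratio * hbo + 0.1 * rng.standard_normal(hbo.shape)
        truth["hbo"][side] = hbo
        sep = np.array([c.separation_cm for c in layout.channels])
        intensity = concentration_to_intensity(
            hbo, hbr, sep, dpf=cfg.dpf,
        )
        raws.append(
            RawNIRS(
                participant_id=side,
                fs=cfg.fs,
                intensity=intensity,
                wavelengths=WAVELENGTHS,
                channel_ids=list(ids),
            )
        )
    return raws[0], raws[1], truth


# ------------------------------------------------------------ full dataset

def default_layout(n_per_roi: int = 8, jitter_seed: int = 12345) -> ChannelLayout:
    """Synthetic 23-channel (or 3*n-1) prefrontal layout: three clusters for
    L.IFG, dmPFC, R.IFG with a nominal 3.5 cm source-detector separation.
    This geometry is illustrative, not a reconstruction of any headcap."""
    rng = np.random.default_rng(jitter_seed)
    centers = {"L.IFG": (-7.0, 5.0, 2.0), "dmPFC": (0.0, 8.5, 5.0),
               "R.IFG": (7.0, 5.0, 2.0)}
    counts = {"L.IFG": n_per_roi, "dmPFC": n_per_roi - 1, "R.IFG": n_per_roi}
    channels = []
    k = 0
    for roi in ROI_LABELS:
        cx, cy, cz = centers[roi]
        for j in range(counts[roi]):
            k += 1
            mid = np.array(
                [cx + 2.0 * (j % 3 - 1), cy + 2.0 * (j // 3 - 1), cz]
            ) + rng.normal(0, 0.15, 3)
            offset = np.array([OPTODE_SEPARATION_CM / 2, 0.0, 0.0])
            channels.append(
                Channel(f"ch{k}", mid - offset, mid + offset, roi=roi)
            )
    return ChannelLayout(channels)


def default_design(dyad_id: str, pid_a: str, pid_b: str,
                   block_s: float = 120.0) -> ExperimentDesign:
    """Contiguous BB -> FM -> IS session of three equal blocks."""
    return ExperimentDesign(
        dyad_id=dyad_id,
        participant_ids=(pid_a, pid_b),
        condition_blocks=(
            ConditionBlock("BB", 0.0, block_s),
            ConditionBlock("FM", block_s, block_s),
            ConditionBlock("IS", 2 * block_s, block_s),
        ),
    )


def simulate_experiment(
    out_dir: str | os.PathLike,
    n_dyads: int,
    *,
    kappa: dict[str, float] | None = None,
    rho: dict[str, float] | None = None,
    lag_ms: float = 0.0,
    block_s: float = 120.0,
    layout: ChannelLayout | None = None,
    n_coupled_pairs: int = 4,
    motion_cfg: MotionSimConfig | None = None,
    nirs_cfg: NIRSSimConfig | None = None,
    seed: int = 0,
) -> dict:
    """Write a complete on-disk dataset in the interchange formats.

    Per condition, movement coupling ``kappa[cond]`` and fNIRS shared-signal
    weight ``rho[cond]`` are applied; the baseline BB condition defaults to
    zero coupling.  ``n_coupled_pairs`` homologous channel pairs receive the
    shared fNIRS component.  Same seed -> byte-identical files.
    """
    if n_dyads < 2:
        raise ValueError("need n_dyads >= 2 (pseudo-dyad construction)")
    kappa = {"BB": 0.0, "FM": 0.0, "IS": 0.8, **(kappa or {})}
    rho = {"BB": 0.0, "FM": 0.3, "IS": 0.6, **(rho or {})}
    layout = layout or default_layout()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dio.write_layout(out / "layout.csv", layout)
    pairs = [(ch, ch) for ch in layout.channel_ids[:n_coupled_pairs]]

    design_rows = []
    manifest = {"designs": [], "motion": [], "nirs": [], "layout": str(out / "layout.csv")}
    root = np.random.default_rng(seed)
    for d in range(n_dyads):
        dyad_id = f"dyad{d + 1:02d}"
        pid_a, pid_b = f"{dyad_id}_p1", f"{dyad_id}_p2"
        design = default_design(dyad_id, pid_a, pid_b, block_s)
        manifest["designs"].append(design)

        traces = []
        nirs_blocks = {"A": [], "B": []}
        for block in design.condition_blocks:
            mseed, nseed = root.integers(0, 2**31 - 1, 2)
            mcfg = motion_cfg or MotionSimConfig()
            mcfg = MotionSimConfig(
                fs=mcfg.fs, duration_s=block.duration_s,
                coupling=kappa[block.condition], lag_ms=lag_ms,
                tau_s=mcfg.tau_s, speed_scale=mcfg.speed_scale, seed=int(mseed),
            )
            tr_a, tr_b = simulate_dyad_motion(mcfg)
            tr_a.participant_id, tr_b.participant_id = pid_a, pid_b
            tr_a.condition = tr_b.condition = block.condition
            traces += [tr_a, tr_b]

            ncfg = nirs_cfg or NIRSSimConfig()
            ncfg = NIRSSimConfig(
                fs=ncfg.fs, duration_s=block.duration_s, band=ncfg.band,
                cardiac_hz=ncfg.cardiac_hz, cardiac_amp=ncfg.cardiac_amp,
                resp_hz=ncfg.resp_hz, resp_amp=ncfg.resp_amp,
                mayer_hz=ncfg.mayer_hz, mayer_amp=ncfg.mayer_amp,
                scalp_amp=ncfg.scalp_amp,
                spike_rate_per_min=ncfg.spike_rate_per_min,
                spike_amp=ncfg.spike_amp, seed=int(nseed),
            )
            plan = {p: rho[block.condition] for p in pairs}
            raw_a, raw_b, _ = simulate_dyad_nirs(ncfg, layout, plan)
            nirs_blocks["A"].append(raw_a.intensity)
            nirs_blocks["B"].append(raw_b.intensity)

        mpath = out / f"motion_{dyad_id}.csv"
        dio.write_motion(mpath, traces, design)
        manifest["motion"].append(str(mpath))

        for side, pid in (("A", pid_a), ("B", pid_b)):
            raw = RawNIRS(
                participant_id=pid,
                fs=(nirs_cfg or NIRSSimConfig()).fs,
                intensity=np.concatenate(nirs_blocks[side], axis=2),
                channel_ids=layout.channel_ids,
            )
            npath = out / f"nirs_{pid}.snirf"
            dio.write_snirf(npath, raw, layout)
            manifest["nirs"].append(str(npath))

        for block in design.condition_blocks:
            design_rows.append(
                dict(dyad=dyad_id, participant_a=pid_a, participant_b=pid_b,
                     condition=block.condition, start_s=block.start_s,
                     duration_s=block.duration_s, group="real")
            )
    pd.DataFrame(design_rows).to_csv(out / "designs.csv", index=False)
    manifest["designs_csv"] = str(out / "designs.csv")
    return manifest
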