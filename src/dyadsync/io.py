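"""Readers and writers for the on-disk interchange formats.

Movement: CSV with header ``time,participant,condition,x,y,z``.
fNIRS: SNIRF (HDF5) written through h5py, or a plain CSV fallback with
header ``time,channel,wavelength,intensity``.
Layout/ROI: CSV ``channel,source_x,...,detector_z,roi``.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .constants import CONDITIONS, ROI_NONE
from .design import (
    Channel,
    ChannelLayout,
    ExperimentDesign,
    MotionTrace,
    RawNIRS,
    check_uniform,
)

MOTION_COLUMNS = ["time", "participant", "condition", "x", "y", "z"]


# ---------------------------------------------------------------- movement

def read_motion(path: str | os.PathLike, design: ExperimentDesign) -> list[MotionTrace]:
    """Load a motion CSV and cut it into per-participant condition blocks.

    Returns one :class:`MotionTrace` per participant x condition block in
    ``design``.  The file must already be uniformly sampled; gaps raise
    instead of being repaired by resampling.
    """
    df = pd.read_csv(path)
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    bad = set(df["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")

    traces = []
    for pid in design.participant_ids:
        sub_p = df[df["participant"] == pid]
        if sub_p.empty:
            raise ValueError(f"participant {pid!r} not present in file")
        for block in design.condition_blocks:
            sub = sub_p[
                (sub_p["condition"] == block.condition)
                & (sub_p["time"] >= block.start_s - 1e-9)
                & (sub_p["time"] < block.stop_s - 1e-9)
            ].sort_values("time")
            if sub.empty:
                raise ValueError(
                    f"empty block: {pid}/{block.condition}"
                )
            t = sub["time"].to_numpy(float)
            fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 0.0
            check_uniform(t, fs)
            traces.append(
                MotionTrace(
                    participant_id=pid,
                    condition=block.condition,
                    fs=fs,
                    pos=sub[["x", "y", "z"]].to_numpy(float),
                )
            )
    return traces


def write_motion(
    path: str | os.PathLike,
    traces: Iterable[MotionTrace],
    design: ExperimentDesign,
) -> None:
    """Write traces back to the movement CSV, restoring absolute block times."""
    frames = []
    for tr in traces:
        block = design.block(tr.condition)
        frames.append(
            pd.DataFrame(
                {
                    "time": block.start_s + tr.t,
                    "participant": tr.participant_id,
                    "condition": tr.condition,
                    "x": tr.pos[:, 0],
                    "y": tr.pos[:, 1],
                    "z": tr.pos[:, 2],
                }
            )
        )
    pd.concat(frames).sort_values(["time", "participant"]).to_csv(path, index=False)


# ------------------------------------------------------------------ layout

LAYOUT_COLUMNS = [
    "channel",
    "source_x", "source_y", "source_z",
    "detector_x", "detector_y", "detector_z",
    "roi",
]


def read_layout(path: str | os.PathLike) -> ChannelLayout:
    df = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    channels = [
        Channel(
            channel_id=str(r["channel"]),
            source_pos=[r["source_x"], r["source_y"], r["source_z"]],
            detector_pos=[r["detector_x"], r["detector_y"], r["detector_z"]],
            roi=str(r["roi"]) if pd.notna(r["roi"]) else ROI_NONE,
        )
        for _, r in df.iterrows()
    ]
    return ChannelLayout(channels)


def write_layout(path: str | os.PathLike, layout: ChannelLayout) -> None:
    rows = []
    for c in layout.channels:
        rows.append(
            dict(
                channel=c.channel_id,
                source_x=c.source_pos[0], source_y=c.source_pos[1],
                source_z=c.source_pos[2],
                detector_x=c.detector_pos[0], detector_y=c.detector_pos[1],
                detector_z=c.detector_pos[2],
                roi=c.roi,
            )
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


# ------------------------------------------------------------------- SNIRF

def write_snirf(
    path: str | os.PathLike,
    raw: RawNIRS,
    layout: ChannelLayout | None = None,
) -> None:
    """Write a minimal continuous-wave SNIRF file (one source-detector pair
    per channel, two wavelengths)."""
    n_ch, n_wl, n_t = raw.intensity.shape

    def _ds(group, name, data, **kw):
        # track_times=False keeps same-seed outputs byte-identical
        return group.create_dataset(name, data=data, track_times=False, **kw)

    with h5py.File(path, "w") as f:
        _ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _ds(meta, "SubjectID", data=raw.participant_id)
        _ds(meta, "MeasurementDate", data="unknown")
        _ds(meta, "MeasurementTime", data="unknown")
        _ds(meta, "LengthUnit", data="cm")
        _ds(meta, "TimeUnit", data="s")
        _ds(meta, "FrequencyUnit", data="Hz")

        probe = nirs.create_group("probe")
        _ds(probe, "wavelengths", data=np.asarray(raw.wavelengths))
        if layout is not None:
            _ds(probe, "sourcePos3D", data=np.stack(
                [c.source_pos for c in layout.channels]))
            _ds(probe, "detectorPos3D", data=np.stack(
                [c.detector_pos for c in layout.channels]))
            _ds(probe, 
                "channelLabels",
                data=np.array(layout.channel_ids, dtype=object),
                dtype=h5py.string_dtype(),
            )
            _ds(probe, 
                "roiLabels",
                data=np.array([c.roi for c in layout.channels], dtype=object),
                dtype=h5py.string_dtype(),
            )
        else:
            _ds(probe, 
                "channelLabels",
                data=np.array(list(raw.channel_ids), dtype=object),
                dtype=h5py.string_dtype(),
            )

        data = nirs.create_group("data1")
        # columns ordered channel-major, wavelength-minor
        dts = raw.intensity.reshape(n_ch * n_wl, n_t).T
        _ds(data, "dataTimeSeries", data=dts)
        _ds(data, "time", data=np.arange(n_t) / raw.fs)
        k = 0
        for i in range(n_ch):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{k + 1}")
                _ds(ml, "sourceIndex", data=i + 1)
                _ds(ml, "detectorIndex", data=i + 1)
                _ds(ml, "wavelengthIndex", data=w + 1)
                _ds(ml, "dataType", data=1)  # CW amplitude
                _ds(ml, "dataTypeIndex", data=1)
                k += 1


def read_snirf(path: str | os.PathLike) -> tuple[RawNIRS, ChannelLayout | None]:
    """Read back a SNIRF file written by :func:`write_snirf`.

    Channels without layout metadata come back with ``layout=None``; channels
    without an ROI tag get roi='none'.
    """
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        t = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(t)))
        dts = np.asarray(data["dataTimeSeries"])  # (time, measurements)
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        )
        src = [int(np.asarray(data[m]["sourceIndex"])) for m in ml_names]
        wli = [int(np.asarray(data[m]["wavelengthIndex"])) for m in ml_names]
        n_ch = max(src)
        n_wl = len(wavelengths)
        if sorted(set(wli)) != list(range(1, n_wl + 1)):
            raise ValueError("missing wavelength in measurement list")
        intensity = np.empty((n_ch, n_wl, dts.shape[0]))
        intensity[:] = np.nan
        for col, m in enumerate(ml_names):
            intensity[src[col] - 1, wli[col] - 1, :] = dts[:, col]
        if np.any(np.isnan(intensity)):
            raise ValueError("missing wavelength for some channel")

        probe = nirs["probe"]
        subject = nirs["metaDataTags"]["SubjectID"][()]
        if isinstance(subject, bytes):
            subject = subject.decode()
        if "channelLabels" in probe:
            ch_ids = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in probe["channelLabels"][()]
            ]
        else:
            ch_ids = [f"ch{i + 1}" for i in range(n_ch)]

        layout = None
        if "sourcePos3D" in probe and "detectorPos3D" in probe:
            spos = np.asarray(probe["sourcePos3D"])
            dpos = np.asarray(probe["detectorPos3D"])
            rois = (
                [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in probe["roiLabels"][()]
                ]
                if "roiLabels" in probe
                else [ROI_NONE] * n_ch
            )
            layout = ChannelLayout(
                [
                    Channel(ch_ids[i], spos[i], dpos[i], rois[i])
                    for i in range(n_ch)
                ]
            )

    raw = RawNIRS(
        participant_id=str(subject),
        fs=fs,
        intensity=intensity,
        wavelengths=wavelengths,
        channel_ids=ch_ids,
    )
    return raw, layout


# -------------------------------------------------------- CSV fNIRS fallback

def write_nirs_csv(path: str | os.PathLike, raw: RawNIRS) -> None:
    n_ch, n_wl, n_t = raw.intensity.shape
    t = np.arange(n_t) / raw.fs
    rows = {
        "time": np.tile(t, n_ch * n_wl),
        "channel": np.repeat(list(raw.channel_ids), n_wl * n_t),
        "wavelength": np.tile(np.repeat(raw.wavelengths, n_t), n_ch),
        "intensity": raw.intensity.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nirs_csv(path: str | os.PathLike, participant_id: str = "unknown") -> RawNIRS:
    df = pd.read_csv(path)
    for c in ("time", "channel", "wavelength", "intensity"):
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
    channels = list(dict.fromkeys(df["channel"]))  # preserve order
    wavelengths = tuple(sorted(df["wavelength"].unique()))
    t = np.sort(df["time"].unique())
    fs = 1.0 / float(np.median(np.diff(t)))
    intensity = np.empty((len(channels), len(wavelengths), len(t)))
    intensity[:] = np.nan
    for (ch, wl), grp in df.groupby(["channel", "wavelength"]):
        i = channels.index(ch)
        w = wavelengths.index(wl)
        intensity[i, w, :] = grp.sort_values("time")["intensity"].to_numpy()
    if np.any(np.isnan(intensity)):
        raise ValueError("missing wavelength for some channel")
    return RawNIRS(
        participant_id=participant_id,
        fs=fs,
        intensity=intensity,
        wavelengths=wavelengths,
        channel_ids=[str(c) for c in channels],
    )


def read_nirs(path: str | os.PathLike) -> tuple[RawNIRS, ChannelLayout | None]:
    """Dispatch on extension: ``.snirf``/``.h5`` -> SNIRF, else CSV."""
    p = str(path)
    if p.endswith((".snirf", ".h5", ".hdf5")):
        return read_snirf(path)
    return read_nirs_csv(path), None
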