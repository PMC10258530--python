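"""Core data containers: experiment design, motion traces, optode layout,
raw two-wavelength fNIRS recordings.

Time convention: after a block is cut out of a recording, its timestamps are
block-relative, ``t[k] = k / fs``.  Every downstream lag and window
computation is therefore expressed in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import CONDITIONS, ROI_LABELS, ROI_NONE, WAVELENGTHS

#: relative tolerance on sample-interval uniformity
_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class ConditionBlock:
    condition: str
    start_s: float
    duration_s: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition label {self.condition!r}")
        if self.duration_s <= 0:
            raise ValueError("block duration must be positive")

    @property
    def stop_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ExperimentDesign:
    """One dyad's session: who took part and when each condition ran."""

    dyad_id: str
    participant_ids: tuple[str, str]
    condition_blocks: tuple[ConditionBlock, ...]
    group: str = "real"

    def __post_init__(self):
        if len(self.participant_ids) != 2:
            raise ValueError("a dyad has exactly 2 participants")
        if self.group not in ("real", "pseudo"):
            raise ValueError("group must be 'real' or 'pseudo'")
        blocks = sorted(self.condition_blocks, key=lambda b: b.start_s)
        for a, b in zip(blocks, blocks[1:]):
            if b.start_s < a.stop_s:
                raise ValueError(
                    f"condition blocks overlap: {a.condition} and {b.condition}"
                )
        object.__setattr__(self, "condition_blocks", tuple(blocks))

    def block(self, condition: str) -> ConditionBlock:
        for b in self.condition_blocks:
            if b.condition == condition:
                return b
        raise KeyError(condition)


@dataclass
class MotionTrace:
    """One participant's 3D hand position during one condition block.

    Axes: x runs along the line between the participants (forward/backward),
    y is the perpendicular horizontal axis (right/left), z is vertical.
    Positions are in device length units; ``fs`` in Hz.
    """

    participant_id: str
    condition: str
    fs: float
    pos: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("pos must be an (n, 3) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


def check_uniform(t: np.ndarray, fs: float) -> None:
    """Raise if timestamps deviate from a uniform 1/fs grid."""
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        return
    dt = np.diff(t)
    if not np.allclose(dt, 1.0 / fs, rtol=_UNIFORM_RTOL, atol=_UNIFORM_RTOL / fs):
        raise ValueError("non-uniform sampling")


@dataclass
class Channel:
    channel_id: str
    source_pos: np.ndarray  # (3,) scalp coordinates, cm
    detector_pos: np.ndarray
    roi: str = ROI_NONE

    def __post_init__(self):
        self.source_pos = np.asarray(self.source_pos, dtype=float)
        self.detector_pos = np.asarray(self.detector_pos, dtype=float)
        if self.roi not in ROI_LABELS + (ROI_NONE,):
            raise ValueError(f"unknown ROI label {self.roi!r}")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.source_pos + self.detector_pos)

    @property
    def separation_cm(self) -> float:
        d = float(np.linalg.norm(self.detector_pos - self.source_pos))
        if d <= 0:
            raise ValueError(f"channel {self.channel_id}: separation must be > 0")
        return d


@dataclass
class ChannelLayout:
    """Scalp geometry and ROI membership of a participant's channels."""

    channels: list[Channel]

    def __post_init__(self):
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def __getitem__(self, channel_id: str) -> Channel:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)

    def midpoints(self) -> np.ndarray:
        return np.stack([c.midpoint for c in self.channels])

    def roi_channels(self, roi: str) -> list[str]:
        return [c.channel_id for c in self.channels if c.roi == roi]

    def with_rois(self, roi_map: dict[str, str]) -> "ChannelLayout":
        """Return a copy with ROI labels taken from ``roi_map``.

        Channels absent from the map get roi='none' and are excluded from all
        coupling computations downstream.  Unknown ROI labels and unknown
        channel ids are errors (closed vocabulary).
        """
        known = set(self.channel_ids)
        for ch_id, roi in roi_map.items():
            if ch_id not in known:
                raise KeyError(f"channel {ch_id!r} not in layout")
            if roi not in ROI_LABELS:
                raise ValueError(f"unknown ROI label {roi!r}")
        new = [
            replace(c, roi=roi_map.get(c.channel_id, ROI_NONE))
            for c in self.channels
        ]
        return ChannelLayout(new)


def assign_rois(layout: ChannelLayout, roi_map: dict[str, str]) -> ChannelLayout:
    """Functional alias for :meth:`ChannelLayout.with_rois`."""
    return layout.with_rois(roi_map)


@dataclass
class RawNIRS:
    """Raw detector intensities: channels x wavelengths x time, > 0."""

    participant_id: str
    fs: float
    intensity: np.ndarray  # (n_channels, n_wavelengths, n_times)
    wavelengths: tuple[float, float] = WAVELENGTHS
    channel_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, time)")
        if self.intensity.shape[1] != len(self.wavelengths):
            raise ValueError("one intensity slab per wavelength is required")
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity <= 0):
            raise ValueError("intensities must be finite and strictly positive")
        if not self.channel_ids:
            self.channel_ids = [
                f"ch{i + 1}" for i in range(self.intensity.shape[0])
            ]
        if len(self.channel_ids) != self.intensity.shape[0]:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    def slice_block(self, block: ConditionBlock) -> "RawNIRS":
        i0 = int(round(block.start_s * self.fs))
        i1 = int(round(block.stop_s * self.fs))
        if i1 > self.n_times:
            raise ValueError("block extends past the recording")
        if i1 <= i0:
            raise ValueError("empty block")
        return RawNIRS(
            participant_id=self.participant_id,
            fs=self.fs,
            intensity=self.intensity[:, :, i0:i1].copy(),
            wavelengths=self.wavelengths,
            channel_ids=list(self.channel_ids),
        )
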