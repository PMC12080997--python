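"""Frame timing, framewise DVR-1 binding potential, detrending, static uptake.

Dynamic reference-tissue PET acquired under a bolus-plus-constant-infusion
protocol reaches a binding equilibrium at which the distribution volume
ratio of a target region equals the instantaneous activity ratio against
the reference tissue. The non-displaceable binding potential is then

    BP_ND = DVR - 1 = C_target(t) / C_reference(t) - 1

evaluated frame by frame, which turns an 80-min dynamic scan into a
region x frame BP_ND time series — the substrate of molecular
connectivity. Early perfusion-dominated frames are discarded and residual
uptake drift is removed with a piecewise-linear detrend before any
correlation is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas import REFERENCE_ID

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "RegionalTimeSeries",
    "BPSeries",
    "StaticImage",
    "framewise_bpnd",
    "discard_and_detrend",
    "static_uptake",
]


@dataclass
class FrameSchedule:
    """PET frame timing in minutes."""

    start_min: np.ndarray
    duration_min: np.ndarray

    def __post_init__(self):
        self.start_min = np.asarray(self.start_min, dtype=float)
        self.duration_min = np.asarray(self.duration_min, dtype=float)
        if self.start_min.shape != self.duration_min.shape:
            raise ValueError("start and duration lists differ in length")
        if np.any(self.duration_min <= 0):
            raise ValueError("frame durations must be positive")
        ends = self.start_min + self.duration_min
        if np.any(np.diff(self.start_min) <= 0) or np.any(self.start_min[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must be strictly increasing and non-overlapping")

    @classmethod
    def uniform(cls, n_frames: int, frame_min: float = 1.0, start: float = 0.0) -> "FrameSchedule":
        starts = start + frame_min * np.arange(n_frames)
        return cls(starts, np.full(n_frames, frame_min))

    @property
    def n_frames(self) -> int:
        return len(self.start_min)

    @property
    def mid_min(self) -> np.ndarray:
        return self.start_min + self.duration_min / 2

    @property
    def end_min(self) -> float:
        return float(self.start_min[-1] + self.duration_min[-1])

    def frames_in_window(self, window_min: tuple[float, float]) -> np.ndarray:
        """Indices of frames whose midpoints lie in the half-open [start, end)."""
        lo, hi = window_min
        return np.nonzero((self.mid_min >= lo) & (self.mid_min < hi))[0]


@dataclass
class DynamicImage:
    """A 4D image series: PET (with a FrameSchedule) or BOLD (with a TR)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    modality: str  # "PET" | "BOLD"
    timing: FrameSchedule | None = None
    repetition_time_s: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dynamic image contains non-finite intensities")
        if self.modality == "PET":
            if self.timing is None:
                raise ValueError("PET image requires a FrameSchedule")
            if self.timing.n_frames != self.data.shape[3]:
                raise ValueError("frame schedule length does not match 4th dimension")
        elif self.modality == "BOLD":
            if self.repetition_time_s is None:
                raise ValueError("BOLD image requires repetition_time_s")
        else:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_mid_min(self) -> np.ndarray:
        if self.modality == "PET":
            return self.timing.mid_min
        tr_min = self.repetition_time_s / 60.0
        return tr_min * (np.arange(self.n_frames) + 0.5)


@dataclass
class RegionalTimeSeries:
    """Region x frame mean-signal matrix with its time axis."""

    values: np.ndarray
    region_ids: list[str]
    frame_mid_min: np.ndarray
    modality: str = "PET"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_mid_min = np.asarray(self.frame_mid_min, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be region x frame")
        if self.values.shape[0] != len(self.region_ids):
            raise ValueError("row count does not match region_ids")
        if self.values.shape[1] != len(self.frame_mid_min):
            raise ValueError("column count does not match frame_mid_min")
        if np.any(np.diff(self.frame_mid_min) <= 0):
            raise ValueError("frame_mid_min must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def row(self, region_id: str) -> np.ndarray:
        return self.values[self.region_ids.index(region_id)]

    def window(self, window_min: tuple[float, float]) -> "RegionalTimeSeries":
        lo, hi = window_min
        keep = (self.frame_mid_min >= lo) & (self.frame_mid_min < hi)
        return RegionalTimeSeries(self.values[:, keep], list(self.region_ids),
                                  self.frame_mid_min[keep], self.modality)


@dataclass
class BPSeries:
    """Region x frame DVR-1 binding-potential series (unitless)."""

    values: np.ndarray
    region_ids: list[str]
    frame_mid_min: np.ndarray
    reference_region: str = REFERENCE_ID
    retained_window_min: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_mid_min = np.asarray(self.frame_mid_min, dtype=float)
        if self.reference_region in self.region_ids:
            raise ValueError("reference region must not appear among BP rows")
        if self.values.shape != (len(self.region_ids), len(self.frame_mid_min)):
            raise ValueError("BPSeries dimensions inconsistent")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def as_timeseries(self) -> RegionalTimeSeries:
        return RegionalTimeSeries(self.values, list(self.region_ids),
                                  self.frame_mid_min, modality="PET")


@dataclass
class StaticImage:
    """A summed-uptake 3D image over a time window."""

    data: np.ndarray
    window_min: tuple[float, float]
    normalization: str = "none"  # "none" | "whole_brain_mean"
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)


def framewise_bpnd(ts: RegionalTimeSeries, reference: str = REFERENCE_ID) -> BPSeries:
    """Framewise DVR-1 binding potential against a reference-tissue row.

    BP_ND(r, t) = activity(r, t) / activity(reference, t) - 1. Valid at the
    bolus-plus-infusion equilibrium, where the instantaneous activity ratio
    approximates the distribution volume ratio. The reference row is removed
    from the output.
    """
    if reference not in ts.region_ids:
        raise ValueError(f"reference region {reference!r} not among rows")
    ref = ts.row(reference)
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive reference activity in frame(s) {bad.tolist()} "
            f"(t = {ts.frame_mid_min[bad].tolist()} min)"
        )
    keep = [i for i, rid in enumerate(ts.region_ids) if rid != reference]
    values = ts.values[keep] / ref[None, :] - 1.0
    return BPSeries(
        values=values,
        region_ids=[ts.region_ids[i] for i in keep],
        frame_mid_min=ts.frame_mid_min,
        reference_region=reference,
        retained_window_min=(float(ts.frame_mid_min[0]), float(ts.frame_mid_min[-1])),
    )


def _linear_spline_design(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Hat-function basis of a continuous linear spline with the given knots."""
    n = len(knots)
    design = np.zeros((len(t), n))
    for i in range(n):
        left = knots[i - 1] if i > 0 else knots[0]
        right = knots[i + 1] if i < n - 1 else knots[-1]
        up = np.zeros_like(t)
        if i > 0:
            up = np.clip((t - left) / (knots[i] - left), 0, 1)
        else:
            up[:] = 1.0
        down = np.ones_like(t)
        if i < n - 1:
            down = np.clip((right - t) / (right - knots[i]), 0, 1)
        design[:, i] = np.minimum(up, down)
    # extrapolate flat outside the knot range (clip handles this already)
    return design


def discard_and_detrend(bp: BPSeries, discard_min: float = 20.0,
                        knot_interval_min: float = 20.0,
                        continuous: bool = True) -> BPSeries:
    """Drop the perfusion-dominated start of the scan, then detrend.

    Frames with midpoints before ``discard_min`` are removed. Per region, a
    least-squares piecewise-linear trend with knots every
    ``knot_interval_min`` (aligned to the retained-window start) is
    subtracted, leaving zero-mean residual fluctuations. ``continuous=True``
    fits one continuous linear spline; ``False`` fits independent lines per
    segment.
    """
    keep = bp.frame_mid_min >= discard_min
    t = bp.frame_mid_min[keep]
    if t.size < 4:
        raise ValueError("retained series too short to detrend")
    x = bp.values[:, keep]
    t0, t1 = float(t[0]), float(t[-1])
    n_knots = int(np.floor((t1 - t0) / knot_interval_min)) + 1
    if n_knots < 2:
        warnings.warn("retained series shorter than two knot intervals; "
                      "fitting a single line", stacklevel=2)
        knots = np.array([t0, t1])
    else:
        knots = t0 + knot_interval_min * np.arange(n_knots)
        if knots[-1] < t1 - 1e-9:
            knots = np.append(knots, t1)

    if continuous:
        design = _linear_spline_design(t, knots)
        coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        trend = (design @ coef).T
    else:
        trend = np.empty_like(x)
        for a, b in zip(knots[:-1], knots[1:]):
            seg = (t >= a) & (t <= b) if b == knots[-1] else (t >= a) & (t < b)
            design = np.column_stack([np.ones(seg.sum()), t[seg]])
            coef, *_ = np.linalg.lstsq(design, x[:, seg].T, rcond=None)
            trend[:, seg] = (design @ coef).T
    resid = x - trend
    resid -= resid.mean(axis=1, keepdims=True)
    return BPSeries(
        values=resid,
        region_ids=list(bp.region_ids),
        frame_mid_min=t,
        reference_region=bp.reference_region,
        retained_window_min=(discard_min, t1),
    )


def static_uptake(image: DynamicImage, window_min: tuple[float, float],
                  normalization: str = "whole_brain_mean",
                  brain_mask: np.ndarray | None = None) -> StaticImage:
    """Sum dynamic frames over a time window into a static uptake image.

    Frames belong to the half-open window [start, end) by their midpoints.
    With ``normalization="whole_brain_mean"`` the summed image is divided by
    its mean over ``brain_mask`` (whole grid if no mask), giving an in-mask
    mean of exactly 1.
    """
    if image.modality != "PET":
        raise ValueError("static uptake is defined for PET images")
    idx = image.timing.frames_in_window(window_min)
    if idx.size == 0:
        raise ValueError(f"no frame midpoints in window {window_min}")
    summed = image.data[..., idx].sum(axis=3)
    if normalization == "whole_brain_mean":
        mask = np.ones(summed.shape, bool) if brain_mask is None else brain_mask
        mean = summed[mask].mean()
        if mean == 0:
            raise ValueError("in-mask mean is zero; cannot normalize")
        summed = summed / mean
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return StaticImage(data=summed, window_min=tuple(window_min),
                       normalization=normalization, voxel_size_mm=image.voxel_size_mm)
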