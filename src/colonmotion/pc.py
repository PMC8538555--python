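"""Phase-contrast cine-MRI velocimetry and wall tracking.

Per velocity frame the analysis reports the ROI-mean through-plane
velocity (with the ROI standard deviation as its error), and peak
antegrade/retrograde velocities as the mean of the k most extreme voxels
in each direction (k = 6 by default; averaging several voxels guards
against single-voxel noise).  A rest scan acquired before any motility
provides the noise floor: its pooled voxel SD is the single-voxel error
used for peak estimates.  Wall motion is tracked from the registered
magnitude images by following the maximum-gradient wall membrane along a
probe ray from the lumen centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .synth import PCSequence
from .tagging import ROI

__all__ = [
    "VelocityTrace",
    "WallTrace",
    "lumen_rois",
    "pc_mean_velocity",
    "pc_peak_velocity",
    "noise_floor",
    "track_wall",
    "velocity_trace",
    "wrap_suspicion",
]


@dataclass
class VelocityTrace:
    """Per-frame ROI velocity summary of a PC cine sequence (cm/s)."""

    frame_times: np.ndarray
    mean_v: np.ndarray
    sd_v: np.ndarray
    peak_pos_v: np.ndarray
    peak_neg_v: np.ndarray
    roi_label: str


@dataclass
class WallTrace:
    """Wall-membrane displacement (mm) from its neutral datum, + inward."""

    frame_times: np.ndarray
    displacement: np.ndarray
    valid: np.ndarray
    neutral_position_mm: float


def lumen_rois(
    magnitude_frame: np.ndarray, central_fraction: float = 0.25
) -> tuple[ROI, ROI]:
    """Segment the lumen from a magnitude frame; full and central ROIs.

    The full-lumen ROI is the largest connected component of the brightest
    intensity class (fluid outshines wall, air and background), separated
    by a two-stage Otsu threshold (the second stage splits wall from fluid
    within the bright class when both are present).  The
    central flow region is an axis-aligned box centred on the mask centroid
    covering ``central_fraction`` of the mask's bounding-box area, used to
    exclude stagnant near-wall fluid.
    """
    if not (0 < central_fraction <= 1):
        raise ValueError("central_fraction must lie in (0, 1]")
    frame = np.asarray(magnitude_frame, dtype=float)
    try:
        thr = threshold_otsu(frame)
    except ValueError:
        raise ValueError(
            "magnitude frame has too little contrast to segment a lumen"
        ) from None
    # Refine to the midpoint of the fluid and wall intensity levels, so
    # partial-volume boundary voxels are assigned by majority fluid
    # fraction.  Two cases: the first Otsu split may leave the wall class
    # above the threshold (split it off, guarded against bisecting a
    # single noisy fluid class), or below it (estimate the wall level from
    # the band just underneath).
    upper = frame[frame > thr]
    if upper.size and np.unique(upper).size > 1:
        thr2 = threshold_otsu(upper)
        lo, hi = upper[upper <= thr2], upper[upper > thr2]
        if (hi.size and lo.size >= 0.25 * upper.size
                and (hi.mean() - lo.mean()) > 0.2 * hi.mean()):
            thr = 0.5 * (lo.mean() + hi.mean())
        else:
            fluid_level = float(np.median(upper))
            band = frame[(frame > thr - 0.5 * (fluid_level - thr))
                         & (frame <= thr)]
            if band.size:
                thr = 0.5 * (fluid_level + float(np.median(band)))
    fg = frame > thr
    if not fg.any():
        raise ValueError("no foreground above threshold; cannot segment lumen")
    lab = cc_label(fg)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = lab == largest
    full = ROI(mask=mask, label="full_lumen")

    ii, jj = np.nonzero(mask)
    ci, cj = ii.mean(), jj.mean()
    hi = ii.max() - ii.min() + 1
    wj = jj.max() - jj.min() + 1
    s = np.sqrt(central_fraction)
    bh, bw = max(1, round(s * hi)), max(1, round(s * wj))
    i0 = int(round(ci - bh / 2 + 0.5))
    j0 = int(round(cj - bw / 2 + 0.5))
    box = np.zeros_like(mask)
    box[max(i0, 0): i0 + bh, max(j0, 0): j0 + bw] = True
    return full, ROI(mask=box, label="central_flow_region")


def pc_mean_velocity(velocity_frame: np.ndarray, roi: ROI) -> tuple[float, float]:
    """ROI mean velocity and its sample SD (reported as the error), cm/s."""
    vals = np.asarray(velocity_frame, dtype=float)[roi.mask]
    if vals.size == 0:
        raise ValueError("ROI selects no voxels")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def pc_peak_velocity(
    velocity_frame: np.ndarray, roi: ROI, k: int = 6
) -> tuple[float, float]:
    """Peak velocities: mean of the k most positive / most negative voxels."""
    vals = np.sort(np.asarray(velocity_frame, dtype=float)[roi.mask])
    if vals.size < k:
        raise ValueError(f"ROI holds {vals.size} voxels, fewer than k = {k}")
    return float(vals[-k:].mean()), float(vals[:k].mean())


def noise_floor(rest_seq: PCSequence, roi: ROI) -> tuple[float, float]:
    """Pooled mean and SD of ROI voxel velocities over a rest scan (cm/s).

    The SD is the single-voxel measurement error, used as the error bar on
    peak-velocity estimates.
    """
    vals = rest_seq.velocity_frames[:, roi.mask].astype(float).ravel()
    return float(vals.mean()), float(vals.std(ddof=1))


def velocity_trace(
    seq: PCSequence,
    roi: ROI | None = None,
    central_fraction: float = 0.25,
    use_central: bool = False,
    k: int = 6,
    refresh_roi_per_frame: bool = True,
) -> VelocityTrace:
    """Mean and peak velocity per frame of a PC sequence.

    With ``roi`` unset, the lumen is segmented from each magnitude frame
    (walls move, so the ROI is refreshed per frame unless
    ``refresh_roi_per_frame`` is False, in which case frame 0's ROI is
    reused).  ``use_central`` switches to the central flow region.
    """
    n = seq.velocity_frames.shape[0]
    mean_v = np.empty(n)
    sd_v = np.empty(n)
    ppos = np.empty(n)
    pneg = np.empty(n)
    static_roi = roi
    if static_roi is None and not refresh_roi_per_frame:
        full, cen = lumen_rois(seq.magnitude_frames[0], central_fraction)
        static_roi = cen if use_central else full
    for i in range(n):
        if static_roi is not None:
            r = static_roi
        else:
            full, cen = lumen_rois(seq.magnitude_frames[i], central_fraction)
            r = cen if use_central else full
        mean_v[i], sd_v[i] = pc_mean_velocity(seq.velocity_frames[i], r)
        ppos[i], pneg[i] = pc_peak_velocity(seq.velocity_frames[i], r, k=k)
    label = (static_roi.label if static_roi is not None
             else ("central_flow_region" if use_central else "full_lumen"))
    return VelocityTrace(
        frame_times=seq.frame_times,
        mean_v=mean_v,
        sd_v=sd_v,
        peak_pos_v=ppos,
        peak_neg_v=pneg,
        roi_label=label,
    )


def _ray_profile(frame, origin, direction, length_vox, step=0.25):
    """Sample intensities along a ray (voxel units, map_coordinates)."""
    s = np.arange(0.0, length_vox, step)
    coords = np.stack(
        [origin[0] + s * direction[0], origin[1] + s * direction[1]]
    )
    vals = ndimage.map_coordinates(
        np.asarray(frame, dtype=float), coords, order=1, mode="nearest"
    )
    return s, vals


def track_wall(
    magnitude_seq,
    frame_times=None,
    origin=None,
    direction=(0.0, -1.0),
    voxel_size: float = 1.0,
    neutral_frame: int = 0,
    min_gradient: float = 0.05,
) -> WallTrace:
    """Track the wall membrane along a probe ray in magnitude images.

    ``magnitude_seq`` may be a PCSequence or a raw (n, ny, nz) stack.  The
    ray starts at ``origin`` (voxel coordinates; lumen centroid of the
    neutral frame by default) and points toward the wall.  Per frame the
    membrane is the maximum-|gradient| location along the ray, refined by
    parabolic interpolation; displacement = neutral position - current
    position (positive inward).  Frames whose gradient peak falls below
    ``min_gradient`` per voxel are flagged.
    """
    if isinstance(magnitude_seq, PCSequence):
        frames = magnitude_seq.magnitude_frames
        if frame_times is None:
            frame_times = magnitude_seq.frame_times
        voxel_size = magnitude_seq.acquisition.voxel_size
    else:
        frames = np.asarray(magnitude_seq)
        if frame_times is None:
            frame_times = np.arange(frames.shape[0], dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if origin is None:
        full, _ = lumen_rois(frames[neutral_frame])
        ii, jj = np.nonzero(full.mask)
        origin = (ii.mean(), jj.mean())

    length = frames.shape[1] / 1.5
    positions = np.full(frames.shape[0], np.nan)
    valid = np.zeros(frames.shape[0], dtype=bool)
    step = 0.25
    for i, frame in enumerate(frames):
        s, vals = _ray_profile(frame, origin, direction, length, step)
        grad = np.abs(np.gradient(vals, s))
        if grad.max() < min_gradient:
            continue
        # the membrane is the FIRST strong edge out from the lumen centre
        # (deeper wall/exterior edges can rival it in contrast)
        strong = np.nonzero(grad >= max(min_gradient, 0.6 * grad.max()))[0]
        m = int(strong[0])
        m += int(np.argmax(grad[m: m + 8]))  # top of this first ramp
        # sub-voxel edge: |gradient|-weighted centroid across the ramp
        lo, hi = max(m - 8, 0), min(m + 9, len(s))
        w = grad[lo:hi]
        positions[i] = float(np.sum(s[lo:hi] * w) / np.sum(w)) * voxel_size
        valid[i] = True

    if not valid[neutral_frame]:
        raise ValueError("wall edge not found in the neutral reference frame")
    neutral = positions[neutral_frame]
    disp = neutral - positions
    return WallTrace(
        frame_times=np.asarray(frame_times, dtype=float),
        displacement=disp,
        valid=valid,
        neutral_position_mm=float(neutral),
    )


def wrap_suspicion(velocity_frame: np.ndarray, roi: ROI, venc: float,
                   k: int = 6, edge_fraction: float = 0.85) -> bool:
    """Heuristic aliasing flag for a velocity map.

    Raised when the k most negative ROI voxels hug -venc while their
    8-neighbourhoods contain values near +venc (or vice versa) — the
    signature of a wrapped velocity, not of genuine counterflow.
    """
    v = np.asarray(velocity_frame, dtype=float)
    flat = np.nonzero(roi.mask)
    vals = v[roi.mask]
    if vals.size < k:
        return False
    for sign in (+1.0, -1.0):
        order = np.argsort(sign * vals)[:k]
        extreme = vals[order]
        if not np.all(sign * extreme < -edge_fraction * venc):
            continue
        for idx in order:
            i, j = flat[0][idx], flat[1][idx]
            nb = v[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2]
            if np.any(sign * nb > edge_fraction * venc):
                return True
    return False
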