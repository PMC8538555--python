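"""Tagged-image analysis: CoV mixing statistic and tag velocimetry.

The coefficient of variation (CoV) scores mixing-related motion from a
tagged cine sequence: voxels whose intensity fluctuates over the scan
(because tag bands sweep through them) have a high temporal standard
deviation, static voxels near zero.  With MI_R and STDEV_R the ROI means
of the temporal mean- and standard-deviation maps,

    CoV = 100 * STDEV_R / MI_R   [%].

Tag velocimetry recovers velocity from the displacement of each tag band
over the application-to-acquisition delay: u = dx / dt with dt the tag
delay.  The centroid displacement of a band gives the average velocity of
the fluid at that axial station, the maximum row displacement the peak
velocity.  Half a voxel of displacement resolution translates into a
velocity uncertainty of (voxel/2) / delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .geometry import CM_PER_S_TO_MM_PER_S, DCMGeometry
from .flow import surface_height
from .synth import TaggedSequence, TagAcquisition

__all__ = [
    "ROI",
    "CoVResult",
    "TagTrack",
    "neutral_lumen_roi",
    "intensity_maps",
    "cov",
    "cov_result",
    "detect_tags",
    "tag_velocities",
    "track_tags",
]


@dataclass
class ROI:
    """Binary region of interest over an image grid."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class CoVResult:
    """Per-voxel temporal mean/SD maps and the scalar CoV (%)."""

    mi_map: np.ndarray
    sd_map: np.ndarray
    cov_percent: float


@dataclass
class TagTrack:
    """Per-frame displacement and velocity estimates of one tag band.

    Displacements are mm relative to the nominal applied band position;
    velocities are cm/s (displacement / tag delay).  Frames where the band
    could not be measured are flagged invalid and carry NaN velocities.
    """

    tag_id: int
    nominal_position: float
    frame_times: np.ndarray
    centroid_displacement_mm: np.ndarray
    peak_displacement_mm: np.ndarray
    valid: np.ndarray
    uncertainty_cms: float

    @property
    def v_avg_cms(self) -> np.ndarray:
        return self.centroid_displacement_mm / self._dt_mm

    @property
    def v_peak_cms(self) -> np.ndarray:
        return self.peak_displacement_mm / self._dt_mm

    _dt_mm: float = 0.0  # tag_delay * 10 (mm per cm/s), set by tag_velocities


def neutral_lumen_roi(
    geometry: DCMGeometry, x_coords, z_coords, label: str = "lumen at neutral wall position"
) -> ROI:
    """ROI enclosing the luminal fluid at the neutral wall position.

    Drawn from the known phantom geometry: inside the tube axially, within
    the neutral radius and below the neutral free surface.  This mirrors a
    manually drawn lumen ROI and deliberately excludes the haustral wall
    compartments.
    """
    X, Z = np.meshgrid(np.asarray(x_coords), np.asarray(z_coords), indexing="ij")
    h = surface_height(geometry.lumen_radius, geometry.fill_fraction)
    mask = (
        (X >= 0)
        & (X <= geometry.tube_length)
        & (np.abs(Z) < geometry.lumen_radius)
        & (Z <= h)
    )
    return ROI(mask=mask, label=label)


def intensity_maps(seq: TaggedSequence, roi: ROI):
    """Temporal mean and sample-SD maps over the sequence, inside the ROI.

    Voxels outside the ROI are NaN.  Requires at least two frames (the
    sample standard deviation is undefined for one).
    """
    frames = seq.frames
    if frames.shape[0] < 2:
        raise ValueError("at least 2 frames are required for temporal SD")
    if roi.mask.shape != frames.shape[1:]:
        raise ValueError("ROI shape does not match frame shape")
    mi = frames.mean(axis=0, dtype=np.float64)
    sd = frames.std(axis=0, ddof=1, dtype=np.float64)
    nan = np.full_like(mi, np.nan)
    return np.where(roi.mask, mi, nan), np.where(roi.mask, sd, nan)


def cov(mi_map, sd_map, roi: ROI) -> float:
    """Scalar CoV (%) = 100 * mean(sd_map) / mean(mi_map) over the ROI.

    Ratio of ROI means, not the mean of per-voxel ratios.
    """
    mi = np.nanmean(np.where(roi.mask, mi_map, np.nan))
    sd = np.nanmean(np.where(roi.mask, sd_map, np.nan))
    if not mi > 0:
        raise ValueError("ROI mean intensity must be positive for CoV")
    return float(100.0 * sd / mi)


def cov_result(seq: TaggedSequence, roi: ROI) -> CoVResult:
    """Convenience: intensity maps plus scalar CoV in one call."""
    mi, sd = intensity_maps(seq, roi)
    return CoVResult(mi_map=mi, sd_map=sd, cov_percent=cov(mi, sd, roi))


@dataclass
class TagDetection:
    """Sub-voxel centreline of one tag band in one frame."""

    tag_id: int
    nominal_position: float
    row_z: np.ndarray          # z coordinates (mm) of measured rows
    row_position: np.ndarray   # detected band centre (mm) per row
    valid: bool
    reason: str = ""


def _refine_minimum(profile: np.ndarray, idx: int) -> float:
    """3-point parabolic sub-sample refinement of a discrete minimum."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    a, b, c = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = a - 2 * b + c
    if denom <= 0:
        return float(idx)
    return idx + 0.5 * (a - c) / denom


def detect_tags(
    frame: np.ndarray,
    x_coords,
    z_coords,
    nominal_positions,
    tag_spacing: float,
    roi: ROI,
    *,
    tag_width: float = 5.0,
    smooth_sigma_mm: float = 1.0,
    contrast_threshold: float = 0.3,
    min_valid_fraction: float = 0.5,
) -> list[TagDetection]:
    """Locate each tag band's centreline, per transverse row, sub-voxel.

    For each tag the search window is nominal position +/- tag_spacing / 2.
    Per ROI row, the Gaussian-smoothed intensity profile's minimum is
    refined by 3-point parabolic interpolation; rows whose band contrast
    falls below ``contrast_threshold`` (relative to the row's bright level)
    or whose minimum sits on the window edge (displacement at or beyond the
    half-spacing ambiguity limit) are dropped.  A tag is flagged invalid
    when fewer than ``min_valid_fraction`` of its candidate rows survive,
    or when its measured centreline approaches an adjacent tag's to within
    one band width (overlapping, indistinguishable bands).
    """
    x = np.asarray(x_coords, dtype=float)
    z = np.asarray(z_coords, dtype=float)
    dx = float(np.median(np.diff(x)))
    sigma_vox = smooth_sigma_mm / dx
    half = tag_spacing / 2.0

    detections: list[TagDetection] = []
    for tid, xk in enumerate(np.asarray(nominal_positions, dtype=float), start=1):
        lo = np.searchsorted(x, xk - half)
        hi = np.searchsorted(x, xk + half, side="right")
        if hi - lo < 5:
            detections.append(
                TagDetection(tid, xk, np.empty(0), np.empty(0), False, "window outside image")
            )
            continue
        win_x = x[lo:hi]
        # candidate rows: window fully usable inside the ROI
        row_ok = roi.mask[lo:hi, :].mean(axis=0) >= 0.9
        rows = np.nonzero(row_ok)[0]
        if rows.size == 0:
            detections.append(
                TagDetection(tid, xk, np.empty(0), np.empty(0), False, "no ROI rows")
            )
            continue

        smoothed = gaussian_filter1d(frame[lo:hi, :].astype(float), sigma_vox, axis=0)
        positions, z_meas = [], []
        n_dropped = 0
        for j in rows:
            prof = smoothed[:, j]
            m = int(np.argmin(prof))
            bright = float(np.max(prof))
            contrast = (bright - prof[m]) / bright if bright > 0 else 0.0
            on_edge = m == 0 or m == len(prof) - 1
            if contrast < contrast_threshold or on_edge:
                n_dropped += 1
                continue
            sub = _refine_minimum(prof, m)
            positions.append(float(np.interp(sub, np.arange(len(win_x)), win_x)))
            z_meas.append(z[j])

        frac_valid = len(positions) / rows.size
        valid = frac_valid >= min_valid_fraction
        reason = "" if valid else f"band lost in {n_dropped}/{rows.size} rows"
        detections.append(
            TagDetection(tid, xk, np.asarray(z_meas), np.asarray(positions), valid, reason)
        )

    # overlap guard: adjacent measured centrelines closer than one band
    # width cannot be told apart
    for a, b in zip(detections[:-1], detections[1:]):
        if a.valid and b.valid and a.row_position.size and b.row_position.size:
            sep = np.median(b.row_position) - np.median(a.row_position)
            if abs(sep) < tag_width:
                a.valid = b.valid = False
                a.reason = b.reason = "overlaps adjacent tag"
    return detections


def tag_velocities(
    detections_per_frame: list[list[TagDetection]],
    nominal_positions,
    acq: TagAcquisition,
    frame_times=None,
    lumen_centre_z: float = 0.0,
) -> list[TagTrack]:
    """Assemble per-tag displacement/velocity tracks from frame detections.

    Per frame and tag: centroid displacement = mean over measured rows of
    (detected - nominal); peak displacement = the row displacement of
    maximum magnitude (sign kept; ties broken toward the lumen centre).
    Velocities are displacement / tag_delay in cm/s.  Invalid tag-frames
    carry NaN displacement.
    """
    nominal = np.asarray(nominal_positions, dtype=float)
    n_frames = len(detections_per_frame)
    if frame_times is None:
        frame_times = acq.frame_interval * np.arange(n_frames)
    dt_mm = acq.tag_delay * CM_PER_S_TO_MM_PER_S

    tracks = []
    for k, xk in enumerate(nominal):
        cent = np.full(n_frames, np.nan)
        peak = np.full(n_frames, np.nan)
        valid = np.zeros(n_frames, dtype=bool)
        for i, dets in enumerate(detections_per_frame):
            det = dets[k]
            if not det.valid or det.row_position.size == 0:
                continue
            disp = det.row_position - xk
            cent[i] = disp.mean()
            order = np.lexsort((np.abs(det.row_z - lumen_centre_z), -np.abs(disp)))
            peak[i] = disp[order[0]]
            valid[i] = True
        tracks.append(
            TagTrack(
                tag_id=k + 1,
                nominal_position=float(xk),
                frame_times=np.asarray(frame_times, dtype=float),
                centroid_displacement_mm=cent,
                peak_displacement_mm=peak,
                valid=valid,
                uncertainty_cms=acq.velocity_uncertainty,
                _dt_mm=dt_mm,
            )
        )
    return tracks


def track_tags(seq: TaggedSequence, roi: ROI, **detect_kwargs) -> list[TagTrack]:
    """Detect tag centrelines in every frame and return per-tag tracks."""
    dets = [
        detect_tags(
            frame,
            seq.x_coords,
            seq.z_coords,
            seq.nominal_tag_positions,
            seq.acquisition.tag_spacing,
            roi,
            tag_width=seq.acquisition.tag_width,
            **detect_kwargs,
        )
        for frame in seq.frames
    ]
    return tag_velocities(
        dets, seq.nominal_tag_positions, seq.acquisition, seq.frame_times
    )
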