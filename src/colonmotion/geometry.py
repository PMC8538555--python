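"""Phantom geometry and wall-motion kinematics.

The phantom is a straight, horizontally mounted tube of ``n_segments``
identical segments mimicking the haustrated ascending colon: segment 1 sits
at the caecal end (x = 0), segment ``n_segments`` abuts the rigid hepatic
flexure (x = tube_length).  A cyclic propagating pressure wave (CPPW) runs
each segment through an identical displacement program, delayed segment to
segment by ``segment_pitch / wave_speed``.

Units: lengths in mm, times in s, speeds in cm/s (converted internally).
Displacement sign convention: positive = inward (toward the tube axis).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

CM_PER_S_TO_MM_PER_S = 10.0

__all__ = [
    "DCMGeometry",
    "WallMotionProgram",
    "wall_displacement",
    "lumen_profile",
    "fill_fraction_from_volume",
    "fill_volume_from_fraction",
]


@dataclass(frozen=True)
class DCMGeometry:
    """Neutral (un-actuated) geometry of the segmented tube phantom.

    Parameters
    ----------
    n_segments : int
        Number of motile segments (default 10).
    tube_length : float
        Length of the motile tube in mm (default 250).
    lumen_radius : float
        Neutral inner radius in mm.  The default 17.3 mm makes the default
        10.40 mm maximal wall excursion a ~60 % occlusion.
    fill_fraction : float
        Fraction of the lumen cross-section filled with liquid, in (0, 1].
        1.0 means no free surface.
    fill_volume : float or None
        Nominal media volume in mL; informational, kept alongside
        ``fill_fraction`` (see :func:`fill_fraction_from_volume`).
    """

    n_segments: int = 10
    tube_length: float = 250.0
    lumen_radius: float = 17.3
    fill_fraction: float = 0.69
    fill_volume: float | None = None

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.tube_length <= 0 or self.lumen_radius <= 0:
            raise ValueError("tube_length and lumen_radius must be positive")
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ValueError("fill_fraction must lie in (0, 1]")

    @property
    def segment_pitch(self) -> float:
        """Axial length of one segment in mm."""
        return self.tube_length / self.n_segments

    def segment_bounds(self, segment_index: int) -> tuple[float, float]:
        """(x_start, x_end) in mm of a 1-based segment."""
        self._check_segment(segment_index)
        p = self.segment_pitch
        return (segment_index - 1) * p, segment_index * p

    def segment_centre(self, segment_index: int) -> float:
        lo, hi = self.segment_bounds(segment_index)
        return 0.5 * (lo + hi)

    def segment_of(self, x) -> np.ndarray:
        """1-based segment index containing axial position x (mm)."""
        x = np.asarray(x, dtype=float)
        k = np.floor(x / self.segment_pitch).astype(int) + 1
        return np.clip(k, 1, self.n_segments)

    def _check_segment(self, segment_index: int) -> None:
        if not (1 <= segment_index <= self.n_segments):
            raise IndexError(
                f"segment_index {segment_index} outside 1..{self.n_segments}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DCMGeometry":
        return cls(**json.loads(text))


def fill_fraction_from_volume(geometry: DCMGeometry, volume_ml: float) -> float:
    """Fraction of the neutral lumen occupied by ``volume_ml`` of media."""
    full_ml = np.pi * geometry.lumen_radius**2 * geometry.tube_length / 1000.0
    frac = volume_ml / full_ml
    if not (0.0 < frac <= 1.0):
        raise ValueError(
            f"volume {volume_ml} mL implies fill fraction {frac:.3f} outside (0, 1]"
        )
    return frac


def fill_volume_from_fraction(geometry: DCMGeometry, fraction: float) -> float:
    """Media volume in mL occupying ``fraction`` of the neutral lumen."""
    full_ml = np.pi * geometry.lumen_radius**2 * geometry.tube_length / 1000.0
    return fraction * full_ml


@dataclass(frozen=True)
class WallMotionProgram:
    """Displacement program of one segment during a CPPW.

    The trajectory is continuous and piecewise linear: an outward relaxation
    stroke to ``-relax_depth`` at ``wall_speed``, an inward contraction
    stroke through neutral to ``+max_displacement`` at the same speed, a
    hold of ``hold_time`` at full contraction, and a slow return to neutral
    at ``return_speed``.  Segment k runs the identical program delayed by
    ``(k - 1) * segment_pitch / wave_speed``.

    Speeds are in cm/s, displacements in mm, times in s.
    """

    wave_speed: float = 0.4
    occlusion_degree: float = 0.60
    relax_depth: float = 3.20
    max_displacement: float = 10.40
    wall_speed: float = 0.80
    hold_time: float = 2.0
    return_speed: float = 0.18
    start_time: float = 0.0

    def __post_init__(self):
        for name in ("wave_speed", "relax_depth", "max_displacement",
                     "wall_speed", "return_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hold_time < 0 or self.start_time < 0:
            raise ValueError("hold_time and start_time must be non-negative")

    # Phase boundaries in local (segment) time, relative to segment onset.
    @property
    def relax_duration(self) -> float:
        return self.relax_depth / (self.wall_speed * CM_PER_S_TO_MM_PER_S)

    @property
    def contract_duration(self) -> float:
        return (self.relax_depth + self.max_displacement) / (
            self.wall_speed * CM_PER_S_TO_MM_PER_S
        )

    @property
    def return_duration(self) -> float:
        return self.max_displacement / (self.return_speed * CM_PER_S_TO_MM_PER_S)

    @property
    def cycle_duration(self) -> float:
        """Active duration of one segment's motion, s."""
        return (
            self.relax_duration
            + self.contract_duration
            + self.hold_time
            + self.return_duration
        )

    def segment_delay(self, geometry: DCMGeometry, segment_index: int) -> float:
        """Onset delay of a 1-based segment relative to segment 1, s."""
        geometry._check_segment(segment_index)
        return (segment_index - 1) * geometry.segment_pitch / (
            self.wave_speed * CM_PER_S_TO_MM_PER_S
        )

    def local_displacement(self, tau) -> np.ndarray:
        """Displacement (mm, positive inward) at local time tau since onset."""
        tau = np.asarray(tau, dtype=float)
        v = self.wall_speed * CM_PER_S_TO_MM_PER_S
        vr = self.return_speed * CM_PER_S_TO_MM_PER_S
        t1 = self.relax_duration
        t2 = t1 + self.contract_duration
        t3 = t2 + self.hold_time
        t4 = t3 + self.return_duration
        d = np.zeros_like(tau)
        m = (tau > 0) & (tau <= t1)
        d[m] = -v * tau[m]
        m = (tau > t1) & (tau <= t2)
        d[m] = -self.relax_depth + v * (tau[m] - t1)
        m = (tau > t2) & (tau <= t3)
        d[m] = self.max_displacement
        m = (tau > t3) & (tau <= t4)
        d[m] = self.max_displacement - vr * (tau[m] - t3)
        return d

    def validate_against(self, geometry: DCMGeometry) -> None:
        """Warn if programmed excursion is inconsistent with occlusion_degree."""
        implied = self.max_displacement / geometry.lumen_radius
        if abs(implied - self.occlusion_degree) > 0.05:
            warnings.warn(
                f"max_displacement/lumen_radius = {implied:.3f} differs from "
                f"occlusion_degree = {self.occlusion_degree:.3f} by more than 0.05",
                stacklevel=2,
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WallMotionProgram":
        return cls(**json.loads(text))


def wall_displacement(
    program: WallMotionProgram,
    geometry: DCMGeometry,
    segment_index: int,
    t,
):
    """Wall displacement (mm, positive inward) of one segment at time(s) t.

    Segment k's motion is segment 1's motion delayed by
    ``(k - 1) * segment_pitch / wave_speed`` exactly.
    """
    geometry._check_segment(segment_index)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = t - program.start_time - program.segment_delay(geometry, segment_index)
    out = program.local_displacement(tau)
    if out.ndim == 0:
        return float(out)
    return out


def _bump_weight(x, geometry: DCMGeometry) -> np.ndarray:
    """Raised-cosine weight: 1 at segment centres, 0 at segment boundaries.

    Inter-segment boundaries are rigid, so the radial excursion is tapered
    to zero there; within segment k the weight is sin^2(pi * xi) with xi the
    fractional position along the segment.
    """
    x = np.asarray(x, dtype=float)
    xi = (x % geometry.segment_pitch) / geometry.segment_pitch
    # Clamp exact tube end into the last segment so w(L) = 0, not w(0).
    return np.sin(np.pi * xi) ** 2


def lumen_profile(geometry: DCMGeometry, program: WallMotionProgram, t: float):
    """Inner lumen radius r(x) in mm at time t, as a vectorized callable.

    r(x, t) = lumen_radius - d_k(t) * w(x), with d_k the displacement of the
    segment containing x and w a raised-cosine bump (1 at segment centre,
    0 at the rigid inter-segment boundaries).  Raises if any r <= 0.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    disp = np.array(
        [
            wall_displacement(program, geometry, k, float(t))
            for k in range(1, geometry.n_segments + 1)
        ]
    )
    if np.max(disp) >= geometry.lumen_radius:
        raise ValueError(
            "configured wall motion fully occludes the lumen (r <= 0); "
            "reduce max_displacement or enlarge lumen_radius"
        )

    def r_of_x(x):
        x = np.asarray(x, dtype=float)
        k = geometry.segment_of(x)
        w = _bump_weight(np.clip(x, 0.0, geometry.tube_length - 1e-9), geometry)
        return geometry.lumen_radius - disp[k - 1] * w

    return r_of_x


def displacement_table(
    program: WallMotionProgram,
    geometry: DCMGeometry,
    times,
):
    """Displacement traces of every segment as a (t, segment) record array.

    Returns a list of dicts (t_s, segment, displacement_mm) convenient for
    CSV export via pandas.
    """
    rows = []
    times = np.asarray(times, dtype=float)
    for k in range(1, geometry.n_segments + 1):
        d = wall_displacement(program, geometry, k, times)
        for ti, di in zip(times, np.atleast_1d(d)):
            rows.append({"t_s": float(ti), "segment": k, "displacement_mm": float(di)})
    return rows
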