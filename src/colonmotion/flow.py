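"""Ground-truth luminal velocity fields.

Two families of streamwise velocity field u(x, z, t) are provided:

* :func:`prescribed_flow` — analytic fields (static, plug, slosh, shear
  profile) with closed-form ground truth, used to calibrate and unit-test
  the velocimetry chain;
* :func:`continuity_flow` — a quasi-1D mass-conservation flow driven by the
  programmed wall motion of the phantom.  The tube is closed at both ends
  and partially filled; squeezing a segment displaces fluid axially, the
  free surface takes up the residual volume.  This reproduces the
  directional phenomenology of peristaltic luminal flow (antegrade surge
  ahead of a contraction, retrograde burst behind it) without claiming to
  be a Navier–Stokes solution.

Positive u points toward the hepatic flexure (antegrade, +x); negative
toward the caecum (retrograde).  Velocities are in cm/s; coordinates in mm
with the tube axis at y = z = 0 and z increasing upward.
"""

from __future__ import annotations

import warnings
import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import RegularGridInterpolator, interp1d

from .geometry import (
    CM_PER_S_TO_MM_PER_S,
    DCMGeometry,
    WallMotionProgram,
    _bump_weight,
    wall_displacement,
)

__all__ = ["FlowField", "prescribed_flow", "continuity_flow", "surface_height"]


def _segment_area_fraction(eta):
    """Fraction of a unit circle's area lying below the chord z = eta."""
    eta = np.clip(eta, -1.0, 1.0)
    return (np.arcsin(eta) + eta * np.sqrt(1.0 - eta**2) + np.pi / 2) / np.pi


# Inverse of the segment-area function, tabulated once.
_ETA_GRID = np.linspace(-1.0, 1.0, 4001)
_FRAC_GRID = _segment_area_fraction(_ETA_GRID)
_ETA_OF_FRAC = interp1d(_FRAC_GRID, _ETA_GRID, bounds_error=False,
                        fill_value=(-1.0, 1.0))


def surface_height(radius, fill_fraction):
    """Free-surface height z (mm) above the axis for a partially filled circle."""
    return np.asarray(radius) * _ETA_OF_FRAC(np.clip(fill_fraction, 0.0, 1.0))


class FlowField:
    """Streamwise velocity field of the luminal fluid.

    Subclasses implement :meth:`_u_section` (section velocity profile before
    masking) and the lumen geometry callbacks.  ``u``/``u3`` return cm/s and
    are zero outside the fluid mask.
    """

    def __init__(self, geometry: DCMGeometry, u_max: float = 3.0):
        self.geometry = geometry
        self.u_max = u_max

    # -- geometry -----------------------------------------------------
    def lumen_radius_at(self, x, t):
        """Local inner radius (mm); static neutral radius by default."""
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(self.geometry.lumen_radius, x.shape).copy()

    def surface_at(self, x, t):
        """Free-surface height z (mm); neutral fill by default."""
        r = self.lumen_radius_at(x, t)
        return surface_height(r, self.geometry.fill_fraction)

    def mask3(self, x, y, z, t):
        """True where (x, y, z) lies in luminal fluid at time t."""
        x, y, z = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
        )
        r = self.lumen_radius_at(x, t)
        h = self.surface_at(x, t)
        inside_tube = (x >= 0) & (x <= self.geometry.tube_length)
        return inside_tube & (y**2 + z**2 < r**2) & (z <= h)

    def mask(self, x, z, t):
        """Sagittal-plane (y = 0) fluid mask."""
        return self.mask3(x, 0.0, z, t)

    # -- velocity -----------------------------------------------------
    def _u_section(self, x, y, z, t):
        raise NotImplementedError

    def u3(self, x, y, z, t):
        x, y, z = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
        )
        out = np.where(self.mask3(x, y, z, t), self._u_section(x, y, z, t), 0.0)
        return out

    def u(self, x, z, t):
        """Sagittal-plane velocity u(x, z, t) in cm/s."""
        return self.u3(x, 0.0, z, t)

    def section_mean(self, x, t):
        """Section-mean velocity at axial position x (cm/s); 0 by default."""
        return np.zeros_like(np.asarray(x, dtype=float))

    def check_bounded(self):
        pass


class _StaticFlow(FlowField):
    def _u_section(self, x, y, z, t):
        return np.zeros(np.broadcast(x, y, z).shape)


class _PlugFlow(FlowField):
    def __init__(self, geometry, u0, **kw):
        super().__init__(geometry, **kw)
        self.u0 = float(u0)
        if abs(self.u0) > self.u_max:
            warnings.warn(f"plug velocity {u0} exceeds u_max {self.u_max}")

    def _u_section(self, x, y, z, t):
        return np.full(np.broadcast(x, y, z).shape, self.u0)

    def section_mean(self, x, t):
        return np.full_like(np.asarray(x, dtype=float), self.u0)


class _SloshFlow(FlowField):
    """Spatially uniform 'to and fro' oscillation u = A sin(2 pi t / T)."""

    def __init__(self, geometry, amplitude, period, **kw):
        super().__init__(geometry, **kw)
        if period <= 0:
            raise ValueError("slosh period must be positive")
        self.amplitude = float(amplitude)
        self.period = float(period)

    def _value(self, t):
        return self.amplitude * np.sin(2 * np.pi * np.asarray(t, float) / self.period)

    def _u_section(self, x, y, z, t):
        return np.broadcast_to(self._value(t), np.broadcast(x, y, z).shape).copy()

    def section_mean(self, x, t):
        return np.full_like(np.asarray(x, dtype=float), float(self._value(t)))


class _ProfileFlow(FlowField):
    """Centre-peaked shear profile: u_c at the lumen axis, 0 at the walls."""

    def __init__(self, geometry, u_centre, **kw):
        super().__init__(geometry, **kw)
        self.u_centre = float(u_centre)

    def _u_section(self, x, y, z, t):
        r = self.lumen_radius_at(x, t)
        rho2 = (np.asarray(y, float)**2 + np.asarray(z, float)**2) / r**2
        return self.u_centre * np.clip(1.0 - rho2, 0.0, None)


_PRESCRIBED = {"static": _StaticFlow, "plug": _PlugFlow, "slosh": _SloshFlow,
               "profile": _ProfileFlow}


def prescribed_flow(kind: str, geometry: DCMGeometry | None = None, **params) -> FlowField:
    """Analytic flow field with known ground truth.

    kind = "static" (u = 0), "plug" (``u0`` cm/s everywhere in fluid),
    "slosh" (uniform ``amplitude`` * sin(2 pi t / ``period``)) or "profile"
    (``u_centre`` at the axis decaying quadratically to 0 at the walls).
    """
    if geometry is None:
        geometry = DCMGeometry()
    try:
        cls = _PRESCRIBED[kind]
    except KeyError:
        raise ValueError(
            f"unknown flow kind {kind!r}; expected one of {sorted(_PRESCRIBED)}"
        ) from None
    return cls(geometry, **params)


class ContinuityFlow(FlowField):
    """Quasi-1D continuity-driven flow; see :func:`continuity_flow`."""

    def __init__(self, geometry, program, damping_tau=0.0, profile="plug",
                 dx=1.0, dt=0.05, t_max=None, u_max=3.0):
        super().__init__(geometry, u_max=u_max)
        if geometry.fill_fraction >= 1.0:
            raise ValueError(
                "continuity flow requires a partially filled lumen "
                "(fill_fraction < 1): rigid closed ends leave no room for "
                "wall-displaced volume"
            )
        if dt > 0.1:
            raise ValueError("time grid resolution dt must be <= 0.1 s")
        if profile not in ("plug", "centred"):
            raise ValueError("profile must be 'plug' or 'centred'")
        self.program = program
        self.damping_tau = float(damping_tau)
        self.profile = profile
        program.validate_against(geometry)

        if t_max is None:
            t_max = (program.start_time
                     + program.segment_delay(geometry, geometry.n_segments)
                     + program.cycle_duration + 2.0)
        L = geometry.tube_length
        self.x_grid = np.arange(0.0, L + dx / 2, dx)
        self.t_grid = np.arange(0.0, t_max + dt / 2, dt)
        nx, nt = len(self.x_grid), len(self.t_grid)

        # radius r(x, t): per-segment displacement times the rigid-boundary bump
        disp = np.empty((geometry.n_segments, nt))
        for k in range(1, geometry.n_segments + 1):
            disp[k - 1] = wall_displacement(program, geometry, k, self.t_grid)
        seg = geometry.segment_of(self.x_grid) - 1
        w = _bump_weight(np.clip(self.x_grid, 0, L - 1e-9), geometry)
        r = geometry.lumen_radius - disp[seg, :] * w[:, None]   # (nx, nt)
        if np.any(r <= 0):
            raise ValueError("wall program fully occludes the lumen (r <= 0)")
        self._radius = r

        # fluid area a(x, t) = f * A + c(t), with c the uniform free-surface
        # compliance chosen so total volume is constant in time
        f = geometry.fill_fraction
        A = np.pi * r**2
        fa = f * A
        V0 = f * np.pi * geometry.lumen_radius**2 * L
        c = (V0 - np.trapezoid(fa, self.x_grid, axis=0)) / L    # (nt,)
        a = fa + c[None, :]
        self._area = a
        self._volume = np.trapezoid(a, self.x_grid, axis=0)

        # flux from continuity: Q(x, t) = -int_0^x da/dt dx', Q(0) = 0;
        # the compliance closure makes Q(L, t) = 0 under the same quadrature
        dadt = np.gradient(a, self.t_grid, axis=1)
        Q = -cumulative_trapezoid(dadt, self.x_grid, axis=0, initial=0.0)
        self._end_flux = Q[-1, :]
        ubar = Q / a                                             # mm/s

        if self.damping_tau > 0:
            # first-order low-pass (viscosity surrogate): exponential
            # moving average with time constant damping_tau
            alpha = np.exp(-dt / self.damping_tau)
            filt = np.empty_like(ubar)
            filt[:, 0] = ubar[:, 0]
            for j in range(1, nt):
                filt[:, j] = alpha * filt[:, j - 1] + (1 - alpha) * ubar[:, j]
            ubar = filt
        self._ubar = ubar

        self._ubar_interp = RegularGridInterpolator(
            (self.x_grid, self.t_grid), ubar,
            bounds_error=False, fill_value=0.0)
        self._radius_interp = RegularGridInterpolator(
            (self.x_grid, self.t_grid), r,
            bounds_error=False, fill_value=geometry.lumen_radius)
        # local fill fraction for the free-surface height
        local_frac = np.clip(a / A, 0.0, 1.0)
        self._frac_interp = RegularGridInterpolator(
            (self.x_grid, self.t_grid), local_frac,
            bounds_error=False, fill_value=f)
        self.check_bounded()

    # -- geometry ------------------------------------------------------
    def _xt(self, x, t):
        x = np.asarray(x, dtype=float)
        tt = np.broadcast_to(np.asarray(t, dtype=float), x.shape)
        return np.stack([np.clip(x, self.x_grid[0], self.x_grid[-1]),
                         np.clip(tt, self.t_grid[0], self.t_grid[-1])], axis=-1)

    def lumen_radius_at(self, x, t):
        return self._radius_interp(self._xt(x, t))

    def surface_at(self, x, t):
        r = self.lumen_radius_at(x, t)
        return surface_height(r, self._frac_interp(self._xt(x, t)))

    # -- velocity ------------------------------------------------------
    def section_mean(self, x, t):
        """Section-mean velocity ubar(x, t) in cm/s."""
        out = self._ubar_interp(self._xt(x, t)) / CM_PER_S_TO_MM_PER_S
        if np.ndim(x) == 0 and np.ndim(t) == 0:
            return float(np.ravel(out)[0])
        return out

    def _u_section(self, x, y, z, t):
        ub = self.section_mean(x, t)
        if self.profile == "plug":
            return ub
        r = self.lumen_radius_at(x, t)
        rho2 = (np.asarray(y, float)**2 + np.asarray(z, float)**2) / r**2
        # centre-weighted (Poiseuille-like) profile with area-mean ~1
        return ub * 2.0 * np.clip(1.0 - rho2, 0.0, None)

    # -- diagnostics ---------------------------------------------------
    @property
    def total_volume(self):
        """Total fluid volume (mm^3) on the time grid."""
        return self._volume

    @property
    def end_flux(self):
        """Flux Q(L, t) at the closed flexure end (mm^3/s)."""
        return self._end_flux

    def check_bounded(self):
        peak = np.max(np.abs(self._ubar)) / CM_PER_S_TO_MM_PER_S
        if peak > self.u_max:
            warnings.warn(
                f"continuity flow peak |u| = {peak:.2f} cm/s exceeds "
                f"u_max = {self.u_max} cm/s", stacklevel=2)


def continuity_flow(geometry: DCMGeometry, program: WallMotionProgram,
                    damping_tau: float = 0.0, **kwargs) -> ContinuityFlow:
    """Mass-conservation flow driven by the programmed wall motion.

    The fluid area is a(x, t) = fill_fraction * A(x, t) + c(t), with
    A = pi r(x, t)^2 and c(t) a spatially uniform free-surface compliance
    term keeping total volume constant.  Volumetric flux follows from
    continuity with a closed caecal end, Q(x, t) = -int_0^x da/dt dx'
    (which forces Q(L, t) = 0 at the closed flexure end), and the
    section-mean velocity is Q/a, optionally low-pass filtered in time with
    time constant ``damping_tau`` (s) as a media-viscosity surrogate.

    ``profile`` = "plug" (default) or "centred" sets the transverse shape.
    """
    return ContinuityFlow(geometry, program, damping_tau=damping_tau, **kwargs)
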