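# Methods

This note documents the models behind `colonmotion`: what is simulated,
what is measured, the defaults and why, and what the synthetic phantom can
and cannot say about real scans.

## Phantom geometry and wall kinematics

The dynamic colon model is represented as a straight horizontal tube of
`n_segments = 10` identical motile segments over `tube_length = 250` mm
(segment pitch 25 mm), closed at the caecal end (x = 0) and at the rigid
hepatic flexure (x = 250 mm). The neutral inner radius defaults to
17.3 mm, chosen so that the programmed 10.40 mm maximal wall excursion
corresponds to a 60 % occlusion degree; the radius is configurable and no
other quantity depends on its absolute value.

One segment's displacement program during a cyclic propagating pressure
wave (CPPW) is continuous and piecewise linear, positive = inward:

1. relaxation to −3.20 mm at 0.80 cm/s (0.40 s),
2. contraction through neutral to +10.40 mm at 0.80 cm/s (1.70 s),
3. hold for 2 s,
4. return to neutral at 0.18 cm/s (5.78 s).

Segment k runs the identical program delayed by
`(k−1) · pitch / wave_speed` — exactly, which is what defines the wave
speed (0.4 cm/s default, 0.8 cm/s for the faster pattern). A full wave
therefore traverses the tube in 62.5 s at 0.4 cm/s, matching a 60 s scan
window. Within a segment the radial excursion is tapered by a
raised-cosine bump, maximal at the segment centre and zero at the rigid
inter-segment boundaries, so the lumen radius r(x, t) is continuous and
inter-segment walls never move.

## Ground-truth flow

Two families of velocity field feed the renderer:

* **Prescribed flows** (static, plug, sinusoidal slosh, centre-peaked
  shear profile) with closed-form truth, used to calibrate the
  velocimetry chain.
* **Continuity flow**: a quasi-1D mass-conservation model. The fluid
  cross-section is `a(x,t) = fill_fraction · πr(x,t)² + c(t)`, with c(t)
  a spatially uniform free-surface compliance chosen so total volume is
  constant — the simplest closure for a closed, partially filled tube.
  Volumetric flux follows from continuity with Q(0, t) = 0; the closure
  forces Q(L, t) = 0 at the other closed end, both at machine precision
  of the shared quadrature. Section-mean velocity is ū = Q/a, and
  u(x, z, t) = ū(x, t) by default (plug transverse profile; a
  Poiseuille-like centred profile is available).

  This model reproduces the directional phenomenology that the analysis
  chain must detect — an antegrade episode ahead of a contraction, a
  retrograde burst behind it, stronger flows for faster waves — but it is
  a phantom, not a Navier–Stokes solution: it has no inertia, no
  gravity-driven backflow at the flexure, and no transverse velocity
  components.

  Media viscosity enters as a first-order low-pass filter on ū with time
  constant `damping_tau` (an exponential moving average). The mapping
  from viscosity to damping is not physically derivable within a
  continuity model, so the two test media are represented by time
  constants in rough proportion to their viscosities (13 vs 98 mPa s):
  LOVIS → 0.10 s, HIVIS → 0.75 s, fixed once before any factorial
  experiment was run. Temporal velocity variance is monotonically
  non-increasing in `damping_tau`, which is what carries the
  viscosity ordering into the CoV statistic.

* **Fill state.** The 150 and 200 mL media loads are represented by fill
  fractions 0.52 and 0.69 of the lumen cross-section (the nominal fill
  percentages of those loads in the physical model). The fluid occupies
  the lower circular segment below a free surface; the conversion between
  volume and fraction for an arbitrary radius is also provided.

## Image formation

Rendering is an image-formation model, not an MR physics simulation:
tissue classes are piecewise-constant intensities (fluid 1.0, wall 0.55,
exterior 0.25, air 0.05), tag bands are raised-cosine nulling profiles,
magnitude noise is Rician and PC velocity noise Gaussian, each seeded per
frame for bit-exact reproducibility. Bloch dynamics, tag fading by T1
relaxation, SENSE artefacts and through-plane encoding are out of scope.

**Tagged sequences** (sagittal x–z, 0.982 mm voxels, 100 frames at
600 ms): a comb of `floor(L / 12 mm) = 20` bands, ~5 mm wide and 90 %
deep, is re-applied at fixed nominal positions 250 ms before each
acquisition (with a 600 ms frame interval and a 250 ms delay, per-frame
re-application is the only consistent reading). Fluid advects each band
by the per-row displacement `d(z) = u(x_k, z, ·) · 250 ms`; the velocity
is sampled at the temporal midpoint of the delay by default (options:
application instant, or RK2 with a spatial half-step). Static tissue
keeps straight tags. The factorial experiments use a 12.5 mm comb pitch
aligned with the segmented architecture — odd tags at segment midpoints,
even tags on the rigid boundaries.

**PC sequences** (transverse y–z, 101 × 101 at 1.136 mm, 30 frames at
2 s): velocity maps average the truth over three sample planes across the
8 mm slice, add Gaussian noise (default σ = 0.0064 cm/s, the magnitude of
a typical rest-scan floor) and wrap into (−VENC, VENC] with VENC =
3 cm/s; non-fluid voxels carry noise only. Magnitude frames are rendered
with 3 × 3 sub-voxel averaging so tissue boundaries carry partial-volume
information — without it, wall position would be quantised to whole
voxels and sub-voxel tracking would be impossible in principle.

## Analysis chain

* **CoV**: per-voxel temporal mean and sample SD (n−1) over the ROI
  drawn around the lumen at the neutral wall position; the scalar is the
  ratio of ROI means (not the mean of per-voxel ratios, which is
  ill-conditioned in low-intensity voxels); a per-voxel map remains
  available as a diagnostic. CoV is invariant under intensity rescaling.
* **Tag detection**: per tag, a search window of ± half the comb pitch;
  per ROI row, the minimum of the Gaussian-smoothed profile refined by
  3-point parabolic interpolation. Rows are dropped when band contrast
  falls below 30 % of the row's bright level or the minimum sits on the
  window edge (at or beyond the half-pitch ambiguity limit — displacement
  beyond it is fundamentally ambiguous for a periodic comb, the tagging
  analogue of VENC aliasing). A tag-frame is invalid when fewer than half
  its rows survive or when adjacent measured centrelines approach within
  one band width (overlapping bands cannot be told apart; this is how the
  faster wave degrades the measurement). Peak displacement ties break
  toward the lumen centre.
* **Velocities**: centroid displacement / 250 ms (average) and extreme
  row displacement / 250 ms (peak), in cm/s; per-measurement uncertainty
  (voxel/2)/delay = 0.20 cm/s at full resolution.
* **PC analysis**: the lumen is segmented per frame from the magnitude
  image (walls move) as the largest connected component of the brightest
  intensity class — a two-stage Otsu whose final threshold is the
  midpoint of the fluid and wall levels, so partial-volume boundary
  voxels are assigned by majority fluid fraction. The central flow region
  is a centred box covering 25 % of the mask's bounding-box area. Mean
  velocity ± ROI SD (reported as the error), peak = mean of the 6 most
  extreme voxels per direction (both directions always reported), rest
  scans give the pooled single-voxel noise floor. No phase unwrapping is
  attempted; a wrap-suspicion heuristic flags peak voxels hugging −VENC
  inside +VENC surroundings.
* **Wall tracking**: along a ray from the lumen centroid toward the
  wall, the membrane is the *first* strong intensity edge (≥ 60 % of the
  ray's maximum gradient — the deeper wall/exterior edge can rival the
  fluid/wall edge in contrast), localised sub-voxel by a
  gradient-weighted centroid across the ramp. Displacement is signed
  positive inward from the neutral frame's position.
* **Statistics**: balanced 2×2×2 fixed-effects ANOVA via ±1 orthogonal
  contrasts (each term 1 df; equals the marginal-mean decomposition and
  is order-independent under balance), F and Tukey studentized-range
  p-values from scipy distributions. The decomposition itself is
  implemented here; statsmodels serves only as an independent
  cross-check in the tests. Tukey mean differences are also exposed
  standalone so they can be computed from published cell-mean tables
  (reported both signed and absolute: the published volume contrast's
  printed sign conflicts with the sign implied by its own cell means, so
  neither is silently preferred). Report rounding is half-away-from-zero
  at 3 decimals, with a 9-decimal pre-quantisation so float
  representation noise cannot flip a true half.

## Numerical choices

* Continuity flow: x grid 1 mm, t grid ≤ 0.1 s (0.05 s at full
  resolution); volume conservation holds to ~1e−14 relative and end
  fluxes vanish to quadrature precision because the same trapezoid rule
  defines both the compliance closure and the flux integral.
* Velocities are capped by a configurable u_max (default the 3 cm/s
  VENC); exceeding it warns rather than fails — the faster CPPW
  legitimately exceeds VENC, which is precisely why its tagged analysis
  degrades.
* Degenerate inputs fail loudly: single-frame SD, empty ROIs, unsegmentable
  frames, over-occluding wall programs, fully filled lumens (no free
  surface to absorb displaced volume), unbalanced ANOVA tables.

## Experiment driver and problem sizes

`run_experiment` composes geometry → flow → rendering → analysis →
statistics per condition × replicate with per-replicate seeds and error
isolation. The default acquisition grids are trimmed two-fold (1.964 mm
tagged voxels, 51 × 51 PC matrix at 2.272 mm) so a full factorial plan
with four replicates runs in well under a minute on one CPU;
`full_resolution=True` restores the native voxel sizes. The measurement
resolution scales accordingly (±0.39 cm/s at trimmed resolution); tests
that assert against the ±0.20 cm/s figure use full resolution.

## What passing tests show — and what they do not

The phantom validates the *analysis operators* against known truth:
sub-voxel tag detection, velocity recovery to well within the stated
resolution, exact ROI statistics, wall-kinematics recovery, and the
qualitative orderings (faster wave > slower wave and low > high damping
in CoV; antegrade/retrograde phase structure; mid-tube mixing maximum;
boundary tags registering stronger flow than segment-centre tags). It
does not emulate real scanner intensities, coil profiles, tag fading or
in vivo motility, so absolute CoV percentages from synthetic runs are not
comparable to scanner values — only orderings and recovered kinematics
are. The factorial experiment is therefore scored on orderings and
contrasts, never on absolute CoV.

## Known limitations

* The continuity model's section-mean velocity spikes inside a nearly
  occluded throat (u = Q/a with small a). Real tagged measurements at a
  contracting segment instead sample a shrinking fluid column; the
  rendered measurement reproduces the damped odd-tag profiles through the
  encroaching static wall, but flow-level velocity maxima at segment
  centres should not be over-interpreted.
* The viscosity → damping_tau mapping is a surrogate with the right
  ordering, not a rheological model.
* Tag-comb velocimetry is periodic-ambiguous beyond half the comb pitch
  per delay (2.4 cm/s at defaults); displacements beyond it are flagged,
  not unwrapped.
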