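# colonmotion

MR tagging and phase-contrast cine-MRI analysis of luminal flow in a
dynamic colon model (DCM) phantom — a ten-segment, pneumatically actuated
in vitro model of the human ascending colon used in biorelevant
dissolution testing.

## The problem

How vigorously the contents of the ascending colon move determines how a
colon-targeted dosage form erodes and releases drug, yet luminal flow in
the colon is hard to measure. Two MRI techniques make it accessible:

* **MR tagging** nulls the signal along a comb of parallel bands ("tags")
  a fixed delay Δt before each image. Fluid that moves during the delay
  carries its band with it, so per-frame band displacement Δx encodes the
  local streamwise velocity, `u = Δx/Δt`. Summarising a tagged cine series
  by the **coefficient of variation**

  `CoV = 100 · STDEV_R / MI_R  [%]`

  (ROI means of the temporal standard-deviation and mean-intensity maps)
  yields a single mixing-motion score that discriminates motility patterns
  and media viscosities.
* **Phase-contrast (PC) cine-MRI** encodes the through-plane velocity of
  every voxel in a transverse slice (within ±VENC), giving ROI mean and
  peak (top-6-voxel) velocities plus wall-membrane displacement tracked in
  the registered magnitude images.

This package implements that full analysis chain, together with a
synthetic phantom that renders tagged and velocity-encoded image sequences
of a peristaltic segmented tube with known ground-truth flow, so every
operator can be validated against programmed truth: wall kinematics of a
cyclic propagating pressure wave (CPPW, 0.4 or 0.8 cm/s, 60 % occlusion),
a quasi-1D continuity flow in the closed partially filled lumen, tag
detection and velocimetry, CoV, PC ROI velocimetry, wall tracking, and the
balanced three-way ANOVA / Tukey HSD comparison of CoV across wave speed ×
media viscosity × fill volume.

## Worked example

`examples/04_tag_velocimetry.py` renders a noiseless tagged sequence of a
known 1.2 cm/s plug flow and recovers it:

```
20 tags at 12.0 mm pitch; 40 valid tag-frames
recovered velocity: 1.201 cm/s (true 1.200)
stated resolution: +/- 0.20 cm/s (half a voxel over the 250 ms delay)
noisy calibration (n = 300 tag-frames): bias +0.0000 cm/s, RMSE 0.0052 cm/s
```

The recovered mean is within 0.001 cm/s of the programmed plug speed; the
±0.20 cm/s line is the intrinsic resolution of tag velocimetry at this
voxel size (0.982 mm) and tag delay (250 ms) — half a voxel of
displacement over the delay.

`examples/02_continuity_flow.py` shows the characteristic peristaltic flow
signature at a probe on the rigid boundary between segments 6 and 7:

```
mean velocity at x = 150 mm while segment 6 (upstream) contracts: +0.23 cm/s
mean velocity at x = 150 mm while segment 7 (downstream) contracts: -0.56 cm/s
```

an antegrade episode while the upstream segment squeezes, then a sharper
retrograde burst when the wave reaches the downstream segment — the
to-and-fro motion of a non-occlusive propagating contraction.

The other examples cover wall kinematics (`01`), the CoV mixing score and
its viscosity sensitivity (`03`), PC velocimetry with wall tracking
(`05`), and the factorial statistics (`06`).

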