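# Methods

## Physical model

An MN array illuminated by a green (543.5 nm) laser is treated as a
distributed source: each tip scatters the incident beam and re-emits
isotropically with reference intensity `I0` at distance `r0`. Two levels of
description are implemented.

**Continuum disk.** Emitters at uniform surface density σ on a disk of
radius `R`. The contribution of the annulus at radius `r` to the on-axis
point at distance ρ is `dI = 2πr σ I0 r0²/(ρ² + r²) dr`; with the
substitution `x = r²` the integral over the disk is elementary and gives

    I(ρ) = π σ I0 r0² ln((ρ² + R²)/ρ²),

multiplied by a Beer–Lambert factor `e^(−αρ)` in an attenuating medium.
The attenuation is a single global factor in the axial depth ρ, not a
per-emitter path factor `e^(−α dᵢ)`; the Monte-Carlo oracle exposes the
per-path variant for sensitivity analysis (it is always ≤ the global form,
since every `dᵢ ≥ ρ`), but it is never substituted silently.

**Discrete grid.** `array_intensity_bruteforce` sums attenuated
inverse-square terms over the 19×19 tip apices and supports off-axis
points, which the closed form does not (ρ is strictly the on-axis
distance). On axis, far from the array, it matches the continuum disk with
the equivalent-area radius `R = pitch·√(n_tips/π)` and `σ = 1/pitch²`.

**Singularity.** The closed form diverges logarithmically at ρ = 0 — the
physical point-source singularity. Values below a configurable guard
`rho_min` (default 1e-6 μm) raise an explicit error; nothing is clamped.

**Directed comparator.** `directed_intensity` defaults to pure
Beer–Lambert decay `I0 e^(−αz)`; an inverse-square dispersion variant is
opt-in. `compare_models`, however, compares the attenuated disk against
the *dispersing* point-source beam `I0 (r0/ρ)² e^(−αρ)` — the disk's own
R→0 limit, i.e. the same emitted power concentrated at one spot. This is
the comparison under which distributing the source demonstrably flattens
the depth fall-off: since `ρ²·ln(1+R²/ρ²)` is increasing in ρ, the
normalized disk profile lies above the beam profile at every depth, for
every R and α. Against the pure exponential the opposite holds (the log
factor only ever decreases), which is why the dispersive comparator is the
default. The ≈30 % figure quoted for direct-coupling attenuation
comparisons is carried in the output as a reference value only; the
parameters behind it (α, R, depth range, normalization) are not stated
anywhere, so it is not a reproducible target.

## Units

Lengths are μm throughout, α in μm⁻¹; conversions happen only at I/O
boundaries. Irradiance is mW/cm² and dose J/cm²
(`dose = irradiance × 10⁻³ × seconds`), exact in rationals at the printed
precision.

## Synthetic imaging

The renderer emulates the lateral photographs of the illuminated array as
a 2-D band pattern, not a ray-traced scene:

- Tip rows (horizontal bands of the base width, on the 350 μm pitch) glow
  uniformly at `tip_law(angle)` — default constant 120 counts, the
  isotropy being demonstrated.
- Gap rows between them carry the transmitted beam at `gap_law(angle)` —
  default `230·cos⁴θ`, chosen so the 57° level is far below the 0° level —
  dimmed to a fixed 0.6 fraction behind each tip column so tip positions
  are visible at the pitch spacing.
- Both are restricted to the illuminated window (default 2000–4000 μm,
  matching the central analysis window); elsewhere a 5-count background.
- Oblique viewing compresses the horizontal axis by cos θ. Each image
  stores its de-projected calibration (μm of array surface per pixel), so
  positions and the analysis window are always in array coordinates. At
  77° the 50 μm inter-tip gap spans ~1.1 px and the downstream
  resolvability check (< 2 px) rejects the image.
- Noise is additive Gaussian (default sd 3 counts) applied before clipping
  and 8-bit quantization; Poisson shot noise is not identifiable at 8-bit
  depth and is not modeled. Red/blue channels are fixed fractions of green
  (0.15/0.10) since the laser line is green.
- Beam masking uses pixel left edges in de-projected coordinates so the
  illuminated columns align exactly with the half-open analysis window;
  tip/gap classification uses pixel centers.

What this does *not* emulate: camera PSF, vignetting, perspective,
speckle, the pyramidal internal-reflection ray paths, or any wavelength
dependence. Passing tests therefore show that the analysis procedure
recovers known band-pattern ground truth through quantization and noise —
not that it would be robust to real-photograph artifacts.

## Profile analysis

The original procedure drew five horizontal lines by hand in ImageJ; hand
placement is not reproducible, so lines are drawn by seeded RNG — uniform
without replacement over the valid gap-band rows ("line"), or the center
rows of five distinct tip bands ("MN"). Per-column means over the five
rows are kept in floating point (no re-quantization). Positions are
`column_index × um_per_px` with a 0-based origin at the left image edge;
the central window [2000, 4000) μm is half-open. The isotropy index is the
population coefficient of variation of the per-angle central-window means
— this package's own summary metric, flagged as such in outputs.

## Seeding and reproducibility

A single global seed fans out to per-stage child seeds through
`SeedSequence` keyed by stage name, so stages are independently
re-runnable and full runs are byte-identical. Within a render set, one
spawned stream per angle gives independent noise draws. Every CSV carries
the config hash (scientific fields only, not output paths) and seed in a
header comment.

## Numerical choices

- Quadrature oracle: `scipy.integrate.quad`, epsabs 1e-10 / epsrel 1e-8.
- Monte-Carlo oracle: area-uniform placement `r = R√u`, 10⁵ emitters in
  the standard checks (standard error ≈ 0.1 % of the value, well inside
  the 3-SE acceptance band, and < 1 s on one CPU).
- Far-field grid-vs-disk check at ρ = 10× the array extent (relative
  deviation ~7e-5, inside the 1 % tolerance).
- Per-tip heights drawn uniformly from 450–500 μm under a seed, or fixed
  at the 475 μm midpoint when deterministic output is requested; height
  variation only shifts apices axially and is negligible in the far field.
- Depth grids for model comparison: 40–50 points over ρ ∈ [R, 5R] in the
  pipeline, [1, 5] in the sweeps — small enough to run in milliseconds,
  dense enough that monotonicity checks are meaningful.

## Design choices that were genuinely open

- **350 vs 50 μm spacing:** stated once as tip spacing 50 μm and once as
  intertip spacing 350 μm; reconciled as base gap (50) vs
  center-to-center pitch (350 = 300 + 50). Pitch is canonical; the gap is
  derived.
- **"Base of 300 μm"** of a square pyramid is read as the square side
  length.
- **Tip-row rendering is uniform along the row** (the tips' scattered
  light dominates the whole row) rather than bright only at tip columns:
  this makes the tip-band mean exactly proportional to the tip law at any
  viewing angle, independent of how tip-column widths round to pixels,
  which is what lets the ground-truth recovery be checked at the
  3·noise_sd/√n level. The pitch structure is carried by the transmission
  shadows in the gap rows instead.
- **um_per_px** is a free parameter (no camera calibration is stated);
  default 10 μm/px makes the 2000–4000 μm window span 200 head-on pixels.

## Limitations

Off-axis closed-form evaluation is deliberately absent (grid oracle only).
The renderer's angular laws are parametric stand-ins, not fits to any
measured photograph. The directed/isotropic comparison is a two-model
contrast, not radiative transfer in turbid tissue; neither model captures
multiple scattering, refraction at the MN–tissue interface, or
wavelength-dependent optical properties.
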