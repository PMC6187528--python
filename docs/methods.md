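# Methods

## Problem and model

A near-spherical object (a suspended cell, bead or microparticle) rotates
about an unknown, possibly oblique 3D axis while a single camera records a
2D grayscale image sequence through a microscope. Because the optics are
monocular and the object is small relative to the working distance, the
imaging is modelled as an orthographic projection, and the object as a
perfect sphere of radius `r` (pixels) centred at `(cx, cy)` in the image.

The measurement chain has four stages:

1. **Localisation.** The object is found by template matching. The match
   score is the normalised cross-correlation
   `R = sum(S*T) / sqrt(sum(S^2) sum(T^2))`, and the search is accelerated
   with a sequential similarity detection algorithm: at each candidate
   position the mean-removed absolute differences are accumulated in a
   seeded random pixel order and the candidate is abandoned as soon as the
   accumulated error crosses a threshold. The true match accumulates error
   slowest, so the candidate surviving the most comparisons wins. The
   radius is estimated once, from the peak of the radial profile of the
   template's gradient magnitude, and held constant over the sequence
   (refitting per frame would leak rim noise into the z-lift).
2. **Preprocessing.** Each frame is shifted additively so its mean equals
   the sequence grand mean (brightness constancy across frames), then
   smoothed with a separable isotropic Gaussian (default sigma 1.5 px).
3. **Dense optical flow.** Horn–Schunck variational flow between
   consecutive frames: the brightness-constancy constraint
   `Ix u + Iy v + It = 0` plus a global smoothness penalty, solved by
   relaxation with the classical 3x3 weighted neighbourhood average
   (1/6 edge, 1/12 diagonal), derivatives from the 2x2x2 cube average over
   both frames.
4. **Spherical back-projection and rotation recovery.** Each in-disc pixel
   maps to the camera-facing surface point
   `p = (x, y, +sqrt(r^2 - x^2 - y^2))` (x right, y up, z toward camera,
   right-handed). The 2D flow `(u, v)` lifts to the tangential surface
   velocity `vo = (u, -v, w)` with `w = -(x u - y v)/z`, the unique
   z-component satisfying `vo . p = 0`. For a rigid rotation
   `vo = w_rad (a x p)`, so every lifted flow is perpendicular to the axis
   `a`: the axis estimate is the eigenvector of the smallest eigenvalue of
   the scatter matrix of the unit lifted flows. The per-pixel amplitude is
   `V = 360 |vo| / (2 pi d)` degrees/frame, with `d` the distance of `p`
   from the axis line; the reported amplitude is the median over valid
   pixels. With the frame rate known, `rad/min = V * fps * 60 * pi/180`
   and `rpm = V * fps * 60 / 360`.

## Axis sign

The scatter-matrix eigenvector determines the axis only up to sign. The
sign is fixed by the net angular momentum of the flow field,
`m = sum_i p_i x vo_i`: for a rotation at rate `w` about `a`,
`m = w sum_i (r^2 a - (p_i . a) p_i)` whose component along `a` is
`w sum_i (r^2 - (p_i . a)^2) >= 0`, so `sign(m . axis)` orients the axis
regardless of which surface points are visible. (A vote built from pairwise
cross products `vo_i x vo_j` is unusable here: each term equals
`[a . (p_i x p_j)] a`, antisymmetric under swapping the pair, so a random
sample averages to zero.) Note the in-plane component of the recovered
axis still flips if the visible texture actually lies on the far
hemisphere — the camera cannot distinguish the two cases, which is why
validation compares axes sign-agnostically.

## Guards and aggregation

The lift `w = -(xu - yv)/z` diverges at the limb, and `V ∝ 1/d` diverges
near the axis. Pixels are therefore excluded when: outside 0.95 r of the
centre; z below 0.1 r; |flow| below 0.05 px (noise votes); or d below
0.2 r (velocity aggregation only). At least 50 surviving pixels are
required, otherwise the frame pair is reported as carrying insufficient
motion. The median (not mean) amplitude is used because the excluded-zone
boundaries still admit heavy-tailed outliers. Per-pair axes are reported
independently, with no temporal smoothing: the axis change between
adjacent frames is treated as negligible, while its drift across the
sequence is itself a measurand.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 10 | (0..255 intensity)^2 | Horn–Schunck regularisation weight; larger = smoother flow |
| `max_iter` / `tol` | 300 / 1e-4 | – / px | relaxation cap and mean-update stopping threshold |
| `sigma` | 1.5 | px | Gaussian preprocessing width |
| `rho_max` | 0.95 | fraction of r | limb exclusion |
| `z_min` | 0.1 | fraction of r | lift singularity guard |
| `mag_floor` | 0.05 | px | flow-noise floor |
| `d_min` | 0.2 | fraction of r | near-axis exclusion for velocity votes |
| SSDA threshold | adaptive | – | 2 x (comparisons so far) x MAD(template) |
| search window | ±15 | px | tracking window after frame 0 |

`alpha` is quoted on the classical 0–255 grayscale scale; frames are
normalised to [0, 1] on load, so the solver rescales intensities by 255
before differentiation (a common intensity scale factor leaves the
recovered displacements unchanged). No coarse-to-fine pyramid is used:
the validated operating band is 0–4 degrees/frame, i.e. sub-2-pixel rim
displacements for radii up to ~50 px, which single-level relaxation
resolves; beyond that band estimates are still returned but flagged
`out_of_band`.

## Electrorotation physics

A polarisable sphere in an AC field of angular frequency `omega`
experiences the rotational torque `4 pi r^3 eps_m Im[K] E_rms^2` with
`K = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*)` and
`eps* = eps - j sigma/omega` (homogeneous-sphere Clausius–Mossotti
factor; membrane-shell models are out of scope). Balancing against the
Stokes drag torque `8 pi eta V r^3` gives
`V = eps_m Im[K] E_rms^2 / (2 eta)` — notably independent of the radius —
and inversely `Im[K] = 2 eta V / (eps_m E_rms^2)`. Two measurements at
distinct frequencies constrain `(eps_p, sigma_p)`; the solver runs bounded
least squares in log-parameter space from a 5x5 grid of starts within wide
physiological bounds (eps_p in [eps_0, 8000 eps_0], sigma_p in
[1e-6, 10] S/m), returns the root with the smallest residual, raises a
no-solution error when the best residual exceeds a relative tolerance,
and warns when several distinct roots fit. Identifiability is the user's
burden: two frequencies on the same side of, and far from, the
Maxwell–Wagner relaxation `f_MW = (sigma_p + 2 sigma_m) /
(2 pi (eps_p + 2 eps_m))` constrain nearly the same parameter combination
and amplify measurement noise; frequencies straddling the relaxation
recover both parameters to a few percent under 1% velocity noise.

## Synthetic ground truth

The rendered globe emulates the validation imagery: a sphere of radius
50 px pinned at the centre of a 207 x 207 frame, rotating a fixed
amplitude per frame about a fixed axis (default unit(1,1,2), 2
degrees/frame, 20 frames). The surface carries 3-octave band-limited
value noise evaluated on the sphere (seeded lattice, smoothstep trilinear
interpolation, fixed affine contrast stretch), so rotating the sample
points rotates the texture rigidly and no external image asset is
shipped. The surface is alpha-composited over a mid-grey background
(default alpha 0.7, i.e. semi-transparent); optional degradations are
per-frame additive Gaussian noise, a linear brightness drift, and static
diagonal sinusoidal fringes. The radius default follows the flow solver's
single-level operating range (rim displacement `w_rad * r` stays below
~2 px at 4 degrees/frame); amplitude, transparency and noise are the
swept study conditions.

What the generator does *not* emulate: texture on the far hemisphere or
intracellular texture (the camera-facing-surface assumption is built into
both renderer and estimator — a real cell violating it flips the in-plane
axis component), refraction and diffraction by the cell body,
non-spherical shape, defocus, and motion of neighbouring objects. Passing
on these renders therefore validates the geometry and numerics of the
chain, not robustness to every optical artefact of OEK imagery.

`analytic_flow` provides the exact image-plane velocity field
`orthographic(w_rad (a x p))` of the same rigid rotation; it is the
oracle for the back-projection stage in isolation (axis to < 1 degree,
amplitude to < 1% over random axes and amplitudes in 0.5–4 deg/frame)
and, through vector-cosine comparison, for the flow stage.

## Numerical choices and degenerate inputs

- Derivative stencils edge-replicate at the right/bottom borders;
  neighbourhood averages reflect at all borders.
- Identical frames are an exact fixed point of the relaxation (zero flow
  at every iteration).
- SSDA ties break by lowest final accumulated error, then row-major
  position; the comparison order is a seeded permutation per candidate
  (default seed 0) so runs are reproducible.
- Subpixel localisation: parabolic fit of the NCC score over the 3x3
  neighbourhood of the integer peak, clamped to ±0.5 px, skipped at
  search-domain borders.
- The radius estimator falls back to `(M-2)/2` for an M-px template with
  no detectable gradient ring (peak below twice the median annulus
  response).
- An all-zero window or template makes NCC undefined and is rejected;
  near-parallel lifted-flow pairs are reported as degenerate rather than
  returning an unstable cross product.

## Validation metrics

A recovered axis is correct within 10 degrees of the true axis line
(sign-agnostic); a recovered amplitude is correct within 10% relative
error (exposed as a flag — the axis criterion is standard, the velocity
criterion is this package's documented choice). Error rates are the
percentage of incorrect frame pairs. Amplitude series over frame gap `n`
check linearity: a sequence stepping `delta` per frame analysed at gap
`n` should report `n * delta`.

## Known limitations

- Single-level flow underestimates large displacements: above ~4
  degrees/frame (for r ~ 50 px) the amplitude error grows with rate, which
  is the documented operating-band restriction rather than a defect.
- The frame-0 template goes stale under rotation (the visible texture
  rotates off the hemisphere), so long sequences of purely rotating
  objects track better with the declared/static geometry than with
  template re-matching.
- The homogeneous CM model cannot represent membrane-dominated dispersion;
  fitted `(eps_p, sigma_p)` are effective whole-cell values.
- Problem sizes in the test suite (6–20 frames, 207 px frames, 5–25
  random axes) were chosen to exercise every code path at interactive
  runtimes while keeping estimator error well inside the asserted
  tolerances.
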