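# Methods

## Reconstruction model

A recorded off-axis hologram is modeled as

```
I(x, y) = A_R² + A_O² + 2·A_R·A_O·cos(2π(f_x·x + f_y·y) + φ(x, y))
```

with a plane-wave fringe carrier `(f_x, f_y)` (cycles/pixel) and object
phase `φ = K·Δn·h`, `K = 2π/λ`, `Δn = n_object − n_medium`. The DFT of `I`
(stored DC-centered) splits into a DC lobe and two conjugate sidebands at
`±(f_x, f_y)`. Reconstruction:

1. **Peak location.** Integer argmax of spectral magnitude over the
   positive-horizontal-frequency half-plane, excluding a disk of radius 8
   bins around DC; ties break to the first bin in row-major order. No
   sub-pixel refinement is attempted — the windowing geometry needs only
   the bin.
2. **Windowing geometry.** `a` = half the horizontal peak-to-DC distance,
   `b` = horizontal distance to the nearer lateral edge, `c`, `d` = vertical
   distances to the top and bottom resolution limits; the maximum square
   has side `Rm = 2·min(a, b, c, d)` (even by construction, so `Rm/2` is
   integral). The default window side is `⌊2Rm/3⌋` snapped down to odd, so
   every window has a unique central pixel; `Rm/2 < SW < Rm` is enforced as
   a hard validation, since `SW ≤ Rm/2` can exclude the peak from an
   off-center window and `SW ≥ Rm` cannot fit inside the maximum square.
3. **Center sampling.** `NR` distinct centers (default 20), the first
   always the peak, the rest drawn uniformly without replacement from the
   `(Rm−SW+1)`-odd-sided eligible square, using a seeded generator.
   Sampling is without replacement because duplicate centers would silently
   reduce the effective ensemble size.
4. **Extraction.** The `SW×SW` block around a center is copied into an
   otherwise-zero spectrum at the DC-centered position; recentering removes
   the carrier. The *same* `(center, SW)` is applied to the reference
   spectrum: an off-peak center leaves a residual linear phase ramp in each
   single reconstruction, and only identical windows make it cancel exactly
   in the object-minus-reference difference.
5. **Phase difference.** `arctan2(Im, Re)` of each inverse transform
   (four-quadrant, wrapped to `[−π, π)`), then the wrapped difference
   object − reference. The difference — not the two maps separately — is
   unwrapped: it has far fewer fringes and residues.
6. **Unwrapping.** Goldstein branch-cut (below), seeded at the pixel of
   maximum object-field magnitude (highest SNR).
7. **Ensemble average.** Each per-center unwrapped difference is snapped to
   the 2π branch that puts its median nearest zero — unwrap output is only
   defined up to a global 2π multiple, and without the snap maps from
   different centers could differ by multiples of `λ/Δn` (6.65 μm for red
   blood cells), corrupting the mean. Heights `Δφ_i/(K·Δn)` are then
   averaged pixelwise; pixels flagged unreliable by the unwrapper are
   dropped from the average at those pixels (the count of contributing
   terms is tracked), falling back to the plain mean where every term is
   flagged. Averaging happens in height (equivalently unwrapped phase), not
   in the complex field and not in wrapped phase, which would bias near ±π.
8. **Leveling.** A least-squares plane fitted to background pixels (default:
   at or below the 25th height percentile) is subtracted once, after
   averaging (leveling commutes with the mean), and the background median
   is set to zero. At micrometer scale the slide is never level, so only
   relative height is physical.

The conventional single-sideband baseline is the `NR = 1` ensemble (the
peak-centered window); the two code paths are identical by construction,
and their outputs bit-identical. The Gaussian baseline convolves the
conventional height map with an isotropic kernel (σ = 2 px default,
reflective boundaries).

## Goldstein unwrapping

Residues are the winding charges of 2×2 plaquettes: the sum of the four
wrapped differences around the loop, divided by 2π and rounded — 0 on any
field whose wrapped gradients stay below π in magnitude, ±1 at phase
vortices. Unbalanced residues are paired greedily: each searches boxes of
Chebyshev radius 1, 2, 4, … for the nearest opposite-charge unbalanced
residue, with the grid border acting as an opposite-charge sink whenever it
is at least as close. Each pairing is rasterized as an 8-connected Bresenham
pixel chain (which a 4-connected integration path cannot cross). Wrapped
gradients are then integrated by a vectorized layered flood fill from the
seed pixel, never entering cut pixels; remaining pixels (the cuts and any
region they enclose) are filled afterwards from their nearest unwrapped
neighbour — still via wrapped gradients, so rewrapping the output
reproduces the input exactly everywhere — and flagged in `unreliable_mask`
for the mask-aware ensemble average. On residue-free inputs no cuts exist
and the result equals any spanning-tree integration exactly; the test suite
checks agreement with an independent spanning-tree oracle and exact
recovery of planes and 6π bumps.

Greedy nearest-neighbour pairing can place longer cuts than the minimal
matching; this only grows the flagged region, never breaks rewrap
consistency.

## Simulator

The simulator emulates the optical configuration the reconstruction
defaults describe: λ = 0.532 μm; object-plane pixel pitch 0.055 μm (2.2 μm
sensor pitch behind a 40×/0.65 NA objective); horizontal carrier 0.1875
cycles/px (sideband at 3/8 of Nyquist — fringes as horizontal as possible,
which maximizes `Rm`); refractive indices 1.42/1.34 for red blood cells in
plasma and 1.5983/1.49 for polystyrene beads in their medium at 532 nm.
A plane-wave carrier replaces the physical two-spherical-wave geometry — at
sensor scale the local fringe model is equivalent and no stage uses
wavefront curvature. Objects are pure phase (transparent); absorption is
out of scope.

Nonuniform illumination is modeled by a shared Gaussian beam-amplitude
envelope (`beam_envelope_sigma`, pixels; `None` = uniform). Its purpose is
to spread the DC term over a broad low-frequency band — the noise source
the random-center averaging decorrelates. Additive Gaussian camera noise
(`noise_sigma`, fraction of full scale; default 0.02), clipping to
`[0, 2^bits − 1]`, and quantization (16-bit default) complete the model;
reference and object frames draw independent noise from one seeded
generator, so pairs are bit-reproducible per seed.

Phantoms: the transmissive bead is the chord-length profile
`h = 2√(r² − ρ²)` (its maximum equals the bead diameter — transmission
cannot distinguish the lower and upper hemisphere); the discocyte is an
Evans–Fung-style polynomial `√(1−u²)·(C0 + C2·u² + C4·u⁴)` rescaled so the
rim maximum equals the requested height. Both are rotationally symmetric
and zero outside their support.

### What the simulator does not model

Speckle, partial coherence, defocus/propagation, lens aberrations, and
wavefront curvature are absent, and real DC spectra are messier than a
Gaussian envelope's. Passing tests therefore demonstrate the *algorithmic*
properties of the pipeline (geometry enforcement, carrier cancellation,
unwrapping correctness, noise-averaging behaviour) under a controlled
noise model — not end-to-end accuracy on any particular instrument.

## Problem sizes and regimes

Two sampling regimes appear in the tests, chosen deliberately:

- **Fine sampling** (512×512 or 256×256 at 0.055 μm pitch): the window
  band covers the object's central spectrum well; a noiseless bead
  reconstructs to ≲ 0.5% peak-height error. Used for the height-accuracy
  checks and the headline bead-diameter recovery.
- **Coarse sampling** (256×256 at 0.11 μm pitch) for the noisy Monte-Carlo
  bench: the bead's steep-edge spectrum then far exceeds any admissible
  window, so single-window reconstructions suffer DC leakage noise and
  occasional unwrap errors — the regime the ensemble average is designed
  for, and the one in which the method-ordering (SSIM up, MSE down,
  background RMS down with growing NR) is asserted over 10 seeded noise
  realizations. Grid sizes keep the full suite around a minute on one CPU.

A related physical limit: windows centered off-peak crop the object band
asymmetrically, so for objects whose spectrum massively overfills the
window (a bead's edge at fine pitch) individual ensemble terms can lose
whole fringes at the support edge. Ensemble averaging is at its best when
per-term errors are noise-like and decorrelated (noisy recordings, gentle
phase objects such as discocytes), which is the regime the method targets.

## Numerical choices

- Wrapping convention `[−π, π)` via `(x + π) mod 2π − π`, applied
  identically in residue computation, integration, and differencing.
- DC-centered spectral layout everywhere in geometry arithmetic;
  conversion to the FFT library's native layout is internal.
- Integer bin argmax for the peak; row-major tie-break (deterministic).
- `Rm` floored to even; `SW` forced odd; `b` measured to the *nearer*
  lateral edge so either fringe-orientation sign works. Vertical-fringe
  holograms are handled by rotating the input 90°, not by extra geometry.
- SSIM: 7×7 uniform window, K1 = 0.01, K2 = 0.03, sample (n−1) covariance,
  border-cropped mean — the original formulation's defaults, exposed as
  parameters. `data_range` is the ideal model's maximum. MSE is reported in
  μm² on leveled maps.
- Random sampling uses `numpy.random.default_rng(seed)` throughout; every
  randomized routine takes an explicit seed.

## Known limitations

- The unwrapper's cut placement is greedy, not minimum-cost; pathological
  residue constellations may flag more pixels than necessary.
- Peak location assumes the sideband outweighs any other off-DC feature on
  its half-plane; a hologram with no fringes (or vertical fringes without
  pre-rotation) is rejected rather than guessed at.
- `NR` trades runtime for noise suppression linearly; beyond ~20 the
  background RMS improvement flattens while cost keeps growing.
- Heights are relative to the fitted background plane; absolute offsets are
  not recoverable from a single pair.
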