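# Methods

This note documents the models, conventions and numerical choices behind
`hsfocus`, in the order data flows through the package.

## Focus measures

All 22 operators map one 2D frame of non-negative detector counts to a
scalar; larger means sharper (LOG is the one signed exception, below).
Conventions that apply across the registry:

* **Valid-region convolution.** Kernel operators (TEN1/TEN2, EOL/SML/DLF,
  MF-DCT) evaluate only where the kernel fits entirely inside the frame.
  Padding would let boundary artifacts — not image content — dominate the
  response on small ROIs.
* **Directionality.** ABG/SAG/BRE/BOD difference along a row (the second
  array axis), which is the spatial axis of a pushbroom frame; the
  wavelength axis of such frames is smooth and carries little defocus
  signal.  For the same reason the registry lags ACF/VOL5 along the
  spatial axis too, although the standalone functions default to the
  classic first-axis indexing of those formulas.  Both are configurable
  (`FMOptions.diff_axis`, `FMOptions.lag_axis`).
* **Threshold θ.** TEN1/TEN2 accumulate only gradient magnitudes above θ,
  ABG/SAG/BRE only absolute differences above θ.  The default is θ = 0
  (deterministic, assumption-free); `threshold="auto"` sets θ to 2× a
  wavelet-MAD noise estimate of the frame, which scales the threshold with
  the noise floor when evaluating noisy stacks.
* **Histograms.** ENT, LOG and WHS use exact integer gray levels for
  integer frames and 256 equal bins (bin centers as levels) for float
  frames.  Rebinned per-frame histograms are the one place where float
  pipelines can mislead: a per-frame min–max range makes entropy *rise*
  under blur, so frames should stay integer counts (the synthetic detector
  guarantees this).
* **LOG sign.** LOG = Σ (l − E)²·ln p_l with E = Σ l·ln p_l is evaluated
  verbatim; since ln p_l ≤ 0 the value is non-positive, and focus curves
  are built from |LOG| so the "peak = best focus" convention holds.  The
  label VAR seen in published rankings is accepted as an alias.
* **DCT scalarization.** The block DCT operator reduces to the sum of
  squared AC coefficients on 8×8 blocks (the non-DC Parseval energy):
  exact, offset-invariant, and consistent with the energy interpretation
  of its mid-frequency 4×4 variant.
* **Wavelets.** WL1–WL3 use one level of Daubechies-6 with *symmetric*
  (mirror) extension.  Mirror extension annihilates constant frames
  exactly (detail energy < 1e−12) and, unlike periodic wrap-around, adds
  no synthetic edge at the frame boundary — with periodic extension the
  seam's detail energy survives blur and eventually dominates, breaking
  the monotone blur response.  Depth and filter are configurable.
* **FFT weighting.** Frames are zero-padded to the next power of two per
  axis, the spectrum is centered, and magnitudes are weighted by radial
  frequency √(u²+v²), which gives the DC term zero weight.
* **DLF diagonals.** The diagonal Laplacian terms use the standard masks
  [[0,0,1],[0,−2,0],[1,0,0]]/√2 and its mirror — the 1/√2 weight accounts
  for the longer diagonal step.

Every kernel/difference operator is cross-checked against an independent
double-loop implementation in the test suite (exact in integer
arithmetic).

## PCA focus reference

For each frame: standardize with the global scalar mean and standard
deviation (a per-pixel mean is ill-defined for a single image), form
C = ImᵀIm/(W·H) over the *smaller* frame axis (the nonzero spectrum is the
same either way and the eigenproblem stays cheap), symmetrize, and clamp
eigenvalues below 1e−10·λ_max to zero.  The reference curve plots, per
focal position, the smallest k whose leading eigenvalues reach the target
variance fraction (default 0.99); its global minimum is the reference
focus, with exact ties resolved to the index nearest the stack center
(deterministic and unbiased for symmetric curves).

Why the minimum sits at focus: a focused frame has maximal signal
variance, so after standardization the detector-noise floor — which is
spread roughly uniformly over all components — occupies the smallest
fraction of the total, and few components cover 99%.  Defocus shrinks the
signal variance while the noise floor stays put, pushing the count up.
Two consequences are worth stating plainly, because they define what the
method can and cannot do:

1. **The reference needs noise.**  On a strictly noise-free stack the
   logic inverts: blurred frames are smoother, hence *lower*-rank, and the
   component count falls with defocus.  Real stacks always carry shot and
   read noise, and so does the default synthetic detector.
2. **The reference needs correlated scene structure.**  Frames whose
   columns are nearly independent (white-noise-like texture at pixel
   scale) start from a high intrinsic count at focus and the minimum
   degrades.  Pushbroom frames are naturally favorable: their spectral
   axis is near-low-rank.

Degenerate (constant) frames are flagged, recorded as NaN in the curve and
excluded from the minimum search.

## Focus-curve criteria

Curves are normalized by shifting the minimum to 0 and scaling the peak
to 1 (idempotent; invariant to affine intensity changes; gives signed
measures ordinary peak semantics).  On the normalized curve:

* **d_acc** — |argmax − reference| in scan steps.  A plateau of equal
  maxima resolves to its midpoint; an even plateau resolves to the
  midpoint candidate nearer the reference.
* **d_uni** — the number of local maxima with prominence ≥ 0.05 (of the
  unit peak), the global peak excluded.  A count, not a binary flag: two
  false peaks trap a focus search worse than one.  The prominence default
  is configurable; 0.05 ignores sampling-level ripple while catching any
  bump a hill-climbing search could stall on.
* **d_50 / d_90** — width of the contiguous region around the peak where
  the curve stays ≥ 0.5 / ≥ 0.9, with linear interpolation at the
  crossings, reported as a fraction of the scanned span so stacks of
  different lengths aggregate on one scale.  A side that never drops below
  the level is clipped at the span edge and flagged.
* **d_smo** — total variation Σ|Δv|.  A noiseless unimodal normalized
  curve gives exactly 2 (up 1, down 1), the natural anchor; jitter adds
  to it.

## Ranking

Criterion vectors are averaged per measure across stacks (robustness
variants enter as additional stacks), then each criterion is divided by
its maximum *within the measure's family* — so every family block carries
a 1.00 per criterion column and each criterion contributes equal weight —
and the overall score D is the Euclidean norm of the five normalized
distances.  Measures are ranked by ascending D within family, ties broken
lexicographically; printed tables round half-up to two decimals.
Normalization after (not before) averaging, and per-family rather than
global scope, are deliberate; both are switchable in the API.

## Synthetic stacks

The generator's job is to give the whole system a testable ground truth,
reproducing the features of real through-focus stacks that the method
actually depends on:

* **Scene.**  The default pushbroom soil frame is a rank-8 mixture of
  smooth reflectance spectra (rows = wavelength) with granular 1D
  abundance profiles along the spatial axis (1/f base plus thresholded
  grain clumps, fixed unit contrast), modulated by 3% of band-limited
  (σ ≈ 0.7 px) non-separable fine structure standing in for per-pixel
  material variation.  This gives the strong inter-column correlation the
  PCA reference requires *and* broadband spatial texture for the gradient
  and frequency operators.  Video-type scenes use an isotropic granular
  texture; a period-doubling bar target and a mixed scene are also
  provided.  Everything is reproducible from the scene seed.
* **Optics.**  ΔZ = λ/(4n(1 − √(1 − (NA/n)²))) with λ = 0.55 μm, n = 1,
  NA = 0.28 gives ΔZ ≈ 3.44 μm; the scan step is ΔZ/2 (Nyquist).  Defocus
  blur is Gaussian with σ = 0.5 px per μm of defocus — about one pixel of
  blur per half-DOF step, consistent with what "depth of field" means and
  with geometric optics at sub-μm effective pixel pitch.  The true PSF of
  any given instrument is unknowable here; only the monotone, symmetric
  growth of blur with defocus matters for evaluating the measures.
* **Detector.**  Frames are integer counts: Poisson shot noise on the
  signal plus Gaussian read noise (σ = 2 counts), clipped to the 12-bit
  range, with mid-range exposure (scene peak ≈ 800 counts).  This
  photon-limited regime is what real cameras deliver and what the PCA
  reference needs.  ``detector=None`` renders ideal frames for analytic
  checks (the center frame then equals the scene bit-for-bit).
* **Robustness protocols.**  Added Poisson noise draws an independent
  variate of mean `level` per pixel (levels 10/25/50/100); an alternative
  signal-scaled mode Poisson(I/level)·level is available.  Noise is added
  to ideal (noise-free-detector) renders so the protocol isolates the
  added noise.  The illumination gradient multiplies every frame by a
  quadratic ramp spanning [0, peak] along the spatial axis, vertex at the
  center (configurable to edge-vertex).

### What the generator does *not* emulate

No diffraction or aberration modeling, no slit/spectrograph smile or
keystone, no stage drift or scene motion between frames, no fixed-pattern
(pixel-response) nonuniformity — the last deliberately, because a fixed
pattern survives blur and would hand every operator a spurious sharp
signal.  Passing tests on these stacks show that the operators, reference
and ranking arithmetic behave as designed under controlled blur and noise;
they do not certify any particular ranking of measures on a real
instrument, which depends on scene content, magnification and band.

## Problem sizes and determinism

Default test-scale conditions are 96×96 frames, 81-frame stacks and 20
seeded replicates for ground-truth recovery; the noise protocol uses 3
scenes × 3 noise seeds per level.  These sizes keep the full suite around
half a minute while leaving every check statistically comfortable at its
tolerance.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns with the same configuration and seed
are bit-identical, and the evaluation pipeline itself contains no
randomness at all.

## Known limitations

* The PCA reference degrades on scenes without inter-column correlation
  and on noise-free data (see above); it is a reference for realistic
  detector data, not an intrinsic sharpness functional.
* d_smo saturates at its anchor 2 for measures whose curves are
  structurally immune to uncorrelated noise (NVR, VOL5): added white noise
  does not roughen their curves measurably at these frame sizes, so
  noise-level trends in d_smo are informative only for the other measures.
* Widths clipped at the scan edge (curves that never fall below 50% or
  90% inside the span) are reported at the span with a flag rather than
  extrapolated.
* Autofocus *search* strategy and speed are out of scope: the package
  evaluates exhaustively sampled stacks.
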