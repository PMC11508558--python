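"""Synthetic through-focus stacks with known ground-truth focus.

Real benchmark stacks come off pushbroom hyperspectral microscopes and are
not redistributable, so this module renders stand-ins with a controlled
ground truth: a seeded textured scene, Gaussian defocus blur whose width
grows linearly and symmetrically with distance from the true focus, a
physical detector model (photon shot noise, read noise, integer
quantization), optional added Poisson noise at the benchmark levels
(10/25/50/100) and an optional multiplicative quadratic illumination
gradient.

Scene model
-----------
The default ``soil`` texture emulates an instantaneous pushbroom frame of a
granular soil sample: a rank-``n_endmembers`` mixture of smooth reflectance
spectra (rows index wavelength) with granular 1D abundance profiles along
the spatial axis, modulated by a few percent of band-limited non-separable
fine structure (per-pixel material variation).  Two properties of real
frames matter and are reproduced deliberately: strong inter-column
correlation (near-low-rank spectral structure), which the PCA focus
reference relies on, and a fine-detail field band-limited at the
diffraction scale (≈0.7 px).  Because Gaussian widths compose in
quadrature, blurring a band-limited component by σ_d is exactly equivalent
to imaging it through the combined PSF.

``edges`` is a bar target with period-doubling stripe widths; ``mixed``
splices soil and bars.  ``spatial_spatial`` scenes (conventional video)
use an isotropic granular soil texture instead of the spectral mixture.

Detector and optics
-------------------
Frames are integer detector counts: Poisson shot noise on the signal plus
Gaussian read noise, clipped to the bit-depth range.  ``detector=None``
renders ideal noise-free frames (useful for analytic checks).  The mean
exposure sits mid-range (peak ≈ 800 counts of 4095) — the photon-limited
regime of a real camera, which the PCA focus reference relies on: defocus
lowers the signal variance while the noise floor stays put, so defocused
frames need more principal components for a fixed variance fraction.

The depth of field ΔZ = λ / (4·n·(1 − sqrt(1 − (NA/n)²))) sets the axial
scale, the through-focus step is ΔZ/2 (Nyquist sampling of the axial
response) and the blur kernel is Gaussian with σ(z) = blur_gain·|z − z_f|
pixels.  Diffraction, aberrations and slit/spectrograph optics are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack_io import FocusStack, ImageFrame

__all__ = [
    "SceneSpec",
    "OpticsSpec",
    "DetectorSpec",
    "make_scene",
    "dof",
    "step_size",
    "render_stack",
    "add_poisson_noise",
    "apply_illumination_gradient",
    "illumination_profile",
]


@dataclass(frozen=True)
class SceneSpec:
    """In-focus scene description (reproducible from its seed).

    ``peak_counts`` is the brightest scene intensity in detector counts;
    ``detail_contrast`` the relative amplitude of the non-separable fine
    structure.  ``psf_sigma`` optionally band-limits the whole in-focus
    scene (the spectral soil texture already band-limits its fine-detail
    field, so the default applies no extra smoothing).
    """

    texture: str = "soil"
    size: tuple[int, int] = (96, 96)
    bit_depth: int = 12
    peak_counts: float = 800.0
    axes: str = "spatial_spectral"
    n_endmembers: int = 8
    detail_contrast: float = 0.03
    psf_sigma: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class OpticsSpec:
    """Axial imaging model of the through-focus scan.

    wavelength_um : effective illumination wavelength λ (μm)
    n             : refractive index of the immersion medium (air ≈ 1)
    na            : numerical aperture of the objective (0 < NA < n)
    blur_gain     : PSF σ in pixels per μm of defocus
    true_focus_z  : focal position of the sharp frame (μm)
    """

    wavelength_um: float = 0.55
    n: float = 1.0
    na: float = 0.28
    blur_gain: float = 0.5
    true_focus_z: float = 0.0


@dataclass(frozen=True)
class DetectorSpec:
    """Camera noise model: Poisson shot noise plus Gaussian read noise."""

    shot_noise: bool = True
    read_noise: float = 2.0


def _fractal_noise(rng: np.random.Generator, shape: tuple[int, int],
                   beta: float) -> np.ndarray:
    """1/f^beta-filtered white noise, normalized to [0, 1]."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0 / max(shape)
    field = np.fft.ifft2(np.fft.fft2(white) / f**beta).real
    field -= field.min()
    return field / field.max()


def _granular_profile(rng: np.random.Generator, width: int) -> np.ndarray:
    """Soil-like 1D abundance profile: 1/f base with thresholded grain clumps."""
    base = _fractal_noise(rng, (1, width), 1.2)[0]
    grains = (_fractal_noise(rng, (1, width), 0.7)[0] > 0.5).astype(float)
    prof = 0.4 * base + 0.6 * grains * base
    prof -= prof.min()
    return prof / max(prof.std(), 1e-9) * 0.25


def _soil_spectral(rng: np.random.Generator, shape: tuple[int, int],
                   k: int, detail_contrast: float) -> np.ndarray:
    """Pushbroom soil frame: low-rank spectral mixture + fine structure."""
    h, w = shape
    lam = np.linspace(0.0, 1.0, h)
    centers = (np.arange(k) + 0.5) / k + rng.uniform(-0.04, 0.04, k)
    widths = rng.uniform(0.06, 0.25, k)
    spectra = np.stack(
        [0.25 + 0.75 * np.exp(-(((lam - c) / wd) ** 2)) for c, wd in zip(centers, widths)]
    )
    profiles = np.stack([_granular_profile(rng, w) for _ in range(k)])
    img = spectra.T @ profiles
    img -= img.min()
    img /= img.max()
    img = 0.15 + 0.85 * img
    detail = gaussian_filter(_fractal_noise(rng, shape, 0.9), 0.7)
    detail = (detail - detail.mean()) / max(detail.std(), 1e-9)
    img = img * (1.0 + detail_contrast * detail)
    img -= min(img.min(), 0.0)
    return img / img.max()


def _soil_isotropic(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Conventional-video soil frame: isotropic 1/f base with grain clumps."""
    base = _fractal_noise(rng, shape, 1.2)
    grains = _fractal_noise(rng, shape, 0.8)
    clumps = gaussian_filter((grains > np.quantile(grains, 0.45)).astype(float), 0.6)
    tex = 0.25 + 0.45 * base + 0.30 * clumps * grains
    return tex / tex.max()


def _bar_target(shape: tuple[int, int]) -> np.ndarray:
    """Vertical bars with period-doubling widths across the frame."""
    w = shape[1]
    profile = np.full(w, 0.15)
    col, widths, k = 0, (1, 2, 4, 8), 0
    while col < w:
        width = widths[k % len(widths)]
        profile[col : col + width] = 0.95
        col += 2 * width
        k += 1
    return np.tile(profile, (shape[0], 1))


def make_scene(spec: SceneSpec) -> ImageFrame:
    """Render the in-focus scene as an integer frame of the given bit depth."""
    rng = np.random.default_rng(spec.seed)
    if spec.texture == "soil":
        if spec.axes == "spatial_spectral":
            tex = _soil_spectral(rng, spec.size, spec.n_endmembers,
                                 spec.detail_contrast)
        else:
            tex = _soil_isotropic(rng, spec.size)
    elif spec.texture == "edges":
        tex = _bar_target(spec.size)
    elif spec.texture == "mixed":
        tex = (_soil_spectral(rng, spec.size, spec.n_endmembers, spec.detail_contrast)
               if spec.axes == "spatial_spectral" else _soil_isotropic(rng, spec.size))
        half = spec.size[1] // 2
        tex[:, half:] = _bar_target(spec.size)[:, half:]
    else:
        raise ValueError(f"unknown texture {spec.texture!r}")
    if spec.psf_sigma > 0:
        tex = gaussian_filter(tex, spec.psf_sigma)
    counts = np.round(tex / tex.max() * spec.peak_counts)
    counts = counts.clip(0, 2**spec.bit_depth - 1)
    return ImageFrame(counts.astype(np.uint16), bit_depth=spec.bit_depth,
                      axes=spec.axes)


def dof(optics: OpticsSpec) -> float:
    """Depth of field ΔZ = λ / (4·n·(1 − sqrt(1 − (NA/n)²))) in μm."""
    if not 0.0 < optics.na < optics.n:
        raise ValueError("need 0 < NA < n")
    if optics.wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    root = np.sqrt(1.0 - (optics.na / optics.n) ** 2)
    return float(optics.wavelength_um / (4.0 * optics.n * (1.0 - root)))


def step_size(optics: OpticsSpec) -> float:
    """Axial scan step: half the depth of field (Nyquist criterion)."""
    return dof(optics) / 2.0


def render_stack(scene: ImageFrame | SceneSpec, optics: OpticsSpec | None = None,
                 n_frames: int = 81,
                 detector: DetectorSpec | None = DetectorSpec(),
                 seed: int = 0) -> FocusStack:
    """Image the scene through focus: σ(z) = blur_gain·|z − z_focus|.

    The scan is centered on the true focus with step ΔZ/2; frames at ±k
    steps are blurred identically, and detector noise (if any) is drawn
    independently per frame from ``seed``.  With ``detector=None`` the
    middle frame (index ``n_frames // 2``) equals the scene exactly.  The
    true focus index is recorded in the stack metadata.
    """
    if isinstance(scene, SceneSpec):
        scene = make_scene(scene)
    optics = optics or OpticsSpec()
    if n_frames < 3:
        raise ValueError("a through-focus stack needs at least 3 frames")
    step = step_size(optics)
    center = n_frames // 2
    z = optics.true_focus_z + (np.arange(n_frames) - center) * step
    base = scene.pixels.astype(np.float64)
    full_scale = 2**scene.bit_depth - 1
    rng = np.random.default_rng(seed)
    frames = []
    for zi in z:
        sigma = optics.blur_gain * abs(zi - optics.true_focus_z)
        px = base if sigma == 0 else gaussian_filter(base, sigma)
        if detector is not None:
            if detector.shot_noise:
                px = rng.poisson(px).astype(np.float64)
            if detector.read_noise > 0:
                px = px + rng.normal(0.0, detector.read_noise, px.shape)
            px = np.round(px).clip(0, full_scale).astype(np.uint16)
        frames.append(replace(scene, pixels=px))
    meta = {
        "true_focus_index": center,
        "step_um": step,
        "dof_um": dof(optics),
        "blur_gain": optics.blur_gain,
        "detector": None if detector is None else
        {"shot_noise": detector.shot_noise, "read_noise": detector.read_noise},
        "seed": seed,
    }
    return FocusStack(frames=frames, z_um=z, meta=meta)


def add_poisson_noise(stack: FocusStack, level: float, seed: int = 0,
                      mode: str = "additive") -> FocusStack:
    """Added Poisson noise at the benchmark levels (10, 25, 50, 100).

    ``additive`` (default) adds an independent Poisson variate of mean
    ``level`` to every pixel — the semantics of the benchmark's noise
    parameter.  ``scaled`` instead redraws signal-dependent shot noise,
    Poisson(I/level)·level.  Values saturate at the detector range.
    """
    if level <= 0:
        raise ValueError("noise level must be positive")
    rng = np.random.default_rng(seed)
    full_scale = 2**stack.bit_depth - 1
    frames = []
    for fr in stack.frames:
        if mode == "additive":
            noisy = fr.pixels + rng.poisson(level, size=fr.pixels.shape)
        elif mode == "scaled":
            noisy = rng.poisson(fr.pixels / level) * float(level)
        else:
            raise ValueError(f"unknown noise mode {mode!r}")
        frames.append(replace(fr, pixels=np.clip(noisy, 0, full_scale)))
    meta = dict(stack.meta, poisson_level=level, poisson_mode=mode, noise_seed=seed)
    return FocusStack(frames=frames, z_um=stack.z_um, dark_frame=stack.dark_frame,
                      meta=meta)


def illumination_profile(width: int, peak: float,
                         orientation: str = "center") -> np.ndarray:
    """Quadratic gray-level ramp in [0, peak] along one axis.

    ``center`` puts the vertex (value ``peak``) mid-axis with zeros at both
    edges; ``edge`` puts it at the first sample with zero at the far edge.
    """
    if not 0.0 < peak <= 1.0:
        raise ValueError("peak must lie in (0, 1]")
    x = np.linspace(0.0, 1.0, width)
    if orientation == "center":
        g = 1.0 - (2.0 * x - 1.0) ** 2
    elif orientation == "edge":
        g = 1.0 - x**2
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return peak * g


def apply_illumination_gradient(stack: FocusStack, peak: float = 0.9,
                                orientation: str = "center",
                                axis: int = 1) -> FocusStack:
    """Multiply every frame by a fixed quadratic illumination ramp.

    Emulates nonuniform lamp illumination: the profile spans [0, peak]
    along ``axis`` (default: along a row, the spatial axis), identically
    for all frames.
    """
    width = stack.frame_shape[axis]
    g = illumination_profile(width, peak, orientation)
    g = g[None, :] if axis == 1 else g[:, None]
    frames = [replace(fr, pixels=fr.pixels * g) for fr in stack.frames]
    meta = dict(stack.meta, illumination_peak=peak,
                illumination_orientation=orientation)
    return FocusStack(frames=frames, z_um=stack.z_um, dark_frame=stack.dark_frame,
                      meta=meta)
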