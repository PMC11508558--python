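"""The 22 focus-measure (FM) operators and their registry.

Each operator maps a 2D frame to one scalar sharpness value; through a stack
these values trace a focus curve whose global peak marks the best focus.
The operators fall into three families:

gradient
    TEN1/TEN2 (Tenengrad on Sobel/Prewitt kernels), EOL (energy of
    Laplacian), SML (sum-modified Laplacian), DLF (diagonal Laplacian),
    ABG/SAG/BRE (thresholded first/second horizontal differences),
    EIG (energy of image gradient), BOD (Boddeke's central difference).
statistics
    NVR (normalized variance), ACF/VOL5 (Vollath F4/F5 autocorrelations),
    ENT (histogram entropy), LOG (variance of the log-histogram, alias VAR),
    WHS (weighted histogram).
frequency
    FFT (radius-weighted Fourier magnitudes), DCT (block AC energy),
    MFDCT (mid-frequency DCT mask), WL1/WL2/WL3 (Daubechies-6 wavelet
    detail-band statistics).

Conventions (all configurable through :class:`FMOptions`):

* kernel operators use the *valid* region only (no padding);
* "horizontal" differencing (ABG/SAG/BRE/BOD) runs along a row, i.e. along
  the second array axis — the spatial axis of a pushbroom frame;
* the ACF/VOL5 functions default to a lag along the first array axis (their
  classic indexing), but the registry lags along the spatial axis so all
  directional operators sense the same direction;
* histogram operators use exact integer levels for integer frames and
  256 bins otherwise;
* LOG is evaluated verbatim (it is non-positive because log p_l <= 0);
  focus curves built from it should use its magnitude (``use_abs`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt
from scipy import fft as sfft
from scipy.signal import correlate2d

from .errors import DegenerateFrameError
from .stack_io import ImageFrame

__all__ = [
    "FMOptions",
    "FMResult",
    "FM_ORDER",
    "FAMILY",
    "ALIASES",
    "canonical_id",
    "compute",
    "compute_all",
    "tenengrad",
    "laplacian_energy",
    "derivative_fm",
    "energy_of_gradient",
    "boddeke",
    "normalized_variance",
    "vollath_f4",
    "vollath_f5",
    "entropy_fm",
    "log_histogram_variance",
    "weighted_histogram",
    "fourier_fm",
    "dct_fm",
    "midfreq_dct_fm",
    "wavelet_fm",
    "estimate_noise_sigma",
]


@dataclass(frozen=True)
class FMOptions:
    """Shared operator options.

    threshold
        Gradient/difference threshold θ in intensity units (TEN1/TEN2 and
        ABG/SAG/BRE).  ``"auto"`` uses 2× a wavelet-MAD noise estimate of
        the frame, scaling the threshold with the noise floor.
    histogram_bins
        Bin count for histogram operators on float frames (``None`` →
        exact integer levels for integer frames, 256 bins otherwise).
    wavelet / wavelet_levels
        Wavelet filter (Daubechies-6) and decomposition depth for WL1–WL3.
    whs_power / whs_root
        Gray-level exponent and histogram-count root of WHS (defaults 5/5,
        the classic empirically chosen values).
    dct_block
        Working block size K of the block DCT operator.
    diff_axis / lag_axis
        Array axis for horizontal differencing (ABG/SAG/BRE/BOD) and for the
        ACF/VOL5 autocorrelation lag.
    """

    threshold: float | str = 0.0
    histogram_bins: int | None = None
    wavelet: str = "db6"
    wavelet_levels: int = 1
    whs_power: float = 5.0
    whs_root: float = 5.0
    dct_block: int = 8
    diff_axis: int = 1
    lag_axis: int = 1


@dataclass(frozen=True)
class FMResult:
    """One operator evaluation: id, family, scalar value, optional error."""

    fm_id: str
    family: str
    value: float
    error: str | None = None


FAMILY: dict[str, str] = {
    "TEN1": "gradient", "TEN2": "gradient", "EOL": "gradient", "SML": "gradient",
    "DLF": "gradient", "ABG": "gradient", "SAG": "gradient", "BRE": "gradient",
    "EIG": "gradient", "BOD": "gradient",
    "NVR": "statistics", "ACF": "statistics", "VOL5": "statistics",
    "ENT": "statistics", "LOG": "statistics", "WHS": "statistics",
    "FFT": "frequency", "DCT": "frequency", "MFDCT": "frequency",
    "WL1": "frequency", "WL2": "frequency", "WL3": "frequency",
}

FM_ORDER: tuple[str, ...] = (
    "TEN1", "TEN2", "EOL", "SML", "DLF", "ABG", "SAG", "BRE", "EIG", "BOD",
    "NVR", "ACF", "VOL5", "ENT", "LOG", "WHS",
    "FFT", "DCT", "MFDCT", "WL1", "WL2", "WL3",
)

#: printed-label aliases seen in the literature
ALIASES: dict[str, str] = {
    "VAR": "LOG",
    "FTF": "FFT",
    "FT": "FFT",
    "MD-DCT": "MFDCT",
    "MF-DCT": "MFDCT",
}

#: operators whose curves should be built from |value| (signed operators)
USE_ABS: frozenset[str] = frozenset({"LOG"})


def canonical_id(fm_id: str) -> str:
    """Resolve printed aliases (VAR, FTF, MD-DCT, ...) to registry ids."""
    fm_id = fm_id.upper()
    fm_id = ALIASES.get(fm_id, fm_id)
    if fm_id not in FAMILY:
        raise KeyError(f"unknown focus measure {fm_id!r}")
    return fm_id


def _pixels(frame) -> np.ndarray:
    px = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    return px.astype(np.float64, copy=False)


def _bit_depth(frame) -> int | None:
    return frame.bit_depth if isinstance(frame, ImageFrame) else None


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def estimate_noise_sigma(frame) -> float:
    """Robust (wavelet-MAD) estimate of the additive noise sigma of a frame."""
    from skimage.restoration import estimate_sigma

    return float(estimate_sigma(_pixels(frame)))


def _resolve_theta(frame, threshold: float | str) -> float:
    if threshold == "auto":
        return 2.0 * estimate_noise_sigma(frame)
    return float(threshold)


# ---------------------------------------------------------------------------
# gradient family


def tenengrad(frame, a: int = 2, theta: float = 0.0) -> float:
    """Tenengrad: sum of squared Sobel (a=2) or Prewitt (a=1) gradients.

    Only interior pixels whose gradient magnitude exceeds ``theta``
    contribute.
    """
    x = _pixels(frame)
    _require(x.shape[0] >= 3 and x.shape[1] >= 3, "tenengrad needs a frame >= 3x3")
    o1 = np.array([[-1.0, 0.0, 1.0], [-a, 0.0, a], [-1.0, 0.0, 1.0]])
    gx = correlate2d(x, o1, mode="valid")
    gy = correlate2d(x, o1.T, mode="valid")
    mag2 = gx * gx + gy * gy
    return float(mag2[mag2 > theta * theta].sum())


_LD1 = np.array([[0.0, 0.0, 1.0], [0.0, -2.0, 0.0], [1.0, 0.0, 0.0]]) / np.sqrt(2.0)
_LD2 = np.array([[1.0, 0.0, 0.0], [0.0, -2.0, 0.0], [0.0, 0.0, 1.0]]) / np.sqrt(2.0)


def laplacian_energy(frame, variant: str = "EOL") -> float:
    """Second-derivative operators EOL, SML and DLF on the common interior.

    EOL sums the squared Laplacian (rx + ry)²; SML sums |rx| + |ry| so
    opposite-signed directions cannot cancel; DLF adds the two diagonal
    responses, weighted 1/√2 for the longer diagonal step.
    """
    x = _pixels(frame)
    _require(x.shape[0] >= 3 and x.shape[1] >= 3, "laplacian needs a frame >= 3x3")
    lx = np.array([[-1.0, 2.0, -1.0]])
    rx = correlate2d(x, lx, mode="valid")[1:-1, :]      # (H-2, W-2)
    ry = correlate2d(x, lx.T, mode="valid")[:, 1:-1]
    if variant == "EOL":
        return float(((rx + ry) ** 2).sum())
    if variant == "SML":
        return float((np.abs(rx) + np.abs(ry)).sum())
    if variant == "DLF":
        d1 = correlate2d(x, _LD1, mode="valid")
        d2 = correlate2d(x, _LD2, mode="valid")
        return float((np.abs(rx) + np.abs(ry) + np.abs(d1) + np.abs(d2)).sum())
    raise ValueError(f"unknown Laplacian variant {variant!r}")


def derivative_fm(frame, k: int = 1, p: float = 1.0, theta: float = 0.0,
                  axis: int = 1) -> float:
    """Thresholded k-step difference |I(j) − I(j+k)|^p summed over the frame.

    (k=1, p=1) is ABG, (k=1, p=2) is SAG, (k=2, p=2) is the Brenner
    function.  Differences run along ``axis`` (default: along a row, the
    spatial axis of a pushbroom frame); only differences whose magnitude
    exceeds ``theta`` are accumulated.
    """
    x = _pixels(frame)
    _require(x.shape[axis] > k, f"frame extent along axis {axis} must exceed k={k}")
    if axis == 1:
        d = np.abs(x[:, :-k] - x[:, k:])
    else:
        d = np.abs(x[:-k, :] - x[k:, :])
    return float((d[d > theta] ** p).sum())


def energy_of_gradient(frame) -> float:
    """EIG: sum of squared forward differences along both axes."""
    x = _pixels(frame)
    _require(x.shape[0] >= 2 and x.shape[1] >= 2, "EIG needs a frame >= 2x2")
    dx = x[1:, :] - x[:-1, :]
    dy = x[:, 1:] - x[:, :-1]
    return float((dx * dx).sum() + (dy * dy).sum())


def boddeke(frame, axis: int = 1) -> float:
    """BOD: squared central differences along the spatial axis only."""
    x = _pixels(frame)
    _require(x.shape[axis] >= 3, "BOD needs at least 3 samples along its axis")
    if axis == 1:
        d = x[:, 2:] - x[:, :-2]
    else:
        d = x[2:, :] - x[:-2, :]
    return float((d * d).sum())


# ---------------------------------------------------------------------------
# statistics family


def normalized_variance(frame) -> float:
    """NVR: population variance divided by the mean intensity."""
    x = _pixels(frame)
    mu = x.mean()
    if mu <= 0:
        raise DegenerateFrameError("NVR undefined for zero-mean (all-dark) frame")
    return float(((x - mu) ** 2).sum() / (mu * x.size))


def vollath_f4(frame, axis: int = 0) -> float:
    """ACF (Vollath F4): lag-1 minus lag-2 autocorrelation products."""
    x = _pixels(frame)
    _require(x.shape[axis] >= 3, "ACF needs at least 3 samples along the lag axis")
    x = x if axis == 0 else x.T
    return float((x[:-1] * x[1:]).sum() - (x[:-2] * x[2:]).sum())


def vollath_f5(frame, axis: int = 0) -> float:
    """VOL5 (Vollath F5): lag-1 products minus H·W·μ² (may be negative)."""
    x = _pixels(frame)
    _require(x.shape[axis] >= 2, "VOL5 needs at least 2 samples along the lag axis")
    mu = x.mean()
    y = x if axis == 0 else x.T
    return float((y[:-1] * y[1:]).sum() - x.size * mu * mu)


def _histogram(frame, bins: int | None):
    """(levels, counts, n_pixels) with empty bins dropped.

    Integer frames use exact gray levels; float frames are binned (default
    256 bins) with bin centers standing in for the gray level l.
    """
    x = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    if bins is None and np.issubdtype(x.dtype, np.integer):
        counts = np.bincount(x.ravel().astype(np.int64))
        levels = np.arange(counts.size, dtype=np.float64)
    else:
        nbins = int(bins) if bins else 256
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
        levels = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return levels[keep], counts[keep].astype(np.float64), x.size


def entropy_fm(frame, bins: int | None = None) -> float:
    """ENT: Shannon entropy (bits) of the intensity histogram."""
    _, counts, n = _histogram(frame, bins)
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def log_histogram_variance(frame, bins: int | None = None) -> float:
    """LOG: Σ (l − E)² ln p_l with E = Σ l·ln p_l, over occupied bins.

    Evaluated verbatim; since ln p_l <= 0 the value is non-positive, and 0
    exactly when all mass sits in one bin.  Focus curves use |LOG|.
    """
    levels, counts, n = _histogram(frame, bins)
    p = counts / n
    logp = np.log(p)
    e_log = float((levels * logp).sum())
    return float((((levels - e_log) ** 2) * logp).sum())


def weighted_histogram(frame, power: float = 5.0, root: float = 5.0,
                       bins: int | None = None) -> float:
    """WHS: Σ 1e−15 · l^power · h(l)^(1/root) — weight on bright pixels."""
    levels, counts, _ = _histogram(frame, bins)
    return float((1e-15 * levels**power * counts ** (1.0 / root)).sum())


# ---------------------------------------------------------------------------
# frequency family


def fourier_fm(frame) -> float:
    """FFT operator: Σ √(u²+v²)·|G(u,v)| with the DC term shifted to center.

    The frame is zero-padded to the next power of two per axis before the
    transform; u, v are measured from the centered zero-frequency bin, so
    the DC component carries zero weight.
    """
    x = _pixels(frame)
    _require(x.shape[0] >= 2 and x.shape[1] >= 2, "FFT operator needs a frame >= 2x2")
    ph = 1 << (x.shape[0] - 1).bit_length()
    pw = 1 << (x.shape[1] - 1).bit_length()
    g = np.fft.fftshift(np.fft.fft2(x, s=(ph, pw)))
    u = np.arange(ph) - ph // 2
    v = np.arange(pw) - pw // 2
    w = np.sqrt(u[:, None] ** 2.0 + v[None, :] ** 2.0)
    return float((w * np.abs(g)).sum())


def dct_fm(frame, block: int = 8) -> float:
    """DCT operator: AC energy of the orthonormal block DCT-II.

    The frame is tiled into K×K blocks (cropped to whole blocks, K shrunk to
    the frame for tiny inputs); the scalar is the sum over blocks of squared
    coefficients with the DC term excluded, i.e. exactly the non-DC Parseval
    energy.
    """
    x = _pixels(frame)
    k = min(block, x.shape[0], x.shape[1])
    nr, nc = x.shape[0] // k, x.shape[1] // k
    _require(nr >= 1 and nc >= 1, "frame smaller than one DCT block")
    blocks = x[: nr * k, : nc * k].reshape(nr, k, nc, k)
    coef = sfft.dctn(blocks, axes=(1, 3), norm="ortho")
    total = (coef * coef).sum()
    dc = (coef[:, 0, :, 0] ** 2).sum()
    return float(total - dc)


_O_MDCT = np.array(
    [
        [1.0, 1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0, -1.0],
        [-1.0, -1.0, 1.0, 1.0],
        [-1.0, -1.0, 1.0, 1.0],
    ]
)


def midfreq_dct_fm(frame) -> float:
    """MF-DCT: squared responses of the 4×4 mid-frequency checker mask."""
    x = _pixels(frame)
    _require(x.shape[0] >= 4 and x.shape[1] >= 4, "MF-DCT needs a frame >= 4x4")
    r = correlate2d(x, _O_MDCT, mode="valid")
    return float((r * r).sum())


def wavelet_fm(frame, variant: str = "WL1", wavelet: str = "db6",
               levels: int = 1, mode: str = "symmetric") -> float:
    """Daubechies-6 detail-band operators WL1/WL2/WL3.

    One (or more) 2D DWT levels with mirror (symmetric) extension, which
    annihilates constant frames exactly and — unlike periodic wrap-around —
    introduces no synthetic edge at the frame boundary.  WL1 sums absolute
    detail coefficients, WL2 their variance around the absolute-value mean,
    WL3 the variance of the signed coefficients.  WL2/WL3 are scaled by the
    original pixel count.
    """
    x = _pixels(frame)
    _require(min(x.shape) >= 2, "frame too small for a wavelet decomposition")
    total = 0.0
    n = x.size
    approx = x
    for _ in range(levels):
        approx, details = pywt.dwt2(approx, wavelet, mode=mode)
        for band in details:
            if variant == "WL1":
                total += np.abs(band).sum()
            elif variant == "WL2":
                a = np.abs(band)
                total += ((a - a.mean()) ** 2).sum()
            elif variant == "WL3":
                total += ((band - band.mean()) ** 2).sum()
            else:
                raise ValueError(f"unknown wavelet variant {variant!r}")
    return float(total if variant == "WL1" else total / n)


# ---------------------------------------------------------------------------
# registry


def _dispatch(fm_id: str, frame, opts: FMOptions) -> float:
    theta = _resolve_theta(frame, opts.threshold)
    bins = opts.histogram_bins
    table: dict[str, Callable[[], float]] = {
        "TEN1": lambda: tenengrad(frame, a=2, theta=theta),
        "TEN2": lambda: tenengrad(frame, a=1, theta=theta),
        "EOL": lambda: laplacian_energy(frame, "EOL"),
        "SML": lambda: laplacian_energy(frame, "SML"),
        "DLF": lambda: laplacian_energy(frame, "DLF"),
        "ABG": lambda: derivative_fm(frame, 1, 1, theta, opts.diff_axis),
        "SAG": lambda: derivative_fm(frame, 1, 2, theta, opts.diff_axis),
        "BRE": lambda: derivative_fm(frame, 2, 2, theta, opts.diff_axis),
        "EIG": lambda: energy_of_gradient(frame),
        "BOD": lambda: boddeke(frame, opts.diff_axis),
        "NVR": lambda: normalized_variance(frame),
        "ACF": lambda: vollath_f4(frame, opts.lag_axis),
        "VOL5": lambda: vollath_f5(frame, opts.lag_axis),
        "ENT": lambda: entropy_fm(frame, bins),
        "LOG": lambda: log_histogram_variance(frame, bins),
        "WHS": lambda: weighted_histogram(frame, opts.whs_power, opts.whs_root, bins),
        "FFT": lambda: fourier_fm(frame),
        "DCT": lambda: dct_fm(frame, opts.dct_block),
        "MFDCT": lambda: midfreq_dct_fm(frame),
        "WL1": lambda: wavelet_fm(frame, "WL1", opts.wavelet, opts.wavelet_levels),
        "WL2": lambda: wavelet_fm(frame, "WL2", opts.wavelet, opts.wavelet_levels),
        "WL3": lambda: wavelet_fm(frame, "WL3", opts.wavelet, opts.wavelet_levels),
    }
    return table[fm_id]()


def compute(fm_id: str, frame, options: FMOptions | None = None) -> float:
    """Evaluate one focus measure (alias-tolerant) on a frame."""
    return _dispatch(canonical_id(fm_id), frame, options or FMOptions())


def compute_all(frame, options: FMOptions | None = None) -> list[FMResult]:
    """Evaluate all 22 operators; per-operator failures are recorded, not raised.

    Results come back in the fixed registry order :data:`FM_ORDER`.
    """
    opts = options or FMOptions()
    out: list[FMResult] = []
    for fm_id in FM_ORDER:
        try:
            value = _dispatch(fm_id, frame, opts)
            out.append(FMResult(fm_id, FAMILY[fm_id], value))
        except Exception as exc:  # noqa: BLE001 - per-entry error capture
            out.append(FMResult(fm_id, FAMILY[fm_id], float("nan"), error=str(exc)))
    return out
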