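"""PCA-based reference focus position.

A sharp frame has a high signal-to-noise ratio, so after standardization its
variance concentrates in a few strong principal components; defocus spreads
the (relatively noisier) variance across many weak ones.  The number of
components needed to retain a fixed fraction (typically 98–99%) of the
variance therefore reaches its global *minimum* at best focus, which makes
it a focus reference that needs no human-comprehensible image content — the
situation in pushbroom hyperspectral frames.  The procedure:

1. standardize each frame to zero mean and unit variance (global scalars),
2. form the column covariance C = Imᵀ·Im / (W·H),
3. count the leading eigenvalues needed to reach the target variance
   fraction,
4. plot the count against focal position; the global minimum is the
   reference ("ideal") focus used to score every focus measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFrameError
from .stack_io import FocusStack

__all__ = [
    "PCAResult",
    "PCAFocusCurve",
    "standardize",
    "covariance_matrix",
    "eigen_spectrum",
    "components_for_fraction",
    "pca_focus_curve",
]

#: eigenvalues below this fraction of the largest are treated as numerically zero
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class PCAResult:
    """Eigen-spectrum of one frame's covariance and its component count."""

    eigenvalues: np.ndarray        # descending, non-negative
    explained_fraction: np.ndarray  # cumulative, ends at 1.0
    n_components: int


@dataclass(frozen=True)
class PCAFocusCurve:
    """Component count per focal position; global minimum = reference focus."""

    z_um: np.ndarray
    component_counts: np.ndarray   # float; NaN where a frame was degenerate
    target_fraction: float
    best_focus_index: int
    excluded: tuple[int, ...] = ()


def standardize(frame) -> np.ndarray:
    """Zero-mean, unit-variance version of a frame (global scalar μ, σ)."""
    x = np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)
    sigma = x.std()
    if sigma == 0:
        raise DegenerateFrameError("constant frame cannot be standardized")
    return (x - x.mean()) / sigma


def covariance_matrix(im: np.ndarray) -> np.ndarray:
    """C = Imᵀ·Im / (W·H) over the smaller frame axis.

    For frames wider than tall the Gram matrix is taken over the row axis
    instead — the nonzero eigen-spectrum is identical and the cost stays
    bounded by the smaller dimension.
    """
    im = np.asarray(im, dtype=np.float64)
    h, w = im.shape
    c = im.T @ im if w <= h else im @ im.T
    return c / (h * w)


def eigen_spectrum(c: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the symmetrized matrix, clamped at zero."""
    c = np.asarray(c, dtype=np.float64)
    lam = np.linalg.eigvalsh((c + c.T) / 2.0)[::-1]
    if lam.size == 0 or lam[0] <= 0:
        raise DegenerateFrameError("covariance has no positive eigenvalue")
    lam[lam < _RANK_RTOL * lam[0]] = 0.0
    return lam


def components_for_fraction(c: np.ndarray, fraction: float = 0.99) -> int:
    """Smallest k whose leading eigenvalues retain ``fraction`` of the variance.

    Accepts either a covariance matrix or an already-computed 1D spectrum.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    c = np.asarray(c, dtype=np.float64)
    lam = np.sort(c)[::-1] if c.ndim == 1 else eigen_spectrum(c)
    total = lam.sum()
    if total <= 0:
        raise DegenerateFrameError("all-zero eigen-spectrum")
    cum = np.cumsum(lam) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def frame_pca(frame, fraction: float = 0.99) -> PCAResult:
    """Standardize a frame and summarize its covariance eigen-spectrum."""
    lam = eigen_spectrum(covariance_matrix(standardize(frame)))
    cum = np.cumsum(lam) / lam.sum()
    return PCAResult(lam, cum, components_for_fraction(lam, fraction))


def _argmin_center_tiebreak(counts: np.ndarray) -> int:
    """Global argmin; among ties, the index nearest the stack center wins."""
    finite = np.isfinite(counts)
    best = counts[finite].min()
    candidates = np.flatnonzero(finite & (counts == best))
    center = (len(counts) - 1) / 2.0
    return int(min(candidates, key=lambda i: (abs(i - center), i)))


def pca_focus_curve(stack: FocusStack, fraction: float = 0.99) -> PCAFocusCurve:
    """Component-count focus curve of a stack; its global minimum is the
    reference focus position.

    Degenerate (constant) frames are recorded as NaN and excluded from the
    minimum search; equal minima resolve to the index nearest the stack
    center, which is unbiased for symmetric curves.
    """
    counts = np.full(len(stack), np.nan)
    excluded: list[int] = []
    for s, frame in enumerate(stack.frames):
        try:
            counts[s] = frame_pca(frame, fraction).n_components
        except DegenerateFrameError:
            excluded.append(s)
    if not np.isfinite(counts).any():
        raise DegenerateFrameError("every frame in the stack is degenerate")
    best = _argmin_center_tiebreak(counts)
    return PCAFocusCurve(
        z_um=stack.z_um,
        component_counts=counts,
        target_fraction=fraction,
        best_focus_index=best,
        excluded=tuple(excluded),
    )
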