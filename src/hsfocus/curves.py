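"""Focus curves and the five ranking criteria.

A focus curve is the per-position scalar trace of one focus measure over a
through-focus stack.  After normalization (minimum shifted to zero, peak
scaled to one) five criterion distances describe how useful the curve is for
autofocus — for every one of them 0 is ideal, except the smoothness anchor
of 2 for a noiseless unimodal curve:

``d_acc``
    accuracy — |curve peak − reference focus| in stack steps, the reference
    coming from the PCA component-count curve;
``d_uni``
    unimodality — number of secondary local maxima with prominence above a
    threshold (false peaks trap a focus search);
``d_50`` / ``d_90``
    width of the main lobe at 50% / 90% of the peak (linear interpolation
    between samples), reported as a fraction of the scanned span;
``d_smo``
    smoothness — total variation Σ|Δv| of the normalized curve, exactly 2
    for any noiseless unimodal curve that rises from 0 to 1 and back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

from .errors import FlatCurveError

__all__ = [
    "FocusCurve",
    "CriterionVector",
    "Width",
    "normalize_curve",
    "peak_index",
    "accuracy_distance",
    "unimodality_count",
    "width_at_fraction",
    "smoothness_index",
    "criterion_vector",
]

DEFAULT_PROMINENCE = 0.05


@dataclass(frozen=True)
class FocusCurve:
    """Scalar values of one measure per focal position."""

    z_um: np.ndarray
    values: np.ndarray
    fm_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "z_um", np.asarray(self.z_um, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.z_um.shape != self.values.shape or self.values.ndim != 1:
            raise ValueError("z_um and values must be matching 1D arrays")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span_steps(self) -> int:
        return len(self.values) - 1


@dataclass(frozen=True)
class CriterionVector:
    """The five criterion distances of one focus measure, plus overall D."""

    fm_id: str
    d_acc: float
    d_uni: float
    d_50: float
    d_90: float
    d_smo: float
    overall: float | None = None
    normalized: bool = False

    def distances(self) -> tuple[float, float, float, float, float]:
        return (self.d_acc, self.d_uni, self.d_50, self.d_90, self.d_smo)


class Width(NamedTuple):
    """Interpolated lobe width in steps; ``clipped`` marks a curve that never
    drops below the level inside the scanned span."""

    steps: float
    clipped: bool


def normalize_curve(curve: FocusCurve) -> FocusCurve:
    """Shift the minimum to 0 and scale the peak to 1.

    The minimum shift gives signed measures (|LOG| handled upstream, VOL5)
    the same "peak = best focus" semantics as everything else and is the
    identity on already-normalized curves.
    """
    if curve.normalized:
        return curve
    v = curve.values - curve.values.min()
    peak = v.max()
    if peak == 0:
        raise FlatCurveError(f"flat focus curve ({curve.fm_id or 'unnamed'})")
    return replace(curve, values=v / peak, normalized=True)


def peak_index(values: np.ndarray, reference: int | None = None,
               rtol: float = 1e-12) -> int:
    """Global argmax with deterministic plateau handling.

    A plateau of equal maxima resolves to its midpoint; when the midpoint
    falls between two samples the one nearer ``reference`` (or the lower
    index without a reference) is chosen.
    """
    v = np.asarray(values, dtype=float)
    vmax = v.max()
    idx = np.flatnonzero(v >= vmax - rtol * max(abs(vmax), 1.0))
    mid = (idx[0] + idx[-1]) / 2.0
    lo, hi = int(np.floor(mid)), int(np.ceil(mid))
    lo = int(idx[np.argmin(np.abs(idx - lo))])
    hi = int(idx[np.argmin(np.abs(idx - hi))])
    if lo == hi or reference is None:
        return lo
    return min((lo, hi), key=lambda i: (abs(i - reference), i))


def accuracy_distance(curve: FocusCurve, reference_index: int) -> float:
    """d_acc: |peak position − reference| in stack steps."""
    return float(abs(peak_index(curve.values, reference_index) - reference_index))


def unimodality_count(curve: FocusCurve, prominence: float = DEFAULT_PROMINENCE) -> float:
    """d_uni: secondary local maxima with at least ``prominence`` (normalized
    height), the global peak excluded."""
    v = normalize_curve(curve).values
    peaks, _ = find_peaks(v, prominence=prominence)
    main = peak_index(v)
    return float(np.sum(peaks != main))


def width_at_fraction(curve: FocusCurve, fraction: float) -> Width:
    """Width (in steps) of the contiguous region around the global peak where
    the normalized curve stays at or above ``fraction``.

    Crossings are linearly interpolated between samples; a side that never
    drops below the level is clipped at the span edge and flagged.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    v = normalize_curve(curve).values
    p = peak_index(v)
    clipped = False

    left = 0.0
    for i in range(p, 0, -1):
        if v[i - 1] < fraction:
            left = (i - 1) + (fraction - v[i - 1]) / (v[i] - v[i - 1])
            break
    else:
        clipped = True

    right = float(len(v) - 1)
    for i in range(p, len(v) - 1):
        if v[i + 1] < fraction:
            right = i + (v[i] - fraction) / (v[i] - v[i + 1])
            break
    else:
        clipped = clipped or True

    # an interior plateau peak reaching the last sample exactly
    if right < left:
        right = left
    return Width(steps=right - left, clipped=clipped)


def smoothness_index(curve: FocusCurve) -> float:
    """d_smo: total variation Σ|v[i+1] − v[i]| of the normalized curve."""
    v = normalize_curve(curve).values
    return float(np.abs(np.diff(v)).sum())


def criterion_vector(curve: FocusCurve, reference_index: int,
                     prominence: float = DEFAULT_PROMINENCE) -> CriterionVector:
    """Assemble the five raw criterion distances for one curve.

    Widths are reported as a fraction of the scanned span so stacks of
    different lengths aggregate on one scale; the overall score stays unset
    until cross-measure normalization (:mod:`hsfocus.ranking`).
    """
    norm = normalize_curve(curve)
    span = norm.span_steps
    if span == 0:
        raise FlatCurveError("a one-frame curve has no criteria")
    return CriterionVector(
        fm_id=curve.fm_id,
        d_acc=accuracy_distance(norm, reference_index),
        d_uni=unimodality_count(norm, prominence),
        d_50=width_at_fraction(norm, 0.5).steps / span,
        d_90=width_at_fraction(norm, 0.9).steps / span,
        d_smo=smoothness_index(norm),
    )
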