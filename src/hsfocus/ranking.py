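"""Cross-stack aggregation, normalization and overall ranking of focus measures.

Criterion vectors measured per stack are averaged per measure, each criterion
is normalized to its maximum within the measure's family (so the worst
performer on each criterion scores 1.00 and every criterion carries equal
weight), and the overall score

    D = sqrt(d_acc² + d_uni² + d_50² + d_90² + d_smo²)

ranks the measures inside each family — the best measure has the lowest D.
Table output rounds half-up to two decimals, the convention of the published
benchmark tables this module is regression-tested against.
"""

from __future__ import annotations

import logging
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .curves import CriterionVector
from .measures import FAMILY, canonical_id

__all__ = [
    "aggregate_over_stacks",
    "normalize_distances",
    "overall_score",
    "rank_table",
    "round_half_up",
    "format_table",
]

log = logging.getLogger(__name__)

_CRITERIA = ("d_acc", "d_uni", "d_50", "d_90", "d_smo")

#: printed column labels of the benchmark tables
TABLE_COLUMNS = {
    "d_acc": "Accuracy",
    "d_uni": "Unimodality",
    "d_50": "Width at 50%",
    "d_90": "Width at 90%",
    "d_smo": "Smoothness",
}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as in the printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def overall_score(d_acc: float, d_uni: float, d_50: float, d_90: float,
                  d_smo: float) -> float:
    """Euclidean overall score D of the five normalized criterion distances."""
    return math.sqrt(d_acc**2 + d_uni**2 + d_50**2 + d_90**2 + d_smo**2)


def aggregate_over_stacks(
    per_stack: Iterable[Mapping[str, CriterionVector]],
) -> tuple[dict[str, CriterionVector], dict[str, int]]:
    """Arithmetic mean of each criterion per measure across stacks.

    Measures missing from some stacks (a failed evaluation) are averaged
    over the stacks that do report them; the per-measure stack counts are
    returned alongside for bookkeeping.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for vectors in per_stack:
        for fm_id, vec in vectors.items():
            fm_id = canonical_id(fm_id)
            d = np.array(vec.distances(), dtype=float)
            if not np.all(np.isfinite(d)):
                log.warning("skipping non-finite criterion vector for %s", fm_id)
                continue
            sums[fm_id] = sums.get(fm_id, 0.0) + d
            counts[fm_id] = counts.get(fm_id, 0) + 1
    if not sums:
        raise ValueError("no criterion vectors to aggregate")
    means = {
        fm_id: CriterionVector(fm_id, *(sums[fm_id] / counts[fm_id]))
        for fm_id in sums
    }
    return means, counts


def normalize_distances(
    mean_vectors: Mapping[str, CriterionVector],
    scope: str = "family",
) -> dict[str, CriterionVector]:
    """Divide each criterion by its maximum within the measure's family.

    Every family block then contains a 1.00 per criterion column (unless a
    column is identically zero, which is left at zero).  ``scope="global"``
    normalizes over all measures at once instead.
    """
    if scope not in ("family", "global"):
        raise ValueError("scope must be 'family' or 'global'")
    groups: dict[str, list[str]] = {}
    for fm_id in mean_vectors:
        key = FAMILY[canonical_id(fm_id)] if scope == "family" else "all"
        groups.setdefault(key, []).append(fm_id)

    out: dict[str, CriterionVector] = {}
    for members in groups.values():
        block = np.array([mean_vectors[fm].distances() for fm in members])
        col_max = block.max(axis=0)
        scale = np.where(col_max > 0, col_max, 1.0)
        for fm_id, row in zip(members, block / scale):
            out[fm_id] = CriterionVector(
                fm_id, *row, overall=overall_score(*row), normalized=True
            )
    return out


def rank_table(normalized: Mapping[str, CriterionVector],
               n_stacks: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Rank measures by ascending overall score within each family.

    Ties share the order of their ids (lexicographic); the returned frame
    carries unrounded values — use :func:`format_table` for printed output.
    """
    rows = []
    for fm_id, vec in normalized.items():
        fm_id = canonical_id(fm_id)
        d = vec.distances()
        rows.append(
            {
                "family": FAMILY[fm_id],
                "fm": fm_id,
                **dict(zip(_CRITERIA, d)),
                "overall_score": vec.overall if vec.overall is not None else overall_score(*d),
                "n_stacks": (n_stacks or {}).get(fm_id, np.nan),
            }
        )
    df = pd.DataFrame(rows).sort_values(["family", "overall_score", "fm"])
    df["rank"] = df.groupby("family").cumcount() + 1
    return df.reset_index(drop=True)


def format_table(df: pd.DataFrame) -> pd.DataFrame:
    """Printed-table view: published column labels, 2-decimal half-up values."""
    def as_printed(x: float) -> str:
        return f"{round_half_up(x, 2):.2f}"

    out = pd.DataFrame(
        {
            "FM": df["fm"],
            **{label: df[key].map(as_printed) for key, label in TABLE_COLUMNS.items()},
            "Overall Score": df["overall_score"].map(as_printed),
            "Ranking": df["rank"],
        }
    )
    out.index = df["family"].to_numpy()
    return out
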