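"""End-to-end stack evaluation and benchmark orchestration.

``evaluate_stack`` turns one through-focus stack into focus curves for the
selected measures, the PCA reference curve and the five criterion distances
per measure.  ``run_benchmark`` repeats that over a set of stacks (optionally
adding Poisson-noise and illumination-gradient variants), aggregates the
criterion vectors, normalizes per family and emits the ranking tables plus a
Markdown report with per-family curve plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as cm
from . import measures as fm
from . import ranking
from .pca import PCAFocusCurve, pca_focus_curve
from .stack_io import FocusStack, ROISpec, crop_roi, subtract_dark
from .synthetic import add_poisson_noise, apply_illumination_gradient

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StackEvaluation", "evaluate_stack", "run_benchmark"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (with the seed)."""

    fms: tuple[str, ...] = fm.FM_ORDER
    pca_fraction: float = 0.99
    roi: ROISpec | None = None
    apply_dark: bool = True
    prominence: float = cm.DEFAULT_PROMINENCE
    fm_options: fm.FMOptions = field(default_factory=fm.FMOptions)
    noise_levels: tuple[float, ...] = ()
    noise_mode: str = "additive"
    illumination_peaks: tuple[float, ...] = ()
    seed: int = 0
    out_dir: Path | None = None
    plots: bool = False


@dataclass
class StackEvaluation:
    """Curves and criterion distances of one stack."""

    curves: dict[str, cm.FocusCurve]
    pca_curve: PCAFocusCurve
    vectors: dict[str, cm.CriterionVector]
    reference_index: int

    def curves_frame(self) -> pd.DataFrame:
        data = {"z_um": next(iter(self.curves.values())).z_um}
        data.update({fm_id: c.values for fm_id, c in self.curves.items()})
        data["PCA_n_components"] = self.pca_curve.component_counts
        return pd.DataFrame(data)

    def criteria_frame(self) -> pd.DataFrame:
        rows = [
            {"fm": v.fm_id, "d_acc": v.d_acc, "d_uni": v.d_uni,
             "d_50": v.d_50, "d_90": v.d_90, "d_smo": v.d_smo}
            for v in self.vectors.values()
        ]
        return pd.DataFrame(rows)


def fm_curves(stack: FocusStack, fms=fm.FM_ORDER,
              options: fm.FMOptions | None = None) -> dict[str, cm.FocusCurve]:
    """Raw focus curve of every selected measure over the stack.

    Signed measures flagged in the registry (LOG) enter their curve as
    magnitudes so the peak marks best focus.  A measure failing on any frame
    is dropped with a log entry rather than aborting the run.
    """
    opts = options or fm.FMOptions()
    ids = [fm.canonical_id(f) for f in fms]
    values: dict[str, list[float]] = {f: [] for f in ids}
    errors: dict[str, str] = {}
    for frame in stack.frames:
        for f in ids:
            try:
                v = fm.compute(f, frame, opts)
            except Exception as exc:  # noqa: BLE001
                errors[f] = str(exc)
                v = float("nan")
            values[f].append(abs(v) if f in fm.USE_ABS else v)
    out = {}
    for f in ids:
        if f in errors:
            log.warning("focus measure %s failed: %s", f, errors[f])
            continue
        out[f] = cm.FocusCurve(z_um=stack.z_um, values=np.array(values[f]), fm_id=f)
    return out


def evaluate_stack(stack: FocusStack, config: RunConfig | None = None) -> StackEvaluation:
    """Curves, PCA reference and criterion vectors for one stack."""
    config = config or RunConfig()
    if config.apply_dark and stack.dark_frame is not None:
        stack = subtract_dark(stack)
    if config.roi is not None:
        stack = crop_roi(stack, config.roi)
    curves = fm_curves(stack, config.fms, config.fm_options)
    pca_curve = pca_focus_curve(stack, config.pca_fraction)
    ref = pca_curve.best_focus_index
    vectors = {}
    for f, curve in curves.items():
        try:
            vectors[f] = cm.criterion_vector(curve, ref, config.prominence)
        except Exception as exc:  # noqa: BLE001
            log.warning("criteria for %s failed: %s", f, exc)
    return StackEvaluation(curves=curves, pca_curve=pca_curve, vectors=vectors,
                           reference_index=ref)


def _variant_stacks(stack: FocusStack, config: RunConfig, base_seed: int):
    yield "clean", stack
    for i, level in enumerate(config.noise_levels):
        yield (
            f"poisson{level:g}",
            add_poisson_noise(stack, level, seed=base_seed + i, mode=config.noise_mode),
        )
    for peak in config.illumination_peaks:
        yield f"illum{peak:g}", apply_illumination_gradient(stack, peak)


def run_benchmark(stacks: list[FocusStack], config: RunConfig | None = None):
    """Evaluate stacks (plus configured robustness variants), aggregate and rank.

    Returns ``(table, evaluations)`` where ``table`` is the unrounded ranking
    DataFrame; when ``config.out_dir`` is set, per-stack curve/criteria CSVs,
    the ranking table (CSV and Markdown) and optional per-family plots are
    written there.
    """
    config = config or RunConfig()
    if not stacks:
        raise ValueError("run_benchmark needs at least one stack")
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_stack, evaluations = [], []
    for si, stack in enumerate(stacks):
        for tag, variant in _variant_stacks(stack, config, config.seed + 1000 * si):
            ev = evaluate_stack(variant, config)
            evaluations.append((si, tag, ev))
            per_stack.append(ev.vectors)
            if out_dir:
                ev.curves_frame().to_csv(out_dir / f"stack{si:02d}_{tag}_curves.csv",
                                         index=False)
                ev.criteria_frame().to_csv(out_dir / f"stack{si:02d}_{tag}_criteria.csv",
                                           index=False)

    means, counts = ranking.aggregate_over_stacks(per_stack)
    table = ranking.rank_table(ranking.normalize_distances(means), counts)
    if out_dir:
        table.to_csv(out_dir / "ranking.csv", index=False)
        _write_report(out_dir, table, evaluations, config)
    return table, evaluations


def _markdown_table(df: pd.DataFrame) -> str:
    cells = [[str(c) for c in df.columns]]
    cells += [[str(v) for v in row] for row in df.itertuples(index=False)]
    widths = [max(len(r[i]) for r in cells) for i in range(len(cells[0]))]
    def fmt(row):
        return "| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([fmt(cells[0]), sep, *(fmt(r) for r in cells[1:])])


def _write_report(out_dir: Path, table: pd.DataFrame, evaluations, config: RunConfig):
    lines = ["# Focus-measure benchmark report", ""]
    lines.append(f"Stacks evaluated: {len(evaluations)} "
                 f"(including robustness variants); seed {config.seed}.")
    lines.append("")
    for family, block in ranking.format_table(table).groupby(level=0, sort=True):
        lines.append(f"## {family.capitalize()} family")
        lines.append("")
        lines.append(_markdown_table(block))
        lines.append("")
        lines.append(f"Full values: [ranking.csv](ranking.csv); per-stack curves in "
                     f"`stackNN_*_curves.csv`, criteria in `stackNN_*_criteria.csv`.")
        lines.append("")
    if config.plots:
        for name in _plot_families(out_dir, evaluations):
            lines.append(f"![{name}]({name})")
        lines.append("")
    (out_dir / "report.md").write_text("\n".join(lines))


def _plot_families(out_dir: Path, evaluations) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []
    si, tag, ev = evaluations[0]
    by_family: dict[str, list[str]] = {}
    for f in ev.curves:
        by_family.setdefault(fm.FAMILY[f], []).append(f)
    for family, members in by_family.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        for f in members:
            c = cm.normalize_curve(ev.curves[f])
            ax.plot(c.z_um, c.values, label=f)
        ax.axvline(ev.pca_curve.z_um[ev.reference_index], color="k", ls="--",
                   lw=0.8, label="PCA reference")
        ax.set_xlabel("z (μm)")
        ax.set_ylabel("normalized FM")
        ax.set_title(f"{family} family (stack {si}, {tag})")
        ax.legend(fontsize=7)
        name = f"curves_{family}.png"
        fig.savefig(out_dir / name, dpi=120)
        plt.close(fig)
        names.append(name)
    return names
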