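"""Static per-step plots of a cascade: anchors, sectors, projected samples."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .cascade import Cascade
from .io_expr import ExpressionMatrix
from .radviz import AnchorLayout, NormalizationModel, SectorRegion, project_weights

_LABEL_COLORS = {"sensitive": "#d62728", "resistant": "#1f77b4", "unknown": "#7f7f7f"}


def _draw_step(
    ax,
    matrix: ExpressionMatrix,
    layout: AnchorLayout,
    normalization: NormalizationModel,
    regions: Sequence[tuple[str, SectorRegion]],
    title: str,
) -> None:
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="0.7", lw=0.8)
    anchors = layout.anchor_positions()
    for (x, y), gene in zip(anchors, layout.genes):
        ax.plot([x], [y], marker="o", ms=6, color="k")
        ax.annotate(gene, (x * 1.12, y * 1.12), ha="center", va="center", fontsize=8)
    for label, region in regions:
        start, width = region.arc(layout)
        for ang in (start, start + width):
            ax.plot(
                [region.r_min * np.cos(ang), np.cos(ang)],
                [region.r_min * np.sin(ang), np.sin(ang)],
                ls="--",
                color=_LABEL_COLORS.get(label, "k"),
                lw=1.2,
            )
        arc = np.linspace(start, start + width, 64)
        ax.plot(
            region.r_min * np.cos(arc),
            region.r_min * np.sin(arc),
            ls="--",
            color=_LABEL_COLORS.get(label, "k"),
            lw=1.0,
        )
    if matrix.n_samples:
        pts = project_weights(normalization.transform(matrix, layout.genes), layout)
        for lab in _LABEL_COLORS:
            mask = np.array([l == lab for l in matrix.labels])
            if mask.any():
                ax.scatter(
                    pts[mask, 0], pts[mask, 1], s=18, color=_LABEL_COLORS[lab],
                    label=lab, alpha=0.85, edgecolors="none",
                )
        ax.legend(loc="lower right", fontsize=7, frameon=False)
    ax.set_title(title, fontsize=9)
    ax.set_aspect("equal")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.axis("off")


def plot_cascade(
    matrix: ExpressionMatrix,
    cascade: Cascade,
    out_dir: str | Path,
    fmt: str = "png",
    prefix: str = "step",
) -> list[Path]:
    """Render one figure per cascade stage; returns the written paths.

    Each figure shows the samples still in play at that stage, projected on
    the stage's layout, with the elimination sector(s) dashed.
    """
    if not cascade.fitted:
        raise ValueError("cascade normalization is unfitted")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    from .cascade import _step_mask  # reuse the exact membership computation

    active = np.ones(matrix.n_samples, dtype=bool)
    stages: list[tuple[str, AnchorLayout, NormalizationModel, list]] = []
    for i, step in enumerate(cascade.steps, start=1):
        stages.append(
            (
                f"{prefix}{i} eliminate {step.eliminate_label}",
                step.layout,
                step.normalization,
                [(step.eliminate_label, step.region)],
            )
        )
    if cascade.final is not None:
        stages.append(
            (
                f"{prefix}{len(cascade.steps) + 1} final",
                cascade.final.layout,
                cascade.final.normalization,
                list(cascade.final.regions.items()),
            )
        )
    for i, (title, layout, norm, regions) in enumerate(stages, start=1):
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        sub = matrix.subset_samples(active) if matrix.n_samples else matrix
        _draw_step(ax, sub, layout, norm, regions, title)
        path = out_dir / f"{prefix}{i}.{fmt}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
        if matrix.n_samples:
            for _, region in regions:
                hit = _step_mask(matrix, layout, norm, region, active)
                active &= ~hit
    return paths
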