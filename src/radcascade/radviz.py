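"""Radial-visualization (RadViz) mathematics.

Genes act as *anchors* fixed on the unit circle; each sample is placed at
the weighted barycentre of the anchors, the weights being the sample's
min-max normalized expression values.  This point is exactly the
equilibrium of the spring analogy: one spring per anchor, stiffness equal
to the normalized expression, so the sum of spring forces
``sum_i u_i (A_i - p)`` vanishes at ``p = sum u_i A_i / sum u_i``.

Elimination regions are closed angular sectors between two adjacent
anchors ("quarters" of a 4-anchor Cartesian layout, "arms" of a 3-anchor
layout) with a small dead-zone radius around the origin, where placement
is maximally ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .io_expr import ExpressionMatrix

TWO_PI = 2.0 * np.pi
_ANGLE_EPS = 1e-9  # closed-arc boundary tolerance


@dataclass(frozen=True)
class AnchorLayout:
    """An ordered circular placement of gene anchors.

    ``genes[i]`` sits at angle ``angles[i]`` (radians).  Listed order must
    proceed counter-clockwise around the circle (strictly increasing angles
    after rotating the first anchor to zero), so adjacency in the list is
    adjacency on the circle.
    """

    genes: tuple[str, ...]
    angles: tuple[float, ...]
    mode: str = "equal_spacing"

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a layout needs at least 2 anchors")
        if len(self.genes) != len(self.angles):
            raise ValueError("genes and angles must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate anchor genes")
        rel = np.mod(np.asarray(self.angles) - self.angles[0], TWO_PI)
        if np.any(np.diff(rel) <= 0):
            raise ValueError("anchor angles must increase counter-clockwise in listed order")
        if self.mode == "cartesian":
            if len(self.genes) != 4:
                raise ValueError("cartesian mode requires exactly 4 anchors")
            want = np.mod(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]), TWO_PI)
            got = np.mod(np.asarray(self.angles), TWO_PI)
            if not np.allclose(np.sort(got), np.sort(want), atol=1e-9):
                raise ValueError("cartesian mode requires angles {0, 90, 180, 270} degrees")

    # -- constructors ------------------------------------------------------

    @classmethod
    def equal_spacing(cls, genes: Sequence[str], phase: float = 0.0) -> "AnchorLayout":
        k = len(genes)
        angles = tuple(np.mod(TWO_PI * i / k + phase, TWO_PI) for i in range(k))
        return cls(genes=tuple(genes), angles=angles, mode="equal_spacing")

    @classmethod
    def cartesian(cls, genes: Sequence[str]) -> "AnchorLayout":
        """4 anchors at 0, 90, 180, 270 degrees in listed order."""
        if len(genes) != 4:
            raise ValueError("cartesian layout requires exactly 4 genes")
        return cls(
            genes=tuple(genes),
            angles=(0.0, np.pi / 2, np.pi, 3 * np.pi / 2),
            mode="cartesian",
        )

    @classmethod
    def for_genes(cls, genes: Sequence[str], mode: str | None = None) -> "AnchorLayout":
        """Default placement: 4 genes -> Cartesian axes; 3 genes -> arms at
        90, 210, 330 degrees; otherwise equal spacing starting at angle 0."""
        if mode == "cartesian" or (mode is None and len(genes) == 4):
            return cls.cartesian(genes)
        phase = np.pi / 2 if len(genes) == 3 else 0.0
        return cls.equal_spacing(genes, phase=phase)

    # -- geometry ----------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.genes)

    def anchor_positions(self) -> np.ndarray:
        """k x 2 array of unit-circle anchor coordinates."""
        a = np.asarray(self.angles)
        return np.column_stack([np.cos(a), np.sin(a)])

    def angle_of(self, gene: str) -> float:
        return self.angles[self.genes.index(gene)]

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Counter-clockwise adjacent anchor pairs, one per sector."""
        return [
            (self.genes[i], self.genes[(i + 1) % self.k]) for i in range(self.k)
        ]

    def is_adjacent(self, a: str, b: str) -> bool:
        pairs = self.adjacent_pairs()
        return (a, b) in pairs or (b, a) in pairs

    def rotated(self, phi: float) -> "AnchorLayout":
        """Same layout rotated by ``phi`` radians (mode demoted if axes move)."""
        angles = tuple(np.mod(np.asarray(self.angles) + phi, TWO_PI))
        mode = self.mode
        if mode == "cartesian":
            d = np.mod(np.asarray(angles), np.pi / 2)
            if not np.all(np.minimum(d, np.pi / 2 - d) < 1e-9):
                mode = "equal_spacing"
        return AnchorLayout(genes=self.genes, angles=angles, mode=mode)


@dataclass(frozen=True)
class NormalizationModel:
    """Per-gene min-max bounds learned on a reference cohort and frozen.

    Freezing the bounds makes every later projection deterministic and
    single-sample capable: out-of-range values at predict time are clipped
    to [0, 1], and a gene that was constant in the reference cohort
    contributes a neutral weight of 0.5.
    """

    genes: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.mins) == len(self.maxs)):
            raise ValueError("genes/mins/maxs must have equal length")
        if any(hi < lo for lo, hi in zip(self.mins, self.maxs)):
            raise ValueError("max < min for some gene")

    def bounds(self, gene: str) -> tuple[float, float]:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not covered by normalization model") from None
        return self.mins[i], self.maxs[i]

    def transform(self, matrix: ExpressionMatrix, genes: Sequence[str] | None = None) -> np.ndarray:
        """n_samples x k matrix of normalized weights in [0, 1]."""
        genes = tuple(genes) if genes is not None else self.genes
        lo = np.array([self.bounds(g)[0] for g in genes])
        hi = np.array([self.bounds(g)[1] for g in genes])
        x = matrix.subset_genes(genes).values
        return normalize_block(x, lo, hi)


def normalize_block(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (x - lo) / np.where(span > 0, span, 1.0)
    u = np.clip(u, 0.0, 1.0)
    u[:, span == 0] = 0.5  # constant reference gene -> neutral weight
    return u


def fit_normalization(matrix: ExpressionMatrix, genes: Sequence[str]) -> NormalizationModel:
    """Learn per-gene min/max bounds over the samples of ``matrix``."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit normalization bounds")
    missing = [g for g in genes if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"gene(s) missing from matrix: {missing}")
    sub = matrix.subset_genes(genes).values
    return NormalizationModel(
        genes=tuple(genes),
        mins=tuple(float(v) for v in sub.min(axis=0)),
        maxs=tuple(float(v) for v in sub.max(axis=0)),
    )


@dataclass(frozen=True)
class Projection:
    """2-D placements of samples under one anchor layout."""

    points: np.ndarray  # n x 2
    layout: AnchorLayout

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be n x 2")
        object.__setattr__(self, "points", pts)


def project_weights(weights: np.ndarray, layout: AnchorLayout) -> np.ndarray:
    """Barycentric placement of pre-normalized weight rows (n x k -> n x 2).

    A row of all zeros maps to the origin (no spring pulls the point).
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if w.shape[1] != layout.k:
        raise ValueError(f"weights have {w.shape[1]} columns, layout has {layout.k} anchors")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    anchors = layout.anchor_positions()
    totals = w.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    pts = (w @ anchors) / safe
    pts[totals[:, 0] == 0] = 0.0
    return pts


def project(
    matrix: ExpressionMatrix,
    model: NormalizationModel,
    layout: AnchorLayout,
) -> Projection:
    """Project samples onto the plane of ``layout`` using frozen normalization.

    For sample j with normalized weights ``u_ij`` the point is
    ``p_j = sum_i u_ij A_i / sum_i u_ij`` — the unique zero of the total
    spring force, hence identical to the physical equilibrium placement.
    """
    if layout.k == 0:
        raise ValueError("empty gene list")
    # accumulate in alphabetical gene order so that permuting genes together
    # with their anchors reproduces points bit-identically
    order = sorted(range(layout.k), key=lambda i: layout.genes[i])
    u = model.transform(matrix, [layout.genes[i] for i in order])
    anchors = layout.anchor_positions()[order]
    totals = u.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    pts = (u @ anchors) / safe
    pts[totals[:, 0] == 0] = 0.0
    return Projection(points=pts, layout=layout)


def spring_oracle(weights: Sequence[float], layout: AnchorLayout) -> np.ndarray:
    """Numeric spring-equilibrium placement (independent of :func:`project`).

    Minimizes the total spring energy ``1/2 sum_i u_i ||A_i - p||^2`` with a
    generic quasi-Newton solver.  Exists as an independent oracle for the
    closed-form projection; do not use it in production paths.
    """
    u = np.asarray(weights, dtype=float)
    if np.any(u < 0):
        raise ValueError("weights must be non-negative")
    if u.sum() <= 0:
        raise ValueError("all-zero weights have no equilibrium")
    anchors = layout.anchor_positions()

    def energy(p: np.ndarray) -> float:
        d = anchors - p
        return 0.5 * float(np.sum(u * np.einsum("ij,ij->i", d, d)))

    def neg_force(p: np.ndarray) -> np.ndarray:
        # gradient of the energy = minus the total spring force
        return -(u[:, None] * (anchors - p)).sum(axis=0)

    res = minimize(
        energy, x0=np.zeros(2), jac=neg_force, method="BFGS",
        options={"gtol": 1e-13 * max(1.0, u.sum())},
    )
    return res.x


@dataclass(frozen=True)
class SectorRegion:
    """Closed angular sector between two adjacent anchors, minus an origin dead-zone.

    ``r_min`` (default 0.05) keeps the near-origin zone — where all springs
    roughly balance and placement is least informative — out of every
    region, so an all-average sample is never eliminated.
    """

    anchor_a: str
    anchor_b: str
    r_min: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_min < 1.0):
            raise ValueError("r_min must lie in [0, 1)")
        if self.anchor_a == self.anchor_b:
            raise ValueError("region anchors must differ")

    def arc(self, layout: AnchorLayout) -> tuple[float, float]:
        """(start angle, width) of the closed arc containing no other anchor."""
        if self.anchor_a not in layout.genes or self.anchor_b not in layout.genes:
            raise ValueError(
                f"region anchors ({self.anchor_a}, {self.anchor_b}) not all in layout"
            )
        if not layout.is_adjacent(self.anchor_a, self.anchor_b):
            raise ValueError(
                f"region anchors ({self.anchor_a}, {self.anchor_b}) are not adjacent in layout"
            )
        ta = layout.angle_of(self.anchor_a)
        tb = layout.angle_of(self.anchor_b)
        # pick the ccw direction in which the pair is consecutive
        if (self.anchor_a, self.anchor_b) in layout.adjacent_pairs():
            start, width = ta, np.mod(tb - ta, TWO_PI)
        else:
            start, width = tb, np.mod(ta - tb, TWO_PI)
        return float(np.mod(start, TWO_PI)), float(width)


def region_mask(points: np.ndarray, region: SectorRegion, layout: AnchorLayout) -> np.ndarray:
    """Vectorized membership of n x 2 ``points`` in ``region`` (closed arc)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    start, width = region.arc(layout)
    radius = np.hypot(pts[:, 0], pts[:, 1])
    phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), TWO_PI)
    t = np.mod(phi - start, TWO_PI)
    in_arc = (t <= width + _ANGLE_EPS) | (t >= TWO_PI - _ANGLE_EPS)
    return in_arc & (radius >= region.r_min)


def in_region(point: Sequence[float], region: SectorRegion, layout: AnchorLayout) -> bool:
    """True iff ``point`` lies in the closed sector at radius >= ``r_min``."""
    return bool(region_mask(np.asarray(point, dtype=float)[None, :], region, layout)[0])
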