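"""Synthetic two-class expression cohorts with the structure the method assumes.

The generator emulates small bulk-microarray cohorts of treated tumours:
a panel of "up" genes elevated in resistant (non-responding) samples, a
"down" panel reduced in them, positive correlation within each panel and
negative correlation across panels (a shared latent factor with opposite
loadings — guaranteed positive semi-definite), plus optional resistant
*subtypes* that each overexpress only a subset of the up panel, so no
single projection step can cover every resistant sample.  Expression is on
an arbitrary log-like scale centred at 8 with unit total SD, echoing
microarray log2 intensities; all downstream code is scale-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .deg_stats import MarkerPanel
from .io_expr import ExpressionMatrix, write_series_matrix

BASELINE = 8.0  # log2-intensity-like centre of the expression scale


def default_panel(n_up: int = 10, n_down: int = 5) -> MarkerPanel:
    """A nameable planted marker panel (RESUP*/RESDN* symbols)."""
    return MarkerPanel(
        up=[f"RESUP{i:02d}" for i in range(1, n_up + 1)],
        down=[f"RESDN{i:02d}" for i in range(1, n_down + 1)],
    )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the mean shift of panel genes in resistant samples,
    in units of the pooled (total) per-gene SD.  ``rho_within`` /
    ``rho_cross`` set the within-panel and cross-panel correlations; the
    block factor model requires ``rho_within + rho_cross >= 0``.
    ``subtypes`` splits the resistant class into sub-populations that each
    overexpress a disjoint round-robin subset of the up panel (the down
    panel shifts in every subtype).
    """

    n_sensitive: int = 30
    n_resistant: int = 30
    panel: MarkerPanel = field(default_factory=default_panel)
    effect_size: float = 1.5
    rho_within: float = 0.4
    rho_cross: float = -0.2
    n_background: int = 200
    subtypes: int = 2
    noise_sd: float = float(np.sqrt(0.6))  # residual SD; total SD = 1 at defaults
    seed: int = 0
    flip_genes: tuple[str, ...] = ()  # panel genes whose planted effect is sign-flipped

    def __post_init__(self) -> None:
        if self.n_sensitive < 0 or self.n_resistant < 0 or self.n_background < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValueError("rho_within must lie in [0, 1)")
        if not (-1.0 < self.rho_cross <= 0.0):
            raise ValueError("rho_cross must lie in (-1, 0]")
        if self.rho_within + self.rho_cross < 0:
            raise ValueError(
                "panel covariance block is not positive semi-definite: "
                f"rho_within ({self.rho_within}) must be >= |rho_cross| "
                f"({abs(self.rho_cross)})"
            )
        if self.subtypes < 1:
            raise ValueError("subtypes must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.flip_genes) - set(self.panel.genes)
        if unknown:
            raise ValueError(f"flip_genes not in panel: {sorted(unknown)}")

    @property
    def total_sd(self) -> float:
        """Marginal per-gene SD implied by the factor model."""
        return float(self.noise_sd / np.sqrt(1.0 - self.rho_within))


def _subtype_up_subset(panel: MarkerPanel, subtypes: int, s: int) -> np.ndarray:
    """Boolean mask over the up panel for subtype ``s`` (round-robin split)."""
    idx = np.arange(len(panel.up))
    if subtypes <= 1:
        return np.ones_like(idx, dtype=bool)
    return (idx % subtypes) == s


def generate_cohort(spec: CohortSpec) -> ExpressionMatrix:
    """Draw one labelled cohort under ``spec`` (deterministic given the seed).

    Sensitive samples sit at baseline; resistant samples of subtype ``s``
    gain ``+effect_size * SD`` on that subtype's up-gene subset and
    ``-effect_size * SD`` on every down gene.  Panel genes share a latent
    factor (loading ``+c`` for up, ``-c`` for down) plus a panel-specific
    factor, reproducing the positive-within / negative-across correlation
    signature; background genes are independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    n_up, n_down = len(panel.up), len(panel.down)
    n = spec.n_sensitive + spec.n_resistant
    genes = list(panel.up) + list(panel.down) + [
        f"BG{i:04d}" for i in range(1, spec.n_background + 1)
    ]

    v = spec.total_sd**2
    c = float(np.sqrt(-spec.rho_cross * v))
    w = float(np.sqrt((spec.rho_within + spec.rho_cross) * v))

    labels = ["sensitive"] * spec.n_sensitive + ["resistant"] * spec.n_resistant
    sample_ids = [f"SEN{i:03d}" for i in range(1, spec.n_sensitive + 1)] + [
        f"RES{i:03d}" for i in range(1, spec.n_resistant + 1)
    ]

    shared = rng.standard_normal((n, 1))
    fac_up = rng.standard_normal((n, 1))
    fac_down = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, len(genes)))

    values = np.empty((n, len(genes)))
    values[:, :n_up] = BASELINE + c * shared + w * fac_up + spec.noise_sd * noise[:, :n_up]
    values[:, n_up : n_up + n_down] = (
        BASELINE - c * shared + w * fac_down + spec.noise_sd * noise[:, n_up : n_up + n_down]
    )
    values[:, n_up + n_down :] = BASELINE + noise[:, n_up + n_down :]

    shift = spec.effect_size * spec.total_sd
    sign = np.array(
        [(-1.0 if g in spec.flip_genes else 1.0) for g in panel.genes]
    )
    for r, j in enumerate(range(spec.n_sensitive, n)):
        s = r % spec.subtypes
        up_mask = _subtype_up_subset(panel, spec.subtypes, s)
        values[j, :n_up][up_mask] += shift * sign[:n_up][up_mask]
        values[j, n_up : n_up + n_down] -= shift * sign[n_up:]
    return ExpressionMatrix(
        sample_ids=sample_ids, gene_ids=genes, values=values, labels=labels
    )


@dataclass(frozen=True)
class CohortPerturbation:
    """Per-cohort multipliers for triple-cohort generation."""

    effect_scale: float = 1.0
    noise_scale: float = 1.0
    flip_genes: tuple[str, ...] = ()


#: Fixed per-cohort seed offset so reruns are bit-identical.
_COHORT_SEED_OFFSET = 1000


def generate_triple_cohorts(
    spec: CohortSpec,
    perturbations: Sequence[CohortPerturbation] | None = None,
) -> list[ExpressionMatrix]:
    """Three independent cohorts sharing the panel (training/training/test style).

    Cohort ``i`` uses ``spec.seed + 1000*i`` and the i-th perturbation's
    effect/noise multipliers and sign-flipped decoy genes, so concordance
    and discordance rules of cross-cohort marker selection can be exercised.
    """
    if perturbations is None:
        perturbations = [CohortPerturbation()] * 3
    if len(perturbations) != 3:
        raise ValueError("need exactly three perturbations")
    cohorts = []
    for i, pert in enumerate(perturbations):
        sub = replace(
            spec,
            effect_size=spec.effect_size * pert.effect_scale,
            noise_sd=spec.noise_sd * pert.noise_scale,
            seed=spec.seed + _COHORT_SEED_OFFSET * i,
            flip_genes=tuple(sorted(set(spec.flip_genes) | set(pert.flip_genes))),
        )
        cohorts.append(generate_cohort(sub))
    return cohorts


def planted_selection_tables(seed: int = 0):
    """Three constructed DEG tables exercising every extended-selection rule.

    Returns ``(tables, panel)`` where ``panel`` is the 12-gene planted
    marker set (8 up, 4 down) that the extended cross-cohort selection must
    return exactly.  The 8 decoys are built so that each exclusion rule
    fires at least once: opposite regulation in the remaining cohort,
    ``|t| < 1`` there, ``p >= 0.075`` there, discordant directions between
    cohorts, and a single-cohort-only hit.  A seeded jitter varies the
    numbers without crossing any decision threshold.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)

    def row(t, p):
        # mean_diff consistent in sign with t; magnitude arbitrary
        return {"mean_diff": 0.4 * np.sign(t) if t != 0 else 0.0, "t_mod": t, "p_raw": p}

    def jitter(t, p):
        # stay well inside the same decision cell
        return (t * (1 + 0.02 * rng.uniform(-1, 1)), min(1.0, p * (1 + 0.02 * rng.uniform(-1, 1))))

    planted_up = [f"PLUP{i}" for i in range(1, 9)]
    planted_down = [f"PLDN{i}" for i in range(1, 5)]
    decoys = [f"DECOY{i}" for i in range(1, 9)]
    fillers = [f"FILL{i:02d}" for i in range(1, 21)]

    # per-gene (t, p) triplets, one per cohort
    spec_rows: dict[str, list[tuple[float, float]]] = {}
    for i, g in enumerate(planted_up):
        if i < 5:  # strong in all three cohorts (also the Venn core)
            spec_rows[g] = [(3.0, 0.004)] * 3
        elif i < 7:  # primary in cohorts 1+2, acceptable in 3 (1 <= |t|, p < 0.075)
            spec_rows[g] = [(2.8, 0.01), (2.5, 0.02), (1.4, 0.06)]
        else:  # primary in cohorts 2+3, acceptable in 1
            spec_rows[g] = [(1.1, 0.07), (2.6, 0.015), (2.9, 0.008)]
    for i, g in enumerate(planted_down):
        if i < 2:
            spec_rows[g] = [(-3.2, 0.003)] * 3
        else:
            spec_rows[g] = [(-2.4, 0.02), (-2.7, 0.012), (-1.2, 0.065)]
    # decoys: each exclusion rule fires at least once
    spec_rows[decoys[0]] = [(2.7, 0.01), (2.4, 0.02), (-1.5, 0.04)]   # opposite sign
    spec_rows[decoys[1]] = [(2.9, 0.009), (2.2, 0.03), (0.5, 0.6)]    # |t| < 1
    spec_rows[decoys[2]] = [(2.5, 0.02), (2.8, 0.01), (1.6, 0.12)]    # p >= 0.075
    spec_rows[decoys[3]] = [(3.5, 0.001), (0.2, 0.8), (0.1, 0.9)]     # one cohort only
    spec_rows[decoys[4]] = [(-2.6, 0.013), (-2.3, 0.025), (1.3, 0.05)]  # down, opposite sign
    spec_rows[decoys[5]] = [(-2.8, 0.01), (-2.5, 0.02), (-0.4, 0.7)]  # down, |t| < 1
    spec_rows[decoys[6]] = [(-2.2, 0.03), (-2.9, 0.008), (-1.7, 0.09)]  # down, p >= 0.075
    spec_rows[decoys[7]] = [(2.6, 0.014), (-2.6, 0.014), (2.1, 0.04)]  # discordant directions
    for g in fillers:
        spec_rows[g] = [(float(rng.uniform(-0.8, 0.8)), float(rng.uniform(0.3, 0.95)))] * 3

    tables = []
    for c in range(3):
        rows = []
        for g, cells in spec_rows.items():
            t, p = jitter(*cells[c])
            rows.append({"gene": g, **row(t, p)})
        df = pd.DataFrame(rows)
        from .deg_stats import bh_adjust

        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df["direction"] = np.where(df["mean_diff"] > 0, "up", "down")
        tables.append(df[["gene", "mean_diff", "t_mod", "p_raw", "p_adj", "direction"]])
    return tables, MarkerPanel(up=planted_up, down=planted_down)


def write_fixture_series_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    probe_map_path: str | Path | None = None,
    duplicate_first_gene: bool = False,
) -> dict[str, str]:
    """Serialize a cohort in GEO Series Matrix layout with synthetic probe ids.

    Each gene gets one ``SPROBE_xxxx`` row (1:1 probe map, returned and
    optionally written as a two-column TSV).  With ``duplicate_first_gene``
    a second probe for the first gene is appended (same values), so reader
    tests exercise the probe-collapse path on realistic bytes.
    """
    path = Path(path)
    probes = [f"SPROBE_{i:04d}" for i in range(1, matrix.n_genes + 1)]
    mapping = dict(zip(probes, matrix.gene_ids))
    values = matrix.values
    gene_ids = list(matrix.gene_ids)
    if duplicate_first_gene and matrix.n_genes:
        extra = f"SPROBE_{matrix.n_genes + 1:04d}"
        probes.append(extra)
        mapping[extra] = gene_ids[0]
        values = np.column_stack([values, values[:, 0]])
    dup = ExpressionMatrix(
        sample_ids=list(matrix.sample_ids),
        gene_ids=probes,
        values=values,
        labels=list(matrix.labels),
    )
    write_series_matrix(dup, path, probe_ids=probes, title="synthetic radcascade cohort")
    if probe_map_path is not None:
        with open(probe_map_path, "w") as fh:
            fh.write("probe\tgene\n")
            for p in probes:
                fh.write(f"{p}\t{mapping[p]}\n")
    return mapping
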