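"""Differential-expression statistics and cross-cohort marker selection.

Two-group comparisons (resistant vs. sensitive) are summarised per gene by
the mean difference and a *moderated* t-statistic: the per-gene residual
variance is shrunk toward a common prior by empirical Bayes, with the prior
``(d0, s0^2)`` estimated by moment matching on the log residual variances
(the classic microarray approach).  On top of the per-cohort tables sit the
two-stage marker-selection rules used to build a cross-cohort resistance
panel: a primary filter (raw p < 0.05 and |t| > 2), the triple-cohort core
intersection, and the extended rule that admits genes concordant in two of
three cohorts provided the remaining cohort does not contradict them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_expr import ExpressionMatrix

#: DEG table column order used throughout (TSV round-trips preserve it).
DEG_COLUMNS = ["gene", "mean_diff", "t_mod", "p_raw", "p_adj", "direction"]


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered up- and downregulated marker gene lists (disjoint, unique)."""

    up: tuple[str, ...]
    down: tuple[str, ...]

    def __init__(self, up: Iterable[str], down: Iterable[str]):
        up = tuple(up)
        down = tuple(down)
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise ValueError("panel lists must not contain duplicates")
        overlap = set(up) & set(down)
        if overlap:
            raise ValueError(f"genes in both up and down lists: {sorted(overlap)}")
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up + self.down

    def direction(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``d0`` is the prior degrees of freedom (``inf`` = total shrinkage to the
    prior, ``0`` = no shrinkage); ``s0_sq`` the prior residual variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0 or self.d0 == 0):
            raise ValueError("s0_sq must be positive")


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve ``psi'(y) = x`` for ``y > 0`` by Newton iteration on 1/psi'.

    Used by the moment-matching estimator of the prior degrees of freedom.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:  # psi'(y) ~ 1/y for tiny y
        return 1.0 / np.sqrt(x)
    if x < 1e-6:  # psi'(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment-match a scaled inverse chi-square prior to observed variances.

    Fits ``(d0, s0_sq)`` so that the theoretical moments of ``log(s2)``
    under the hierarchical model match the sample moments across genes.
    Genes with zero residual variance carry no information about the prior
    and are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need at least two genes with positive residual variance")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    target = e_var - float(special.polygamma(1, df / 2.0))
    if target > 0:
        d0 = 2.0 * trigamma_inverse(target)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    matrix: ExpressionMatrix,
    moderation: str = "empirical_bayes",
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Per-gene two-group statistics (resistant minus sensitive).

    Parameters
    ----------
    matrix
        Expression matrix whose labels contain both ``resistant`` and
        ``sensitive`` with at least two samples each.
    moderation
        ``empirical_bayes`` (default) shrinks per-gene variances toward a
        moment-matched prior; ``none`` gives the classical pooled-variance
        two-sample t-test.
    params
        Optional pre-set shrinkage hyperparameters (overrides estimation);
        mainly for testing limiting behaviour.

    Returns
    -------
    DataFrame with columns gene, mean_diff, t_mod, p_raw, p_adj, direction
    (one row per gene; ``p_adj`` is Benjamini-Hochberg adjusted).
    """
    if moderation not in ("empirical_bayes", "none"):
        raise ValueError(f"unknown moderation {moderation!r}")
    res = matrix.label_mask("resistant")
    sen = matrix.label_mask("sensitive")
    n1, n2 = int(res.sum()), int(sen.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 samples per group (resistant={n1}, sensitive={n2})"
        )
    x1 = matrix.values[res, :]
    x2 = matrix.values[sen, :]
    mean_diff = x1.mean(axis=0) - x2.mean(axis=0)
    df_resid = n1 + n2 - 2
    ss = x1.var(axis=0, ddof=1) * (n1 - 1) + x2.var(axis=0, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    if moderation == "empirical_bayes":
        if params is None:
            params = estimate_moderation(s2, df_resid)
        d0, s0_sq = params.d0, params.s0_sq
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
        else:
            s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    else:
        s2_tilde = s2
        df_total = float(df_resid)

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), 0.0)
    # zero residual + zero difference -> null gene (t=0, p=1), not an error;
    # zero residual with a real difference -> infinitely significant.
    degenerate = (se == 0) & (mean_diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(mean_diff) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (mean_diff == 0), 1.0, p)

    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "mean_diff": mean_diff,
            "t_mod": t,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "direction": np.where(mean_diff > 0, "up", "down"),
        }
    )
    return table[DEG_COLUMNS]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def primary_filter(
    table: pd.DataFrame,
    p_max: float = 0.05,
    t_min: float = 2.0,
) -> tuple[set[str], set[str]]:
    """DEG sets at raw p < ``p_max`` and moderated t beyond ``+-t_min``.

    All inequalities are strict (a gene at exactly t = 2 is excluded).
    Blank/unnamed gene symbols are never admitted.
    """
    named = table["gene"].astype(str).str.strip() != ""
    sig = (table["p_raw"] < p_max) & named
    up = set(table.loc[sig & (table["t_mod"] > t_min), "gene"])
    down = set(table.loc[sig & (table["t_mod"] < -t_min), "gene"])
    return up, down


def venn_core(
    up_sets: Sequence[set[str]],
    down_sets: Sequence[set[str]],
) -> tuple[set[str], set[str]]:
    """Triple-intersection core markers: genes dysregulated the same way in all cohorts."""
    if len(up_sets) != 3 or len(down_sets) != 3:
        raise ValueError("expected three up sets and three down sets")
    core_up = set.intersection(*(set(s) for s in up_sets))
    core_down = set.intersection(*(set(s) for s in down_sets))
    return core_up, core_down


def extended_marker_selection(
    tables: Sequence[pd.DataFrame],
    p_max: float = 0.05,
    t_min: float = 2.0,
    t_secondary: float = 1.0,
    p_secondary: float = 0.075,
) -> MarkerPanel:
    """Two-stage cross-cohort marker panel from three DEG tables.

    A gene becomes a candidate when it passes the primary filter in the same
    direction in at least two of the three cohorts.  It is then excluded if,
    in any cohort where it did *not* pass, it shows opposite regulation
    (sign of the mean difference against the candidate direction),
    ``|t| < t_secondary``, or only unacceptable significance
    (``p_raw >= p_secondary``).  Core triple-intersection genes are always
    retained.  The returned lists are ordered by decreasing mean |t| across
    cohorts (ties alphabetical) so the strongest markers lead the panel.
    """
    if len(tables) != 3:
        raise ValueError("extended selection requires exactly three DEG tables")
    universes = [set(t["gene"]) for t in tables]
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("DEG tables have disjoint gene universes")

    primaries = [primary_filter(t, p_max=p_max, t_min=t_min) for t in tables]
    core_up, core_down = venn_core([p[0] for p in primaries], [p[1] for p in primaries])
    indexed = [t.set_index("gene") for t in tables]

    selected: dict[str, str] = {}
    for direction, dir_idx in (("up", 0), ("down", 1)):
        sign = 1.0 if direction == "up" else -1.0
        for gene in shared:
            hits = [i for i in range(3) if gene in primaries[i][dir_idx]]
            if len(hits) < 2:
                continue
            keep = True
            for i in set(range(3)) - set(hits):
                row = indexed[i].loc[gene]
                if (
                    sign * row["mean_diff"] < 0
                    or abs(row["t_mod"]) < t_secondary
                    or row["p_raw"] >= p_secondary
                ):
                    keep = False
                    break
            if keep:
                selected[gene] = direction
    for gene in core_up:
        selected[gene] = "up"
    for gene in core_down:
        selected[gene] = "down"

    def strength(gene: str) -> float:
        vals = [abs(float(t.loc[gene, "t_mod"])) for t in indexed if gene in t.index]
        return float(np.mean(vals))

    ordered = sorted(selected, key=lambda g: (-strength(g), g))
    return MarkerPanel(
        up=[g for g in ordered if selected[g] == "up"],
        down=[g for g in ordered if selected[g] == "down"],
    )


def correlation_matrix(
    matrix: ExpressionMatrix,
    genes: MarkerPanel | Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations across samples with significance tiers.

    Returns ``(r, p, stars)`` gene x gene DataFrames.  Two-sided p-values use
    the exact t transform with n-2 degrees of freedom; the star tiers are
    ``*`` p < 0.05, ``**`` p < 0.005, ``***`` p < 0.001.  Pairs involving a
    zero-variance gene are reported as missing (NaN / empty star) with a
    warning rather than an error.
    """
    names = list(genes.genes) if isinstance(genes, MarkerPanel) else list(genes)
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sub = matrix.subset_genes(names).values  # n x k
    sd = sub.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"zero-variance gene(s) {[g for g, c in zip(names, constant) if c]}: "
            "correlations reported as missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))
    p[np.isnan(r)] = np.nan

    def tier(pv: float) -> str:
        if np.isnan(pv):
            return ""
        if pv < 0.001:
            return "***"
        if pv < 0.005:
            return "**"
        if pv < 0.05:
            return "*"
        return ""

    stars = np.vectorize(tier, otypes=[object])(p)
    idx = pd.Index(names, name="gene")
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(stars, index=idx, columns=idx),
    )


def write_deg_table(table: pd.DataFrame, path, header_comments: dict | None = None) -> None:
    """DEG table TSV with optional ``# key=value`` provenance header lines."""
    with open(path, "w") as fh:
        for k, v in (header_comments or {}).items():
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
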