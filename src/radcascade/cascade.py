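"""The step-by-step eliminative classifier.

A *cascade* is an ordered list of elimination steps.  Each step projects the
not-yet-called samples onto a small RadViz layout (3 or 4 marker genes) and
calls every sample falling inside one angular sector with a single label
("homogeneous samples only"); survivors proceed to the next step.  An
optional final stage carries two labelled sectors on one shared layout —
one per response class — and whatever remains is *undetermined* ("hard to
interpret"), reported as its own category and never coerced to a label.

Training replaces the interactive, hand-drawn regions of the original
workflow with an objective purity-constrained exhaustive search: all gene
subsets of the candidate pool, all distinct circular orderings, and all
adjacent-anchor sectors are scored on a seeded 70% split of each class and
re-verified on the full cohort.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_expr import ExpressionMatrix
from .radviz import (
    AnchorLayout,
    NormalizationModel,
    SectorRegion,
    fit_normalization,
    project_weights,
    region_mask,
)

CALL_LABELS = ("sensitive", "resistant")


@dataclass(frozen=True)
class EliminationStep:
    """One projection + sector + eliminated-label rule."""

    layout: AnchorLayout
    region: SectorRegion
    eliminate_label: str
    normalization: NormalizationModel | None = None

    def __post_init__(self) -> None:
        if self.eliminate_label not in CALL_LABELS:
            raise ValueError(f"eliminate_label must be one of {CALL_LABELS}")
        self.region.arc(self.layout)  # validates anchors present + adjacent
        if self.normalization is not None and set(self.layout.genes) - set(
            self.normalization.genes
        ):
            raise ValueError("normalization model does not cover all layout genes")

    @property
    def fitted(self) -> bool:
        return self.normalization is not None


@dataclass(frozen=True)
class FinalStep:
    """Last stage: one shared layout with one labelled sector per class.

    Samples in neither sector remain undetermined.
    """

    layout: AnchorLayout
    regions: Mapping[str, SectorRegion]  # label -> region
    normalization: NormalizationModel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", dict(self.regions))
        bad = set(self.regions) - set(CALL_LABELS)
        if bad:
            raise ValueError(f"invalid final-step labels: {sorted(bad)}")
        if not self.regions:
            raise ValueError("final step needs at least one labelled region")
        for region in self.regions.values():
            region.arc(self.layout)

    @property
    def fitted(self) -> bool:
        return self.normalization is not None


@dataclass
class Cascade:
    """Ordered elimination steps plus an optional dual-region final stage."""

    steps: list[EliminationStep] = field(default_factory=list)
    final: FinalStep | None = None

    def __post_init__(self) -> None:
        if not self.steps and self.final is None:
            raise ValueError("a cascade needs at least one step")

    def __len__(self) -> int:
        return len(self.steps) + (1 if self.final is not None else 0)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for step in self.steps:
            out.extend(g for g in step.layout.genes if g not in out)
        if self.final is not None:
            out.extend(g for g in self.final.layout.genes if g not in out)
        return out

    @property
    def fitted(self) -> bool:
        ok = all(s.fitted for s in self.steps)
        return ok and (self.final is None or self.final.fitted)


@dataclass
class CascadeResult:
    """Per-sample final calls with the 1-based step index that decided each."""

    sample_ids: list[str]
    calls: list[str]
    decided_at_step: list[int | None]
    true_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not self.true_labels:
            self.true_labels = ["unknown"] * n
        if not (len(self.calls) == len(self.decided_at_step) == len(self.true_labels) == n):
            raise ValueError("result fields must have equal length")
        for call, step in zip(self.calls, self.decided_at_step):
            if call not in CALL_LABELS + ("undetermined",):
                raise ValueError(f"invalid call {call!r}")
            if (call == "undetermined") != (step is None):
                raise ValueError("decided_at_step must be present iff a call was made")

    def counts(self) -> dict[str, int]:
        out = {"sensitive": 0, "resistant": 0, "undetermined": 0}
        for c in self.calls:
            out[c] += 1
        return out


@dataclass
class EvaluationReport:
    """Per-class Selected/Correct tallies plus the undetermined remainder."""

    selected: dict[str, int]
    correct: dict[str, int]
    percent_correct: dict[str, float]
    undetermined: int
    false_sensitive: int  # truly resistant samples called sensitive
    false_resistant: int  # truly sensitive samples called resistant

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": cls,
                "selected": self.selected[cls],
                "correct": self.correct[cls],
                "percent_correct": self.percent_correct[cls],
            }
            for cls in CALL_LABELS
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The published FOLFOX cascade
# ---------------------------------------------------------------------------


def published_folfox_cascade(r_min: float = 0.05) -> Cascade:
    """The four-stage FOLFOX-response cascade built on the 14 named markers.

    Step 1 (Cartesian, TMEM182/MCM9/LRRFIP1/LAMP1) eliminates sensitive
    samples in the LAMP1-LRRFIP1 quarter; step 2 (FAM161A/KLHL36/ETV5 arms)
    eliminates resistant samples in the FAM161A-ETV5 arm; step 3 (Cartesian,
    RNF168/SRSF11/NCKAP5/CRTAP) eliminates sensitive samples in the
    CRTAP-RNF168 quarter; the final stage (VAMP2/ZBTB49/RIMBP2) labels the
    VAMP2-RIMBP2 arm sensitive and the RIMBP2-ZBTB49 arm resistant, leaving
    the rest undetermined.  Normalization models are unfitted: fit them
    against the cohort of interest with :func:`fit_cascade_normalization`.
    """
    step1 = EliminationStep(
        layout=AnchorLayout.cartesian(["TMEM182", "MCM9", "LRRFIP1", "LAMP1"]),
        region=SectorRegion("LRRFIP1", "LAMP1", r_min=r_min),
        eliminate_label="sensitive",
    )
    step2 = EliminationStep(
        layout=AnchorLayout.for_genes(["FAM161A", "KLHL36", "ETV5"]),
        region=SectorRegion("ETV5", "FAM161A", r_min=r_min),
        eliminate_label="resistant",
    )
    step3 = EliminationStep(
        layout=AnchorLayout.cartesian(["RNF168", "SRSF11", "NCKAP5", "CRTAP"]),
        region=SectorRegion("CRTAP", "RNF168", r_min=r_min),
        eliminate_label="sensitive",
    )
    final = FinalStep(
        layout=AnchorLayout.for_genes(["VAMP2", "ZBTB49", "RIMBP2"]),
        regions={
            "sensitive": SectorRegion("RIMBP2", "VAMP2", r_min=r_min),
            "resistant": SectorRegion("ZBTB49", "RIMBP2", r_min=r_min),
        },
    )
    return Cascade(steps=[step1, step2, step3], final=final)


def fit_cascade_normalization(cascade: Cascade, matrix: ExpressionMatrix) -> Cascade:
    """Return a copy of ``cascade`` with min-max bounds fitted on ``matrix``.

    Bounds are frozen: later predictions on other cohorts reuse them.
    """
    steps = []
    for i, step in enumerate(cascade.steps, start=1):
        missing = [g for g in step.layout.genes if g not in matrix.gene_ids]
        if missing:
            raise KeyError(f"gene(s) {missing} required by step {i} missing from matrix")
        steps.append(replace(step, normalization=fit_normalization(matrix, step.layout.genes)))
    final = cascade.final
    if final is not None:
        missing = [g for g in final.layout.genes if g not in matrix.gene_ids]
        if missing:
            raise KeyError(
                f"gene(s) {missing} required by the final step missing from matrix"
            )
        final = replace(final, normalization=fit_normalization(matrix, final.layout.genes))
    return Cascade(steps=steps, final=final)


# ---------------------------------------------------------------------------
# Applying a cascade
# ---------------------------------------------------------------------------


def _step_mask(
    matrix: ExpressionMatrix,
    layout: AnchorLayout,
    normalization: NormalizationModel,
    region: SectorRegion,
    active: np.ndarray,
) -> np.ndarray:
    u = normalization.transform(matrix, layout.genes)
    pts = project_weights(u, layout)
    return region_mask(pts, region, layout) & active


def apply_cascade(matrix: ExpressionMatrix, cascade: Cascade) -> CascadeResult:
    """Run a fitted cascade over a cohort.

    Steps are applied in order to the samples not yet called; a sample whose
    projected point lies in the step's sector receives that step's label and
    the step index.  After the final stage's labelled sectors (if any), the
    remaining samples are undetermined.
    """
    if not cascade.fitted:
        raise ValueError(
            "cascade normalization is unfitted; call fit_cascade_normalization first"
        )
    n = matrix.n_samples
    calls = ["undetermined"] * n
    decided: list[int | None] = [None] * n
    active = np.ones(n, dtype=bool)
    for i, step in enumerate(cascade.steps, start=1):
        missing = [g for g in step.layout.genes if g not in matrix.gene_ids]
        if missing:
            raise KeyError(f"gene(s) {missing} required by step {i} missing from matrix")
        if not active.any():
            break
        hit = _step_mask(matrix, step.layout, step.normalization, step.region, active)
        for j in np.flatnonzero(hit):
            calls[j] = step.eliminate_label
            decided[j] = i
        active &= ~hit
    if cascade.final is not None and active.any():
        fstep = cascade.final
        missing = [g for g in fstep.layout.genes if g not in matrix.gene_ids]
        if missing:
            raise KeyError(f"gene(s) {missing} required by the final step missing from matrix")
        idx = len(cascade.steps) + 1
        # fixed label order so a point on the shared anchor boundary is
        # resolved deterministically
        for label in CALL_LABELS:
            if label not in fstep.regions:
                continue
            hit = _step_mask(
                matrix, fstep.layout, fstep.normalization, fstep.regions[label], active
            )
            for j in np.flatnonzero(hit):
                calls[j] = label
                decided[j] = idx
            active &= ~hit
    return CascadeResult(
        sample_ids=list(matrix.sample_ids),
        calls=calls,
        decided_at_step=decided,
        true_labels=list(matrix.labels),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

POOL_CAP = 12  # keeps the k=4 exhaustive search around 1.5k layouts


def _circular_orderings(genes: Sequence[str]) -> list[tuple[str, ...]]:
    """All (k-1)!/2 distinct circular orderings (rotation/reflection dedup)."""
    genes = sorted(genes)
    first, rest = genes[0], genes[1:]
    seen = []
    for perm in itertools.permutations(rest):
        if len(perm) >= 2 and perm[0] > perm[-1]:
            continue  # reflection duplicate
        seen.append((first,) + perm)
    return seen


def _stratified_train_mask(
    labels: Sequence[str], train_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded split taking ``train_frac`` of each class (at least one sample)."""
    labels = np.asarray(labels)
    mask = np.zeros(len(labels), dtype=bool)
    for cls in CALL_LABELS:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            continue
        n_take = max(1, int(round(train_frac * idx.size)))
        take = rng.choice(idx, size=min(n_take, idx.size), replace=False)
        mask[take] = True
    return mask


def _purity_coverage(
    hit: np.ndarray, target: np.ndarray, subset: np.ndarray
) -> tuple[float, int]:
    covered = hit & subset
    n_cov = int(covered.sum())
    if n_cov == 0:
        return 0.0, 0
    return float((covered & target).sum() / n_cov), n_cov


def fit_step(
    matrix: ExpressionMatrix,
    candidate_genes: Sequence[str],
    k: int,
    target_label: str,
    purity_min: float = 1.0,
    coverage_min: int = 3,
    train_frac: float = 0.7,
    seed: int = 0,
    r_min: float = 0.05,
    pool_cap: int = POOL_CAP,
    normalization: NormalizationModel | None = None,
) -> EliminationStep | None:
    """Exhaustively search one elimination step on a labelled cohort.

    Enumerates every size-``k`` gene subset of the pool, every distinct
    circular ordering, and every adjacent-anchor sector; keeps candidates
    whose region reaches ``purity_min`` / ``coverage_min`` on a seeded
    ``train_frac`` split of each class and re-verifies the same constraints
    on the full cohort.  Returns the verified candidate with maximal full
    coverage (ties: higher purity, then lexicographic gene order), or
    ``None`` if nothing qualifies.

    ``normalization`` optionally supplies frozen min-max bounds learned on
    a reference cohort (e.g. the full training cohort when this step sees
    only the samples surviving earlier eliminations); by default bounds are
    fitted on ``matrix`` itself.
    """
    if target_label not in CALL_LABELS:
        raise ValueError(f"target_label must be one of {CALL_LABELS}")
    pool = sorted(dict.fromkeys(candidate_genes))
    if len(pool) > pool_cap:
        raise ValueError(
            f"candidate pool of {len(pool)} genes exceeds the cap of {pool_cap}; "
            "pre-rank genes by |t_mod| (direction-stratified) and pass the top ones"
        )
    if k not in (3, 4):
        raise ValueError("steps use 3 or 4 anchors")
    if k > len(pool):
        raise ValueError(f"k={k} larger than candidate pool of {len(pool)}")
    if not (0.0 < train_frac <= 1.0):
        raise ValueError("train_frac must lie in (0, 1]")
    labels = np.asarray(matrix.labels)
    if not {"resistant", "sensitive"} <= set(labels):
        raise ValueError("both response labels must be present for training")

    rng = np.random.default_rng(seed)
    train = _stratified_train_mask(labels, train_frac, rng)
    full = labels != "unknown"
    target = labels == target_label

    # per-gene frozen bounds shared by every candidate
    if normalization is None:
        norm_all = fit_normalization(matrix, pool)
    else:
        missing = [g for g in pool if g not in normalization.genes]
        if missing:
            raise KeyError(f"normalization model lacks gene(s) {missing}")
        norm_all = normalization
    u_all = norm_all.transform(matrix, pool)
    col = {g: i for i, g in enumerate(pool)}

    best = None  # (coverage, purity) of the verified winner
    for combo in itertools.combinations(pool, k):
        for ordering in _circular_orderings(combo):
            layout = AnchorLayout.for_genes(ordering)
            pts = project_weights(u_all[:, [col[g] for g in ordering]], layout)
            for a, b in layout.adjacent_pairs():
                region = SectorRegion(a, b, r_min=r_min)
                hit = region_mask(pts, region, layout)
                tr_pur, tr_cov = _purity_coverage(hit, target, train & full)
                if tr_cov < coverage_min or tr_pur < purity_min:
                    continue
                fu_pur, fu_cov = _purity_coverage(hit, target, full)
                if fu_cov < coverage_min or fu_pur < purity_min:
                    continue
                # deterministic preference: coverage, then purity; iteration
                # order supplies the lexicographic tie-break
                if best is None or (fu_cov, fu_pur) > (best[0], best[1]):
                    best = (fu_cov, fu_pur, ordering, region)
    if best is None:
        return None
    _, _, ordering, region = best
    step_norm = NormalizationModel(
        genes=ordering,
        mins=tuple(norm_all.bounds(g)[0] for g in ordering),
        maxs=tuple(norm_all.bounds(g)[1] for g in ordering),
    )
    return EliminationStep(
        layout=AnchorLayout.for_genes(ordering),
        region=region,
        eliminate_label=target_label,
        normalization=step_norm,
    )


def _fit_second_region(
    matrix: ExpressionMatrix,
    step: EliminationStep,
    other_label: str,
    purity_min: float,
    coverage_min: int,
    train: np.ndarray,
) -> SectorRegion | None:
    """Best sector for the opposite label on an already-chosen final layout."""
    labels = np.asarray(matrix.labels)
    full = labels != "unknown"
    target = labels == other_label
    u = step.normalization.transform(matrix, step.layout.genes)
    pts = project_weights(u, step.layout)
    taken = step.region.arc(step.layout)
    best = None
    for a, b in step.layout.adjacent_pairs():
        region = SectorRegion(a, b, r_min=step.region.r_min)
        if region.arc(step.layout) == taken:
            continue
        hit = region_mask(pts, region, step.layout)
        tr_pur, tr_cov = _purity_coverage(hit, target, train & full)
        if tr_cov < coverage_min or tr_pur < purity_min:
            continue
        fu_pur, fu_cov = _purity_coverage(hit, target, full)
        if fu_cov < coverage_min or fu_pur < purity_min:
            continue
        if best is None or (fu_cov, fu_pur) > (best[0], best[1]):
            best = (fu_cov, fu_pur, region)
    return None if best is None else best[2]


def rank_panel_genes(matrix: ExpressionMatrix, panel, cap: int = POOL_CAP) -> list[str]:
    """Direction-stratified top-|t| panel genes, at most ``cap`` of them.

    Slots are allocated to the up and down lists proportionally to their
    sizes (at least one each when non-empty), ranking within each direction
    by |moderated t| on the given cohort.
    """
    from .deg_stats import moderated_t  # local import avoids a cycle

    present = [g for g in panel.genes if g in matrix.gene_ids]
    if len(present) <= cap:
        return present
    table = moderated_t(matrix.subset_genes(present)).set_index("gene")
    up = [g for g in panel.up if g in table.index]
    down = [g for g in panel.down if g in table.index]
    n_up = min(len(up), max(1, int(round(cap * len(up) / (len(up) + len(down))))))
    n_down = min(len(down), cap - n_up)
    n_up = cap - n_down  # give unused down slots back to up
    ranked_up = sorted(up, key=lambda g: (-abs(table.loc[g, "t_mod"]), g))[:n_up]
    ranked_down = sorted(down, key=lambda g: (-abs(table.loc[g, "t_mod"]), g))[:n_down]
    return ranked_up + ranked_down


def fit_cascade(
    matrix: ExpressionMatrix,
    panel,
    schedule: Sequence[tuple[int, str]],
    purity_min: float = 1.0,
    coverage_min: int = 3,
    train_frac: float = 0.7,
    seed: int = 0,
    r_min: float = 0.05,
    allow_reuse: bool = False,
    pool_cap: int = POOL_CAP,
    final_dual: bool = True,
    renormalize_per_step: bool = False,
) -> Cascade:
    """Greedily train a cascade following ``schedule`` (list of ``(k, label)``).

    Each entry fits one step on the samples not yet eliminated and removes
    the samples its region covers.  The last entry additionally searches the
    chosen layout for a sector of the opposite label, yielding the
    dual-region final stage (disable with ``final_dual=False``).  Panel
    genes already used by earlier steps are excluded unless ``allow_reuse``;
    when the remaining pool exceeds ``pool_cap`` it is pre-ranked by
    |moderated t| on the remaining samples, stratified by direction.

    Min-max bounds are learned once on the full training cohort and frozen
    for every step (so projections do not drift as samples are eliminated);
    ``renormalize_per_step=True`` instead refits bounds on each step's
    surviving samples, mirroring interactive tools that renormalize the
    displayed subset.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    panel_present = [g for g in panel.genes if g in matrix.gene_ids]
    if not panel_present:
        raise ValueError("no panel gene present in the matrix")
    norm_full = None if renormalize_per_step else fit_normalization(matrix, panel_present)
    remaining = np.ones(matrix.n_samples, dtype=bool)
    used: set[str] = set()
    steps: list[EliminationStep] = []
    final: FinalStep | None = None

    for pos, (k, target) in enumerate(schedule):
        is_last = pos == len(schedule) - 1
        sub = matrix.subset_samples(remaining)
        labels = np.asarray(sub.labels)
        if min((labels == c).sum() for c in CALL_LABELS) == 0:
            warnings.warn(
                f"schedule entry {pos + 1}: a class is exhausted among remaining "
                "samples; entry skipped",
                stacklevel=2,
            )
            continue
        pool = [g for g in panel.genes if g in matrix.gene_ids and (allow_reuse or g not in used)]
        if len(pool) < k:
            warnings.warn(
                f"schedule entry {pos + 1}: only {len(pool)} unused panel genes left; "
                "entry skipped",
                stacklevel=2,
            )
            continue
        if len(pool) > pool_cap:
            sub_panel = type(panel)(
                up=[g for g in panel.up if g in pool], down=[g for g in panel.down if g in pool]
            )
            pool = rank_panel_genes(sub, sub_panel, cap=pool_cap)
        step_seed = int((seed * 1_000_003 + pos) % 2**31)
        step = fit_step(
            sub,
            pool,
            k=k,
            target_label=target,
            purity_min=purity_min,
            coverage_min=coverage_min,
            train_frac=train_frac,
            seed=step_seed,
            r_min=r_min,
            pool_cap=pool_cap,
            normalization=norm_full,
        )
        if step is None:
            warnings.warn(
                f"schedule entry {pos + 1}: no ({k}-gene, {target}) step reached "
                f"purity {purity_min} with coverage {coverage_min}; entry skipped",
                stacklevel=2,
            )
            continue
        used.update(step.layout.genes)

        if is_last and final_dual:
            other = "resistant" if target == "sensitive" else "sensitive"
            rng = np.random.default_rng(step_seed)
            train = _stratified_train_mask(sub.labels, train_frac, rng)
            second = _fit_second_region(
                sub, step, other, purity_min, coverage_min, train
            )
            regions = {target: step.region}
            if second is not None:
                regions[other] = second
            final = FinalStep(
                layout=step.layout, regions=regions, normalization=step.normalization
            )
        else:
            steps.append(step)
            hit = _step_mask(
                matrix, step.layout, step.normalization, step.region,
                remaining,
            )
            remaining &= ~hit
    if not steps and final is None:
        raise ValueError("no schedule entry produced a step; relax the constraints")
    return Cascade(steps=steps, final=final)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(result: CascadeResult, labels: Sequence[str] | None = None) -> EvaluationReport:
    """Tally Selected / Correct / percent per class, plus error counts.

    ``false_sensitive`` counts truly resistant samples called sensitive (the
    clinically costly direction) and ``false_resistant`` the converse.
    Undetermined samples are counted separately and never as correct.
    """
    truth = list(labels) if labels is not None else list(result.true_labels)
    if len(truth) != len(result.calls):
        raise ValueError("labels length must match result")
    known = [lb != "unknown" for lb in truth]
    if not any(known):
        raise ValueError("all true labels unknown: nothing to evaluate")
    selected = {c: 0 for c in CALL_LABELS}
    correct = {c: 0 for c in CALL_LABELS}
    undetermined = 0
    false_sensitive = 0
    false_resistant = 0
    for call, lab, ok in zip(result.calls, truth, known):
        if not ok:
            continue
        if call == "undetermined":
            undetermined += 1
            continue
        selected[call] += 1
        if call == lab:
            correct[call] += 1
        elif call == "sensitive":
            false_sensitive += 1
        else:
            false_resistant += 1
    percent = {
        c: (round(100.0 * correct[c] / selected[c]) if selected[c] else float("nan"))
        for c in CALL_LABELS
    }
    return EvaluationReport(
        selected=selected,
        correct=correct,
        percent_correct=percent,
        undetermined=undetermined,
        false_sensitive=false_sensitive,
        false_resistant=false_resistant,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _norm_to_dict(norm: NormalizationModel | None):
    if norm is None:
        return None
    return {
        g: [float(lo), float(hi)]
        for g, lo, hi in zip(norm.genes, norm.mins, norm.maxs)
    }


def _norm_from_dict(data) -> NormalizationModel | None:
    if data is None:
        return None
    genes = tuple(data)
    return NormalizationModel(
        genes=genes,
        mins=tuple(float(data[g][0]) for g in genes),
        maxs=tuple(float(data[g][1]) for g in genes),
    )


def _region_to_dict(region: SectorRegion):
    return {"a": region.anchor_a, "b": region.anchor_b, "r_min": region.r_min}


def _region_from_dict(d) -> SectorRegion:
    return SectorRegion(d["a"], d["b"], r_min=float(d.get("r_min", 0.05)))


def cascade_to_dict(cascade: Cascade) -> dict:
    data: dict = {"steps": []}
    for step in cascade.steps:
        data["steps"].append(
            {
                "genes": list(step.layout.genes),
                "mode": step.layout.mode,
                "angles_deg": [float(round(np.degrees(a), 6)) for a in step.layout.angles],
                "region": _region_to_dict(step.region),
                "eliminate": step.eliminate_label,
                "normalization": _norm_to_dict(step.normalization),
            }
        )
    if cascade.final is not None:
        data["final"] = {
            "genes": list(cascade.final.layout.genes),
            "mode": cascade.final.layout.mode,
            "angles_deg": [float(round(np.degrees(a), 6)) for a in cascade.final.layout.angles],
            "regions": {lb: _region_to_dict(r) for lb, r in cascade.final.regions.items()},
            "normalization": _norm_to_dict(cascade.final.normalization),
        }
    return data


def _layout_from_dict(d) -> AnchorLayout:
    if "angles_deg" in d:
        return AnchorLayout(
            genes=tuple(d["genes"]),
            angles=tuple(np.radians(a) for a in d["angles_deg"]),
            mode=d.get("mode", "equal_spacing"),
        )
    return AnchorLayout.for_genes(d["genes"], mode=d.get("mode"))


def cascade_from_dict(data: Mapping) -> Cascade:
    steps = [
        EliminationStep(
            layout=_layout_from_dict(sd),
            region=_region_from_dict(sd["region"]),
            eliminate_label=sd["eliminate"],
            normalization=_norm_from_dict(sd.get("normalization")),
        )
        for sd in data.get("steps", [])
    ]
    final = None
    if data.get("final"):
        fd = data["final"]
        final = FinalStep(
            layout=_layout_from_dict(fd),
            regions={lb: _region_from_dict(rd) for lb, rd in fd["regions"].items()},
            normalization=_norm_from_dict(fd.get("normalization")),
        )
    return Cascade(steps=steps, final=final)


def save_cascade(cascade: Cascade, path: str | Path) -> None:
    path = Path(path)
    data = cascade_to_dict(cascade)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1) + "\n")


def load_cascade(path: str | Path) -> Cascade:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml") else json.loads(text)
    return cascade_from_dict(data)


def write_evaluation_report(report: EvaluationReport, path: str | Path) -> None:
    """TSV mirroring the Selected/Correct presentation, plus error counts."""
    with open(path, "w") as fh:
        fh.write(f"# undetermined={report.undetermined}\n")
        fh.write(f"# false_sensitive={report.false_sensitive}\n")
        fh.write(f"# false_resistant={report.false_resistant}\n")
        report.to_frame().to_csv(fh, sep="\t", index=False)
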