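"""Eliminative cascade: preset structure, application, training, evaluation."""

import warnings

import numpy as np
import pytest

from radcascade import (
    CohortSpec,
    ExpressionMatrix,
    MarkerPanel,
    apply_cascade,
    evaluate,
    fit_cascade,
    fit_cascade_normalization,
    fit_step,
    generate_cohort,
    load_cascade,
    published_folfox_cascade,
    save_cascade,
)
from radcascade.cascade import (
    Cascade,
    CascadeResult,
    cascade_to_dict,
    _purity_coverage,
    _step_mask,
)
from conftest import make_marker_matrix

SCHEDULE = [(4, "sensitive"), (3, "resistant"), (4, "sensitive"), (3, "resistant")]

PUBLISHED_GENES = [
    "TMEM182", "MCM9", "LRRFIP1", "LAMP1",
    "FAM161A", "KLHL36", "ETV5",
    "RNF168", "SRSF11", "NCKAP5", "CRTAP",
    "VAMP2", "ZBTB49", "RIMBP2",
]


class TestPublishedCascade:
    def test_has_four_stages(self):
        assert len(published_folfox_cascade()) == 4

    def test_step1_gene_set(self):
        casc = published_folfox_cascade()
        assert set(casc.steps[0].layout.genes) == {"TMEM182", "MCM9", "LRRFIP1", "LAMP1"}
        assert casc.steps[0].eliminate_label == "sensitive"

    def test_final_regions_share_rimbp2(self):
        casc = published_folfox_cascade()
        anchors = {lb: {r.anchor_a, r.anchor_b} for lb, r in casc.final.regions.items()}
        assert "RIMBP2" in anchors["sensitive"] & anchors["resistant"]
        assert anchors["sensitive"] == {"VAMP2", "RIMBP2"}
        assert anchors["resistant"] == {"ZBTB49", "RIMBP2"}

    def test_unfitted_until_bound_to_cohort(self):
        casc = published_folfox_cascade()
        assert not casc.fitted
        m = make_marker_matrix(PUBLISHED_GENES, seed=3)
        fitted = fit_cascade_normalization(casc, m)
        assert fitted.fitted
        result = apply_cascade(m, fitted)
        assert len(result.calls) == m.n_samples

    def test_missing_gene_named_in_error(self):
        genes = [g for g in PUBLISHED_GENES if g != "RIMBP2"]
        m = make_marker_matrix(genes, seed=3)
        with pytest.raises(KeyError, match="RIMBP2"):
            fit_cascade_normalization(published_folfox_cascade(), m)


class TestApplyCascade:
    def fitted_published(self, seed=5):
        m = make_marker_matrix(PUBLISHED_GENES, seed=seed)
        return m, fit_cascade_normalization(published_folfox_cascade(), m)

    def test_empty_cohort_gives_empty_result(self):
        m, casc = self.fitted_published()
        empty = ExpressionMatrix([], m.gene_ids, np.empty((0, m.n_genes)), labels=[])
        res = apply_cascade(empty, casc)
        assert res.calls == []

    def test_pure_lamp1_lrrfip1_sample_called_sensitive_at_step1(self):
        # reference samples span [0,1] per gene; test sample loads only on
        # LAMP1 and LRRFIP1 -> its point sits mid-sector at radius ~0.7
        genes = PUBLISHED_GENES
        lo = np.zeros(len(genes))
        hi = np.ones(len(genes))
        probe = np.zeros(len(genes))
        for g in ("LAMP1", "LRRFIP1"):
            probe[genes.index(g)] = 1.0
        m = ExpressionMatrix(
            ["lo", "hi", "probe"], genes, np.vstack([lo, hi, probe]),
            labels=["unknown", "unknown", "unknown"],
        )
        casc = fit_cascade_normalization(published_folfox_cascade(), m)
        res = apply_cascade(m, casc)
        i = m.sample_ids.index("probe")
        assert res.calls[i] == "sensitive"
        assert res.decided_at_step[i] == 1

    def test_partition_invariant_fuzzed(self):
        for seed in range(8):
            m, casc = self.fitted_published(seed=seed)
            res = apply_cascade(m, casc)
            counts = res.counts()
            assert sum(counts.values()) == m.n_samples

    def test_monotone_elimination_under_later_step_edits(self):
        m, casc = self.fitted_published()
        full = apply_cascade(m, casc)
        truncated = Cascade(steps=casc.steps[:2], final=None)
        part = apply_cascade(m, truncated)
        for i in range(m.n_samples):
            if part.decided_at_step[i] is not None:
                assert full.calls[i] == part.calls[i]
                assert full.decided_at_step[i] == part.decided_at_step[i]

    def test_concatenation_equals_per_cohort_results(self):
        m, casc = self.fitted_published()
        a = m.subset_samples(np.arange(0, 8))
        b = m.subset_samples(np.arange(8, 16))
        res_all = apply_cascade(m, casc)
        res_a = apply_cascade(a, casc)
        res_b = apply_cascade(b, casc)
        assert res_all.calls == res_a.calls + res_b.calls

    def test_unfitted_cascade_rejected(self):
        m = make_marker_matrix(PUBLISHED_GENES)
        with pytest.raises(ValueError, match="unfitted"):
            apply_cascade(m, published_folfox_cascade())


def separable_matrix(seed=0):
    """One gene (T1) cleanly elevated in every resistant sample.

    The decoy genes are constant, so they contribute the neutral weight 0.5
    and every sample's point lies exactly on the T1 axis: positive multiples
    of the T1 anchor for resistant samples, negative for sensitive ones.
    """
    rng = np.random.default_rng(seed)
    n = 10
    genes = ["T1", "N1", "N2", "N3"]
    x = np.full((2 * n, 4), 5.0)
    x[:, 0] = rng.normal(8, 0.1, size=2 * n)
    x[n:, 0] += 6.0
    return ExpressionMatrix(
        [f"s{i}" for i in range(2 * n)], genes, x,
        labels=["sensitive"] * n + ["resistant"] * n,
    )


class TestFitStep:
    def test_separable_data_fully_covered(self):
        m = separable_matrix()
        step = fit_step(m, m.gene_ids, k=3, target_label="resistant",
                        purity_min=1.0, coverage_min=3, seed=1)
        assert step is not None
        hit = _step_mask(m, step.layout, step.normalization, step.region,
                         np.ones(m.n_samples, dtype=bool))
        labels = np.asarray(m.labels)
        assert set(np.flatnonzero(hit)) == set(np.flatnonzero(labels == "resistant"))

    def test_infeasible_purity_returns_none(self, rng):
        # labels independent of expression: no pure sector of >= 8 samples
        x = rng.normal(8, 1, size=(16, 4))
        m = ExpressionMatrix(
            [f"s{i}" for i in range(16)], ["a", "b", "c", "d"], x,
            labels=["sensitive", "resistant"] * 8,
        )
        step = fit_step(m, m.gene_ids, k=3, target_label="resistant",
                        purity_min=1.0, coverage_min=8, seed=0)
        assert step is None

    def test_training_guarantee_holds_by_construction(self):
        spec = CohortSpec(seed=11)
        m = generate_cohort(spec)
        pool = list(spec.panel.up[:6]) + list(spec.panel.down[:3])
        step = fit_step(m, pool, k=4, target_label="sensitive",
                        purity_min=1.0, coverage_min=3, seed=2)
        assert step is not None
        hit = _step_mask(m, step.layout, step.normalization, step.region,
                         np.ones(m.n_samples, dtype=bool))
        labels = np.asarray(m.labels)
        purity, coverage = _purity_coverage(hit, labels == "sensitive",
                                            labels != "unknown")
        assert coverage >= 3
        assert purity >= 1.0

    def test_bit_stable_under_fixed_seed(self):
        m = generate_cohort(CohortSpec(seed=4))
        spec = CohortSpec(seed=4)
        pool = list(spec.panel.genes)[:10]
        s1 = fit_step(m, pool, k=4, target_label="sensitive", seed=9)
        s2 = fit_step(m, pool, k=4, target_label="sensitive", seed=9)
        assert s1.layout == s2.layout
        assert s1.region == s2.region
        assert s1.normalization == s2.normalization

    def test_pool_cap_exceeded_instructs_preranking(self):
        m = generate_cohort(CohortSpec(seed=0))
        with pytest.raises(ValueError, match="pre-rank"):
            fit_step(m, list(m.gene_ids[:20]), k=4, target_label="sensitive")

    def test_k_larger_than_pool_is_error(self):
        m = separable_matrix()
        with pytest.raises(ValueError, match="larger than"):
            fit_step(m, ["T1", "N1"], k=3, target_label="resistant")


class TestFitCascade:
    def test_single_entry_schedule_on_separable_data(self):
        m = separable_matrix()
        panel = MarkerPanel(up=["T1", "N1"], down=["N2", "N3"])
        casc = fit_cascade(m, panel, [(3, "resistant")], seed=0, final_dual=False)
        assert len(casc.steps) == 1
        rep = evaluate(apply_cascade(m, casc))
        assert rep.correct["resistant"] == rep.selected["resistant"] == 10

    def test_subtype_heterogeneity_needs_multiple_steps(self):
        # two resistant subtypes with strong, disjoint up-gene signatures:
        # each is separable on its own, but no single sector holds both
        spec = CohortSpec(seed=3, subtypes=2, effect_size=3.0, n_background=50)
        m = generate_cohort(spec)
        from radcascade.cascade import rank_panel_genes

        pool = rank_panel_genes(m, spec.panel, 12)
        n_res = int(np.sum(np.asarray(m.labels) == "resistant"))
        # exhaustive single-step search cannot cover all resistant samples purely
        single = fit_step(m, pool, k=3, target_label="resistant",
                          purity_min=1.0, coverage_min=n_res, seed=0)
        assert single is None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            casc = fit_cascade(
                m, spec.panel,
                [(3, "resistant"), (3, "resistant")],
                seed=0, final_dual=False,
            )
        res = apply_cascade(m, casc)
        covered = sum(c == "resistant" for c in res.calls)
        per_step = [sum(1 for s in res.decided_at_step if s == k) for k in (1, 2)]
        assert len(casc.steps) >= 2
        assert covered == n_res
        assert covered > max(per_step)

    def test_seeded_runs_reproducible(self):
        spec = CohortSpec(seed=6)
        m = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = fit_cascade(m, spec.panel, SCHEDULE, seed=13)
            c2 = fit_cascade(m, spec.panel, SCHEDULE, seed=13)
        assert cascade_to_dict(c1) == cascade_to_dict(c2)

    def test_round_trip_through_config_file(self, tmp_path):
        spec = CohortSpec(seed=6)
        m = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            casc = fit_cascade(m, spec.panel, SCHEDULE, seed=13)
        for name in ("c.json", "c.yaml"):
            path = tmp_path / name
            save_cascade(casc, path)
            back = load_cascade(path)
            assert apply_cascade(m, back).calls == apply_cascade(m, casc).calls

    def test_training_partition_is_pure(self):
        spec = CohortSpec(seed=2)
        m = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            casc = fit_cascade(m, spec.panel, SCHEDULE, seed=2)
        rep = evaluate(apply_cascade(m, casc))
        assert rep.correct == {
            cls: rep.selected[cls] for cls in ("sensitive", "resistant")
        }


class TestEvaluate:
    def result(self, calls, labels, steps=None):
        n = len(calls)
        if steps is None:
            steps = [None if c == "undetermined" else 1 for c in calls]
        return CascadeResult(
            sample_ids=[f"s{i}" for i in range(n)],
            calls=calls, decided_at_step=steps, true_labels=labels,
        )

    def test_all_correct(self):
        labels = ["sensitive"] * 3 + ["resistant"] * 2
        rep = evaluate(self.result(list(labels), labels))
        assert rep.percent_correct == {"sensitive": 100, "resistant": 100}
        assert rep.false_sensitive == rep.false_resistant == 0

    def test_single_false_sensitive(self):
        labels = ["resistant", "resistant", "sensitive"]
        calls = ["sensitive", "resistant", "sensitive"]
        rep = evaluate(self.result(calls, labels))
        assert rep.false_sensitive == 1
        assert rep.false_resistant == 0
        assert rep.correct["resistant"] == 1

    def test_undetermined_never_counted_correct(self):
        labels = ["sensitive", "sensitive"]
        rep = evaluate(self.result(["undetermined", "sensitive"], labels))
        assert rep.undetermined == 1
        assert rep.correct["sensitive"] == 1

    def test_random_confusion_matches_brute_tally(self, rng):
        labels = list(rng.choice(["sensitive", "resistant"], 60))
        calls = list(rng.choice(["sensitive", "resistant", "undetermined"], 60))
        rep = evaluate(self.result(calls, labels))
        for cls in ("sensitive", "resistant"):
            sel = sum(1 for c in calls if c == cls)
            cor = sum(1 for c, l in zip(calls, labels) if c == cls and l == cls)
            assert rep.selected[cls] == sel
            assert rep.correct[cls] == cor
            if sel:
                assert rep.percent_correct[cls] == round(100 * cor / sel)
        assert rep.undetermined == calls.count("undetermined")

    def test_all_unknown_labels_error(self):
        rep = self.result(["sensitive"], ["unknown"])
        with pytest.raises(ValueError, match="unknown"):
            evaluate(rep)

    def test_percentages_round_to_integers(self):
        labels = ["sensitive"] * 3
        calls = ["sensitive", "sensitive", "resistant"]
        rep = evaluate(self.result(calls, labels))
        assert rep.percent_correct["sensitive"] == 100
        assert rep.selected["sensitive"] == 2
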