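"""Correlation metrics with oracles, FDR, group tests and the voting classifier."""

import numpy as np
import pytest
from scipy import stats

from hist2rna import AlignmentError, InvalidInputError
from hist2rna.evaluation import (
    SubtypeModel,
    classification_metrics,
    evaluate,
    evaluate_across_genes,
    evaluate_across_patients,
    fit_subtype_classifier,
    group_difference_tests,
    predict_subtype,
    spearman_with_p,
)
from hist2rna.expression import ExpressionMatrix
from hist2rna.synthetic import make_cohort


def _brute_spearman(a, b):
    """Independent oracle: explicit midranks, Pearson on ranks, t-based p."""
    def midranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        i = 0
        xs = np.asarray(x)[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and xs[j + 1] == xs[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = midranks(a), midranks(b)
    num = np.sum((ra - ra.mean()) * (rb - rb.mean()))
    den = np.sqrt(np.sum((ra - ra.mean()) ** 2) * np.sum((rb - rb.mean()) ** 2))
    rho = num / den
    n = len(a)
    if abs(rho) >= 1:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * stats.t.sf(abs(t), n - 2)


def _brute_bh(p):
    """Step-up Benjamini-Hochberg by hand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    ids = [f"P{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(ids, genes, values, scale="log2p1")


class TestSpearman:
    def test_identity_gives_rho_one_p_zero(self):
        rho, p = spearman_with_p([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == 1.0 and p == 0.0

    def test_reversal_gives_rho_minus_one(self):
        rho, p = spearman_with_p([1, 2, 3, 4], [9, 7, 5, 3])
        assert rho == -1.0 and p == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 0.5 * a
        if seed % 2:  # exercise tie handling
            a = np.round(a, 1)
            b = np.round(b, 1)
        rho, p = spearman_with_p(a, b)
        orho, op = _brute_spearman(a, b)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        rho, p = spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman_with_p([1, 2], [3, 4])


class TestAcrossPatientsAndGenes:
    def test_perfect_prediction_everywhere(self):
        truth = _expr(np.random.default_rng(0).standard_normal((5, 6)) + 10)
        per_patient = evaluate_across_patients(truth, truth)
        per_gene, n_sig = evaluate_across_genes(truth, truth)
        assert (per_patient["rho"] == 1).all()
        assert (per_gene["rho"] == 1).all()
        np.testing.assert_allclose(per_gene["r2"], 1.0, atol=1e-12)
        assert n_sig == 6

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        pred = _expr(rng.standard_normal((10, 8)))
        truth = _expr(rng.standard_normal((10, 8)))
        per_patient = evaluate_across_patients(pred, truth)
        per_gene, _ = evaluate_across_genes(pred, truth)
        for i in range(10):
            orho, op = _brute_spearman(pred.values[i], truth.values[i])
            assert per_patient["rho"][i] == pytest.approx(orho, abs=1e-12)
            assert per_patient["p"][i] == pytest.approx(op, abs=1e-12)
        for j in range(8):
            orho, _ = _brute_spearman(pred.values[:, j], truth.values[:, j])
            assert per_gene["rho"][j] == pytest.approx(orho, abs=1e-12)
        np.testing.assert_allclose(per_gene["q"], _brute_bh(per_gene["p"]), atol=1e-12)

    def test_shuffled_prediction_uncorrelated(self):
        rng = np.random.default_rng(7)
        truth = _expr(rng.standard_normal((6, 30)))
        medians = []
        for rep in range(50):
            perm = rng.permutation(30)
            pred = _expr(truth.values[:, perm])
            medians.append(evaluate_across_patients(pred, truth)["rho"].median())
        assert abs(np.mean(medians)) < 0.1

    def test_r2_negative_for_bad_fit(self):
        truth = _expr([[0.0, 1, 2], [1, 2, 3], [2, 3, 4], [3, 4, 5]])
        pred = _expr(truth.values[::-1].copy())
        per_gene, _ = evaluate_across_genes(pred, truth)
        assert (per_gene["r2"] < 0).all()

    def test_single_gene_q_equals_p(self):
        rng = np.random.default_rng(1)
        pred = _expr(rng.standard_normal((8, 1)))
        truth = _expr(rng.standard_normal((8, 1)))
        per_gene, _ = evaluate_across_genes(pred, truth)
        assert per_gene["q"][0] == pytest.approx(per_gene["p"][0], abs=1e-15)

    def test_bh_hand_worked_example(self):
        # p = (0.01, 0.02, 0.04, 0.5) -> q = (0.04, 0.04, 0.0533..., 0.5)
        np.testing.assert_allclose(
            _brute_bh([0.01, 0.02, 0.04, 0.5]),
            [0.04, 0.04, 0.04 * 4 / 3, 0.5], atol=1e-12)
        rng = np.random.default_rng(0)
        # embed: craft data whose p-values we then BH-adjust through the API
        pred = _expr(rng.standard_normal((12, 4)))
        truth = _expr(rng.standard_normal((12, 4)))
        per_gene, _ = evaluate_across_genes(pred, truth)
        np.testing.assert_allclose(per_gene["q"], _brute_bh(per_gene["p"]), atol=1e-12)

    def test_disjoint_patients_rejected(self):
        a = _expr(np.zeros((3, 2)) + np.arange(3)[:, None])
        b = ExpressionMatrix(["X0", "X1", "X2"], a.gene_symbols, a.values,
                             scale="log2p1")
        with pytest.raises(AlignmentError):
            evaluate_across_patients(a, b)


class TestGroupTests:
    def test_identical_groups_give_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = group_difference_tests({"pos": x, "neg": list(x)})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert res.test == "welch_t"

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        res = group_difference_tests({
            "neg": rng.normal(0, 0.1, 40), "pos": rng.normal(10, 0.1, 40)})
        assert res.p_value < 1e-6

    def test_three_group_anova_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(i * 0.5, 1.0, 12) for i, g in enumerate("abc")}
        res = group_difference_tests(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2)
                        for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert res.test == "anova"
        assert res.statistic == pytest.approx(f_oracle, rel=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(InvalidInputError):
            group_difference_tests({"a": [1.0], "b": [1.0, 2.0]})


class _StubEnsemble:
    def __init__(self, proba, classes):
        self._p = np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._p


class TestSubtypeClassifier:
    def test_unanimous_members_give_certain_vote(self):
        probs = np.mean([np.array([[1.0, 0, 0]])] * 4, axis=0)
        model = SubtypeModel(_StubEnsemble(probs, ["A", "B", "C"]),
                             ("A", "B", "C"), ("G1",), seed=0)
        labels, proba = predict_subtype(model, _expr([[0.0]], genes=["G1"]))
        assert labels[0] == "A" and proba[0, 0] == 1.0

    def test_soft_vote_is_arithmetic_mean_with_class_order_tiebreak(self):
        members = np.array([
            [0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6], [0.4, 0.4, 0.2]])
        voted = members.mean(axis=0)
        np.testing.assert_allclose(voted, [0.35, 0.35, 0.30], atol=1e-12)
        model = SubtypeModel(_StubEnsemble(voted[None, :], ["A", "B", "C"]),
                             ("A", "B", "C"), ("G1",), seed=0)
        labels, _ = predict_subtype(model, _expr([[0.0]], genes=["G1"]))
        assert labels[0] == "A"  # argmax tie broken by first class in order

    def test_separable_synthetic_subtypes_classified_accurately(self):
        # 20 patches/patient keeps the patch-mean noise on the latent subtype
        # axes small, so the label-defining thresholds are recoverable
        cohort = make_cohort(300, 20, 16, 30, noise_sd=0.05, seed=8)
        pam = [i for i, f in enumerate(cohort.panel.pam50_flags) if f]
        expr = ExpressionMatrix(cohort.patient_ids,
                                tuple(cohort.panel.symbols[i] for i in pam),
                                cohort.expression.values[:, pam], scale="log2p1")
        labels = np.asarray(cohort.subtype_labels)
        tr = ExpressionMatrix(expr.patient_ids[:200], expr.gene_symbols,
                              expr.values[:200], scale="log2p1")
        te = ExpressionMatrix(expr.patient_ids[200:], expr.gene_symbols,
                              expr.values[200:], scale="log2p1")
        model = fit_subtype_classifier(tr, labels[:200], seed=0)
        pred, proba = predict_subtype(model, te)
        metrics = classification_metrics(labels[200:], pred, proba, model.classes)
        assert metrics["accuracy"] > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_subtype_classifier(_expr(np.zeros((4, 2)) + np.arange(4)[:, None]),
                                   ["LumA"] * 4)


class TestClassificationMetrics:
    def test_perfect_separation_gives_unit_auroc(self):
        y = ["A", "A", "B", "B"]
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        m = classification_metrics(y, y, proba, ["A", "B"])
        assert m["auroc"]["A"] == 1.0 and m["auroc"]["B"] == 1.0
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0

    def test_auroc_matches_pairwise_oracle_with_half_credit_ties(self):
        rng = np.random.default_rng(4)
        y = rng.choice(["A", "B"], size=30)
        scores = np.round(rng.random(30), 1)  # coarse scores force ties
        proba = np.column_stack([scores, 1 - scores])
        m = classification_metrics(y, y, proba, ["A", "B"])
        pos = scores[y == "A"]
        neg = scores[y == "B"]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        assert m["auroc"]["A"] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(5)
        aurocs = []
        for rep in range(100):
            y = rng.choice(["A", "B"], size=40)
            scores = rng.random(40)
            proba = np.column_stack([scores, 1 - scores])
            aurocs.append(classification_metrics(y, y, proba, ["A", "B"])["auroc"]["A"])
        assert abs(np.mean(aurocs) - 0.5) < 0.03

    def test_absent_class_flagged_nan(self):
        y = ["A", "A", "A"]
        proba = np.array([[0.5, 0.5]] * 3)
        m = classification_metrics(y, y, proba, ["A", "B"])
        assert np.isnan(m["auroc"]["B"])


def test_full_report_medians_and_counts(small_cohort):
    report = evaluate(small_cohort.oracle_predictions(), small_cohort.expression)
    assert -1 <= report.medians["per_gene"] <= 1
    assert report.medians["per_patient"] > 0.9
    assert 0 <= report.n_significant_genes <= small_cohort.expression.n_genes
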