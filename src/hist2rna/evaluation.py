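"""Regression and classification metrics for predicted expression.

Two complementary correlation views are reported: across patients (one
Spearman rho per patient, over all panel genes — sensitive to the shared
expression profile) and across genes (one rho per gene, over all patients —
sensitive to per-gene signal, with Benjamini-Hochberg FDR control and a
per-gene R²).  Group comparisons use Welch t-tests (two groups) or one-way
ANOVA (three or more).  Subtype calls from predicted PAM50 genes come from a
four-member soft-voting ensemble (random forest, multilayer perceptron,
linear discriminant analysis, logistic regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, VotingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.neural_network import MLPClassifier
from statsmodels.stats.multitest import multipletests

from ._errors import AlignmentError, InvalidInputError
from .expression import ExpressionMatrix

__all__ = [
    "EvalReport",
    "SubtypeModel",
    "spearman_with_p",
    "evaluate_across_patients",
    "evaluate_across_genes",
    "evaluate",
    "group_difference_tests",
    "fit_subtype_classifier",
    "predict_subtype",
    "classification_metrics",
]


@dataclass
class EvalReport:
    """Per-patient and per-gene correlation summaries of a prediction run."""

    per_patient: pd.DataFrame  # columns: patient_id, rho, p
    per_gene: pd.DataFrame  # columns: gene_symbol, rho, p, q, r2
    medians: dict
    n_significant_genes: int
    fdr_threshold: float = 0.05

    def to_csv(self, patient_path, gene_path) -> None:
        self.per_patient.to_csv(patient_path, index=False)
        self.per_gene.to_csv(gene_path, index=False)

    def summary(self) -> dict:
        return {
            "median_rho_per_patient": self.medians.get("per_patient"),
            "median_rho_per_gene": self.medians.get("per_gene"),
            "n_significant_genes": self.n_significant_genes,
            "fdr_threshold": self.fdr_threshold,
        }


def spearman_with_p(a, b) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-distribution p-value.

    Ranks use midranks for ties; the p-value comes from
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on ``n - 2`` degrees of freedom.
    A perfect correlation (|rho| = 1) is reported with p = 0.  Constant input
    vectors have no defined rank correlation: (nan, nan) is returned and such
    entries are excluded from summaries.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("inputs must be 1-D vectors of equal length")
    n = a.size
    if n < 3:
        raise InvalidInputError(f"need at least 3 observations, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    da = ra - ra.mean()
    db = rb - rb.mean()
    rho = float(np.clip(np.sum(da * db) / np.sqrt(np.sum(da * da) * np.sum(db * db)),
                        -1.0, 1.0))
    if 1.0 - abs(rho) < 1e-12:  # identical or reversed rankings, up to rounding
        rho = float(np.sign(rho))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _aligned_values(pred: ExpressionMatrix, truth: ExpressionMatrix):
    if pred.patient_ids != truth.patient_ids:
        if set(pred.patient_ids) != set(truth.patient_ids):
            raise AlignmentError("prediction and truth cover different patients")
        order = [truth.patient_ids.index(p) for p in pred.patient_ids]
        truth_vals = truth.values[order]
    else:
        truth_vals = truth.values
    if pred.gene_symbols != truth.gene_symbols:
        if set(pred.gene_symbols) != set(truth.gene_symbols):
            raise AlignmentError("prediction and truth cover different genes")
        gorder = [truth.gene_symbols.index(g) for g in pred.gene_symbols]
        truth_vals = truth_vals[:, gorder]
    return pred.values, truth_vals


def evaluate_across_patients(pred: ExpressionMatrix, truth: ExpressionMatrix) -> pd.DataFrame:
    """One (rho, p) per patient, correlating predicted vs true values over genes."""
    pv, tv = _aligned_values(pred, truth)
    rows = []
    for i, pid in enumerate(pred.patient_ids):
        rho, p = spearman_with_p(pv[i], tv[i])
        rows.append((pid, rho, p))
    return pd.DataFrame(rows, columns=["patient_id", "rho", "p"])


def evaluate_across_genes(
    pred: ExpressionMatrix, truth: ExpressionMatrix, fdr_threshold: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Per-gene (rho, p, BH q, R²) over patients, plus the significant-gene count.

    R² = 1 - SS_res / SS_tot against the true per-gene mean; it can be
    negative when predictions fit worse than the mean.  Genes with undefined
    correlation (constant vectors) keep NaN rho/p/q and are excluded from the
    BH adjustment and the significance count.
    """
    pv, tv = _aligned_values(pred, truth)
    if pv.shape[0] < 3:
        raise InvalidInputError("across-gene evaluation needs at least 3 patients")
    rows = []
    for j, sym in enumerate(pred.gene_symbols):
        rho, p = spearman_with_p(pv[:, j], tv[:, j])
        ss_tot = float(np.sum((tv[:, j] - tv[:, j].mean()) ** 2))
        ss_res = float(np.sum((tv[:, j] - pv[:, j]) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        rows.append((sym, rho, p, r2))
    df = pd.DataFrame(rows, columns=["gene_symbol", "rho", "p", "r2"])
    q = np.full(len(df), np.nan)
    defined = df["p"].notna().to_numpy()
    if defined.any():
        q[defined] = multipletests(df.loc[defined, "p"], method="fdr_bh")[1]
    df.insert(3, "q", q)
    n_sig = int(np.nansum(q < fdr_threshold))
    return df, n_sig


def evaluate(
    pred: ExpressionMatrix, truth: ExpressionMatrix, fdr_threshold: float = 0.05
) -> EvalReport:
    """Full report: across-patient and across-gene summaries."""
    per_patient = evaluate_across_patients(pred, truth)
    per_gene, n_sig = evaluate_across_genes(pred, truth, fdr_threshold)
    medians = {
        "per_patient": float(per_patient["rho"].median(skipna=True)),
        "per_gene": float(per_gene["rho"].median(skipna=True)),
    }
    return EvalReport(per_patient, per_gene, medians, n_sig, fdr_threshold)


@dataclass
class GroupTestResult:
    test: str  # "welch_t" | "student_t" | "anova"
    statistic: float
    p_value: float
    group_sizes: dict


def group_difference_tests(groups: dict, flavour: str = "welch") -> GroupTestResult:
    """Two groups: two-sided t-test (Welch by default); three or more: one-way ANOVA."""
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InvalidInputError(f"group {k!r} has fewer than 2 observations")
    sizes = {k: int(v.size) for k, v in arrays.items()}
    vals = list(arrays.values())
    if len(vals) == 2:
        equal_var = flavour == "student"
        stat, p = stats.ttest_ind(vals[0], vals[1], equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        return GroupTestResult(name, float(stat), float(p), sizes)
    stat, p = stats.f_oneway(*vals)
    return GroupTestResult("anova", float(stat), float(p), sizes)


@dataclass
class SubtypeModel:
    """Soft-voting ensemble of RF, MLP, LDA and LR over PAM50 gene expression."""

    ensemble: VotingClassifier = field(repr=False)
    classes: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    seed: int
    fitted: bool = True


def fit_subtype_classifier(
    expr: ExpressionMatrix, labels, seed: int = 0, mlp_max_iter: int = 500
) -> SubtypeModel:
    """Fit the four-member soft-voting subtype classifier on (PAM50) expression.

    Member hyperparameters are the library defaults with a fixed seed; the
    voted probability is the arithmetic mean of the members' class
    probabilities and the call is its argmax (ties broken by class order).
    """
    labels = np.asarray([str(x) for x in labels])
    if labels.size != expr.n_patients:
        raise AlignmentError(f"{labels.size} labels for {expr.n_patients} patients")
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("need at least 2 classes to fit the subtype classifier")
    members = [
        ("rf", RandomForestClassifier(random_state=seed)),
        ("mlp", MLPClassifier(random_state=seed, max_iter=mlp_max_iter)),
        ("lda", LinearDiscriminantAnalysis()),
        ("lr", LogisticRegression(random_state=seed, max_iter=1000)),
    ]
    ens = VotingClassifier(members, voting="soft")
    ens.fit(expr.values, labels)
    return SubtypeModel(ens, tuple(ens.classes_), expr.gene_symbols, seed)


def predict_subtype(model: SubtypeModel, expr: ExpressionMatrix):
    """Voted labels and class probabilities for new patients."""
    if expr.gene_symbols != model.gene_symbols:
        raise AlignmentError("gene symbols differ from the classifier's training genes")
    proba = model.ensemble.predict_proba(expr.values)
    labels = np.asarray(model.classes)[np.argmax(proba, axis=1)]
    return labels, proba


def classification_metrics(y_true, y_pred, proba, classes) -> dict:
    """Accuracy, macro-F1 and per-class one-vs-rest AUROC from voted probabilities.

    A class absent from the truth has no defined AUROC and is reported as NaN.
    """
    y_true = np.asarray([str(x) for x in y_true])
    y_pred = np.asarray([str(x) for x in y_pred])
    if y_true.shape != y_pred.shape:
        raise AlignmentError("label vectors differ in length")
    proba = np.asarray(proba, dtype=float)
    classes = tuple(str(c) for c in classes)
    auroc = {}
    for j, cls in enumerate(classes):
        pos = (y_true == cls).astype(int)
        if pos.min() == pos.max():  # class absent (or the only one) in truth
            auroc[cls] = float("nan")
        else:
            auroc[cls] = float(roc_auc_score(pos, proba[:, j]))
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_f1": float(f1_score(y_true, y_pred, average="macro")),
        "auroc": auroc,
    }
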