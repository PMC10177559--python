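"""End-to-end orchestration, the patch-based reference trainer and energy accounting.

The aggregation route trains on one record per patient and epoch; the
patch-based reference route trains the identical head on one record per patch
(every patch labelled with its patient's expression vector), with per-patient
predictions formed by averaging the patch predictions.  Instrumentation
counters record samples seen per epoch for both, which is the mechanism
behind the aggregation route's order-of-magnitude training-cost advantage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import pathlib
from dataclasses import asdict, dataclass

import numpy as np

from ._errors import InvalidInputError, StateError
from .evaluation import EvalReport, evaluate
from .expression import ExpressionMatrix
from .features import FeatureTensor, aggregate
from .head import HeadConfig, TrainConfig, TrainedHead, predict_matrix, train_head, train_on_matrix
from .synthetic import make_cohort, make_survival

__all__ = [
    "EnergyReport",
    "energy_report",
    "render_kwh",
    "patch_based_reference_train",
    "predict_per_patient_patchwise",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnergyReport:
    """GPU-hours energy bookkeeping: devices x hours x watts, and the kWh value."""

    n_devices: float
    watts_per_device: float
    hours: float
    product_watt_hours: float
    kilowatt_hours: float


def energy_report(n_devices: float, hours: float, watts_per_device: float = 300.0) -> EnergyReport:
    """Energy used by a training run: ``n_devices * hours * watts`` watt-hours.

    The kilowatt-hour field divides the product by 1000.
    """
    if min(n_devices, hours, watts_per_device) < 0:
        raise InvalidInputError("energy inputs must be nonnegative")
    product = n_devices * hours * watts_per_device
    return EnergyReport(
        n_devices=n_devices,
        watts_per_device=watts_per_device,
        hours=hours,
        product_watt_hours=product,
        kilowatt_hours=product / 1000.0,
    )


def render_kwh(kwh: float) -> str:
    """Render a kWh value; values below 1 are truncated (not rounded) to two decimals."""
    if kwh < 1.0:
        return f"{math.floor(kwh * 100) / 100:.2f}"
    return f"{kwh:g}"


def patch_based_reference_train(
    tensors: list[FeatureTensor],
    targets: ExpressionMatrix,
    train_cfg: TrainConfig = TrainConfig(),
    head_cfg: HeadConfig | None = None,
) -> TrainedHead:
    """Reference trainer consuming every patch row individually.

    Each patch's feature vector is a separate training record labelled with
    its patient's target vector, so an epoch touches sum(N_i) records instead
    of one per patient.  The head architecture and recipe are identical to the
    aggregation trainer.
    """
    if targets.scale != "log2p1":
        raise StateError("targets must be log2(1+x)-transformed before training")
    feats = {t.patient_id: t.values for t in tensors}
    missing = [p for p in targets.patient_ids if p not in feats]
    if missing:
        raise InvalidInputError(f"feature tensors missing for patients {missing[:5]}")
    X = np.vstack([feats[p] for p in targets.patient_ids])
    Y = np.vstack(
        [np.repeat(targets.values[i : i + 1], feats[p].shape[0], axis=0)
         for i, p in enumerate(targets.patient_ids)]
    )
    return train_on_matrix(X, Y, train_cfg, head_cfg)


def predict_per_patient_patchwise(model: TrainedHead, tensors: list[FeatureTensor],
                                  patient_ids) -> np.ndarray:
    """Per-patient prediction of the patch-based model: mean over patch predictions."""
    feats = {t.patient_id: t.values for t in tensors}
    return np.stack([predict_matrix(model, feats[p]).mean(axis=0) for p in patient_ids])


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run."""

    n_patients: int = 120
    test_fraction: float = 0.33
    patches_per_patient: int = 20
    n_features: int = 32
    n_genes: int = 20
    noise_sd: float = 0.1
    seed: int = 7
    fdr_threshold: float = 0.05
    max_epochs: int = 150
    run_subtype: bool = True
    run_survival: bool = True
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _split(cohort, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed + 1)
    n = cohort.n_patients
    n_test = max(1, int(round(test_fraction * n)))
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return train_idx, test_idx


def _subset_expr(expr: ExpressionMatrix, idx) -> ExpressionMatrix:
    ids = tuple(expr.patient_ids[i] for i in idx)
    return ExpressionMatrix(ids, expr.gene_symbols, expr.values[list(idx)], scale=expr.scale)


def run_pipeline(config: RunConfig) -> dict:
    """Run cohort generation -> aggregation -> training -> evaluation (-> subtype, survival).

    Returns a result dictionary; when ``config.outdir`` is set, per-stage
    manifests (carrying the config hash and seed) and the evaluation CSVs are
    written there.  Deterministic for a fixed config.
    """
    from .evaluation import classification_metrics, fit_subtype_classifier, predict_subtype
    from .expression import select_panel
    from .survival import concordance_index, cox_fit, dichotomise, logrank

    outdir = pathlib.Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.config_hash(), "stages": []}

    cohort = make_cohort(
        config.n_patients, config.patches_per_patient, config.n_features,
        config.n_genes, config.noise_sd, config.seed,
    )
    manifest["stages"].append("fixtures")
    tensors = [FeatureTensor(p, cohort.features[p], "synthetic") for p in cohort.patient_ids]
    aggregated = [aggregate(t) for t in tensors]
    manifest["stages"].append("aggregate")

    train_idx, test_idx = _split(cohort, config.test_fraction, config.seed)
    train_ids = {cohort.patient_ids[i] for i in train_idx}
    expr_train = _subset_expr(cohort.expression, train_idx)
    expr_test = _subset_expr(cohort.expression, test_idx)
    agg_train = [a for a in aggregated if a.patient_id in train_ids]
    agg_test = [a for a in aggregated if a.patient_id not in train_ids]

    cfg = TrainConfig(seed=config.seed, max_epochs=config.max_epochs)
    trained = train_head(agg_train, expr_train, cfg,
                         HeadConfig(output_dim=config.n_genes))
    manifest["stages"].append("train")

    X_test = np.stack([a.values for a in agg_test])
    pred_vals = predict_matrix(trained, X_test)
    pred = ExpressionMatrix(expr_test.patient_ids, expr_test.gene_symbols,
                            pred_vals, scale="log2p1")
    report: EvalReport = evaluate(pred, expr_test, config.fdr_threshold)
    manifest["stages"].append("evaluate")
    results = {
        "report": report,
        "manifest": manifest,
        "best_epoch": trained.best_epoch,
        "samples_per_epoch": trained.samples_seen_per_epoch[0],
    }

    if config.run_subtype:
        pam50 = ExpressionMatrix(
            cohort.expression.patient_ids,
            cohort.panel.pam50_symbols,
            select_panel(cohort.expression, cohort.panel).values[:, [
                i for i, f in enumerate(cohort.panel.pam50_flags) if f]],
            scale="log2p1",
        )
        labels = np.asarray(cohort.subtype_labels)
        train_expr = _subset_expr(pam50, train_idx)
        test_expr = _subset_expr(pam50, test_idx)
        if len(set(labels[train_idx])) >= 2:
            model = fit_subtype_classifier(train_expr, labels[train_idx], seed=config.seed)
            pred_labels, proba = predict_subtype(model, test_expr)
            results["subtype_metrics"] = classification_metrics(
                labels[test_idx], pred_labels, proba, model.classes)
            manifest["stages"].append("subtype")

    if config.run_survival:
        clin = make_survival(cohort.subtype_labels, hazard_ratio_lumB=2.0,
                             censor_rate=0.005, seed=config.seed)
        groups = dichotomise(clin)
        lum = groups["lumB"].notna()
        if lum.sum() >= 4 and groups.loc[lum, "lumB"].nunique() == 2:
            sub = clin[lum]
            chi2, p = logrank(sub["followup_time"], sub["event"], groups.loc[lum, "lumB"])
            cix = concordance_index(groups.loc[lum, "lumB"].to_numpy(),
                                    sub["followup_time"].to_numpy(), sub["event"].to_numpy())
            uni = cox_fit(sub.assign(lumB=groups.loc[lum, "lumB"]),
                          ["lumB"], mode="univariate")
            results["survival"] = {"logrank_chi2": chi2, "logrank_p": p,
                                   "c_index": cix, "cox": uni}
            manifest["stages"].append("survival")

    if outdir:
        report.to_csv(outdir / "per_patient.csv", outdir / "per_gene.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({**manifest, "summary": report.summary()}, fh, indent=2)
    return results
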