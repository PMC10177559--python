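"""Reproducible desk-scale experiments exercising the full method.

These are the study conditions the package's synthetic validation runs under:
cohorts small enough for a single CPU, with every random draw controlled by an
explicit seed.  The training recipe follows the published defaults (Adam,
learning rate 0.001, minibatch 12, MSE, at most 150 epochs) with the early
stopping patience re-expressed at the reduced cohort size: patience 4 epochs
at the original ~28 updates/epoch is ~112 parameter updates, which is ~16
epochs at ~7 updates/epoch here, monitored on the (deterministic end-of-epoch)
training loss.
"""

from __future__ import annotations

import numpy as np

from .evaluation import evaluate
from .expression import ExpressionMatrix
from .features import FeatureTensor
from .head import HeadConfig, TrainConfig, predict_matrix, train_on_matrix
from .pipeline import patch_based_reference_train, predict_per_patient_patchwise
from .survival import concordance_index, cox_fit, dichotomise
from .synthetic import make_cohort, make_survival

__all__ = [
    "desk_scale_train_config",
    "parameter_recovery",
    "efficiency_comparison",
    "hazard_recovery",
    "random_risk_concordance",
]


def desk_scale_train_config(seed: int, max_epochs: int = 150,
                            patience: int = 16) -> TrainConfig:
    """The published recipe with stopping patience scaled to the reduced cohort."""
    return TrainConfig(seed=seed, monitor="train", validation_fraction=0.0,
                       early_stop_patience=patience, max_epochs=max_epochs)


def _cohort_matrices(cohort):
    X = np.stack([cohort.features[p].mean(axis=0) for p in cohort.patient_ids])
    return X, cohort.expression.values


def parameter_recovery(
    seeds=(1, 2, 3, 4, 5),
    n_train: int = 80,
    n_test: int = 40,
    patches_per_patient: int = 20,
    n_features: int = 32,
    n_genes: int = 20,
    noise_sd: float = 0.1,
) -> dict:
    """Train on synthetic cohorts and measure held-out correlation, per seed.

    For each seed a cohort of ``n_train + n_test`` patients is generated; the
    head trains on the first ``n_train`` and is evaluated on the rest, giving
    a median per-patient and median per-gene Spearman rho per seed.
    """
    per_patient, per_gene = [], []
    for seed in seeds:
        cohort = make_cohort(n_train + n_test, patches_per_patient, n_features,
                             n_genes, noise_sd, seed=seed)
        X, Y = _cohort_matrices(cohort)
        trained = train_on_matrix(X[:n_train], Y[:n_train],
                                  desk_scale_train_config(seed),
                                  HeadConfig(output_dim=n_genes))
        pred_vals = predict_matrix(trained, X[n_train:])
        ids = cohort.patient_ids[n_train:]
        pred = ExpressionMatrix(ids, cohort.expression.gene_symbols, pred_vals,
                                scale="log2p1")
        truth = ExpressionMatrix(ids, cohort.expression.gene_symbols, Y[n_train:],
                                 scale="log2p1")
        report = evaluate(pred, truth)
        per_patient.append(report.medians["per_patient"])
        per_gene.append(report.medians["per_gene"])
    return {
        "per_seed_median_rho_per_patient": per_patient,
        "per_seed_median_rho_per_gene": per_gene,
        "median_rho_per_patient": float(np.median(per_patient)),
        "median_rho_per_gene": float(np.median(per_gene)),
        "n_train": n_train,
        "n_test": n_test,
    }


def efficiency_comparison(
    base_seed: int = 101,
    n_seeds: int = 3,
    n_train: int = 64,
    n_test: int = 32,
    patches_per_patient: int = 20,
    n_features: int = 32,
    n_genes: int = 20,
    patch_max_epochs: int = 12,
) -> dict:
    """Aggregation trainer vs patch-based reference trainer on noiseless cohorts.

    Both use the same head and recipe; the patch route consumes every patch
    row per epoch (``patches_per_patient``-fold more records) and converges in
    far fewer epochs, so its epoch budget is capped at ``patch_max_epochs``.
    Median held-out per-patient rho is compared across ``n_seeds`` cohorts.
    """
    rho_agg, rho_patch, agg_samples, patch_samples = [], [], [], []
    for k in range(n_seeds):
        seed = base_seed + k
        cohort = make_cohort(n_train + n_test, patches_per_patient, n_features,
                             n_genes, noise_sd=0.0, seed=seed)
        X, Y = _cohort_matrices(cohort)
        ids = cohort.patient_ids
        test_ids = ids[n_train:]
        truth = ExpressionMatrix(test_ids, cohort.expression.gene_symbols,
                                 Y[n_train:], scale="log2p1")

        agg = train_on_matrix(X[:n_train], Y[:n_train],
                              desk_scale_train_config(seed),
                              HeadConfig(output_dim=n_genes))
        pred_a = ExpressionMatrix(test_ids, truth.gene_symbols,
                                  predict_matrix(agg, X[n_train:]), scale="log2p1")
        rho_agg.append(evaluate(pred_a, truth).medians["per_patient"])
        agg_samples.append(agg.samples_seen_per_epoch[0])

        tensors = [FeatureTensor(p, cohort.features[p], "synthetic") for p in ids]
        expr_train = ExpressionMatrix(ids[:n_train], truth.gene_symbols,
                                      Y[:n_train], scale="log2p1")
        patch = patch_based_reference_train(
            tensors[:n_train], expr_train,
            desk_scale_train_config(seed, max_epochs=patch_max_epochs),
            HeadConfig(output_dim=n_genes),
        )
        pred_vals = predict_per_patient_patchwise(patch, tensors, test_ids)
        pred_p = ExpressionMatrix(test_ids, truth.gene_symbols, pred_vals,
                                  scale="log2p1")
        rho_patch.append(evaluate(pred_p, truth).medians["per_patient"])
        patch_samples.append(patch.samples_seen_per_epoch[0])
    return {
        "median_rho_aggregation": float(np.median(rho_agg)),
        "median_rho_patch_based": float(np.median(rho_patch)),
        "rho_gap": float(abs(np.median(rho_agg) - np.median(rho_patch))),
        "samples_per_epoch_aggregation": int(agg_samples[0]),
        "samples_per_epoch_patch_based": int(patch_samples[0]),
        "samples_per_epoch_ratio": float(patch_samples[0] / agg_samples[0]),
    }


def hazard_recovery(
    base_seed: int = 1,
    n_seeds: int = 20,
    n_patients: int = 400,
    hazard_ratio: float = 2.0,
    baseline_rate: float = 0.01,
    censor_rate: float = 0.005,
    interval: tuple[float, float] = (1.4, 2.8),
) -> dict:
    """Univariate Cox recovery of the generating Luminal-B hazard ratio."""
    hrs, hits = [], 0
    lo, hi = interval
    for k in range(n_seeds):
        seed = base_seed + k
        rng = np.random.default_rng(seed + 5000)
        labels = np.where(rng.random(n_patients) < 0.5, "LumB", "LumA")
        clin = make_survival(labels, hazard_ratio_lumB=hazard_ratio,
                             baseline_rate=baseline_rate,
                             censor_rate=censor_rate, seed=seed)
        groups = dichotomise(clin)
        res = cox_fit(clin.assign(lumB=groups["lumB"]), ["lumB"], mode="univariate")
        hr = float(res["HR"].iloc[0])
        hrs.append(hr)
        hits += int(lo <= hr <= hi)
    return {
        "median_hr": float(np.median(hrs)),
        "fraction_within_interval": hits / n_seeds,
        "n_seeds": n_seeds,
        "n_patients": n_patients,
    }


def random_risk_concordance(base_seed: int = 0, n_reps: int = 200,
                            n_patients: int = 200) -> dict:
    """Mean concordance of random risk scores (should sit at 0.5)."""
    cs = []
    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + rep + 900)
        times = rng.exponential(10.0, n_patients)
        risk = rng.standard_normal(n_patients)
        cs.append(concordance_index(risk, times, np.ones(n_patients, dtype=int)))
    return {"mean_c_index": float(np.mean(cs)), "n_replicates": n_reps}
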