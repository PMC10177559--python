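"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end without any external data:

* :func:`make_stain_image` renders a two-stain Beer-Lambert image from known
  stain vectors and concentration maps, so stain estimation and normalization
  can be checked against the generating truth.
* :func:`make_cohort` draws per-patient patch-feature tensors whose means map
  linearly (plus optional Gaussian noise) to a log-scale expression matrix —
  the regression head's target is realisable by construction.
* :func:`make_survival` draws exponential proportional-hazards survival times
  with a Luminal-B hazard ratio and independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from ._errors import InvalidInputError
from .expression import ExpressionMatrix, GenePanel
from .stain import StainMatrix
from .tiling import RGBImage

__all__ = [
    "SUBTYPES",
    "SyntheticCohort",
    "make_stain_image",
    "hne_like_concentrations",
    "make_cohort",
    "make_survival",
    "write_cohort_features_h5",
    "write_clinical_tsv",
    "load_clinical_tsv",
]

SUBTYPES = ("LumA", "LumB", "Basal", "HER2")


@dataclass(frozen=True)
class SyntheticCohort:
    """A fully known-ground-truth cohort of patch features and expression targets.

    ``expression.values[p] == features[p].mean(axis=0) @ true_coefficients
    + true_intercept + noise`` where the noise has the stated standard
    deviation; the scalar intercept shifts all values to be nonnegative so the
    matrix is a valid log-scale expression table.
    """

    patient_ids: tuple[str, ...]
    features: dict[str, np.ndarray] = field(repr=False)  # id -> N x F
    true_coefficients: np.ndarray = field(repr=False)  # F x G
    true_intercept: float
    expression: ExpressionMatrix = field(repr=False)
    noise: np.ndarray = field(repr=False)  # patients x G, the realised noise
    noise_sd: float
    subtype_labels: tuple[str, ...]
    latents: np.ndarray = field(repr=False)  # patients x latent_rank
    panel: GenePanel
    seed: int

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def mean_features(self) -> np.ndarray:
        """Patients x F matrix of per-patient patch-feature means (the oracle input)."""
        return np.stack([self.features[p].mean(axis=0) for p in self.patient_ids])

    def oracle_predictions(self) -> ExpressionMatrix:
        """Noise-free predictions from the generating linear map (the oracle predictor)."""
        vals = self.mean_features() @ self.true_coefficients + self.true_intercept
        return ExpressionMatrix(self.patient_ids, self.expression.gene_symbols,
                                np.clip(vals, 0.0, None), scale="log2p1")


def make_stain_image(
    stain_matrix: StainMatrix,
    concentration_maps: np.ndarray,
    background: int = 245,
) -> RGBImage:
    """Render a Beer-Lambert two-stain image from known concentrations.

    Each pixel is ``background * exp(-S @ c)`` per channel, rounded to 8-bit,
    where ``S`` is the 3x2 stain basis and ``c`` the pixel's two nonnegative
    stain concentrations.
    """
    conc = np.asarray(concentration_maps, dtype=float)
    if conc.ndim != 3 or conc.shape[2] != 2:
        raise InvalidInputError(f"concentration maps must be HxWx2, got {conc.shape}")
    if not np.all(np.isfinite(conc)) or np.any(conc < 0):
        raise InvalidInputError("concentrations must be finite and nonnegative")
    if not 0 < background <= 255:
        raise InvalidInputError("background must be an 8-bit intensity in (0, 255]")
    od = conc @ stain_matrix.matrix.T  # H x W x 3, natural-log optical density
    pixels = np.clip(np.rint(background * np.exp(-od)), 0, 255).astype(np.uint8)
    return RGBImage(pixels, resolution_um_per_px=0.25)


def hne_like_concentrations(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Concentration maps mimicking H&E structure: nuclei, stroma and mixed pixels.

    About a third of pixels are hematoxylin-dominant (nuclei-like), a third
    eosin-dominant (stroma-like) and the rest mixed.  The presence of nearly
    pure pixels of each stain is what real tissue offers the extreme-angle
    stain estimator; fixtures without them make the estimation ill-posed.
    """
    h, w = shape
    c = rng.gamma(2.0, 0.25, size=(h, w, 2))
    kind = rng.random((h, w))
    nuclei = kind < 0.35
    stroma = (kind >= 0.35) & (kind < 0.7)
    c[nuclei, 1] *= 0.05
    c[nuclei, 0] += rng.gamma(3.0, 0.4, size=int(nuclei.sum()))
    c[stroma, 0] *= 0.05
    c[stroma, 1] += rng.gamma(3.0, 0.4, size=int(stroma.sum()))
    return c


def _subtype_from_latents(lat0: float, lat1: float) -> str:
    if lat0 > 0:
        return "LumA" if lat1 > 0 else "LumB"
    return "Basal" if lat1 > 0 else "HER2"


def make_cohort(
    n_patients: int,
    patches_per_patient: int,
    n_features: int,
    n_genes: int,
    noise_sd: float,
    seed: int,
    latent_rank: int = 5,
) -> SyntheticCohort:
    """Generate a cohort whose expression is a known linear map of mean features.

    Patch features are standard normal per entry plus a rank-``latent_rank``
    per-patient latent offset, so patients differ systematically (the
    across-patient correlation structure real slides show).  Subtype labels
    come from the signs of the first two latent dimensions, which makes a
    gene-based subtype classifier learnable by construction.
    """
    if min(n_patients, patches_per_patient, n_features, n_genes) < 1:
        raise InvalidInputError("all cohort dimensions must be >= 1")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    latent_rank = min(latent_rank, n_features)
    rng = np.random.default_rng(seed)
    patient_ids = tuple(f"P{i + 1:04d}" for i in range(n_patients))
    loadings = rng.standard_normal((latent_rank, n_features))  # latent -> feature space
    latents = rng.standard_normal((n_patients, latent_rank))
    coeffs = rng.standard_normal((n_features, n_genes)) / np.sqrt(n_features)
    features: dict[str, np.ndarray] = {}
    for i, pid in enumerate(patient_ids):
        base = rng.standard_normal((patches_per_patient, n_features))
        features[pid] = base + latents[i] @ loadings
    means = np.stack([features[p].mean(axis=0) for p in patient_ids])
    noise = (rng.standard_normal((n_patients, n_genes)) * noise_sd
             if noise_sd > 0 else np.zeros((n_patients, n_genes)))
    raw = means @ coeffs + noise
    intercept = float(np.ceil(max(0.0, -raw.min())))
    values = raw + intercept
    panel = GenePanel.synthetic(n_genes, n_pam50=min(50, n_genes))
    expr = ExpressionMatrix(patient_ids, panel.symbols, values, scale="log2p1")
    labels = tuple(_subtype_from_latents(latents[i, 0],
                                         latents[i, 1] if latent_rank > 1 else latents[i, 0])
                   for i in range(n_patients))
    return SyntheticCohort(
        patient_ids=patient_ids,
        features=features,
        true_coefficients=coeffs,
        true_intercept=intercept,
        expression=expr,
        noise=noise,
        noise_sd=noise_sd,
        subtype_labels=labels,
        latents=latents,
        panel=panel,
        seed=seed,
    )


def make_survival(
    subtype_labels,
    hazard_ratio_lumB: float = 2.0,
    baseline_rate: float = 0.01,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival times with independent censoring.

    Luminal-B patients have hazard ``baseline_rate * hazard_ratio_lumB``; all
    other subtypes have the baseline hazard (per month).  Censoring times are
    independent exponentials with rate ``censor_rate``; a rate of zero means
    no censoring (every event indicator is 1).  Clinical covariates (grade,
    size, age, nodal status) are drawn independently of survival, so they are
    null covariates by construction.
    """
    labels = tuple(str(s) for s in subtype_labels)
    bad = sorted(set(labels) - set(SUBTYPES))
    if bad:
        raise InvalidInputError(f"unknown subtype labels {bad}; expected one of {SUBTYPES}")
    if hazard_ratio_lumB <= 0:
        raise InvalidInputError("hazard_ratio_lumB must be positive")
    if baseline_rate <= 0:
        raise InvalidInputError("baseline_rate must be positive")
    if censor_rate < 0:
        raise InvalidInputError("censor_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(labels)
    hazard = np.where(np.asarray(labels) == "LumB",
                      baseline_rate * hazard_ratio_lumB, baseline_rate)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "followup_time": time,
            "event": event,
            "grade": rng.choice([1, 2, 3], size=n, p=[0.2, 0.45, 0.35]),
            "size_mm": np.round(rng.gamma(4.0, 6.0, size=n), 1),
            "age_years": np.round(rng.normal(58.0, 12.0, size=n), 1),
            "ln_status": rng.choice(["pos", "neg"], size=n, p=[0.4, 0.6]),
            "ihc_subtype": labels,
            "predicted_subtype": labels,
        }
    )


def write_cohort_features_h5(cohort: SyntheticCohort, path, backbone_id: str = "synthetic") -> None:
    """Write per-patient feature tensors to HDF5 (/patients/{id}/features)."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("patients")
        for pid in cohort.patient_ids:
            arr = cohort.features[pid].astype(np.float32)
            ds = grp.create_group(pid).create_dataset("features", data=arr)
            ds.attrs["backbone_id"] = backbone_id
            ds.attrs["F"] = arr.shape[1]


def write_clinical_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_clinical_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
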