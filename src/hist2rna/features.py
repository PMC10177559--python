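"""Patch-level feature extraction and slide-level aggregation.

A pluggable backbone maps 224x224 RGB patches to fixed-length feature vectors;
the slide-level representation is simply the mean of the patch vectors,

    z = (1/N) * sum_i x_i,

so each patient contributes one length-F vector regardless of patch count.
The mean is what makes downstream training O(patients) instead of O(patches).

The default registry ships a seeded "toy" backbone — a fixed random projection
of 16x16-downsampled grey pixels to 64 features — so the full pipeline runs
without pretrained weights or downloads.  The five standard pretrained
architectures (efficientnet, regnet, densenet, inception, resnet) are
registered as plug-in slots: calling them requires the user to attach a
feature function (e.g. wrapping a deep-learning framework's pooled embedding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import h5py
import numpy as np

from ._errors import ConfigurationError, InvalidInputError

__all__ = [
    "FeatureTensor",
    "AggregatedFeature",
    "register_backbone",
    "list_backbones",
    "toy_backbone_features",
    "extract_features",
    "aggregate",
    "save_features_h5",
    "load_features_h5",
]

TOY_BACKBONE_SEED = 20230430
TOY_GRID = 16
TOY_N_FEATURES = 64


@dataclass(frozen=True)
class FeatureTensor:
    """N patches x F features for one patient."""

    patient_id: str
    values: np.ndarray = field(repr=False)
    backbone_id: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise InvalidInputError(f"feature tensor must be N x F with N,F >= 1, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("feature values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AggregatedFeature:
    """The slide-level mean feature vector z for one patient."""

    patient_id: str
    values: np.ndarray = field(repr=False)
    n_patches_used: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1 or not np.all(np.isfinite(v)):
            raise InvalidInputError("aggregated feature must be a finite non-empty vector")
        object.__setattr__(self, "values", v)


_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray] | None] = {}


def register_backbone(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register (or replace) a backbone: a function (N,224,224,3) uint8 -> (N,F)."""
    _REGISTRY[name] = fn


def list_backbones() -> list[str]:
    return sorted(_REGISTRY)


def _toy_projection_matrix() -> np.ndarray:
    rng = np.random.default_rng(TOY_BACKBONE_SEED)
    return rng.standard_normal((TOY_GRID * TOY_GRID, TOY_N_FEATURES)) / np.sqrt(TOY_GRID * TOY_GRID)


def toy_backbone_features(patches: np.ndarray) -> np.ndarray:
    """Closed-form toy backbone: grey 16x16 block means, scaled to [0,1], then
    a fixed seeded Gaussian projection to 64 features."""
    patches = np.asarray(patches, dtype=float)
    n, h, w, _ = patches.shape
    grey = patches.mean(axis=3) / 255.0  # N x H x W
    bh, bw = h // TOY_GRID, w // TOY_GRID
    ds = grey[:, : bh * TOY_GRID, : bw * TOY_GRID]
    ds = ds.reshape(n, TOY_GRID, bh, TOY_GRID, bw).mean(axis=(2, 4))  # N x 16 x 16
    return ds.reshape(n, -1) @ _toy_projection_matrix()


register_backbone("toy", toy_backbone_features)
for _name in ("efficientnet", "regnet", "densenet", "inception", "resnet"):
    _REGISTRY.setdefault(_name, None)  # plug-in slot: needs user-attached weights


def extract_features(patches, backbone: str = "toy") -> FeatureTensor:
    """Run the named backbone over a PatchSet (or (N,224,224,3) array).

    One feature row per patch, in patch order; deterministic for a fixed
    backbone (the toy backbone is a fixed seeded linear projection).
    """
    if backbone not in _REGISTRY:
        raise ConfigurationError(
            f"unknown backbone {backbone!r}; registered: {list_backbones()}"
        )
    fn = _REGISTRY[backbone]
    if fn is None:
        raise ConfigurationError(
            f"backbone {backbone!r} is a plug-in slot with no feature function attached; "
            f"use register_backbone({backbone!r}, fn) or the 'toy' backbone"
        )
    patient_id = getattr(patches, "patient_id", "sample")
    arr = patches.as_array() if hasattr(patches, "as_array") else np.asarray(patches)
    if arr.ndim != 4 or arr.shape[1:3] != (224, 224) or arr.shape[3] != 3:
        raise InvalidInputError(f"expected (N, 224, 224, 3) patches, got {arr.shape}")
    if arr.shape[0] == 0:
        raise InvalidInputError("no patches to extract features from")
    return FeatureTensor(patient_id, fn(arr), backbone_id=backbone)


def aggregate(features: FeatureTensor) -> AggregatedFeature:
    """Mean over patches: z[j] = (1/N) sum_i values[i, j]."""
    return AggregatedFeature(
        patient_id=features.patient_id,
        values=features.values.mean(axis=0),
        n_patches_used=features.n_patches,
    )


def save_features_h5(tensors, path) -> None:
    """Persist FeatureTensors to HDF5 at /patients/{id}/features (32-bit)."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("patients")
        for t in tensors:
            ds = grp.create_group(t.patient_id).create_dataset(
                "features", data=t.values.astype(np.float32)
            )
            ds.attrs["backbone_id"] = t.backbone_id
            ds.attrs["F"] = t.n_features


def load_features_h5(path) -> list[FeatureTensor]:
    out = []
    with h5py.File(path, "r") as fh:
        for pid in fh["patients"]:
            ds = fh[f"patients/{pid}/features"]
            out.append(FeatureTensor(pid, ds[()], backbone_id=ds.attrs.get("backbone_id", "unknown")))
    return out
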