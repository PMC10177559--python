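"""Macenko-style stain estimation and colour normalization for H&E patches.

Stained tissue attenuates light multiplicatively, so stain mixing is linear in
optical-density (OD) space: ``OD = -log10(I / I0)`` with ``I0`` the background
(glass) intensity.  A two-stain H&E image therefore produces an OD point cloud
lying (up to noise) in the cone spanned by the two unit stain vectors.  The
Macenko procedure recovers those vectors from the extreme angular percentiles
of the cloud projected onto its top-2 singular plane, and normalization maps
per-stain concentrations onto a common reference basis and scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import EstimationError, InvalidInputError

__all__ = [
    "StainMatrix",
    "DEFAULT_TARGET_STAIN_MATRIX",
    "REFERENCE_MAX_CONCENTRATION",
    "to_optical_density",
    "od_to_rgb",
    "estimate_stain_matrix",
    "stain_concentrations",
    "normalise",
]

#: Reference 99th-percentile concentrations (hematoxylin, eosin) used when
#: rescaling source concentrations onto the target basis.
REFERENCE_MAX_CONCENTRATION = (1.9705, 1.0308)

_MIN_TISSUE_PIXELS = 100
_MIN_COLUMN_ANGLE_DEG = 1.0


@dataclass(frozen=True)
class StainMatrix:
    """A 3x2 unit optical-density basis: column 0 hematoxylin-like, column 1 eosin-like.

    Columns are unit-norm with nonnegative entries and must not be collinear
    (pairwise angle greater than 1 degree).  The hematoxylin-like column is,
    by convention, the one with the larger blue-channel OD.
    """

    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 2):
            raise InvalidInputError(f"stain matrix must be 3x2, got {m.shape}")
        if not np.all(np.isfinite(m)) or np.any(m < -1e-9):
            raise InvalidInputError("stain matrix entries must be finite and nonnegative")
        m = np.clip(m, 0.0, None)
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms <= 0):
            raise InvalidInputError("stain matrix columns must be nonzero")
        m = m / norms
        cosang = float(np.clip(m[:, 0] @ m[:, 1], -1.0, 1.0))
        angle = np.degrees(np.arccos(cosang))
        if angle <= _MIN_COLUMN_ANGLE_DEG:
            raise InvalidInputError(
                f"stain columns are collinear (angle {angle:.3f} deg <= {_MIN_COLUMN_ANGLE_DEG})"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.matrix[:, 1]

    def column_angle_deg(self) -> float:
        cosang = float(np.clip(self.matrix[:, 0] @ self.matrix[:, 1], -1.0, 1.0))
        return float(np.degrees(np.arccos(cosang)))

    @classmethod
    def from_columns(cls, hematoxylin, eosin) -> "StainMatrix":
        return cls(np.column_stack([hematoxylin, eosin]))


#: The package's default reference basis (classic H&E OD vectors).
DEFAULT_TARGET_STAIN_MATRIX = StainMatrix.from_columns(
    hematoxylin=(0.65, 0.70, 0.29), eosin=(0.07, 0.99, 0.11)
)


def to_optical_density(pixels: np.ndarray, background: float = 255.0) -> np.ndarray:
    """Convert 8-bit intensities to optical density ``-log10(I / background)``.

    Zero intensities are clamped to 1 before the log so the result is finite;
    intensities above the background are clamped to the background so the OD
    is nonnegative.
    """
    if background <= 0:
        raise InvalidInputError("background intensity must be positive")
    i = np.asarray(pixels, dtype=float)
    i = np.clip(i, 1.0, background)
    return -np.log10(i / background)


def od_to_rgb(od: np.ndarray, background: float = 255.0) -> np.ndarray:
    """Inverse of :func:`to_optical_density`, rounded to 8-bit."""
    i = background * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(i), 0, 255).astype(np.uint8)


def _tissue_od(pixels: np.ndarray, background: float, od_threshold: float) -> np.ndarray:
    od = to_optical_density(pixels, background).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) > od_threshold
    return od[keep]


def estimate_stain_matrix(
    pixels: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    background: float = 255.0,
) -> StainMatrix:
    """Estimate the two stain vectors of an H&E image (Macenko procedure).

    Steps: convert to OD, drop near-background pixels (OD magnitude below
    ``od_threshold``), project the cloud onto its top-2 singular plane, and
    take the directions at the ``angle_percentile`` and
    ``100 - angle_percentile`` percentiles of the projected angle as the two
    stain vectors.  Columns are ordered hematoxylin-first (larger blue OD).

    Raises
    ------
    EstimationError
        If fewer than 100 tissue pixels are available, or the OD cloud is
        effectively one-dimensional (single stain).
    """
    od = _tissue_od(np.asarray(pixels), background, od_threshold)
    if od.shape[0] < _MIN_TISSUE_PIXELS:
        raise EstimationError(
            f"only {od.shape[0]} tissue pixels above OD {od_threshold}; "
            f"need at least {_MIN_TISSUE_PIXELS}"
        )
    # Top-2 right singular directions of the (uncentered) OD cloud.
    _, s, vt = np.linalg.svd(od, full_matrices=False)
    if s[1] <= 1e-8 * s[0]:
        raise EstimationError("OD cloud is rank-1 (single stain); cannot form a 2-stain basis")
    plane = vt[:2].T  # 3x2
    # Orient plane axes so projections are mostly positive.
    for j in range(2):
        if np.sum(od @ plane[:, j]) < 0:
            plane[:, j] = -plane[:, j]
    proj = od @ plane  # n x 2
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v_lo = plane @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = plane @ np.array([np.cos(hi), np.sin(hi)])
    cols = []
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        nrm = np.linalg.norm(v)
        if nrm <= 0:
            raise EstimationError("degenerate stain direction estimated")
        cols.append(v / nrm)
    a, b = cols
    cosang = float(np.clip(a @ b, -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) <= _MIN_COLUMN_ANGLE_DEG:
        raise EstimationError("estimated stain columns are collinear (single stain?)")
    # Hematoxylin convention: larger blue-channel OD first.
    if a[2] >= b[2]:
        return StainMatrix.from_columns(a, b)
    return StainMatrix.from_columns(b, a)


def stain_concentrations(
    pixels: np.ndarray, stains: StainMatrix, background: float = 255.0
) -> np.ndarray:
    """Per-pixel nonnegative stain concentrations (H, E) via least squares in OD space."""
    od = to_optical_density(np.asarray(pixels), background).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(stains.matrix, od.T, rcond=None)
    return np.clip(conc.T, 0.0, None)  # n x 2


def normalise(
    pixels: np.ndarray,
    target: StainMatrix = DEFAULT_TARGET_STAIN_MATRIX,
    concentration_percentile: float = 99.0,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    background: float = 255.0,
    source: StainMatrix | None = None,
) -> np.ndarray:
    """Map an image onto the target stain basis at the reference concentration scale.

    The source basis is estimated from the image unless supplied.  Per-stain
    concentrations are rescaled so that their ``concentration_percentile``
    matches :data:`REFERENCE_MAX_CONCENTRATION`, then re-rendered through the
    target basis.  Images with too few tissue pixels for estimation (e.g. pure
    background) are returned unchanged (pass-through).
    """
    arr = np.asarray(pixels)
    if source is None:
        try:
            source = estimate_stain_matrix(
                arr, od_threshold=od_threshold, angle_percentile=angle_percentile,
                background=background,
            )
        except EstimationError:
            return arr.astype(np.uint8, copy=True)  # nothing to normalize
    conc = stain_concentrations(arr, source, background)
    ref = np.asarray(REFERENCE_MAX_CONCENTRATION)
    scale = np.ones(2)
    for j in range(2):
        pj = np.percentile(conc[:, j], concentration_percentile)
        if pj > 1e-8:
            scale[j] = ref[j] / pj
    od_new = (conc * scale) @ target.matrix.T
    return od_to_rgb(od_new, background).reshape(arr.shape)
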