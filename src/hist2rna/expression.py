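"""Gene-expression targets: loading, log transformation and panel selection.

Expression arrives as RSEM-style normalised counts (patients x genes).  Counts
are shifted by one and log-transformed — log2(1 + x) — before regression so the
model is not dominated by the most strongly expressed genes; a gene panel
(default length 138, with a PAM50 subset flagged) restricts and orders the
target columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import FormatError, InvalidInputError, StateError

__all__ = [
    "ExpressionMatrix",
    "GenePanel",
    "log_transform",
    "inverse_log_transform",
    "select_panel",
    "load_expression_tsv",
    "write_expression_tsv",
    "load_panel_tsv",
    "write_panel_tsv",
]

_PATIENT_TOKENS = {"patient_id", "patient", "sample", "sample_id"}
_GENE_TOKENS = {"gene_symbol", "gene", "symbol", "hugo_symbol"}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Patients x genes expression values with an explicit scale flag."""

    patient_ids: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    scale: str = "raw"  # "raw" | "log2p1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        object.__setattr__(self, "gene_symbols", tuple(str(g) for g in self.gene_symbols))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.patient_ids), len(self.gene_symbols)):
            raise InvalidInputError(
                f"values shape {v.shape} inconsistent with "
                f"{len(self.patient_ids)} patients x {len(self.gene_symbols)} genes"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise InvalidInputError("gene symbols must be unique")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise InvalidInputError("patient ids must be unique")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("expression values must be finite")
        if self.scale not in ("raw", "log2p1"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and np.any(v < 0):
            raise InvalidInputError("raw expression values must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.patient_ids),
                            columns=list(self.gene_symbols))


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene list with a PAM50 membership flag per symbol."""

    symbols: tuple[str, ...]
    pam50_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))
        object.__setattr__(self, "pam50_flags", tuple(bool(f) for f in self.pam50_flags))
        if len(self.symbols) != len(self.pam50_flags):
            raise InvalidInputError("symbols and pam50_flags must have equal length")
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidInputError("panel symbols must be unique")
        if not self.symbols:
            raise InvalidInputError("panel must contain at least one symbol")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def pam50_symbols(self) -> tuple[str, ...]:
        return tuple(s for s, f in zip(self.symbols, self.pam50_flags) if f)

    @classmethod
    def synthetic(cls, n_genes: int = 138, n_pam50: int = 50) -> "GenePanel":
        """Placeholder panel G001..Gnnn with the first ``n_pam50`` flagged as PAM50."""
        symbols = tuple(f"G{i + 1:03d}" for i in range(n_genes))
        flags = tuple(i < min(n_pam50, n_genes) for i in range(n_genes))
        return cls(symbols, flags)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(1 + x); raw-scale input only (no double transform)."""
    if matrix.scale != "raw":
        raise StateError(f"matrix is already on scale {matrix.scale!r}")
    return replace(matrix, values=np.log2(1.0 + matrix.values), scale="log2p1")


def inverse_log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Recover raw counts from a log2(1 + x) matrix."""
    if matrix.scale != "log2p1":
        raise StateError(f"matrix scale is {matrix.scale!r}, expected 'log2p1'")
    raw = np.clip(np.exp2(matrix.values) - 1.0, 0.0, None)
    return replace(matrix, values=raw, scale="raw")


def select_panel(matrix: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Restrict and re-order columns to the panel's gene order.

    Case mismatches are resolved only when unambiguous; missing symbols raise
    an error listing them.
    """
    lookup = {g: i for i, g in enumerate(matrix.gene_symbols)}
    lower: dict[str, int | None] = {}
    for i, g in enumerate(matrix.gene_symbols):
        key = g.lower()
        lower[key] = None if key in lower else i  # None marks ambiguity
    idx, missing = [], []
    for sym in panel.symbols:
        if sym in lookup:
            idx.append(lookup[sym])
        elif lower.get(sym.lower()) is not None:
            idx.append(lower[sym.lower()])
        else:
            missing.append(sym)
    if missing:
        raise InvalidInputError(f"panel symbols missing from matrix: {missing}")
    return replace(
        matrix,
        gene_symbols=tuple(panel.symbols),
        values=matrix.values[:, idx],
    )


def write_expression_tsv(matrix: ExpressionMatrix, path, orientation: str = "patients") -> None:
    """Write as TSV; ``orientation`` 'patients' puts patients in rows, 'genes' transposes."""
    df = matrix.to_frame()
    if orientation == "patients":
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t", float_format="%.6g")
    elif orientation == "genes":
        dft = df.T
        dft.index.name = "gene_symbol"
        dft.to_csv(path, sep="\t", float_format="%.6g")
    else:
        raise InvalidInputError(f"unknown orientation {orientation!r}")


def load_expression_tsv(path, scale: str = "raw") -> ExpressionMatrix:
    """Read a TSV expression table, auto-detecting orientation from the header token.

    The first header cell names the row axis ('patient_id'-like tokens mean
    patients in rows, 'gene_symbol'-like tokens mean genes in rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    token = (df.index.name or "").strip().lower()
    if token in _GENE_TOKENS:
        df = df.T
    elif token not in _PATIENT_TOKENS:
        raise FormatError(
            f"cannot detect orientation: header token {token!r} not in "
            f"{sorted(_PATIENT_TOKENS | _GENE_TOKENS)}"
        )
    dupes = df.columns[df.columns.duplicated()].tolist()
    if dupes:
        raise FormatError(f"duplicate gene symbols: {sorted(set(dupes))}")
    dup_pat = df.index[df.index.duplicated()].tolist()
    if dup_pat:
        raise FormatError(f"duplicate patient ids: {sorted(set(dup_pat))}")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise FormatError("non-numeric or missing expression values")
    return ExpressionMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
                            values, scale=scale)


def write_panel_tsv(panel: GenePanel, path) -> None:
    pd.DataFrame({"symbol": panel.symbols, "pam50": [int(f) for f in panel.pam50_flags]}).to_csv(
        path, sep="\t", index=False
    )


def load_panel_tsv(path) -> GenePanel:
    df = pd.read_csv(path, sep="\t")
    if "symbol" not in df.columns or "pam50" not in df.columns:
        raise FormatError("panel TSV requires columns 'symbol' and 'pam50'")
    return GenePanel(tuple(df["symbol"].astype(str)), tuple(df["pam50"].astype(bool)))
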