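"""Reading, encoding and normalizing per-data-type omics matrices.

Each data type is a patients x genes matrix: point mutations as binary
presence/absence (derivable from a MAF file), copy-number alterations as
log2 tumor/normal ratios, promoter methylation as beta-values in [0, 1],
and expression as z-scores.  Before kernel construction every matrix is
clipped (CNA and expression only, at +/-10) and min-max scaled to [0, 1]
so all data types share a common range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DATA_TYPES = ("mutation", "cna", "methylation", "expression")

#: data types whose raw values are clipped before normalization
CLIPPED_TYPES = frozenset({"cna", "expression"})

DEFAULT_CLIP_BOUND = 10.0


class OmicsValidationError(ValueError):
    """Raised when an input matrix violates a structural precondition."""


class OmicsParseError(ValueError):
    """Raised when a file cannot be parsed as an omics matrix."""


@dataclass(frozen=True)
class OmicsMatrix:
    """One data type's patients x genes value matrix.

    Parameters
    ----------
    sample_ids : ordered patient identifiers (rows).
    feature_ids : ordered gene identifiers (columns).
    values : float array of shape (N, M), no missing entries.
    data_type : one of ``mutation``, ``cna``, ``methylation``, ``expression``.
    normalized : whether the matrix has been min-max scaled to [0, 1].
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    data_type: str
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if self.data_type not in DATA_TYPES:
            raise OmicsValidationError(
                f"unknown data_type {self.data_type!r}; expected one of {DATA_TYPES}"
            )
        if values.ndim != 2:
            raise OmicsValidationError("values must be a 2-D matrix")
        n, m = values.shape
        if n != len(self.sample_ids) or m != len(self.feature_ids):
            raise OmicsValidationError(
                f"shape {values.shape} does not match {len(self.sample_ids)} samples "
                f"x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(values)):
            raise OmicsValidationError("matrix contains non-finite entries after ingestion")
        if self.normalized and values.size and (values.min() < 0 or values.max() > 1):
            raise OmicsValidationError("normalized matrix has entries outside [0, 1]")
        if self.data_type == "mutation" and values.size:
            if not np.all((values == 0) | (values == 1)):
                raise OmicsValidationError("mutation matrix entries must be exactly 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


@dataclass(frozen=True)
class MultiOmicsDataset:
    """Normalized matrices for D data types sharing one ordered patient list."""

    matrices: tuple[OmicsMatrix, ...]
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        matrices = tuple(self.matrices)
        object.__setattr__(self, "matrices", matrices)
        if not matrices:
            raise OmicsValidationError("dataset needs at least one matrix")
        shared = matrices[0].sample_ids
        object.__setattr__(self, "sample_ids", shared)
        for m in matrices:
            if m.sample_ids != shared:
                raise OmicsValidationError("member matrices disagree on sample order")
            if not m.normalized:
                raise OmicsValidationError(
                    f"{m.data_type} matrix is not normalized; call normalize_01 first"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def data_types(self) -> tuple[str, ...]:
        return tuple(m.data_type for m in self.matrices)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise OmicsValidationError(f"duplicate {what} id {x!r}")
        seen.add(x)


def read_matrix(
    path: str | Path,
    data_type: str,
    orientation: str = "samples-in-rows",
) -> OmicsMatrix:
    """Read a TSV matrix (one header row, first column = row ids).

    ``orientation="genes-in-rows"`` transposes so the result is always
    samples-in-rows.  Missing entries are imputed with the matrix median
    (logged); non-numeric cells raise :class:`OmicsParseError` naming the
    offending row and column.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise OmicsValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise OmicsParseError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        ) from None
    if orientation == "genes-in-rows":
        numeric = numeric.T
    values = numeric.to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        med = float(np.nanmedian(values))
        values = np.where(np.isnan(values), med, values)
        logger.warning("imputed %d missing entries with median %.4g in %s", n_missing, med, path)
    return OmicsMatrix(
        sample_ids=tuple(str(s) for s in numeric.index),
        feature_ids=tuple(str(f) for f in numeric.columns),
        values=values,
        data_type=data_type,
        normalized=False,
    )


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write back to the same TSV dialect ``read_matrix`` consumes."""
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode")


def read_maf(
    path: str | Path,
    sample_universe: Sequence[str],
    gene_universe: Sequence[str] | None = None,
) -> OmicsMatrix:
    """Collapse a MAF file to a binary patient x gene mutation matrix.

    Entry (patient, gene) is 1 iff the MAF holds at least one somatic
    variant record for the pair; duplicate records collapse to a single 1.
    Patients in ``sample_universe`` without any record get all-zero rows;
    records for patients outside the universe are ignored with a warning.
    """
    universe = tuple(str(s) for s in sample_universe)
    _check_unique(universe, "sample")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise OmicsParseError(f"MAF file {path} lacks required columns {missing}")
    known = df["Tumor_Sample_Barcode"].isin(universe)
    n_outside = int((~known).sum())
    if n_outside:
        warnings.warn(
            f"{n_outside} MAF records for patients outside the sample universe were ignored",
            stacklevel=2,
        )
        df = df[known]
    if gene_universe is None:
        genes = tuple(sorted(df["Hugo_Symbol"].unique()))
    else:
        genes = tuple(gene_universe)
    _check_unique(genes, "feature")
    values = np.zeros((len(universe), len(genes)), dtype=float)
    sample_idx = {s: i for i, s in enumerate(universe)}
    gene_idx = {g: j for j, g in enumerate(genes)}
    for gene, barcode in zip(df["Hugo_Symbol"], df["Tumor_Sample_Barcode"]):
        j = gene_idx.get(gene)
        if j is not None:
            values[sample_idx[barcode], j] = 1.0
    return OmicsMatrix(universe, genes, values, data_type="mutation", normalized=False)


def clip_extremes(m: OmicsMatrix, bound: float = DEFAULT_CLIP_BOUND) -> OmicsMatrix:
    """Clamp CNA log2 ratios and expression z-scores to [-bound, +bound].

    A no-op (beyond validation) for mutation and methylation matrices,
    whose natural ranges are already bounded.
    """
    if bound <= 0:
        raise OmicsValidationError(f"clip bound must be positive, got {bound}")
    if m.data_type not in CLIPPED_TYPES:
        return m
    return replace(m, values=np.clip(m.values, -bound, bound))


def normalize_01(m: OmicsMatrix) -> OmicsMatrix:
    """Global per-matrix min-max scaling to [0, 1].

    The transform is (v - min) / (max - min) over the whole matrix, so
    matrices already spanning [0, 1] (binary mutations, beta-values with
    observed min 0 and max 1) are returned unchanged in value.  A constant
    matrix maps to all zeros with a warning.
    """
    if m.normalized:
        return m
    lo, hi = float(m.values.min()), float(m.values.max())
    if hi == lo:
        warnings.warn(
            f"constant {m.data_type} matrix (all entries {lo}); normalized to all zeros",
            stacklevel=2,
        )
        values = np.zeros_like(m.values)
    else:
        values = (m.values - lo) / (hi - lo)
    return replace(m, values=values, normalized=True)


def preprocess(m: OmicsMatrix, bound: float = DEFAULT_CLIP_BOUND) -> OmicsMatrix:
    """Clip (where applicable) then min-max normalize one matrix."""
    return normalize_01(clip_extremes(m, bound=bound))


def align_samples(matrices: Sequence[OmicsMatrix]) -> MultiOmicsDataset:
    """Restrict matrices to their shared patients, in lexicographic order.

    Patients missing from any data type are dropped (counts logged per
    matrix); an empty intersection is an error.
    """
    if not matrices:
        raise OmicsValidationError("need at least one matrix to align")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if not shared:
        raise OmicsValidationError("no patients shared across all data types")
    order = tuple(sorted(shared))
    aligned = []
    for m in matrices:
        dropped = m.n_samples - len(order)
        if dropped:
            logger.info("align_samples: dropped %d patients from %s matrix", dropped, m.data_type)
        idx = [m.sample_ids.index(s) for s in order]
        aligned.append(replace(m, sample_ids=order, values=m.values[idx]))
    return MultiOmicsDataset(matrices=tuple(aligned))
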