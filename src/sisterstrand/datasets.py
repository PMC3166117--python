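"""Expression-matrix ingestion, sample matching and dataset-level expression calls.

Expression matrices are feature-by-sample tables of non-negative microarray
intensities. The internal canonical scale is *linear*: files encoded as log2
intensities are exponentiated on load, so that downstream log2(5'/3') ratios
are always taken between raw intensity values.

The dataset-level "expressed" call follows the median rule: a feature is
expressed in a sample iff its intensity is strictly greater than the median of
the whole matrix it belongs to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_SCALES = ("linear", "log2")

METADATA_COLUMNS = ("sample_id", "dataset_id", "tissue", "condition")


@dataclass
class ExpressionMatrix:
    """A validated feature-by-sample intensity matrix (linear scale).

    Parameters
    ----------
    data:
        DataFrame with feature ids as index, sample ids as columns and
        finite, non-negative linear-scale intensities as values.
    scale_tag:
        Encoding of the *source* file this matrix was loaded from
        (``"linear"`` or ``"log2"``). Stored values are always linear.
    """

    data: pd.DataFrame
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        if self.scale_tag not in VALID_SCALES:
            raise ValueError(f"scale_tag must be one of {VALID_SCALES}, got {self.scale_tag!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicated feature ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicated sample ids: {dups}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if vals.size and (vals < 0).any():
            raise ValueError("expression matrix contains negative values (linear scale required)")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.scale_tag)

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write the matrix (linear values) as a TSV with a ``feature_id`` header."""
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_matrix(path: Union[str, Path], scale_tag: str = "linear") -> ExpressionMatrix:
    """Load an expression TSV (header of sample ids, first column feature ids).

    ``scale_tag="log2"`` files are converted to linear scale (``2**x``) on load.
    Duplicate identifiers or non-numeric cells raise ``ValueError``.
    """
    if scale_tag not in VALID_SCALES:
        raise ValueError(f"scale_tag must be one of {VALID_SCALES}, got {scale_tag!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    data = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell in {path}: row {row!r}, column {col!r} "
                f"(value {raw.loc[row, col]!r})"
            )
        if converted.isna().any():
            row = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"missing cell in {path}: row {row!r}, column {col!r}")
        data[col] = converted
    if scale_tag == "log2":
        data = np.exp2(data)
    return ExpressionMatrix(data, scale_tag)


def read_sample_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Load the sample-metadata TSV (sample_id, dataset_id, tissue, condition)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
        raise ValueError(f"duplicated sample_id in metadata: {dups}")
    return meta


def check_metadata_coverage(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> None:
    """Every sample of the matrix must have exactly one metadata record."""
    known = set(metadata["sample_id"])
    orphans = [s for s in matrix.sample_ids if s not in known]
    if orphans:
        raise ValueError(f"samples without metadata record: {orphans}")


def match_samples(
    mirna: ExpressionMatrix, genes: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared samples, in miRNA-matrix order.

    Integrated miRNA/gene analyses require profiles measured in exactly the
    same samples; samples present in only one matrix are dropped (and logged).
    An empty intersection is an error.
    """
    gene_set = set(genes.sample_ids)
    shared = [s for s in mirna.sample_ids if s in gene_set]
    if not shared:
        raise ValueError("no shared samples between miRNA and gene matrices")
    dropped = sorted(set(mirna.sample_ids).symmetric_difference(gene_set))
    if dropped:
        log.warning("match_samples: dropping %d unmatched samples: %s", len(dropped), dropped)
    return mirna.subset_samples(shared), genes.subset_samples(shared)


def expression_threshold(matrix: ExpressionMatrix) -> float:
    """Dataset-level expression cutoff: the median over all matrix entries.

    For an even entry count this is the mean of the two central order
    statistics.
    """
    vals = matrix.values
    if vals.size == 0:
        raise ValueError("cannot take the median of an empty matrix")
    return float(np.median(vals))


def call_expressed(matrix: ExpressionMatrix, threshold: float) -> pd.DataFrame:
    """Boolean calls: TRUE iff the intensity is strictly greater than the cutoff.

    Ties at the threshold are *not* expressed (the call is "higher than the
    median", strictly).
    """
    return matrix.data.gt(float(threshold))
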