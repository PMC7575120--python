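"""Expression matrices and sample metadata: containers, TSV I/O, and unit handling.

The central container is :class:`ExpressionMatrix`, a validated gene x sample
table of non-negative abundances in either TPM (transcripts per million) or
raw-count units.  All on-disk exchange uses a fixed tab-separated dialect:
UTF-8, first header cell ``gene_id``, sample identifiers in the header row,
one gene per row, decimal point, no thousands separators.  Writers mirror
readers so that a write/read round trip is bit-exact for representable values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TPM_TOTAL = 1_000_000.0

#: allowed values of the ``cell_type_class`` metadata column
CELL_TYPE_CLASSES = ("mononuclear", "DC")

ANNOTATION_COLUMNS = ("sample_id", "tissue", "cell_type_class",
                      "cell_type_label", "bioproject")


class MatrixError(ValueError):
    """Raised for malformed expression matrices or metadata tables."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise MatrixError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with unit bookkeeping.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Values must be finite and non-negative; absence is
        encoded as 0, never as NaN.
    unit
        ``"TPM"`` or ``"counts"``.
    """

    data: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "counts"):
            raise MatrixError(f"unknown unit {self.unit!r}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise MatrixError("expression values must be finite (no NaN/inf)")
        if values.size and (values < 0).any():
            gene = self.data.index[np.where(values < 0)[0][0]]
            raise MatrixError(f"negative expression value in gene {gene!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise MatrixError(f"gene not present in matrix: {missing[0]!r}")
        return ExpressionMatrix(self.data.loc[genes], unit=self.unit)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise MatrixError(f"sample not present in matrix: {missing[0]!r}")
        return ExpressionMatrix(self.data[samples], unit=self.unit)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: tissue, cell-type class/label and BioProject batch.

    ``cell_type_class`` is the coarse monocyte/macrophage-vs-DC dichotomy used
    by the marker screen; ``cell_type_label`` is free text (e.g. "microglia",
    "cDC1"); ``bioproject`` identifies the originating study/batch.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise MatrixError(f"annotation missing column(s): {missing}")
        _check_unique(self.table["sample_id"], "sample")
        bad = set(self.table["cell_type_class"]) - set(CELL_TYPE_CLASSES)
        if bad:
            raise MatrixError(
                f"cell_type_class must be one of {CELL_TYPE_CLASSES}, got {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_where(self, column: str, value: str) -> list[str]:
        if column not in self.table.columns:
            raise MatrixError(f"unknown annotation column {column!r}")
        mask = self.table[column] == value
        return list(self.table.loc[mask, "sample_id"])

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must be annotated exactly once."""
        known = set(self.sample_ids)
        missing = [s for s in matrix.sample_ids if s not in known]
        if missing:
            raise MatrixError(f"sample {missing[0]!r} has no annotation row")


# -- TSV I/O -------------------------------------------------------------------

def read_tpm_table(path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a gene x sample expression table from the TSV dialect.

    First column holds gene identifiers (header cell ``gene_id``), remaining
    header cells are sample identifiers.  Duplicate identifiers, negative
    values and ragged rows raise :class:`MatrixError`; pandas reports the
    offending line number for ragged input.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows: keep the line number
        raise MatrixError(f"malformed matrix file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    matrix = ExpressionMatrix(df.astype(float), unit=unit)
    logger.info("read %d genes x %d samples from %s",
                matrix.n_genes, matrix.n_samples, path)
    return matrix


def write_tpm_table(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the TSV dialect (mirror of :func:`read_tpm_table`)."""
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# -- replicate aggregation and unit conversion ---------------------------------

def aggregate_replicates(draws: Sequence[ExpressionMatrix],
                         method: str = "median") -> ExpressionMatrix:
    """Aggregate replicate draws cell-wise (default: median).

    All draws must share identical gene and sample axes; with an even number
    of draws the median is the mean of the two central order statistics.
    """
    if not draws:
        raise MatrixError("no draws to aggregate")
    if method not in ("median", "mean"):
        raise MatrixError(f"unknown aggregation method {method!r}")
    first = draws[0]
    for i, d in enumerate(draws[1:], start=1):
        if d.gene_ids != first.gene_ids:
            diff = next(
                (a, b) for a, b in zip(d.gene_ids, first.gene_ids) if a != b)
            raise MatrixError(
                f"draw {i} gene axis differs from draw 0 (first mismatch: "
                f"{diff[0]!r} vs {diff[1]!r})")
        if d.sample_ids != first.sample_ids:
            raise MatrixError(f"draw {i} sample axis differs from draw 0")
        if d.unit != first.unit:
            raise MatrixError(f"draw {i} unit differs from draw 0")
    stack = np.stack([d.values for d in draws])
    agg = np.median(stack, axis=0) if method == "median" else stack.mean(axis=0)
    return ExpressionMatrix(
        pd.DataFrame(agg, index=first.data.index, columns=first.data.columns),
        unit=first.unit)


def counts_to_tpm(counts: ExpressionMatrix,
                  lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Convert raw counts to TPM given effective transcript lengths (nt).

    TPM_g = 1e6 * (count_g / length_g) / sum_g'(count_g' / length_g') per
    column, so every column with any signal sums to exactly 1e6.  Columns
    with no reads at all stay zero and are logged.  Only relative lengths
    matter; uniform rescaling of all lengths leaves the result unchanged.
    """
    if counts.unit != "counts":
        raise MatrixError("counts_to_tpm expects a matrix in count units")
    lens = pd.Series({g: float(lengths[g]) for g in counts.gene_ids if g in lengths})
    missing = [g for g in counts.gene_ids if g not in lens.index]
    if missing:
        raise MatrixError(f"no length for gene {missing[0]!r}")
    vals = counts.values
    larr = lens.loc[counts.gene_ids].to_numpy()
    nonzero_rows = vals.sum(axis=1) > 0
    if (larr[nonzero_rows] <= 0).any():
        gene = np.asarray(counts.gene_ids)[nonzero_rows][
            np.where(larr[nonzero_rows] <= 0)[0][0]]
        raise MatrixError(f"non-positive length for expressed gene {gene!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(larr[:, None] > 0, vals / larr[:, None], 0.0)
    totals = rates.sum(axis=0)
    empty = totals == 0
    if empty.any():
        logger.warning("counts_to_tpm: %d all-zero librar%s left at zero TPM",
                       int(empty.sum()), "y" if empty.sum() == 1 else "ies")
    safe = np.where(empty, 1.0, totals)
    tpm = TPM_TOTAL * rates / safe
    tpm[:, empty] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns),
        unit="TPM")
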