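"""Detection filtering and gene selection.

Transcripts never reaching a minimum abundance anywhere in the atlas are
dominated by stochastic sampling noise and are removed before any network is
built.  The canonical gate is >= 10 TPM in at least one sample; the detection
summary additionally reports how many genes are detected in at least a given
fraction of libraries and how many have median expression strictly above the
threshold.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


def filter_detected(matrix: ExpressionMatrix, min_tpm: float = 10.0,
                    min_samples: int = 1) -> ExpressionMatrix:
    """Retain genes with TPM >= ``min_tpm`` in at least ``min_samples`` samples.

    Both comparisons are inclusive: a gene sitting exactly at the threshold
    in exactly ``min_samples`` samples is kept.  Idempotent; the sample axis
    is never changed.
    """
    if min_tpm <= 0:
        raise FilterError("min_tpm must be > 0")
    if not 1 <= min_samples <= matrix.n_samples:
        raise FilterError(
            f"min_samples must be in [1, {matrix.n_samples}], got {min_samples}")
    detected = (matrix.values >= min_tpm).sum(axis=1) >= min_samples
    if not detected.any():
        logger.warning("filter_detected removed every gene "
                       "(min_tpm=%g, min_samples=%d)", min_tpm, min_samples)
    kept = matrix.data.loc[detected]
    logger.info("detection filter: %d of %d genes retained",
                int(detected.sum()), matrix.n_genes)
    return ExpressionMatrix(kept, unit=matrix.unit)


def detection_summary(matrix: ExpressionMatrix, min_tpm: float = 10.0,
                      fractions: tuple[float, ...] = (0.9,),
                      round_up: bool = True) -> dict:
    """Detection-breadth summary of a matrix.

    Returns counts of genes detected (TPM >= ``min_tpm``) in at least
    ``ceil(f * n_samples)`` samples for each fraction ``f`` (``round_up=False``
    switches to floor), and of genes whose median TPM is strictly above
    ``min_tpm``.
    """
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise FilterError("matrix is empty")
    vals = matrix.values
    n = matrix.n_samples
    n_detected = (vals >= min_tpm).sum(axis=1)
    rounder = math.ceil if round_up else math.floor
    by_fraction = {
        f: int((n_detected >= max(rounder(f * n), 1)).sum()) for f in fractions}
    medians = np.median(vals, axis=1)
    return {
        "n_genes": matrix.n_genes,
        "n_samples": n,
        "min_tpm": min_tpm,
        "n_detected_ge_fraction": by_fraction,
        "n_median_above": int((medians > min_tpm).sum()),
    }


def select_top_genes(matrix: ExpressionMatrix, n: int = 500,
                     ranking_matrix: ExpressionMatrix | None = None) -> list[str]:
    """Top ``n`` genes by summed abundance, ties broken lexicographically.

    When ``ranking_matrix`` is given (e.g. rank single-cell genes but select
    from a bulk matrix), its totals define the order but the returned genes
    must exist in ``matrix``.
    """
    ranking = matrix if ranking_matrix is None else ranking_matrix
    candidates = [g for g in ranking.gene_ids if g in set(matrix.gene_ids)]
    if n > len(candidates):
        raise FilterError(
            f"asked for top {n} genes but only {len(candidates)} available")
    totals = ranking.data.loc[candidates].sum(axis=1)
    order = sorted(candidates, key=lambda g: (-totals[g], g))
    return order[:n]
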