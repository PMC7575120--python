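"""Library-level and gene-level quality statistics.

A healthy RNA-seq library has a rank-abundance distribution close to Zipf's
law: abundance approximately proportional to 1/rank, i.e. slope near -1 on a
log-log plot of TPM against rank.  :func:`fit_power_law` fits that slope by
ordinary least squares and gates libraries on it.  Gene-level dispersion
(mean, SD, CoV = SD/mean) summarises how variable each transcript is across
the atlas; genuinely "housekeeping" behaviour corresponds to low CoV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class ZipfFit:
    """OLS fit of log10(abundance) against log10(rank) for one library."""

    slope: float
    intercept: float
    r_squared: float
    n_ranks_used: int
    compliant: bool


def fit_power_law(
    library_tpm,
    min_tpm: float = 1.0,
    slope_band: tuple[float, float] = (-1.5, -0.5),
    min_r_squared: float = 0.8,
) -> ZipfFit:
    """Fit the rank-abundance power law of one library.

    Genes with TPM >= ``min_tpm`` are ranked in descending abundance and an
    OLS line is fitted to (log10 rank, log10 TPM).  A library is compliant
    when the slope falls in ``slope_band`` and R^2 >= ``min_r_squared``.
    The fit is invariant to uniform rescaling of the vector: only the
    intercept shifts.
    """
    x = np.asarray(library_tpm, dtype=float)
    x = x[x >= min_tpm]
    if x.size < 10:
        raise QcError(
            f"only {x.size} genes at TPM >= {min_tpm}; need >= 10 for a fit")
    x = np.sort(x)[::-1]
    ranks = np.arange(1, x.size + 1)
    res = stats.linregress(np.log10(ranks), np.log10(x))
    # constant vectors give slope 0 and undefined r; treat r^2 as 0
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue ** 2)
    slope = float(res.slope)
    compliant = (slope_band[0] <= slope <= slope_band[1]) and r2 >= min_r_squared
    return ZipfFit(slope=slope, intercept=float(res.intercept),
                   r_squared=r2, n_ranks_used=int(x.size), compliant=compliant)


def zipf_report(matrix: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """Per-library power-law fits (one row per sample)."""
    rows = []
    for s in matrix.sample_ids:
        fit = fit_power_law(matrix.data[s].to_numpy(), **kwargs)
        rows.append({"sample_id": s, "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.r_squared,
                     "n_ranks_used": fit.n_ranks_used,
                     "compliant": fit.compliant})
    return pd.DataFrame(rows)


def dispersion_stats(matrix: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Per-gene mean, SD and coefficient of variation across samples.

    ``ddof=1`` gives the sample SD (default); set ``ddof=0`` for the
    population convention.  CoV is NaN (flagged, not an error) for genes with
    zero mean, where it is undefined.
    """
    vals = matrix.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "cov": cov, "cov_defined": mean > 0},
        index=matrix.data.index)


def cumulative_fraction(matrix: ExpressionMatrix, gene_subset) -> pd.Series:
    """Per-sample share of total abundance carried by a gene subset.

    Answers questions like "what fraction of each library do the top-200
    transcripts account for"; values lie in [0, 1].
    """
    subset = list(gene_subset)
    if not subset:
        raise QcError("gene_subset is empty")
    sub = matrix.subset_genes(subset)
    total = matrix.values.sum(axis=0)
    part = sub.values.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, part / total, 0.0)
    return pd.Series(frac, index=matrix.sample_ids, name="cumulative_fraction")
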