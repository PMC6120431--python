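"""Low-expression filtering, library-size normalization, and a shrunken log transform.

Genes seen at fewer than ``min_count`` reads in more than ``max_fraction_below``
of samples are removed before any statistics are computed.  Library sizes are
estimated by the median-of-ratios method and rescaled to geometric mean 1.

The expression matrix used by the discriminant-axis, concordance and dynamics
stages is a regularized log transform: ``log2(count / s_j + c)`` with per-gene
shrinkage of the sample values toward the gene mean.  The shrinkage weight

    lambda_g = alpha_g / (alpha_g + 1 / mean_normalized_count_g),  clipped to [0, max_shrinkage],

pulls harder on genes whose variability is dominated by overdispersion.  The
dispersion entering lambda is the fitted mean-dispersion trend evaluated at the
gene's mean — a smooth function of the mean pooled over all genes — so the
per-gene shrinkage factor is essentially independent of the gene's own noise
realization and cannot couple otherwise independent group means.  The cap
(default 0.5) guarantees that at least half of every gene's deviation from its
mean is retained, so cross-gene rank statistics computed on the transformed
values stay informative.  The formula
is documented here and in the returned object so the transform is pluggable:
downstream statistics only require a monotone, variance-stabilized log-scale
matrix.  Differential-expression testing runs on raw counts plus size factors,
not on this matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CountMatrix, PipelineError, SampleDesign

__all__ = [
    "ExprMatrix",
    "filter_low_expression",
    "size_factors",
    "rlog_transform",
    "moment_dispersion",
    "dispersion_trend",
]

logger = logging.getLogger(__name__)


@dataclass
class ExprMatrix:
    """Regularized log2-scale expression values (genes x samples)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray
    pseudocount: float = 1.0
    shrinkage: np.ndarray | None = None  # per-gene lambda actually applied

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise PipelineError("ExprMatrix shape does not match its gene/sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise PipelineError("ExprMatrix contains non-finite values")
        sf = np.asarray(self.size_factors, dtype=float)
        if np.any(sf <= 0):
            raise PipelineError("size factors must be strictly positive")
        if abs(float(np.mean(np.log(sf)))) > 1e-9:
            raise PipelineError("size factors must have geometric mean 1")
        self.size_factors = sf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExprMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise PipelineError(f"genes not in expression matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_ids]
        return ExprMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx],
            self.size_factors,
            self.pseudocount,
            self.shrinkage[idx] if self.shrinkage is not None else None,
        )


def filter_low_expression(
    counts: CountMatrix, min_count: int = 10, max_fraction_below: float = 0.90
) -> CountMatrix:
    """Remove genes with fewer than ``min_count`` reads in more than
    ``max_fraction_below`` of samples.

    Both comparisons are strict: a gene is *kept* iff the fraction of samples
    with count < ``min_count`` is <= ``max_fraction_below``.  A gene with all
    counts exactly equal to ``min_count`` is therefore kept.
    """
    frac_below = (counts.counts < min_count).mean(axis=1)
    keep = frac_below <= max_fraction_below
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return counts.subset_genes(keep)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean across samples; only
    genes with a positive geometric mean (nonzero in every sample) contribute.
    If no such gene exists the estimator falls back to total-count ratios with
    a logged warning.
    """
    arr = counts.counts.astype(float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        loggeo = np.log(arr[positive]).mean(axis=1)
        ratios = np.log(arr[positive]) - loggeo[:, None]
        logsf = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene expressed in all %d samples; falling back to total-count size factors",
            counts.n_samples,
        )
        totals = arr.sum(axis=0)
        if np.any(totals <= 0):
            raise PipelineError("cannot estimate size factors: a sample has zero total count")
        logsf = np.log(totals)
    logsf = logsf - logsf.mean()
    return np.exp(logsf)


def moment_dispersion(
    normalized: np.ndarray,
    groups: np.ndarray | None = None,
    floor: float = 1e-8,
) -> np.ndarray:
    """Method-of-moments NB dispersion on normalized counts (``var = mu + alpha mu^2``).

    ``groups`` is an optional integer label per sample; variances are pooled
    within groups so that real between-group effects do not inflate the
    estimate.  Values are floored at ``floor``.
    """
    z = np.asarray(normalized, dtype=float)
    n = z.shape[1]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    ss = np.zeros(z.shape[0])
    df = 0
    for g in np.unique(groups):
        cols = z[:, groups == g]
        if cols.shape[1] < 2:
            continue
        ss += ((cols - cols.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += cols.shape[1] - 1
    if df == 0:
        raise PipelineError("dispersion estimation needs >= 2 samples in some group")
    var_w = ss / df
    mean = z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mean) / mean**2
    alpha[~np.isfinite(alpha)] = floor
    return np.maximum(alpha, floor)


def dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Robust fit of alpha(m) = a0 + a1 / m over genes, evaluated at each gene's mean."""
    ok = (mean > 0) & (alpha_mom > 1e-6)
    fallback = float(np.median(alpha_mom[alpha_mom > 1e-6])) if (alpha_mom > 1e-6).any() else 1e-2
    if ok.sum() < 20:
        return np.full_like(mean, max(fallback, 1e-8))
    x, yv = 1.0 / mean[ok], alpha_mom[ok]
    keep = np.ones(ok.sum(), dtype=bool)
    a0, a1 = fallback, 0.0
    for _ in range(3):
        A = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(A, yv[keep], rcond=None)
        a0, a1 = coef
        resid = yv - (a0 + a1 * x)
        mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
        keep = np.abs(resid) < 5 * 1.4826 * mad
        if keep.sum() < 20:
            break
    trend = a0 + a1 / np.maximum(mean, 1e-12)
    return np.clip(trend, 1e-8, None)


def rlog_transform(
    counts: CountMatrix,
    size_factors_: np.ndarray | None = None,
    design: SampleDesign | None = None,
    pseudocount: float = 1.0,
    shrink: bool = True,
    max_shrinkage: float = 0.5,
) -> ExprMatrix:
    """Regularized log transform (see module docstring for the exact formula).

    When a design is supplied, the dispersion feeding the shrinkage weight is
    estimated within (site, tide, time) cells so that real treatment effects
    are not mistaken for noise.
    """
    sf = size_factors(counts) if size_factors_ is None else np.asarray(size_factors_, float)
    z = counts.counts / sf[None, :]
    logz = np.log2(z + pseudocount)
    if not shrink:
        return ExprMatrix(list(counts.gene_ids), list(counts.sample_ids), logz, sf,
                          pseudocount, np.zeros(counts.n_genes))
    if design is not None:
        codes = pd.MultiIndex.from_frame(design.table[["site", "tide", "time_h"]]).codes
        groups = np.ravel_multi_index(codes, [c.max() + 1 for c in map(np.asarray, codes)])
    else:
        groups = None
    alpha_mom = moment_dispersion(z, groups)
    mean_norm = np.maximum(z.mean(axis=1), 1e-12)
    alpha = dispersion_trend(mean_norm, alpha_mom)
    lam = alpha / (alpha + 1.0 / mean_norm)
    lam = np.clip(lam, 0.0, max_shrinkage)
    gene_mean = logz.mean(axis=1, keepdims=True)
    values = gene_mean + (1.0 - lam[:, None]) * (logz - gene_mean)
    return ExprMatrix(list(counts.gene_ids), list(counts.sample_ids), values, sf,
                      pseudocount, lam)
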