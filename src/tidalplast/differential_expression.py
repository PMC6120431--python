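"""Per-gene negative-binomial Wald tests for two-group contrasts, with BH correction.

Two families of contrasts drive the gene classification:

* divergence contrasts: intertidal vs subtidal at 0 h within one site
  ("has the gene evolved a baseline expression difference?");
* plasticity contrasts: stressed time t vs 0 h within one site, with the
  intertidal and subtidal samples of the site pooled into one group per time
  point, since the two populations of a site derive from the same ancestral
  population.

The model per gene is an NB GLM with log link, offset ``log(s_j)`` and a
single two-level group factor, so the fit separates into two independent
one-parameter fits (one log-mean per group) solved by Newton iteration on the
score equation ``sum_j (y_j - mu_j) / (1 + alpha mu_j) = 0``.  The gene-wise
dispersion is a method-of-moments estimate on normalized counts, floored at
1e-8 and shrunk in log space toward a fitted mean-dispersion trend
``alpha(m) = a0 + a1 / m``; with only a handful of replicates per group the
gene-wise moment estimate is mostly noise, so the trend carries all of the
weight by default (the gene-wise estimate enters only through the trend fit).  The Wald statistic ``beta1 / SE`` is referred to a
standard normal, two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CountMatrix,
    DEResult,
    DesignError,
    PipelineError,
    SampleDesign,
    align_counts_to_design,
)
from .normalization import dispersion_trend, moment_dispersion
from .normalization import size_factors as estimate_size_factors

__all__ = [
    "Contrast",
    "divergence_contrast",
    "plasticity_contrast",
    "standard_contrasts",
    "nb_wald_test",
    "bh_adjust",
    "call_significant",
]

logger = logging.getLogger(__name__)


@dataclass
class Contrast:
    """A named two-group comparison on a subset of samples.

    ``subset`` maps design columns to required levels (scalar or list);
    ``factor`` is the grouping column restricted to exactly the two levels
    ``baseline`` and ``alt``.  The reported effect is alt minus baseline on
    the log2 scale.
    """

    name: str
    subset: Mapping[str, object]
    factor: str
    baseline: object
    alt: object

    def group_masks(self, design: SampleDesign) -> tuple[np.ndarray, np.ndarray]:
        sel = design.mask(**self.subset)
        col = design.table[self.factor]
        a = sel & (col == self.baseline).to_numpy()
        b = sel & (col == self.alt).to_numpy()
        if a.sum() < 2 or b.sum() < 2:
            raise DesignError(
                f"contrast {self.name!r} needs >= 2 samples per group; "
                f"got {int(a.sum())} baseline, {int(b.sum())} alt"
            )
        return a, b


def divergence_contrast(site: str) -> Contrast:
    """Intertidal vs subtidal among unstressed (0 h) samples of one site."""
    return Contrast(
        name=f"divergence:{site}",
        subset={"site": site, "time_h": 0},
        factor="tide",
        baseline="S",
        alt="I",
    )


def plasticity_contrast(site: str, time_h: int) -> Contrast:
    """Stressed time vs 0 h within one site, tidal levels pooled per time point."""
    return Contrast(
        name=f"plasticity:{site}:{time_h}h",
        subset={"site": site, "time_h": [0, time_h]},
        factor="time_h",
        baseline=0,
        alt=time_h,
    )


def standard_contrasts(design: SampleDesign) -> list[Contrast]:
    """The study's contrast battery: one divergence contrast per site and one
    plasticity contrast per site per stressed time."""
    out = [divergence_contrast(site) for site in design.sites]
    for site in design.sites:
        for t in design.stress_times:
            out.append(plasticity_contrast(site, t))
    return out


# ---------------------------------------------------------------------------
# NB fitting machinery (vectorized across genes)
# ---------------------------------------------------------------------------

def _fit_log_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE of eta = log(m) in mu_j = s_j * m for NB(mu, alpha), vectorized over genes.

    Returns (eta_hat, var_eta from Fisher information, converged flag).
    Groups with zero total count get a half-count continuity correction.
    """
    tot = y.sum(axis=1)
    zero = tot == 0
    eta = np.log(np.maximum(tot, 0.5) / s.sum())
    converged = np.zeros(y.shape[0], dtype=bool)
    active = ~zero
    for _ in range(max_iter):
        if not active.any():
            break
        mu = s[None, :] * np.exp(eta[:, None])
        denom = 1.0 + alpha[:, None] * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = np.where(active & (fp != 0), f / fp, 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta - step
        done = np.abs(step) < tol
        converged |= active & done
        active = active & ~done
    mu = s[None, :] * np.exp(eta[:, None])
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    var = np.where(info > 0, 1.0 / np.maximum(info, 1e-300), np.inf)
    # zero-count groups: continuity-corrected estimate, conservative variance
    var = np.where(zero, np.maximum(var, 2.0), var)
    converged |= zero
    return eta, var, converged


def estimate_dispersions(
    y: np.ndarray,
    s: np.ndarray,
    groups: np.ndarray,
    shrinkage: float = 1.0,
    floor: float = 1e-8,
) -> np.ndarray:
    """Gene-wise MoM dispersion shrunk toward the mean-dispersion trend.

    ``shrinkage`` is the weight on the trend in log space (0 = raw gene-wise
    moments, 1 = trend only).
    """
    z = y / s[None, :]
    alpha_mom = moment_dispersion(z, groups, floor=floor)
    trend = dispersion_trend(z.mean(axis=1), alpha_mom)
    logmix = shrinkage * np.log(trend) + (1.0 - shrinkage) * np.log(np.maximum(alpha_mom, floor))
    return np.maximum(np.exp(logmix), floor)


def nb_wald_test(
    counts: CountMatrix,
    design: SampleDesign,
    contrast: Contrast,
    size_factors: np.ndarray | None = None,
    dispersion_shrinkage: float = 1.0,
) -> DEResult:
    """Per-gene NB Wald test for one contrast; returns BH-adjusted results.

    Genes with zero counts throughout the contrast subset are flagged
    ``all_zero`` with effect 0 and p = 1.  Genes with a degenerate (zero or
    non-finite) standard error are likewise set to p = 1 (conservative).
    """
    counts = align_counts_to_design(counts, design)
    sf = estimate_size_factors(counts) if size_factors is None else np.asarray(size_factors, float)
    mask_a, mask_b = contrast.group_masks(design)
    sel = mask_a | mask_b
    y = counts.counts[:, sel].astype(float)
    s = sf[sel]
    groups = mask_b[sel].astype(int)  # 0 = baseline, 1 = alt

    alpha = estimate_dispersions(y, s, groups, shrinkage=dispersion_shrinkage)
    eta_a, var_a, conv_a = _fit_log_mean(y[:, groups == 0], s[groups == 0], alpha)
    eta_b, var_b, conv_b = _fit_log_mean(y[:, groups == 1], s[groups == 1], alpha)

    beta = eta_b - eta_a  # natural log
    se = np.sqrt(var_a + var_b)
    log2_effect = beta / np.log(2.0)
    se_log2 = se / np.log(2.0)

    all_zero = y.sum(axis=1) == 0
    degenerate = ~np.isfinite(se) | (se == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, beta / se)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(all_zero | degenerate, 1.0, pvalue)
    log2_effect = np.where(all_zero, 0.0, log2_effect)

    nonconv = ~(conv_a & conv_b) & ~all_zero
    if nonconv.any():
        # fall back to a likelihood-ratio test for genes whose Newton fit stalled
        for g in np.flatnonzero(nonconv):
            pvalue[g] = _lrt_pvalue(y[g], s, groups, alpha[g])

    flag = np.where(all_zero, "all_zero", np.where(degenerate, "degenerate",
                    np.where(nonconv, "lrt_fallback", "")))
    qvalue = bh_adjust(pvalue)
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2_effect": log2_effect,
            "se": se_log2,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "flag": flag,
        }
    )
    return DEResult(contrast=contrast.name, table=table)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    return float(np.sum(stats.nbinom.logpmf(y, r, r / (r + mu))))


def _lrt_pvalue(y: np.ndarray, s: np.ndarray, groups: np.ndarray, alpha: float) -> float:
    """Likelihood-ratio test of the two-group model against a common mean."""
    def fit(yy: np.ndarray, ss: np.ndarray) -> float:
        e, _, _ = _fit_log_mean(yy[None, :], ss, np.array([alpha]))
        return float(e[0])

    e0 = fit(y, s)
    ll0 = _nb_loglik(y, s * np.exp(e0), alpha)
    ll1 = 0.0
    for g in (0, 1):
        eg = fit(y[groups == g], s[groups == g])
        ll1 += _nb_loglik(y[groups == g], s[groups == g] * np.exp(eg), alpha)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return float(stats.chi2.sf(lr, df=1))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: ``q_(i) = min_{j>=i} p_(j) * m / j``, capped at 1.

    NaN entries propagate as NaN (with a warning) and do not count toward m.
    Delegates the clean part to statsmodels' ``fdr_bh``.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise PipelineError("p-values must lie in [0, 1]")
    nan = np.isnan(p)
    q = np.full_like(p, np.nan)
    if nan.any():
        warnings.warn(f"{int(nan.sum())} NaN p-value(s) propagated through BH adjustment",
                      stacklevel=2)
    if (~nan).any():
        q[~nan] = multipletests(p[~nan], method="fdr_bh")[1]
    return q


def call_significant(de: DEResult, alpha: float = 0.05, use_adjusted: bool = True) -> set[str]:
    """Gene IDs with (adjusted, by default) p strictly below ``alpha``."""
    col = "qvalue" if use_adjusted else "pvalue"
    v = de.table[col].to_numpy(float)
    hits = np.flatnonzero(v < alpha)
    ids = de.table["gene_id"].astype(str).to_numpy()
    return set(ids[hits])
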