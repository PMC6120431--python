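"""Counts of genes with increased plasticity per gene set, population and time.

"Plasticity" of gene g in population P at stressed time t is the magnitude of
its plastic change ``|Delta_g^P(t)| = |mean(P, t) - mean(P, 0 h)|`` on the
regularized log scale, computed within one site.  The evolved change in
plasticity is ``|Delta_g^I(t)| - |Delta_g^S(t)|`` (intertidal minus subtidal).

A gene is counted as showing *increased* plasticity for population P at time t
under one of two rules:

* ``vs_counterpart`` (default): its plasticity magnitude in P exceeds that of
  the other population at the same time — the population-comparison reading of
  evolved plasticity change;
* ``vs_zero``: its plasticity magnitude at t exceeds that at the other
  stressed time — a within-population temporal reading.

Percentages are compared between 6 h and 24 h within each (gene set,
population) with a pooled two-proportion z-test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PipelineError, SampleDesign
from .normalization import ExprMatrix
from .plasticity_concordance import plasticity_vector, round_half_up

__all__ = [
    "evolved_plasticity_change",
    "increased_plasticity_counts",
    "two_proportion_pvalue",
]


def evolved_plasticity_change(
    expr: ExprMatrix, design: SampleDesign, gene_set, site: str, time_h: int
) -> np.ndarray:
    """Per-gene ``|Delta^I(t)| - |Delta^S(t)|`` within one site.

    Positive values mean the intertidal population responds more strongly than
    the subtidal one; swapping the population labels negates the vector.
    """
    d_i = plasticity_vector(expr, design, site, time_h, tide="I", gene_set=gene_set)
    d_s = plasticity_vector(expr, design, site, time_h, tide="S", gene_set=gene_set)
    return np.abs(d_i) - np.abs(d_s)


def two_proportion_pvalue(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test; p = 1 for degenerate inputs."""
    if min(n1, n2) == 0:
        return 1.0
    p_pool = (x1 + x2) / (n1 + n2)
    var = p_pool * (1 - p_pool) * (1 / n1 + 1 / n2)
    if var <= 0:
        return 1.0
    z = (x1 / n1 - x2 / n2) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def increased_plasticity_counts(
    expr: ExprMatrix,
    design: SampleDesign,
    gene_sets: Mapping[str, Sequence[str]],
    site: str,
    rule: str = "vs_counterpart",
) -> pd.DataFrame:
    """Tabulate increased-plasticity counts and 6 h vs 24 h comparisons (one site).

    Returns one row per (gene set, population, time) with columns n_increased,
    n_total, percent, and the p-value of the pooled two-proportion z-test
    between the two stressed times within the (gene set, population);
    ``significant`` marks p < 0.05.  Empty gene sets yield rows with
    n_total = 0 and NaN percent.
    """
    if rule not in ("vs_counterpart", "vs_zero"):
        raise PipelineError(f"unknown rule {rule!r}")
    times = design.stress_times
    tides = [t for t in ("I", "S") if t in design.tides]
    rows = []
    for name, genes in gene_sets.items():
        genes = sorted(set(genes) & set(expr.gene_ids))
        if not genes:
            for tide in tides:
                for t in times:
                    rows.append(
                        dict(gene_set=name, population=tide, time_h=t,
                             n_increased=0, n_total=0, percent=np.nan,
                             p_6_vs_24=np.nan, significant=False)
                    )
            continue
        mag = {
            (tide, t): np.abs(plasticity_vector(expr, design, site, t, tide=tide, gene_set=genes))
            for tide in tides
            for t in times
        }
        counts: dict[tuple[str, int], int] = {}
        for tide in tides:
            other = [x for x in tides if x != tide][0]
            for t in times:
                if rule == "vs_counterpart":
                    inc = mag[(tide, t)] > mag[(other, t)]
                else:
                    other_t = [x for x in times if x != t][0]
                    inc = mag[(tide, t)] > mag[(tide, other_t)]
                counts[(tide, t)] = int(np.sum(inc))
        n_total = len(genes)
        for tide in tides:
            t1, t2 = times[0], times[-1]
            p = two_proportion_pvalue(counts[(tide, t1)], n_total, counts[(tide, t2)], n_total)
            for t in times:
                rows.append(
                    dict(
                        gene_set=name,
                        population=tide,
                        time_h=t,
                        n_increased=counts[(tide, t)],
                        n_total=n_total,
                        percent=round_half_up(100.0 * counts[(tide, t)] / n_total, 2),
                        p_6_vs_24=p,
                        significant=bool(p < 0.05),
                    )
                )
    return pd.DataFrame(rows)
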