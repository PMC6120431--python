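"""End-to-end orchestration: counts -> filter -> normalize -> DE -> gene sets ->
concordance, dynamics, and discriminant-axis shift tables.

``run_pipeline`` is deterministic given the input data and seed: running it
twice with identical arguments produces byte-identical output tables.  Every
table is written as TSV with a JSON sidecar recording the configuration and
seeds used.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    CountMatrix,
    SampleDesign,
    align_counts_to_design,
    write_counts,
    write_design,
    write_result_table,
)
from .dapc_plasticity import fit_dapc, mcmc_shift_inference, shift_magnitude
from .differential_expression import nb_wald_test, standard_contrasts
from .gene_classification import classify_genes
from .normalization import filter_low_expression, rlog_transform, size_factors
from .plasticity_concordance import permutation_test
from .plasticity_dynamics import increased_plasticity_counts
from .synthetic_data import SimConfig, simulate_counts, write_truth

__all__ = ["run_pipeline"]


def run_pipeline(
    counts: CountMatrix,
    design: SampleDesign,
    outdir: str | Path,
    seed: int,
    alpha: float = 0.05,
    min_count: int = 10,
    max_fraction_below: float = 0.90,
    n_permutations: int = 1000,
    mcmc_samples: int = 2800,
    within_site_rule: str = "union",
    dynamics_rule: str = "vs_counterpart",
    run_dapc: bool = True,
    config_extra: Mapping[str, object] | None = None,
) -> dict:
    """Run the full analysis and write result tables under ``outdir``.

    Returns a dict with the in-memory intermediates (expression matrix, DE
    results, gene sets, concordance/dynamics tables, DAPC summaries).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {
        "tidalplast_version": __version__,
        "seed": seed,
        "alpha": alpha,
        "min_count": min_count,
        "max_fraction_below": max_fraction_below,
        "n_permutations": n_permutations,
        "mcmc_samples": mcmc_samples,
        "within_site_rule": within_site_rule,
        "dynamics_rule": dynamics_rule,
        **dict(config_extra or {}),
    }

    counts = align_counts_to_design(counts, design)
    filtered = filter_low_expression(counts, min_count, max_fraction_below)
    sf = size_factors(filtered)
    expr = rlog_transform(filtered, sf, design=design)
    expr.to_frame().to_csv(outdir / "expr.tsv", sep="\t", index_label="gene_id")

    de_results = {}
    for contrast in standard_contrasts(design):
        de = nb_wald_test(filtered, design, contrast, size_factors=sf)
        de_results[contrast.name] = de
        fname = "de_" + contrast.name.replace(":", "_") + ".tsv"
        write_result_table(de.table, outdir / fname, {**cfg, "contrast": contrast.name})

    gene_sets = classify_genes(
        de_results, design.sites, design.stress_times, alpha=alpha,
        within_site_rule=within_site_rule,
    )
    gene_sets.write_json(outdir / "genesets.json")

    rng = np.random.default_rng(seed)
    conc_rows = []
    set_map = {
        "evolutionarily_divergent": gene_sets.divergent,
        "concordantly_plastic": gene_sets.plastic,
        "adaptive_plastic": gene_sets.adaptive,
    }
    for set_name, genes in set_map.items():
        for site in design.sites:
            for t in design.stress_times:
                sub_seed = int(rng.integers(2**31 - 1))
                if not genes:
                    continue
                res = permutation_test(
                    expr, design, genes, site, t, B=n_permutations,
                    seed=sub_seed, gene_set_name=set_name,
                )
                conc_rows.append(res.as_row())
    concordance = pd.DataFrame(conc_rows)
    write_result_table(concordance, outdir / "concordance.tsv", cfg)

    dynamics = pd.concat(
        [
            increased_plasticity_counts(expr, design, set_map, site, rule=dynamics_rule).assign(
                site=site
            )
            for site in design.sites
        ],
        ignore_index=True,
    )
    write_result_table(dynamics, outdir / "dynamics.tsv", cfg)

    dapc_rows = []
    dapc_models = {}
    if run_dapc:
        for site in design.sites:
            sub_seed = int(rng.integers(2**31 - 1))
            model = fit_dapc(expr, design, site=site)
            dapc_models[site] = model
            site_design = SampleDesign(
                design.table.loc[design.mask(site=site)].reset_index(drop=True)
            )
            inference = mcmc_shift_inference(
                model.scores, site_design, n_retained=mcmc_samples, seed=sub_seed
            )
            for tide in site_design.tides:
                for t in site_design.stress_times:
                    est = shift_magnitude(model, site_design, tide, t)
                    post = next(
                        e for e in inference["estimates"]
                        if e.population == tide and e.time_h == t
                    )
                    dapc_rows.append(
                        dict(
                            site=site,
                            population=tide,
                            time_h=t,
                            shift=est.shift,
                            magnitude=est.magnitude,
                            posterior_shift=post.shift,
                            ci_low=post.ci_low,
                            ci_high=post.ci_high,
                            p_mcmc=post.p_mcmc,
                            n_mcmc=post.n_mcmc,
                            converged=inference["converged"],
                        )
                    )
        write_result_table(pd.DataFrame(dapc_rows), outdir / "dapc_shifts.tsv", cfg)

    return {
        "config": cfg,
        "filtered_counts": filtered,
        "size_factors": sf,
        "expr": expr,
        "de_results": de_results,
        "gene_sets": gene_sets,
        "concordance": concordance,
        "dynamics": dynamics,
        "dapc": pd.DataFrame(dapc_rows),
        "dapc_models": dapc_models,
    }


def simulate_and_write(config: SimConfig, outdir: str | Path) -> None:
    """Generate a synthetic dataset and write counts.tsv, design.csv, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, design, truth = simulate_counts(config)
    write_counts(counts, outdir / "counts.tsv")
    write_design(design, outdir / "design.csv")
    write_truth(truth, outdir / "truth.tsv")
    write_result_table(
        pd.DataFrame({"sample_id": design.sample_ids, "true_size_factor": truth.size_factors}),
        outdir / "size_factors.tsv",
        dataclasses.asdict(config),
    )
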