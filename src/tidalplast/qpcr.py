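"""Relative qPCR quantification by the Livak 2^-ddCt method.

Cycle-threshold (Ct) values of a target gene are first normalized against a
reference gene measured in the same sample (dCt = Ct_gene - Ct_ref), then
against a calibrator condition (ddCt = dCt_sample - dCt_calibrator, the
unstressed 0 h sample in the study design); the relative expression is
2^-ddCt.  Technical duplicates are averaged on the Ct scale before dCt is
formed.  Any shared instrument offset added to both the gene and the
reference Ct cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist

from .data_model import ParseError, PipelineError

__all__ = ["CtTable", "livak_fold_change", "fold_change_table", "cluster_profiles"]


@dataclass
class CtTable:
    """Long-format Ct measurements: columns gene, sample_id, ct.

    ``reference_gene`` must be measured in every sample; Ct values must be
    finite and positive.  Technical duplicates (repeated (gene, sample) rows)
    are averaged on the Ct scale.
    """

    table: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in ("gene", "sample_id", "ct") if c not in df.columns]
        if missing:
            raise ParseError(f"Ct table missing columns: {missing}")
        df = df.loc[:, ["gene", "sample_id", "ct"]].copy()
        df["gene"] = df["gene"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        df["ct"] = df["ct"].astype(float)
        bad = df[~np.isfinite(df["ct"]) | (df["ct"] <= 0)]
        if len(bad):
            r = bad.iloc[0]
            raise ParseError(f"invalid Ct for gene {r.gene!r}, sample {r.sample_id!r}: {r.ct}")
        self.table = df.groupby(["gene", "sample_id"], as_index=False)["ct"].mean()
        samples = set(self.table["sample_id"])
        ref = set(self.table.loc[self.table["gene"] == self.reference_gene, "sample_id"])
        if samples - ref:
            raise PipelineError(
                f"reference gene {self.reference_gene!r} missing for samples "
                f"{sorted(samples - ref)[:5]}"
            )

    def ct(self, gene: str, sample: str) -> float:
        sel = self.table[(self.table["gene"] == gene) & (self.table["sample_id"] == sample)]
        if sel.empty:
            raise PipelineError(f"missing Ct for gene {gene!r}, sample {sample!r}")
        return float(sel["ct"].iloc[0])

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.table["gene"]) - {self.reference_gene})

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))


def livak_fold_change(table: CtTable, gene: str, sample: str, calibrator_sample: str) -> float:
    """2^-ddCt of ``gene`` in ``sample`` relative to ``calibrator_sample``."""
    dct_sample = table.ct(gene, sample) - table.ct(table.reference_gene, sample)
    dct_cal = table.ct(gene, calibrator_sample) - table.ct(table.reference_gene, calibrator_sample)
    return float(2.0 ** (-(dct_sample - dct_cal)))


def fold_change_table(table: CtTable, calibrator_sample: str) -> pd.DataFrame:
    """Fold changes of every target gene in every sample vs the calibrator (genes x samples)."""
    data = {
        s: [livak_fold_change(table, g, s, calibrator_sample) for g in table.genes]
        for s in table.samples
    }
    return pd.DataFrame(data, index=table.genes)


def cluster_profiles(fold_changes: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of log2 fold-change profiles
    (Euclidean distance); returns the scipy linkage matrix."""
    if len(fold_changes) < 2:
        raise PipelineError("clustering needs >= 2 genes")
    return average(pdist(np.log2(fold_changes.to_numpy()), metric="euclidean"))
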