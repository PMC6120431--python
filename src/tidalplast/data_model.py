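"""Core containers and file I/O for count-based expression analyses.

The pipeline works from two primary inputs: a gene x sample matrix of raw
integer read counts (:class:`CountMatrix`) and a per-sample factor table
(:class:`SampleDesign`) describing the two-site, two-tidal-level,
three-time-point, replicated common-garden design.  Everything downstream
(filtering, normalization, differential expression, gene classification,
concordance statistics) consumes these two objects.

TSV is the canonical interchange format for count matrices; MatrixMarket
(``.mtx`` plus ``.genes.txt`` / ``.samples.txt`` sidecars) is supported
read-only.  Result tables are written as TSV with a JSON sidecar carrying
the run configuration and RNG seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PipelineError",
    "ParseError",
    "DesignError",
    "CountMatrix",
    "SampleDesign",
    "DEResult",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "align_counts_to_design",
    "write_result_table",
]

#: Tidal levels recognized by the design reader: I = intertidal, S = subtidal.
TIDE_LEVELS = ("I", "S")

DESIGN_COLUMNS = ("sample_id", "site", "tide", "time_h", "replicate")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A malformed input file (bad header, negative/non-integer count, duplicate ID)."""


class DesignError(PipelineError):
    """A sample design that violates the replication or factor-level requirements."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for the rows and columns.
    counts
        Non-negative integer array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ParseError(
                f"count matrix shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise ParseError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            g, s = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.counts = arr.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to ``keep`` (IDs or boolean mask), order preserved."""
        mask = np.asarray(keep)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            wanted = set(map(str, keep))
            idx = np.array([i for i, g in enumerate(self.gene_ids) if g in wanted], dtype=int)
        return CountMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DesignError(f"samples not present in count matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), [str(s) for s in sample_ids], self.counts[:, idx])


@dataclass
class SampleDesign:
    """Per-sample experimental factors: site, tide (I/S), time_h, replicate.

    The time levels form a declared ordered set whose smallest member is the
    unstressed baseline (0 h in the study design).  Every (site, tide, time)
    cell must contain at least two replicates so that dispersions and group
    variances are estimable.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        df = df.loc[:, list(DESIGN_COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["site"] = df["site"].astype(str)
        df["tide"] = df["tide"].astype(str)
        df["time_h"] = df["time_h"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        _check_unique(df["sample_id"].tolist(), "sample")
        bad_tide = sorted(set(df["tide"]) - set(TIDE_LEVELS))
        if bad_tide:
            raise DesignError(f"unknown tide level(s) {bad_tide}; expected {TIDE_LEVELS}")
        if (df["replicate"] < 1).any():
            raise DesignError("replicate numbers must be positive integers")
        small = df.groupby(["site", "tide", "time_h"]).size()
        small = small[small < 2]
        if len(small):
            cells = ", ".join(f"{s}-{t}_{h}h (n={n})" for (s, t, h), n in small.items())
            raise DesignError(f"design cell(s) with fewer than 2 replicates: {cells}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.table["site"]))

    @property
    def tides(self) -> list[str]:
        return list(dict.fromkeys(self.table["tide"]))

    @property
    def times(self) -> list[int]:
        return sorted(self.table["time_h"].unique().tolist())

    @property
    def baseline_time(self) -> int:
        return self.times[0]

    @property
    def stress_times(self) -> list[int]:
        return self.times[1:]

    def mask(self, *, site: object = None, tide: object = None, time_h: object = None) -> np.ndarray:
        """Boolean sample mask; each keyword may be a scalar level or an iterable of levels."""
        m = np.ones(len(self.table), dtype=bool)
        for col, val in (("site", site), ("tide", tide), ("time_h", time_h)):
            if val is None:
                continue
            if isinstance(val, (str, int, np.integer)):
                m &= (self.table[col] == val).to_numpy()
            else:
                m &= self.table[col].isin(list(val)).to_numpy()
        return m

    def samples_where(self, **kwargs: object) -> list[str]:
        return self.table.loc[self.mask(**kwargs), "sample_id"].tolist()


@dataclass
class DEResult:
    """Per-gene effect estimates and p-values for one named two-group contrast.

    ``table`` columns: gene_id, log2_effect, se, pvalue, qvalue, flag.
    ``flag`` marks degenerate fits (e.g. ``all_zero`` genes set to p = 1).
    """

    contrast: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "log2_effect", "se", "pvalue", "qvalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise PipelineError(f"DEResult table missing columns: {sorted(missing)}")
        if "flag" not in self.table.columns:
            self.table = self.table.assign(flag="")
        for col in ("pvalue", "qvalue"):
            v = self.table[col].to_numpy(float)
            ok = np.isnan(v) | ((v >= 0) & (v <= 1))
            if not ok.all():
                raise PipelineError(f"{col} outside [0, 1] in contrast {self.contrast!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].astype(str).tolist()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV (header = sample IDs, first column = gene IDs)
    or MatrixMarket (``.mtx`` with ``<stem>.genes.txt`` / ``<stem>.samples.txt``).

    The on-disk row and column order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", header=0, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"could not parse count TSV {path}: {exc}") from exc
        if df.index.hasnans or any(str(c).startswith("Unnamed") for c in df.columns):
            raise ParseError(f"malformed header or gene-ID column in {path}")
        return CountMatrix(df.index.astype(str).tolist(), [str(c) for c in df.columns], df.to_numpy())
    if format == "mtx":
        from scipy.io import mmread

        genes_file = path.with_suffix("").with_suffix(".genes.txt")
        samples_file = path.with_suffix("").with_suffix(".samples.txt")
        for side in (genes_file, samples_file):
            if not side.exists():
                raise ParseError(f"MatrixMarket sidecar file missing: {side}")
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path))
        genes = genes_file.read_text().split()
        samples = samples_file.read_text().split()
        return CountMatrix(genes, samples, mat)
    raise ValueError(f"unknown count format {format!r}")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV (round-trips bit-exactly through :func:`read_counts`)."""
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> SampleDesign:
    """Read the sample metadata CSV (columns sample_id, site, tide, time_h, replicate)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"could not parse design CSV {path}: {exc}") from exc
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def align_counts_to_design(counts: CountMatrix, design: SampleDesign) -> CountMatrix:
    """Match counts to a design by exact sample-ID join, reordering columns to design order.

    Raises :class:`DesignError` if the two sample-ID sets differ, so that no
    downstream computation can run on silently misaligned columns.
    """
    cset, dset = set(counts.sample_ids), set(design.sample_ids)
    if cset != dset:
        only_counts = sorted(cset - dset)
        only_design = sorted(dset - cset)
        raise DesignError(
            "sample IDs of counts and design differ; "
            f"only in counts: {only_counts[:5]}, only in design: {only_design[:5]}"
        )
    return counts.reorder_samples(design.sample_ids)


def write_result_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    """Write a result table as TSV plus a ``.json`` sidecar with the run configuration."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = dict(config or {})
    payload.setdefault("table", path.name)
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
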