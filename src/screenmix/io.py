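"""Reading screen count tables and computing per-guide log2 fold changes.

The on-disk format is the MAGeCK-style delimited count table: one header
row ``sgRNA<tab>gene<tab><sample>...``, one row per guide, non-negative
integer counts.  Guides whose gene field equals the negative-control
sentinel (default ``"negative_control"``) are non-targeting controls; they
are excluded from gene scoring but are the basis of the empirical null.

Counts are normalized with median-of-ratios size factors and collapsed to
one log2 fold change per guide by averaging replicate-wise log ratios.
Users with DESeq2 (or other) moderated LFCs can skip this module and load
a precomputed LFC table with :func:`read_lfc_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_SENTINEL",
    "CountMatrix",
    "read_count_table",
    "write_count_table",
    "size_factors",
    "compute_lfc",
    "make_guide_table",
    "validate_guide_table",
    "read_lfc_table",
    "write_guide_table",
]

CONTROL_SENTINEL = "negative_control"


def _read_delimited(path, sep: str | None) -> pd.DataFrame:
    """Delimited read with exact float round-tripping (tab/comma sniffed)."""
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")

#: canonical GuideTable columns
GUIDE_TABLE_COLUMNS = ["guide_id", "gene_id", "lfc", "is_negative_control"]


@dataclass
class CountMatrix:
    """Raw guide-level counts: guides x samples plus the guide->gene map.

    ``counts`` is indexed by guide id with one integer column per sample;
    ``gene`` maps each guide to its gene id (controls keep the sentinel);
    ``conditions`` maps each sample name to a condition tag.
    """

    counts: pd.DataFrame
    gene: pd.Series
    conditions: pd.Series
    control_label: str = CONTROL_SENTINEL

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate guide ids: {dups[:5]}")
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.gene.index.equals(self.counts.index):
            raise ValueError("gene map must be indexed by the same guides as counts")
        # canonical labels so write -> read is an exact fixed point
        self.counts.index.name = "sgRNA"
        self.gene = self.gene.rename("gene").rename_axis("sgRNA")

    @property
    def is_negative_control(self) -> pd.Series:
        return self.gene == self.control_label

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def read_count_table(
    path,
    control_label: str = CONTROL_SENTINEL,
    *,
    conditions: dict[str, str] | None = None,
    sep: str | None = None,
) -> CountMatrix:
    """Read a MAGeCK-style count table (sgRNA, gene, one column per sample).

    ``conditions`` maps sample column names to condition tags; by default
    every sample gets its own name as condition (assign conditions before
    calling :func:`compute_lfc`).
    """
    df = _read_delimited(path, sep)
    if df.shape[1] < 4:
        # guide + gene + >=2 samples
        raise ValueError("count table needs guide, gene and at least 2 sample columns")
    guide_col, gene_col = df.columns[:2]
    df = df.set_index(guide_col)
    gene = df[gene_col].astype(str)
    counts = df.drop(columns=[gene_col])
    for c in counts.columns:
        col = pd.to_numeric(counts[c], errors="coerce")
        if col.isna().any():
            raise ValueError(f"non-numeric counts in sample {c!r}")
        counts[c] = col
    if conditions is None:
        conditions = {s: s for s in counts.columns}
    cond = pd.Series(conditions).reindex(counts.columns)
    return CountMatrix(counts=counts, gene=gene, conditions=cond, control_label=control_label)


def write_count_table(cm: CountMatrix, path, *, sep: str = "\t") -> None:
    """Write a CountMatrix back to the MAGeCK-style delimited layout."""
    out = cm.counts.copy()
    out.insert(0, "gene", cm.gene)
    out.index.name = "sgRNA"
    out.to_csv(path, sep=sep)


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per sample.

    For each guide with strictly positive counts in every sample, take the
    ratio of its count to its across-sample geometric mean; the size factor
    of a sample is the median of these ratios.
    """
    mat = np.asarray(counts, dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no guide has nonzero counts in all samples")
    sub = mat[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean, axis=0))
    return factors


def compute_lfc(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    *,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide mean log2 fold change of condition_b over condition_a.

    Counts are divided by median-of-ratios size factors, a pseudocount is
    added, and log2 ratios are averaged over replicate pairs.  When the two
    conditions have unequal replicate counts, each sample of the smaller
    condition is paired against the mean normalized count of the larger one.

    Returns the canonical guide table (guide_id, gene_id, lfc,
    is_negative_control).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a_samples = cm.conditions.index[cm.conditions == condition_a].tolist()
    b_samples = cm.conditions.index[cm.conditions == condition_b].tolist()
    if not a_samples or not b_samples:
        raise ValueError(
            f"conditions {condition_a!r}/{condition_b!r} must each have >= 1 sample"
        )
    factors = size_factors(cm.counts)
    norm = cm.counts.to_numpy(dtype=float) / factors[np.newaxis, :]
    norm = pd.DataFrame(norm, index=cm.counts.index, columns=cm.counts.columns)

    a = norm[a_samples].to_numpy()
    b = norm[b_samples].to_numpy()
    if a.shape[1] != b.shape[1]:
        # collapse the larger condition to its mean profile
        if a.shape[1] < b.shape[1]:
            b = b.mean(axis=1, keepdims=True).repeat(a.shape[1], axis=1)
        else:
            a = a.mean(axis=1, keepdims=True).repeat(b.shape[1], axis=1)
    lfc = np.mean(np.log2(b + pseudocount) - np.log2(a + pseudocount), axis=1)

    return make_guide_table(
        guide_id=cm.counts.index.to_numpy(),
        gene_id=cm.gene.to_numpy(),
        lfc=lfc,
        is_negative_control=cm.is_negative_control.to_numpy(),
    )


def make_guide_table(guide_id, gene_id, lfc, is_negative_control) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "guide_id": np.asarray(guide_id, dtype=object),
            "gene_id": np.asarray(gene_id, dtype=object),
            "lfc": np.asarray(lfc, dtype=float),
            "is_negative_control": np.asarray(is_negative_control, dtype=bool),
        }
    )
    validate_guide_table(table)
    return table


def validate_guide_table(table: pd.DataFrame) -> None:
    """Check guide-table invariants; raises ``ValueError`` on violation."""
    missing = [c for c in GUIDE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"guide table missing columns: {missing}")
    if table["guide_id"].duplicated().any():
        raise ValueError("duplicate guide ids in guide table")
    if not np.all(np.isfinite(table["lfc"].to_numpy(dtype=float))):
        raise ValueError("non-finite log2 fold changes")
    if not (~table["is_negative_control"]).any():
        raise ValueError("guide table contains no gene-targeting guides")


def read_lfc_table(path, *, sep: str | None = None) -> pd.DataFrame:
    """Load a precomputed LFC table (sgRNA, gene, lfc, is_control columns)."""
    df = _read_delimited(path, sep)
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "guide_id": ("guide_id", "sgrna", "guide"),
        "gene_id": ("gene_id", "gene"),
        "lfc": ("lfc", "log2fc", "log2foldchange"),
        "is_negative_control": ("is_negative_control", "is_control", "control"),
    }.items():
        for a in aliases:
            if a in cols:
                rename[cols[a]] = want
                break
    df = df.rename(columns=rename)
    if "is_negative_control" not in df.columns:
        df["is_negative_control"] = df["gene_id"].astype(str) == CONTROL_SENTINEL
    df["is_negative_control"] = df["is_negative_control"].astype(bool)
    validate_guide_table(df)
    return df[GUIDE_TABLE_COLUMNS]


def write_guide_table(table: pd.DataFrame, path, *, sep: str = "\t") -> None:
    table[GUIDE_TABLE_COLUMNS].to_csv(path, sep=sep, index=False)
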