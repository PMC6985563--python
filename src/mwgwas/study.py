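"""Published summary tables from the swine feed-efficiency study the method
was developed on, with the arithmetic that reproduces their derived columns.

Bundled tables: per-tissue RNA-Seq read totals (30 libraries per tissue),
per-tissue expressed-gene counts, per-module heritability estimates for the
five analysis layouts (unweighted/weighted at thresholds t = 5 and t = 2 and
weighted with all SNP), and counts of significant SNP overlapping known
feed-efficiency QTL.  These are reference inputs — everything derived from
them here (totals, means, h2-per-SNP ratios, overlap percentages) is
recomputed, not stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("mwgwas") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t")


def sequencing_summary() -> pd.DataFrame:
    """Per-tissue read totals and library counts."""
    return _read("sequencing_summary.tsv")


def sequencing_totals() -> dict:
    """Overall read total and mean reads per library across all tissues."""
    df = sequencing_summary()
    total = int(df["total_reads"].sum())
    n_lib = int(df["n_libraries"].sum())
    return {
        "total_reads": total,
        "n_libraries": n_lib,
        "mean_reads_per_library": total / n_lib,
    }


def expressed_genes() -> pd.DataFrame:
    return _read("expressed_genes.tsv")


def mean_expressed_genes() -> float:
    """Average number of expressed genes per tissue."""
    return float(expressed_genes()["n_expressed"].mean())


def heritability_estimates(analysis: str | None = None) -> pd.DataFrame:
    """Per-module heritability estimates; optionally filter one analysis
    layout (unweighted_t5, weighted_t5, weighted_all, unweighted_t2,
    weighted_t2)."""
    df = _read("heritability_estimates.tsv")
    if analysis is not None:
        df = df[df["analysis"] == analysis].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown analysis {analysis!r}")
    return df


def h2_per_snp(analysis: str) -> pd.Series:
    """Heritability per marker (h2 / #SNP) for one analysis layout."""
    df = heritability_estimates(analysis)
    return pd.Series(
        (df["h2"] / df["n_snp"]).to_numpy(), index=df["dataset"], name="h2_per_snp"
    )


def qtl_overlap() -> pd.DataFrame:
    return _read("qtl_overlap.tsv").set_index("quantity")


def qtl_overlap_pct() -> float:
    """Percentage of weighted-analysis significant SNP inside known
    feed-efficiency QTL."""
    t = qtl_overlap()["count"]
    return 100.0 * t["significant_snp_in_feed_efficiency_qtl"] / t["significant_snp_weighted"]
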