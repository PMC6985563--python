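"""SNP weights from module gene P-values, and relationship matrices.

SNP inside a gene interval inherit that gene's ADFI-association evidence as
a nonnegative weight w = -log10(P); intergenic SNP get zero (raised to a
small floor in the all-SNP weighted mode so every marker stays in the
model).  Weighted genomic relationships follow VanRaden's method 1 with a
diagonal weight matrix D:

    M* = M D,    G = M* M*' / (2 sum_i p_i (1 - p_i)),

where M holds B-allele dosages centered by twice the allele frequency.
Pedigree relationships (the numerator relationship matrix A) use
Henderson's tabular method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_FLOOR = 0.00001


def map_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign every SNP to the gene interval(s) containing it.

    Coordinates are 1-based with both interval ends inclusive.  Returns one
    row per (snp, containing gene) plus a row with gene_id = NA for
    intergenic SNP.  Chromosome names must agree between the two tables.

    ``snps``: columns snp_id, chrom, pos.  ``genes``: gene_id, chrom, start, end.
    """
    snp_chroms = set(snps["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    unmatched = snp_chroms - gene_chroms
    if unmatched and not (snp_chroms & gene_chroms):
        raise ValueError(f"no shared chromosome names; SNP-only chromosomes: {sorted(unmatched)}")

    rows = []
    genes_by_chrom = {c: g for c, g in genes.groupby(genes["chrom"].astype(str))}
    for snp in snps.itertuples(index=False):
        chrom = str(snp.chrom)
        hit = False
        if chrom in genes_by_chrom:
            g = genes_by_chrom[chrom]
            inside = g[(g["start"] <= snp.pos) & (snp.pos <= g["end"])]
            for gid in inside["gene_id"]:
                rows.append((snp.snp_id, gid))
                hit = True
        if not hit:
            rows.append((snp.snp_id, None))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id"])


@dataclass
class WeightTable:
    """Per-SNP nonnegative weights with provenance."""

    weights: pd.Series  # index snp_id
    source_gene: pd.Series
    mode: str  # "all_weighted" | "thresholded" | "raw"
    floor: float = DEFAULT_WEIGHT_FLOOR
    threshold: float | None = None


def snp_weights(
    assignments: pd.DataFrame,
    gene_pvalues: pd.Series,
    mode: str = "raw",
    floor: float = DEFAULT_WEIGHT_FLOOR,
) -> WeightTable:
    """Convert module gene P-values into per-SNP weights.

    w = -log10(P) of the assigned gene; intergenic SNP get 0.  SNP inside
    several overlapping genes take the maximum weight (the strongest prior
    signal).  In ``all_weighted`` mode zero weights are raised to ``floor``
    so the weighted GRM keeps every SNP.  P must lie in (0, 1]; P = 0 is an
    error (infinite weight) — clamp before calling.
    """
    pv = gene_pvalues.astype(float)
    if (pv <= 0).any():
        raise ValueError("P-values must be > 0 (clamp zeros before weighting)")
    if (pv > 1).any():
        raise ValueError("P-values must be <= 1")
    merged = assignments.merge(
        pv.rename("p_value"), left_on="gene_id", right_index=True, how="left"
    )
    merged["w"] = -np.log10(merged["p_value"])
    merged.loc[merged["gene_id"].isna() | merged["p_value"].isna(), "w"] = 0.0
    agg = merged.sort_values("w", ascending=False).groupby("snp_id", sort=False).first()
    order = assignments["snp_id"].drop_duplicates()
    weights = agg.loc[order, "w"].astype(float)
    source = agg.loc[order, "gene_id"]
    source[weights == 0.0] = None
    if mode == "all_weighted":
        weights = weights.where(weights > 0.0, floor)
    elif mode not in ("raw", "thresholded"):
        raise ValueError(f"unknown mode {mode!r}")
    return WeightTable(weights=weights, source_gene=source, mode=mode, floor=floor)


def select_snps(weights: WeightTable | pd.Series, t: float) -> list:
    """SNP ids with weight strictly greater than t, input order preserved."""
    w = weights.weights if isinstance(weights, WeightTable) else weights
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    selected = list(w.index[w > t])
    if not selected:
        raise ValueError(f"no SNP pass threshold t={t}")
    return selected


@dataclass
class Grm:
    """(Weighted) genomic relationship matrix with construction metadata."""

    G: np.ndarray
    animal_ids: list
    D: np.ndarray  # diagonal weight factors, per included SNP
    denominator: float  # 2 * sum p(1-p) over included SNP
    M_star: np.ndarray  # centered, weighted genotypes (animals x included SNP)
    snp_ids: list = field(default_factory=list)
    excluded_monomorphic: list = field(default_factory=list)
    allele_freqs: np.ndarray | None = None


def build_grm(
    genotypes: pd.DataFrame,
    weights: pd.Series | WeightTable | None = None,
) -> Grm:
    """VanRaden genomic relationship matrix, optionally SNP-weighted.

    ``genotypes``: animals x SNP B-allele dosage codes in {0, 1, 2} (index =
    animal ids, columns = snp ids).  Allele frequencies are computed from
    the supplied animals.  Monomorphic SNP (p in {0, 1}) are excluded from
    numerator and denominator (logged).  With ``weights`` None, D is the
    identity (standard unweighted G).
    """
    M_raw = genotypes.to_numpy(dtype=float)
    codes = np.unique(M_raw)
    if not np.all(np.isin(codes, [0.0, 1.0, 2.0])):
        raise ValueError("genotype codes must be 0/1/2")
    p = M_raw.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNP monomorphic")
    excluded = list(genotypes.columns[~poly])
    if excluded:
        logger.info("excluding %d monomorphic SNP from GRM", len(excluded))

    snp_ids = list(genotypes.columns[poly])
    if weights is None:
        d = np.ones(len(snp_ids))
    else:
        w = weights.weights if isinstance(weights, WeightTable) else weights
        d = w.reindex(snp_ids).to_numpy(dtype=float)
        if np.any(~np.isfinite(d)) or np.any(d < 0):
            raise ValueError("weights must be finite and nonnegative for all included SNP")

    p_inc = p[poly]
    M = M_raw[:, poly] - 2.0 * p_inc
    M_star = M * d  # M D with D diagonal
    denominator = float(2.0 * np.sum(p_inc * (1.0 - p_inc)))
    G = (M_star @ M_star.T) / denominator
    G = 0.5 * (G + G.T)  # enforce exact symmetry against round-off
    return Grm(
        G=G,
        animal_ids=list(genotypes.index),
        D=d,
        denominator=denominator,
        M_star=M_star,
        snp_ids=snp_ids,
        excluded_monomorphic=excluded,
        allele_freqs=p_inc,
    )


def build_nrm(pedigree: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Numerator relationship matrix by Henderson's tabular method.

    ``pedigree``: columns animal, sire, dam; unknown parents coded 0, "0",
    None or NaN.  Animals are topologically sorted so parents precede
    offspring; a cycle raises.  Returns (A, animal_ids) with A in the input
    row order.
    """
    ped = pedigree.copy()
    animals = list(ped["animal"])
    if len(set(animals)) != len(animals):
        raise ValueError("duplicate animals in pedigree")

    def norm(x):
        if pd.isna(x) or x == 0 or x == "0":
            return None
        return x

    parents = {row.animal: (norm(row.sire), norm(row.dam)) for row in ped.itertuples(index=False)}

    # topological order (parents first)
    order: list = []
    state: dict = {}

    def visit(a, stack):
        if a is None or a not in parents:
            return
        st = state.get(a)
        if st == "done":
            return
        if st == "visiting":
            raise ValueError(f"pedigree cycle involving {a!r}")
        state[a] = "visiting"
        s, d = parents[a]
        visit(s, stack)
        visit(d, stack)
        state[a] = "done"
        order.append(a)

    for a in animals:
        visit(a, [])

    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = idx[a]
        s, d = parents[a]
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        f = 0.0 if si is None or di is None else 0.5 * A[si, di]
        A[i, i] = 1.0 + f
        for b in order[: order.index(a)]:
            j = idx[b]
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val

    # return in the input row order
    perm = [idx[a] for a in animals]
    return A[np.ix_(perm, perm)], animals
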