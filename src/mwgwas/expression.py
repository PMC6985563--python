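"""Normalization, expression filtering and assembly of the gene x individual
x tissue expression tensor.

Per-tissue gene-level count matrices are normalized by median-of-ratios
(sample size factor = median over reference genes of the count divided by
that gene's geometric mean across samples), lowly expressed genes are
removed only when below threshold in every tissue, and the surviving genes
are stacked into an order-3 array omega[gene, individual, tissue] with
deterministic (lexicographic) axis ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionTensor:
    """Order-3 normalized expression array with axis labels.

    ``omega`` has shape (n_genes, n_individuals, n_tissues); label lists are
    ordered to match.
    """

    omega: np.ndarray
    gene_ids: list[str]
    individual_ids: list[str]
    tissue_ids: list[str]

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (len(self.gene_ids), len(self.individual_ids), len(self.tissue_ids)):
            raise ValueError("omega shape does not match axis labels")
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.omega.shape

    def tissue_slice(self, tissue: str) -> pd.DataFrame:
        k = self.tissue_ids.index(tissue)
        return pd.DataFrame(self.omega[:, :, k], index=self.gene_ids, columns=self.individual_ids)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            omega=self.omega,
            gene_ids=np.array(self.gene_ids, dtype=object),
            individual_ids=np.array(self.individual_ids, dtype=object),
            tissue_ids=np.array(self.tissue_ids, dtype=object),
        )

    @classmethod
    def load(cls, path) -> "ExpressionTensor":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                omega=z["omega"],
                gene_ids=list(z["gene_ids"]),
                individual_ids=list(z["individual_ids"]),
                tissue_ids=list(z["tissue_ids"]),
            )


def median_ratio_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios normalization of a genes x samples count matrix.

    Reference genes are those with strictly positive counts in every sample;
    each sample's size factor is the median over reference genes of
    count / geometric-mean-across-samples.  Normalized counts are the raw
    counts divided column-wise by the size factors.

    Returns (size_factors, normalized) and raises if no gene is positive in
    all samples (no reference genes to anchor the geometric means).
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    all_positive = np.all(values > 0, axis=1)
    if not all_positive.any():
        raise ValueError("no reference genes: no gene has positive counts in every sample")
    ref = values[all_positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geomean
    factors = np.exp(np.median(ratios, axis=0))
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return size_factors, normalized


def filter_low_expression(
    normalized_by_tissue: dict[str, pd.DataFrame], threshold: float = 100.0
) -> list[str]:
    """Genes kept for downstream analysis.

    A gene is removed only if its arithmetic mean normalized expression is
    strictly below ``threshold`` in every tissue; equality in any single
    tissue keeps it.  All matrices must share the same gene universe.
    """
    tissues = list(normalized_by_tissue)
    universe = normalized_by_tissue[tissues[0]].index
    for t in tissues[1:]:
        other = normalized_by_tissue[t].index
        if not universe.equals(other):
            offenders = sorted(set(universe).symmetric_difference(other))
            raise ValueError(f"gene universes differ across tissues: {offenders[:10]}")
    means = pd.DataFrame({t: m.mean(axis=1) for t, m in normalized_by_tissue.items()})
    keep = ~(means < threshold).all(axis=1)
    return list(universe[keep])


def expressed_per_tissue(
    normalized: pd.DataFrame, threshold: float = 100.0, min_libraries: int | None = None
) -> int:
    """Count genes 'expressed' in a tissue.

    A gene counts as expressed when its normalized expression is >= threshold
    in at least ``min_libraries`` libraries (default: half, rounded up).
    """
    n_lib = normalized.shape[1]
    if n_lib < 1:
        raise ValueError("need at least one library")
    if min_libraries is None:
        min_libraries = -(-n_lib // 2)  # ceil(n/2)
    n_passing = (normalized.to_numpy() >= threshold).sum(axis=1)
    return int((n_passing >= min_libraries).sum())


def assemble_tensor(
    normalized_by_tissue: dict[str, pd.DataFrame], meta: pd.DataFrame
) -> ExpressionTensor:
    """Stack per-tissue normalized matrices into an ExpressionTensor.

    ``meta`` maps sample columns to (individual_id, tissue): columns
    sample_id, individual_id, tissue.  The design must be complete — every
    individual measured in every tissue exactly once.  Axis labels are
    sorted lexicographically.
    """
    pairs = meta[["individual_id", "tissue"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise ValueError(f"duplicated (individual, tissue) pair: {tuple(dup)}")
    sample_lookup = meta.set_index(["individual_id", "tissue"])["sample_id"]

    tissues = sorted(normalized_by_tissue)
    individuals = sorted(meta["individual_id"].unique())
    genes = sorted(normalized_by_tissue[tissues[0]].index)

    omega = np.empty((len(genes), len(individuals), len(tissues)))
    for k, tissue in enumerate(tissues):
        mat = normalized_by_tissue[tissue].loc[genes]
        for j, ind in enumerate(individuals):
            try:
                sample = sample_lookup[(ind, tissue)]
            except KeyError:
                raise ValueError(f"missing (individual, tissue) pair: ({ind!r}, {tissue!r})")
            if sample not in mat.columns:
                raise ValueError(f"sample {sample!r} absent from {tissue!r} matrix")
            omega[:, j, k] = mat[sample].to_numpy()
    return ExpressionTensor(omega, genes, individuals, tissues)
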