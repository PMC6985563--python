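"""Module characterization: variance partition of individual loadings and
per-gene phenotype association through tensor projection.

For module r, the eigen-individual loadings are regressed on average daily
feed intake (ADFI), contemporary group and gender, and the share of
variance explained by each covariate is taken from sequential (Type I) sums
of squares in that order.  Gene-level ADFI association works on the tensor
projected through the module's eigen-tissue: for every gene, projected
expression across individuals is regressed on the same covariates and the
ADFI coefficient is tested two-sided (exact t reference under normal-error
theory).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionTensor

logger = logging.getLogger(__name__)

COVARIATE_ORDER = ["adfi", "cg", "gender"]


@dataclass
class VariancePartition:
    module_index: int
    proportions: dict  # covariate -> fraction of total SS
    residual_fraction: float
    coefficients: dict
    warnings: list = field(default_factory=list)


def _design_blocks(covariates: pd.DataFrame) -> tuple[list[tuple[str, np.ndarray]], list[str]]:
    """Per-covariate design blocks (treatment coding, sorted first level as
    reference); constant covariates are dropped with a warning."""
    n = len(covariates)
    blocks: list[tuple[str, np.ndarray]] = []
    dropped: list[str] = []
    adfi = covariates["adfi"].to_numpy(dtype=float)
    if not np.all(np.isfinite(adfi)):
        raise ValueError("non-finite ADFI values")
    if np.ptp(adfi) == 0:
        dropped.append("adfi")
    else:
        blocks.append(("adfi", adfi.reshape(n, 1)))
    for name, col in (("cg", "cg"), ("gender", "gender")):
        levels = sorted(covariates[col].astype(str).unique())
        if len(levels) < 2:
            dropped.append(name)
            continue
        dummies = np.column_stack(
            [(covariates[col].astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
        )
        blocks.append((name, dummies))
    for name in dropped:
        logger.warning("covariate %r constant; dropped from model", name)
    return blocks, dropped


def _full_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, int]], list[str]]:
    blocks, dropped = _design_blocks(covariates)
    n = len(covariates)
    cols = [np.ones((n, 1))]
    layout = [("intercept", 1)]
    for name, B in blocks:
        cols.append(B)
        layout.append((name, B.shape[1]))
    return np.hstack(cols), layout, dropped


def variance_partition(
    eigen_individual: np.ndarray,
    covariates: pd.DataFrame,
    module_index: int = 0,
) -> VariancePartition:
    """Sequential (Type I) ANOVA partition of eigen-individual loadings.

    Covariates enter in the fixed order ADFI, contemporary group, gender;
    each term's proportion is its sequential sum of squares over the total
    (mean-centered) sum of squares.  Proportions are invariant to affine
    rescaling of the loadings.

    ``covariates`` needs columns individual_id (or index), adfi, cg, gender
    aligned to the loadings.
    """
    y = np.asarray(eigen_individual, dtype=float)
    n = len(y)
    if len(covariates) != n:
        raise ValueError("covariates do not match loadings length")
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if total_ss == 0:
        raise ValueError("degenerate loadings: zero total sum of squares")

    blocks, dropped = _design_blocks(covariates)
    warns = [f"constant covariate dropped: {d}" for d in dropped]

    X = np.ones((n, 1))
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    ss_prev = float(resid @ resid)
    proportions: dict[str, float] = {}
    name_map = {"adfi": "ADFI", "cg": "contemporary_group", "gender": "gender"}
    rank_prev = 1
    for name, B in blocks:
        X = np.hstack([X, B])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_now = float(resid @ resid)
        if rank < X.shape[1] and rank == rank_prev:
            warns.append(f"collinear covariate: {name}")
        proportions[name_map[name]] = (ss_prev - ss_now) / total_ss
        ss_prev = ss_now
        rank_prev = rank
    for short, long in name_map.items():
        proportions.setdefault(long, 0.0)
    residual_fraction = ss_prev / total_ss

    beta_full = np.linalg.lstsq(X, y, rcond=None)[0]
    coefficients = {"beta": beta_full}
    return VariancePartition(
        module_index=module_index,
        proportions=proportions,
        residual_fraction=residual_fraction,
        coefficients=coefficients,
        warnings=warns,
    )


def project_tensor(tensor: ExpressionTensor | np.ndarray, eigen_tissue: np.ndarray) -> np.ndarray:
    """Tissue-weighted sum of tensor slices: Omega(., ., T) = sum_k T_k Omega[:, :, k].

    Returns a genes x individuals matrix; linear in both arguments.
    """
    omega = tensor.omega if isinstance(tensor, ExpressionTensor) else np.asarray(tensor, float)
    t = np.asarray(eigen_tissue, dtype=float)
    if t.shape != (omega.shape[2],):
        raise ValueError(f"eigen-tissue length {t.shape} does not match n_T={omega.shape[2]}")
    return np.einsum("gik,k->gi", omega, t)


def gene_adfi_pvalues(
    projected: np.ndarray,
    covariates: pd.DataFrame,
    gene_ids: list[str] | None = None,
    module_index: int = 0,
) -> pd.DataFrame:
    """Per-gene test of the ADFI effect on tissue-projected expression.

    For every gene, OLS of projected expression on intercept + ADFI +
    contemporary group + gender; two-sided t-test of the ADFI coefficient.
    Genes with zero-variance projection (or a rank-deficient design) get
    p = 1 and are flagged inestimable.  A Benjamini-Hochberg FDR column is
    added for reporting only; downstream weighting uses raw P.

    Returns a DataFrame with gene_id, beta2, se, p_value, fdr, flag.
    """
    Y = np.asarray(projected, dtype=float)
    n_genes, n = Y.shape
    if len(covariates) != n:
        raise ValueError("covariates do not match individual axis")
    X, layout, dropped = _full_design(covariates)
    if "adfi" in dropped:
        raise ValueError("ADFI is constant; its effect is not estimable")
    p = X.shape[1]
    adfi_col = 1  # intercept first, then ADFI (always present here)

    XtX = X.T @ X
    rank = np.linalg.matrix_rank(X)
    inestimable_design = rank < p
    dof = n - rank

    beta2 = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pvals = np.ones(n_genes)
    flags = np.array([""] * n_genes, dtype=object)

    XtX_inv = np.linalg.pinv(XtX)
    H = XtX_inv @ X.T
    B = H @ Y.T  # p x n_genes
    resid = Y.T - X @ B
    rss = np.sum(resid**2, axis=0)
    gene_var = Y.var(axis=1)

    if inestimable_design or dof <= 0:
        flags[:] = "inestimable"
        return _assemble_assoc(gene_ids, n_genes, beta2, se, pvals, flags, module_index)

    sigma2 = rss / dof
    var_b2 = sigma2 * XtX_inv[adfi_col, adfi_col]
    ok = (gene_var > 0) & (var_b2 > 0)
    beta2[:] = B[adfi_col]
    se[ok] = np.sqrt(var_b2[ok])
    tstat = np.zeros(n_genes)
    tstat[ok] = beta2[ok] / se[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    flags[~ok] = "inestimable"
    pvals[~ok] = 1.0
    # guard against exact-zero P from underflow: weights need P in (0, 1]
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return _assemble_assoc(gene_ids, n_genes, beta2, se, pvals, flags, module_index)


def _assemble_assoc(gene_ids, n_genes, beta2, se, pvals, flags, module_index) -> pd.DataFrame:
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    fdr = _bh_fdr(pvals)
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "module_index": module_index,
            "beta2": beta2,
            "se": se,
            "p_value": pvals,
            "fdr": fdr,
            "flag": flags,
        }
    )


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
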