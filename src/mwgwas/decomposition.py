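"""Successive sign-constrained rank-1 tensor decomposition.

The normalized expression tensor Omega (genes x individuals x tissues) is
approximated by a sum of R rank-1 terms

    Omega ~ sum_r  lambda_r  G_r (x) I_r (x) T_r,

with unit-norm factor vectors (the eigen-gene, eigen-individual and
eigen-tissue of module r) and lambda_r >= 0.  Each term is fitted to the
current residual by alternating least squares and then deflated.  The
eigen-tissue is constrained to a single sign: at every ALS sweep the raw
tissue contraction is thresholded both to >= 0 and to <= 0 and the variant
with the larger Euclidean norm is kept, which maximizes the captured
singular value among the two sign-feasible candidates.  A single-signed
eigen-tissue makes a module attributable to the tissues where its loading
is non-zero instead of mixing an up- and a down-module.

Module membership cutoffs come from a permutation null: gene labels are
permuted independently within every (individual, tissue) fiber, each null
tensor is decomposed the same way, and the (1 - alpha) quantile of the
pooled null eigen-gene loadings per component index is the cutoff c_r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionTensor

logger = logging.getLogger(__name__)


@dataclass
class Component:
    """One rank-1 module: singular value plus unit-norm factor vectors."""

    lambda_: float
    eigen_gene: np.ndarray
    eigen_individual: np.ndarray
    eigen_tissue: np.ndarray
    tissue_sign: str  # "nonnegative" | "nonpositive"
    n_iter: int
    converged: bool
    degenerate: bool = False


@dataclass
class Decomposition:
    components: list[Component]
    residual_norms: list[float]  # Frobenius norm after each deflation

    @property
    def R(self) -> int:
        return len(self.components)

    def lambdas(self) -> np.ndarray:
        return np.array([c.lambda_ for c in self.components])


@dataclass
class PermutationNull:
    n_perm: int
    alpha: float
    cutoffs: np.ndarray  # one cutoff per component index
    seed: int
    n_excluded: list = field(default_factory=list)


def _init_factors(omega: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leading left singular vector of each mode unfolding (deterministic)."""
    factors = []
    for mode in range(3):
        unfolded = np.moveaxis(omega, mode, 0).reshape(omega.shape[mode], -1)
        u, _, _ = np.linalg.svd(unfolded, full_matrices=False)
        v = u[:, 0]
        # deterministic sign: largest-|.| entry positive
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        factors.append(v)
    return factors[0], factors[1], factors[2]


def _threshold_tissue(t_raw: np.ndarray) -> tuple[np.ndarray, str]:
    """Pick the single-signed thresholding of the tissue contraction with the
    larger norm; ties go to nonnegative."""
    pos = np.clip(t_raw, 0.0, None)
    neg = np.clip(t_raw, None, 0.0)
    if np.linalg.norm(pos) >= np.linalg.norm(neg):
        return pos, "nonnegative"
    return neg, "nonpositive"


def rank1_constrained(
    omega: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    n_restarts: int = 0,
) -> Component:
    """Best sign-constrained rank-1 approximation of an order-3 tensor.

    Alternating updates: each factor is set to the tensor contracted against
    the other two and renormalized; the tissue factor is computed twice
    (thresholded >= 0 and <= 0) keeping the larger-norm variant.  lambda is
    the inner product <omega, g x i x t>.  Convergence: relative change of
    lambda below ``tol``.

    ``n_restarts`` adds random restarts (seeded) on top of the deterministic
    SVD initialization, keeping the best lambda.
    """
    omega = np.asarray(omega, dtype=float)
    norm = np.linalg.norm(omega)
    if norm == 0.0:
        n_g, n_i, n_t = omega.shape
        return Component(
            lambda_=0.0,
            eigen_gene=np.full(n_g, 1.0 / np.sqrt(n_g)),
            eigen_individual=np.full(n_i, 1.0 / np.sqrt(n_i)),
            eigen_tissue=np.full(n_t, 1.0 / np.sqrt(n_t)),
            tissue_sign="nonnegative",
            n_iter=0,
            converged=True,
            degenerate=True,
        )

    inits = [_init_factors(omega)]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            fs = []
            for dim in omega.shape:
                v = rng.standard_normal(dim)
                fs.append(v / np.linalg.norm(v))
            inits.append(tuple(fs))

    best: Component | None = None
    for g, i, t in inits:
        comp = _als(omega, g, i, t, tol=tol, max_iter=max_iter)
        if best is None or comp.lambda_ > best.lambda_:
            best = comp
    assert best is not None
    return best


def _als(omega, g, i, t, tol: float, max_iter: int) -> Component:
    lam_prev = -np.inf
    sign = "nonnegative"
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_raw = np.einsum("gik,i,k->g", omega, i, t)
        ng = np.linalg.norm(g_raw)
        if ng == 0:
            return _degenerate(omega.shape, it)
        g = g_raw / ng

        i_raw = np.einsum("gik,g,k->i", omega, g, t)
        ni = np.linalg.norm(i_raw)
        if ni == 0:
            return _degenerate(omega.shape, it)
        i = i_raw / ni

        t_raw = np.einsum("gik,g,i->k", omega, g, i)
        t_thr, sign = _threshold_tissue(t_raw)
        nt = np.linalg.norm(t_thr)
        if nt == 0:
            return _degenerate(omega.shape, it)
        t = t_thr / nt

        lam = float(np.einsum("gik,g,i,k->", omega, g, i, t))
        if np.isfinite(lam_prev) and abs(lam - lam_prev) <= tol * max(abs(lam), 1e-300):
            converged = True
            lam_prev = lam
            break
        lam_prev = lam

    # fix the eigen-gene / eigen-individual sign ambiguity: largest-|.|
    # entry of the eigen-individual made positive (joint flip keeps lambda)
    j = int(np.argmax(np.abs(i)))
    if i[j] < 0:
        i = -i
        g = -g
    return Component(
        lambda_=float(lam_prev),
        eigen_gene=g,
        eigen_individual=i,
        eigen_tissue=t,
        tissue_sign=sign,
        n_iter=it,
        converged=converged,
    )


def _degenerate(shape, it) -> Component:
    n_g, n_i, n_t = shape
    return Component(
        lambda_=0.0,
        eigen_gene=np.full(n_g, 1.0 / np.sqrt(n_g)),
        eigen_individual=np.full(n_i, 1.0 / np.sqrt(n_i)),
        eigen_tissue=np.full(n_t, 1.0 / np.sqrt(n_t)),
        tissue_sign="nonnegative",
        n_iter=it,
        converged=True,
        degenerate=True,
    )


def decompose(
    tensor: ExpressionTensor | np.ndarray,
    R: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    n_restarts: int = 0,
    stop_tol: float = 1e-12,
) -> Decomposition:
    """Successive rank-1 extraction with deflation.

    Each component is fitted to the current residual and subtracted
    (``residual -= lambda * g x i x t``), so residual Frobenius norms are
    non-increasing.  If the residual norm drops below ``stop_tol`` times the
    input norm, remaining components are zero-padded (logged).
    """
    omega = tensor.omega if isinstance(tensor, ExpressionTensor) else np.asarray(tensor, float)
    if R < 1:
        raise ValueError("R must be >= 1")
    residual = omega.copy()
    total_norm = np.linalg.norm(omega)
    components: list[Component] = []
    residual_norms: list[float] = []
    for r in range(R):
        if np.linalg.norm(residual) < stop_tol * max(total_norm, 1e-300):
            logger.info("residual exhausted after %d components; zero-padding", r)
            components.append(_degenerate(residual.shape, 0))
            residual_norms.append(float(np.linalg.norm(residual)))
            continue
        comp = rank1_constrained(residual, tol=tol, max_iter=max_iter, seed=seed, n_restarts=n_restarts)
        if comp.degenerate:
            logger.warning("degenerate component at r=%d", r)
        residual -= comp.lambda_ * np.einsum(
            "g,i,k->gik", comp.eigen_gene, comp.eigen_individual, comp.eigen_tissue
        )
        components.append(comp)
        residual_norms.append(float(np.linalg.norm(residual)))
    lams = [c.lambda_ for c in components]
    if any(l2 > l1 + 1e-12 for l1, l2 in zip(lams, lams[1:])):
        warnings.warn("singular values not monotonically decreasing across components", stacklevel=2)
    return Decomposition(components=components, residual_norms=residual_norms)


def permute_tensor(
    tensor: ExpressionTensor | np.ndarray, seed: int | None = None
) -> np.ndarray:
    """Null tensor: gene values permuted independently in every
    (individual, tissue) fiber, preserving each fiber's multiset exactly."""
    omega = tensor.omega if isinstance(tensor, ExpressionTensor) else np.asarray(tensor, float)
    rng = np.random.default_rng(seed)
    n_g, n_i, n_t = omega.shape
    null = np.empty_like(omega)
    for j in range(n_i):
        for k in range(n_t):
            null[:, j, k] = omega[rng.permutation(n_g), j, k]
    return null


def pooled_cutoff(loadings, alpha: float) -> float:
    """(1 - alpha) quantile (linear interpolation) of pooled null loadings."""
    sample = np.concatenate([np.asarray(x, dtype=float).ravel() for x in loadings])
    if sample.size == 0:
        raise ValueError("no null loadings to pool")
    return float(np.quantile(sample, 1.0 - alpha))


def permutation_cutoffs(
    tensor: ExpressionTensor | np.ndarray,
    R: int,
    n_perm: int = 100,
    alpha: float = 0.005,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PermutationNull:
    """Per-component top-gene cutoffs from a permutation null.

    Each of ``n_perm`` null tensors is decomposed to R components; for each
    component index r the null eigen-gene loadings are pooled across
    replicates and the cutoff c_r is their (1 - alpha) quantile (linear
    interpolation).  Degenerate null components are excluded (logged); if
    every replicate is degenerate for some r, an error is raised.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled: list[list[np.ndarray]] = [[] for _ in range(R)]
    n_excluded = [0] * R
    for _ in range(n_perm):
        null = permute_tensor(tensor, seed=int(rng.integers(2**31)))
        dec = decompose(null, R=R, tol=tol, max_iter=max_iter)
        for r, comp in enumerate(dec.components):
            if comp.degenerate:
                n_excluded[r] += 1
            else:
                pooled[r].append(comp.eigen_gene)
    cutoffs = np.empty(R)
    for r in range(R):
        if not pooled[r]:
            raise ValueError(f"all null decompositions degenerate for component {r}")
        cutoffs[r] = pooled_cutoff(pooled[r], alpha)
    return PermutationNull(
        n_perm=n_perm, alpha=alpha, cutoffs=cutoffs, seed=seed if seed is not None else -1,
        n_excluded=n_excluded,
    )


def top_genes(
    component: Component, cutoff: float, gene_ids: list[str] | None = None
) -> list:
    """Genes with eigen-gene loading strictly above the cutoff, sorted by
    descending loading.  Returns labels if ``gene_ids`` given, else indices."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    loadings = component.eigen_gene
    idx = np.where(loadings > cutoff)[0]
    order = idx[np.argsort(-loadings[idx], kind="stable")]
    if gene_ids is not None:
        return [gene_ids[i] for i in order]
    return list(order)
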