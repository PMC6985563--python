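"""REML variance components, corrected heritability, SNP-effect back-solving.

The animal model is y = X beta + u + e with u ~ N(0, K sigma2_a) for a
relationship matrix K (pedigree A or a possibly weighted genomic G) and
e ~ N(0, I sigma2_e).  Variance components maximize the restricted
likelihood, profiled to a one-dimensional search over h2 = sigma2_a /
(sigma2_a + sigma2_e) on the eigenbasis of K; standard errors come from
the expected information of (sigma2_a, sigma2_e) with a delta-method SE
for h2.

A weighted G inflates the additive (hence phenotypic) variance estimate, so
heritability from a weighted fit is corrected against an unweighted
reference: h2_w = (Var(P_u) - Var(E_w)) / Var(P_u), the unweighted
phenotypic variance minus the weighted fit's residual variance, over the
unweighted phenotypic variance.

SNP effects are back-solved from the predicted animal effects:
a_hat = M*' [M* M*']^- u_hat, then standardized to Z-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .weighting import Grm, WeightTable, build_grm, select_snps

logger = logging.getLogger(__name__)

VARIANT_LABELS = ("weighted_all", "unweighted_threshold", "weighted_threshold")


@dataclass
class VarianceComponents:
    sigma2_a: float  # additive variance on the scale of the supplied K
    sigma2_e: float
    h2: float  # share of phenotypic variance (K normalized to mean diag 1)
    se_h2: float
    loglik: float
    var_P: float = float("nan")  # phenotypic variance on the observed scale
    converged: bool = True
    boundary: bool = False
    var_P_u: float | None = None  # phenotypic variance of the unweighted reference fit
    var_E_w: float | None = None  # residual variance of this (weighted) fit
    h2_corrected: float | None = None


@dataclass
class SnpEffects:
    snp_ids: list
    a_hat: np.ndarray
    z: np.ndarray
    mean_a: float
    sd_a: float
    significance_threshold: float
    significant_ids: list


@dataclass
class AnalysisVariant:
    """One of the three weighting schemes evaluated per module.

    weighted_all: every SNP, weights floored at a small positive value.
    unweighted_threshold: only SNP with weight > t, D = identity.
    weighted_threshold: only SNP with weight > t, weights kept.
    """

    label: str
    t: float | None = None
    module_index: int | None = None

    def __post_init__(self) -> None:
        if self.label not in VARIANT_LABELS:
            raise ValueError(f"unknown variant label {self.label!r}")
        if self.label != "weighted_all" and self.t is None:
            raise ValueError("threshold t required for thresholded variants")


def _restricted_loglik(h2: float, lam: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray) -> float:
    """Profiled restricted log-likelihood at heritability h2 (up to a constant)."""
    n, p = Xstar.shape
    d = h2 * lam + (1.0 - h2)
    if np.any(d <= 0):
        return -np.inf
    w = 1.0 / d
    XtWX = (Xstar * w[:, None]).T @ Xstar
    XtWy = (Xstar * w[:, None]).T @ ystar
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    r = ystar - Xstar @ beta
    rss = float(r @ (w * r))
    sign, logdet_X = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(d)) + logdet_X)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    K: np.ndarray,
    psd_tol: float = 1e-6,
) -> VarianceComponents:
    """REML variance components for y = X beta + u + e, var(u) = K sigma2_a.

    Restricted likelihood is profiled over h2 on the eigenbasis of K and
    maximized by bounded scalar search; sigma2 estimates follow in closed
    form.  Estimates at the h2 boundary (0 or 1) are returned flagged.
    ``X`` defaults to an intercept.  K must be symmetric PSD within
    ``psd_tol`` (relative to its largest eigenvalue).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("K does not match y")
    if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
        raise ValueError("K must be symmetric")
    # h2 is a share of observed variance, so K is normalized to mean
    # diagonal 1 for the fit; sigma2_a is reported back on the input scale,
    # making h2 invariant to rescaling K
    k_scale = float(np.mean(np.diag(K)))
    if k_scale <= 0:
        raise ValueError("K diagonal must have positive mean")
    lam, U = np.linalg.eigh(K / k_scale)
    if lam[-1] <= 0:
        raise ValueError("K has no positive eigenvalue")
    if lam[0] < -psd_tol * lam[-1]:
        raise ValueError("K is not PSD within tolerance")
    lam = np.clip(lam, 0.0, None)
    ystar = U.T @ y
    Xstar = U.T @ X

    neg = lambda h2: -_restricted_loglik(h2, lam, ystar, Xstar)
    # coarse grid then bounded refinement: the profile can be multi-modal
    grid = np.linspace(0.0, 1.0 - 1e-9, 41)
    vals = np.array([neg(h) for h in grid])
    i0 = int(np.nanargmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    h2 = float(res.x)
    ll = -float(res.fun)
    converged = bool(res.success)

    p_rank = np.linalg.matrix_rank(X)
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    XtWX = (Xstar * w[:, None]).T @ Xstar
    beta = np.linalg.lstsq(XtWX, (Xstar * w[:, None]).T @ ystar, rcond=None)[0]
    r = ystar - Xstar @ beta
    sigma2_p = float(r @ (w * r)) / (n - p_rank)
    sigma2_a = h2 * sigma2_p / k_scale
    sigma2_e = (1.0 - h2) * sigma2_p

    boundary = h2 < 1e-4 or h2 > 1.0 - 1e-4
    se_h2 = _se_h2(h2, sigma2_p, lam, Xstar, w)
    return VarianceComponents(
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        h2=h2,
        se_h2=se_h2,
        loglik=ll,
        var_P=sigma2_p,
        converged=converged,
        boundary=boundary,
    )


def _se_h2(h2, sigma2_p, lam, Xstar, w) -> float:
    """Delta-method SE of h2 from the expected information of (s2a, s2e).

    On the eigenbasis, V = diag(s2a*lam + s2e); the REML projection P is
    V^-1 - V^-1 X (X'V^-1 X)^- X'V^-1 and I_jk = tr(P V_j P V_k)/2 with
    V_a = diag(lam), V_e = I.
    """
    n = len(lam)
    Vinv = w / sigma2_p
    WX = Xstar * Vinv[:, None]
    XtVX = Xstar.T @ WX
    try:
        P = np.diag(Vinv) - WX @ np.linalg.solve(XtVX, WX.T)
    except np.linalg.LinAlgError:
        P = np.diag(Vinv) - WX @ np.linalg.pinv(XtVX) @ WX.T
    PA = P * lam[None, :]  # P @ diag(lam)
    I_aa = 0.5 * np.sum(PA * PA.T)
    I_ae = 0.5 * np.sum(PA * P.T)
    I_ee = 0.5 * np.sum(P * P.T)
    info = np.array([[I_aa, I_ae], [I_ae, I_ee]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    s2a = h2 * sigma2_p
    s2e = (1 - h2) * sigma2_p
    tot = s2a + s2e
    grad = np.array([s2e, -s2a]) / tot**2
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def corrected_heritability(var_P_u: float, var_E_w: float) -> float:
    """h2_w = (Var(P_u) - Var(E_w)) / Var(P_u).

    Var(P_u): phenotypic variance from the unweighted-G reference fit;
    Var(E_w): residual variance from the weighted-G fit.  Values outside
    [0, 1] are returned as-is with a warning.
    """
    if var_P_u <= 0:
        raise ValueError("reference phenotypic variance must be positive")
    h2w = (var_P_u - var_E_w) / var_P_u
    if not 0.0 <= h2w <= 1.0:
        warnings.warn(f"corrected heritability {h2w:.3f} outside [0, 1]", stacklevel=2)
    return h2w


def predict_u(y: np.ndarray, X: np.ndarray | None, K: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """BLUP of animal genetic effects: u_hat = s2a K V^-1 (y - X beta_gls)."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    V = vc.sigma2_a * K + vc.sigma2_e * np.eye(n)
    Vinv = np.linalg.pinv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.lstsq(XtVX, X.T @ Vinv @ y, rcond=None)[0]
    return vc.sigma2_a * K @ Vinv @ (y - X @ beta)


def backsolve_snp_effects(M_star: np.ndarray, u_hat: np.ndarray) -> np.ndarray:
    """Back-solve per-SNP effects: a_hat = M*' [M* M*']^- u_hat.

    Uses the Moore-Penrose pseudo-inverse (relative cutoff 1e-10), so
    M* a_hat is the projection of u_hat onto the row space of M*.
    """
    M_star = np.asarray(M_star, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    if M_star.shape[0] != len(u_hat):
        raise ValueError("u_hat does not match rows of M_star")
    MMt = M_star @ M_star.T
    return M_star.T @ (np.linalg.pinv(MMt, rcond=1e-10) @ u_hat)


def snp_zscores(
    a_hat: np.ndarray, threshold: float = 4.0, snp_ids: list | None = None
) -> SnpEffects:
    """Standardize SNP effects to Z-scores and call |Z| >= threshold.

    Z_i = (a_i - mean(a)) / SD(a) using the sample (ddof=1) SD.
    """
    a_hat = np.asarray(a_hat, dtype=float).ravel()
    if len(a_hat) < 2:
        raise ValueError("need at least two SNP effects")
    mean_a = float(a_hat.mean())
    sd_a = float(a_hat.std(ddof=1))
    if sd_a == 0:
        raise ValueError("zero SD of SNP effects")
    z = (a_hat - mean_a) / sd_a
    if snp_ids is None:
        snp_ids = list(range(len(a_hat)))
    sig = [s for s, zi in zip(snp_ids, z) if abs(zi) >= threshold]
    return SnpEffects(
        snp_ids=list(snp_ids),
        a_hat=a_hat,
        z=z,
        mean_a=mean_a,
        sd_a=sd_a,
        significance_threshold=threshold,
        significant_ids=sig,
    )


def run_variant(
    genotypes: pd.DataFrame,
    weights: WeightTable,
    y: np.ndarray,
    X: np.ndarray | None,
    variant: AnalysisVariant,
    reference_fit: VarianceComponents | None = None,
    z_threshold: float = 4.0,
) -> tuple[VarianceComponents, SnpEffects, Grm]:
    """Fit one analysis variant end to end.

    Builds the variant's weighted/selected GRM, fits REML, applies the
    corrected heritability against ``reference_fit`` (required whenever
    weights enter G), back-solves SNP effects from the BLUP animal effects
    and standardizes them to Z-scores.
    """
    w = weights.weights
    if variant.label == "weighted_all":
        w_use = w.where(w > 0.0, weights.floor)
        geno = genotypes
        d = w_use
    else:
        kept = select_snps(weights, variant.t)
        geno = genotypes[kept]
        d = None if variant.label == "unweighted_threshold" else w.loc[kept]

    grm = build_grm(geno, d)
    vc = reml_fit(y, X, grm.G)
    weighted = variant.label in ("weighted_all", "weighted_threshold")
    if weighted:
        if reference_fit is None:
            raise ValueError("weighted variants require the unweighted reference fit")
        vc.var_P_u = reference_fit.var_P
        vc.var_E_w = vc.sigma2_e
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc.h2_corrected = corrected_heritability(vc.var_P_u, vc.var_E_w)
    u_hat = predict_u(y, X, grm.G, vc)
    a_hat = backsolve_snp_effects(grm.M_star, u_hat)
    effects = snp_zscores(a_hat, threshold=z_threshold, snp_ids=grm.snp_ids)
    return vc, effects, grm
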