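"""Synthetic inputs with the statistical structure the method assumes.

Every stage of the pipeline can be exercised without external data:

* a low-rank-plus-Gaussian-noise expression tensor (planted rank-1 modules
  with single-signed tissue patterns, one module optionally tied linearly
  to a simulated ADFI covariate),
* genotypes from Hardy-Weinberg allele frequencies on synthetic
  chromosomes, with a configurable fraction of SNP placed inside generated
  gene intervals,
* phenotypes with a chosen heritability under a supplied relationship
  matrix,
* electronic-feeder event records with a known fraction of aberrant events
  that each violate exactly one QC rule.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionTensor
from .phenotype_qc import QcThresholds


@dataclass
class PlantedComponent:
    lambda_: float
    gene_support: int  # number of genes with non-zero loading
    tissue_pattern: tuple  # per-tissue magnitudes (single-signed applied later)
    sign: str = "nonnegative"
    adfi_link: float = 0.0  # correlation-scale coupling of I_r to ADFI


@dataclass
class SimConfig:
    """Study-shaped defaults: 2000 genes x 30 individuals x 4 tissues with 3
    planted modules, 500 genotyped+phenotyped animals and 2000 SNP."""

    n_G: int = 2000
    n_I: int = 30
    n_T: int = 4
    components: list = field(default_factory=lambda: [
        PlantedComponent(lambda_=1500.0, gene_support=2000, tissue_pattern=(1, 1, 1, 1)),
        PlantedComponent(lambda_=900.0, gene_support=150, tissue_pattern=(1, 0, 0, 0), adfi_link=0.8),
        PlantedComponent(lambda_=600.0, gene_support=120, tissue_pattern=(0, 1, 1, 0), sign="nonpositive"),
    ])
    noise_sd: float = 1.0
    n_animals: int = 500
    m_snp: int = 2000
    maf_range: tuple = (0.05, 0.5)
    genic_fraction: float = 0.5
    n_chromosomes: int = 5
    h2_true: float = 0.4
    n_causal: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2_true <= 1):
            raise ValueError("h2_true must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def small_config(seed: int = 0) -> SimConfig:
    """Small preset for fast tests: 60 x 12 x 3 tensor, 80 animals, 60 SNP."""
    return SimConfig(
        n_G=60,
        n_I=12,
        n_T=3,
        components=[
            PlantedComponent(lambda_=80.0, gene_support=60, tissue_pattern=(1, 1, 1)),
            PlantedComponent(lambda_=40.0, gene_support=12, tissue_pattern=(1, 0, 0), adfi_link=0.8),
        ],
        noise_sd=0.5,
        n_animals=80,
        m_snp=60,
        n_chromosomes=2,
        n_causal=4,
        seed=seed,
    )


def study_config(seed: int = 0) -> SimConfig:
    """Study-shaped preset (the defaults)."""
    return SimConfig(seed=seed)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def simulate_tensor(
    config: SimConfig, seed: int | None = None
) -> tuple[ExpressionTensor, list, pd.DataFrame]:
    """Expression tensor Omega = sum_r lambda_r G_r x I_r x T_r + noise.

    Planted eigen-tissues are single-signed.  A component with
    ``adfi_link > 0`` has its eigen-individual built as a linear blend of
    the standardized ADFI covariate and independent noise, so downstream
    variance-partition and per-gene P-value stages have known truth
    (the component's supported genes are the planted ADFI-associated set).

    Returns (tensor, ground-truth components, covariate table with columns
    individual_id, adfi, cg, gender).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_G, n_I, n_T = config.n_G, config.n_I, config.n_T

    individual_ids = [f"ind{j:03d}" for j in range(n_I)]
    adfi = rng.normal(2.44, 0.35, size=n_I)  # kg/day, spanning divergent intake
    cg = np.array([f"cg{j % 4}" for j in range(n_I)])
    # gender blocked so each contemporary group has both sexes
    gender = np.array(["barrow" if (j // 4) % 2 == 0 else "gilt" for j in range(n_I)])
    covariates = pd.DataFrame(
        {"individual_id": individual_ids, "adfi": adfi, "cg": cg, "gender": gender}
    )

    adfi_std = (adfi - adfi.mean()) / adfi.std()
    omega = np.zeros((n_G, n_I, n_T))
    truth = []
    for comp in config.components:
        g = np.zeros(n_G)
        support = rng.choice(n_G, size=comp.gene_support, replace=False)
        g[support] = np.abs(rng.normal(1.0, 0.3, size=comp.gene_support))
        g = _unit(g)
        if comp.adfi_link > 0:
            raw = comp.adfi_link * adfi_std + np.sqrt(1 - comp.adfi_link**2) * rng.standard_normal(n_I)
            i_vec = _unit(raw)
        else:
            i_vec = _unit(np.abs(rng.normal(1.0, 0.3, size=n_I)))
        t_vec = np.asarray(comp.tissue_pattern, dtype=float)
        if len(t_vec) != n_T:
            raise ValueError("tissue_pattern length must equal n_T")
        t_vec = _unit(t_vec)
        if comp.sign == "nonpositive":
            t_vec = -t_vec
        omega += comp.lambda_ * np.einsum("g,i,k->gik", g, i_vec, t_vec)
        truth.append(
            {
                "lambda": comp.lambda_,
                "eigen_gene": g,
                "eigen_individual": i_vec,
                "eigen_tissue": t_vec,
                "support": np.sort(support),
                "adfi_link": comp.adfi_link,
                "sign": comp.sign,
            }
        )
    omega += config.noise_sd * rng.standard_normal(omega.shape)

    tensor = ExpressionTensor(
        omega=omega,
        gene_ids=[f"gene{i:05d}" for i in range(n_G)],
        individual_ids=individual_ids,
        tissue_ids=[f"tissue{k}" for k in range(n_T)],
    )
    return tensor, truth, covariates


def simulate_genotypes(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Hardy-Weinberg genotypes plus SNP map and gene intervals.

    Dosages are Binomial(2, p_i) with p_i uniform in ``maf_range``.  SNP are
    laid out on ``n_chromosomes`` synthetic chromosomes; a fraction
    ``genic_fraction`` of them falls inside generated gene intervals.

    Returns (genotypes animals x SNP, snp map [snp_id, chrom, pos],
    gene intervals [gene_id, chrom, start, end]).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config.m_snp
    p = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, p, size=(config.n_animals, m))
    animal_ids = [f"an{i:04d}" for i in range(config.n_animals)]
    snp_ids = [f"snp{i:05d}" for i in range(m)]

    chroms = np.sort(rng.integers(1, config.n_chromosomes + 1, size=m))
    gene_len = 20_000
    spacing = 50_000
    rows_snp, rows_gene = [], []
    gene_counter = 0
    pos_counter: dict[int, int] = {}
    genic = rng.random(m) < config.genic_fraction
    for i in range(m):
        c = int(chroms[i])
        pos_counter[c] = pos_counter.get(c, 0) + spacing
        base = pos_counter[c]
        if genic[i]:
            start = base
            end = base + gene_len - 1
            pos = int(rng.integers(start, end + 1))
            rows_gene.append((f"sgene{gene_counter:05d}", f"chr{c}", start, end))
            gene_counter += 1
            pos_counter[c] = end + spacing
        else:
            pos = base
        rows_snp.append((snp_ids[i], f"chr{c}", pos))

    genotypes = pd.DataFrame(dosages, index=animal_ids, columns=snp_ids)
    snp_map = pd.DataFrame(rows_snp, columns=["snp_id", "chrom", "pos"])
    gene_intervals = pd.DataFrame(rows_gene, columns=["gene_id", "chrom", "start", "end"])
    return genotypes, snp_map, gene_intervals


def simulate_phenotypes(
    K: np.ndarray, h2_true: float, n: int | None = None, seed: int | None = None, mu: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes y = mu + u + e with u ~ N(0, K h2) and var(e) = 1 - h2.

    Total expected variance is 1 (on the scale of an average K diagonal of
    1), so h2_true is the expected heritability.  Returns (y, u).
    """
    K = np.asarray(K, dtype=float)
    if n is None:
        n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("K does not match n")
    rng = np.random.default_rng(seed)
    eigvals, U = np.linalg.eigh(K)
    if eigvals[0] < -1e-8 * max(eigvals[-1], 1.0):
        raise ValueError("K is not PSD")
    eigvals = np.clip(eigvals, 0.0, None)
    L = U * np.sqrt(eigvals)
    if h2_true > 0:
        u = np.sqrt(h2_true) * (L @ rng.standard_normal(n))
    else:
        u = np.zeros(n)
    e = np.sqrt(1.0 - h2_true) * rng.standard_normal(n)
    return mu + u + e, u


def simulate_causal_scenario(
    n_animals: int = 500,
    m_snp: int = 400,
    n_causal: int = 10,
    n_decoy: int = 90,
    h2_true: float = 0.4,
    seed: int | None = None,
    maf_range: tuple = (0.05, 0.5),
):
    """Weighted-GWAS power scenario with known causal SNP.

    Half the SNP sit inside genes (one per gene).  ``n_causal`` genic SNP
    carry real phenotype effects scaled so the causal signal explains
    ``h2_true`` of the phenotypic variance; their genes get very small
    association P-values (weights > 5), as do ``n_decoy`` non-causal genic
    genes, so a weight threshold of 5 selects causal and decoy SNP
    together.  Remaining genes get uninformative P-values.

    Returns a dict with genotypes, snp_map, gene_intervals, gene_pvalues,
    causal_snp ids and phenotypes y.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_animals=n_animals, m_snp=m_snp, maf_range=maf_range,
        genic_fraction=0.5, seed=int(rng.integers(2**31)),
    )
    genotypes, snp_map, gene_intervals = simulate_genotypes(cfg)
    from .weighting import map_snps_to_genes  # local import avoids a cycle

    assignments = map_snps_to_genes(snp_map, gene_intervals)
    genic = assignments.dropna(subset=["gene_id"])
    genic_snp = list(genic["snp_id"])
    snp_to_gene = dict(zip(genic["snp_id"], genic["gene_id"]))

    chosen = rng.choice(len(genic_snp), size=n_causal + n_decoy, replace=False)
    causal_snp = [genic_snp[i] for i in chosen[:n_causal]]
    decoy_snp = [genic_snp[i] for i in chosen[n_causal:]]

    pvals = pd.Series(
        rng.uniform(0.05, 1.0, size=len(gene_intervals)), index=gene_intervals["gene_id"]
    )
    hot = [snp_to_gene[s] for s in causal_snp + decoy_snp]
    pvals.loc[hot] = 10.0 ** (-rng.uniform(5.5, 7.0, size=len(hot)))

    M = genotypes[causal_snp].to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    beta = rng.choice([-1.0, 1.0], size=n_causal)
    g = M @ beta
    g *= np.sqrt(h2_true) / g.std()
    e = rng.standard_normal(n_animals) * np.sqrt(1.0 - h2_true)
    y = 10.0 + g + e
    return {
        "genotypes": genotypes,
        "snp_map": snp_map,
        "gene_intervals": gene_intervals,
        "gene_pvalues": pvals,
        "causal_snp": causal_snp,
        "decoy_snp": decoy_snp,
        "assignments": assignments,
        "phenotypes": y,
    }


def simulate_feeding_events(
    n_animals: int = 20,
    n_days: int = 10,
    aberrant_fraction: float = 0.1,
    seed: int | None = None,
    events_per_day: int = 6,
    thresholds: QcThresholds | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feeder events with a known fraction of aberrant records.

    Normal events sit safely inside the QC bounds; each aberrant event
    violates exactly one labeled rule (duration, amount or rate).  Returns
    (events, truth) where ``truth`` holds the violated rule per event
    ("ok" for clean ones), indexed like ``events``.
    """
    if not 0 <= aberrant_fraction < 1:
        raise ValueError("aberrant_fraction must be in [0, 1)")
    thresholds = thresholds or QcThresholds()
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    pens = max(1, n_animals // 10)
    for a in range(n_animals):
        pen = f"pen{a % pens}"
        animal = f"an{a:04d}"
        for day in range(1, n_days + 1):
            for _ in range(events_per_day):
                aberrant = rng.random() < aberrant_fraction
                if not aberrant:
                    dur = rng.uniform(120, 1200)
                    # rate kept under half the limit, amount well inside bounds
                    max_amt = min(2.5, 0.5 * thresholds.max_rate_kg_min * dur / 60.0)
                    amt = rng.uniform(0.05, max(0.06, max_amt))
                    labels.append("ok")
                else:
                    # each aberrant event breaks exactly one rule, the
                    # others stay inside their bounds
                    rule = rng.choice(["duration", "amount", "rate"])
                    if rule == "duration":
                        if rng.random() < 0.5:
                            dur = 0.95  # below min; rate 0.021*60/0.95 ~ 1.3 stays legal
                            amt = 0.021
                        else:
                            dur = thresholds.max_duration_s + rng.uniform(1, 600)
                            amt = rng.uniform(0.1, 1.0)
                    elif rule == "amount":
                        dur = rng.uniform(300, 1800)
                        amt = float(rng.choice([0.01, thresholds.max_amount_kg + rng.uniform(0.1, 1.0)]))
                    else:  # rate: short visit, amount within bounds
                        dur = rng.uniform(30, 76)
                        amt = thresholds.max_rate_kg_min * dur / 60.0 * rng.uniform(1.05, 1.12)
                    labels.append(rule)
                rows.append((animal, pen, day, dur, amt))
    events = pd.DataFrame(rows, columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"])
    return events, pd.Series(labels, index=events.index, name="truth")
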