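"""End-to-end orchestration: tensor modules -> gene P-values -> SNP weights
-> three analysis variants per module and threshold, with reference fits.

``run_all`` takes in-memory inputs (tensor, covariates, genotypes, SNP map,
gene intervals, phenotypes, optional pedigree) and produces, per module r
and threshold t, the weighted-all / unweighted-threshold /
weighted-threshold variant fits, plus the unweighted all-SNP genomic and
pedigree reference fits.  The summary table carries h2, SE, corrected h2,
SNP count and h2-per-SNP for every row; a manifest records the
configuration hash and seed so reruns are bitwise comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .association import gene_adfi_pvalues, project_tensor, variance_partition
from .decomposition import decompose, permutation_cutoffs, top_genes
from .expression import ExpressionTensor
from .gwas import AnalysisVariant, reml_fit, run_variant
from .weighting import build_grm, build_nrm, map_snps_to_genes, snp_weights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    R: int = 10
    alpha: float = 0.005
    n_perm: int = 100
    thresholds: list = field(default_factory=lambda: [2.0, 5.0])
    floor: float = 0.00001
    z_threshold: float = 4.0
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    summary: pd.DataFrame
    variance_partitions: list
    weights_by_module: dict
    snp_effects: dict  # (module, t, variant_label) -> SnpEffects
    reference_fits: dict
    cutoffs: np.ndarray | None
    manifest: dict


def run_all(
    tensor: ExpressionTensor,
    covariates: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_map: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    phenotypes: np.ndarray,
    pedigree: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the full module-weighted GWAS workflow.

    ``phenotypes`` are per-animal adjusted intakes aligned to the rows of
    ``genotypes``.  A module x threshold variant whose SNP selection is
    empty yields a summary row with n_snp = 0 and NaN estimates instead of
    halting (degenerate outcome, logged); any other stage failure halts
    with the stage name.
    """
    config = config or RunConfig()
    y = np.asarray(phenotypes, dtype=float)

    # --- decomposition ---
    dec = decompose(tensor, R=config.R, tol=config.tol, max_iter=config.max_iter, seed=config.seed)
    cutoffs = None
    if config.n_perm > 0:
        null = permutation_cutoffs(
            tensor, R=config.R, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed, tol=config.tol, max_iter=config.max_iter,
        )
        cutoffs = null.cutoffs

    # --- module association ---
    partitions = []
    assoc_by_module = {}
    for r, comp in enumerate(dec.components, start=1):
        if comp.degenerate:
            logger.warning("module %d degenerate; skipped in association", r)
            continue
        partitions.append(variance_partition(comp.eigen_individual, covariates, module_index=r))
        projected = project_tensor(tensor, comp.eigen_tissue)
        assoc_by_module[r] = gene_adfi_pvalues(
            projected, covariates, gene_ids=tensor.gene_ids, module_index=r
        )

    # --- SNP weighting ---
    assignments = map_snps_to_genes(snp_map, gene_intervals)
    weights_by_module = {}
    for r, assoc in assoc_by_module.items():
        pv = assoc.set_index("gene_id")["p_value"]
        weights_by_module[r] = snp_weights(assignments, pv, mode="raw", floor=config.floor)

    # --- reference fits ---
    grm_ref = build_grm(genotypes)
    fit_genomic = reml_fit(y, None, grm_ref.G)
    reference_fits = {"genomic_unweighted": fit_genomic}
    n_all_snp = len(grm_ref.snp_ids)
    rows = [
        _row("genomic_unweighted", "reference", None, fit_genomic, None, n_all_snp),
    ]
    if pedigree is not None:
        A, ped_ids = build_nrm(pedigree)
        order = [ped_ids.index(a) for a in genotypes.index]
        fit_ped = reml_fit(y, None, A[np.ix_(order, order)])
        reference_fits["pedigree"] = fit_ped
        rows.append(_row("pedigree", "reference", None, fit_ped, None, n_all_snp))

    # --- variants ---
    snp_effects = {}
    for r, wt in sorted(weights_by_module.items()):
        for t in config.thresholds:
            for label in ("weighted_all", "unweighted_threshold", "weighted_threshold"):
                variant = AnalysisVariant(label=label, t=t, module_index=r)
                try:
                    vc, eff, grm = run_variant(
                        genotypes, wt, y, None, variant,
                        reference_fit=fit_genomic, z_threshold=config.z_threshold,
                    )
                except ValueError as exc:
                    if "no SNP pass threshold" in str(exc):
                        logger.warning("module %d t=%g %s: empty selection", r, t, label)
                        rows.append(_empty_row(f"module_{r}", label, t))
                        continue
                    raise RuntimeError(f"stage gwas failed (module {r}, t={t}, {label})") from exc
                snp_effects[(r, t, label)] = eff
                rows.append(_row(f"module_{r}", label, t, vc, eff, len(grm.snp_ids)))

    summary = pd.DataFrame(rows)
    summary["h2_per_snp"] = summary["h2"] / summary["n_snp"]

    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_genes": tensor.shape[0],
        "n_individuals": tensor.shape[1],
        "n_tissues": tensor.shape[2],
        "n_animals": len(y),
        "n_snp": genotypes.shape[1],
        "residual_norms": dec.residual_norms,
        "lambdas": [c.lambda_ for c in dec.components],
        "top_gene_counts": (
            [len(top_genes(c, cutoffs[i])) for i, c in enumerate(dec.components)]
            if cutoffs is not None else None
        ),
    }
    result = RunResult(
        summary=summary,
        variance_partitions=partitions,
        weights_by_module=weights_by_module,
        snp_effects=snp_effects,
        reference_fits=reference_fits,
        cutoffs=cutoffs,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), config)
    return result


def _row(dataset, variant, t, vc, eff, n_snp):
    weighted = variant in ("weighted_all", "weighted_threshold")
    h2 = vc.h2_corrected if (weighted and vc.h2_corrected is not None) else vc.h2
    return {
        "dataset": dataset,
        "variant": variant,
        "t": t,
        "h2": h2,
        "h2_raw": vc.h2,
        "se": vc.se_h2,
        "h2_corrected": vc.h2_corrected,
        "n_snp": n_snp,
        "n_significant": len(eff.significant_ids) if eff is not None else 0,
    }


def _empty_row(dataset, variant, t):
    return {
        "dataset": dataset, "variant": variant, "t": t, "h2": np.nan, "h2_raw": np.nan,
        "se": np.nan, "h2_corrected": np.nan, "n_snp": 0, "n_significant": 0,
    }


def summarize(result: RunResult) -> dict:
    """Union of significant SNP across modules plus per-analysis counts."""
    per_analysis = {}
    union: set = set()
    for (r, t, label), eff in result.snp_effects.items():
        ids = set(eff.significant_ids)
        per_analysis[f"module_{r}_t{t:g}_{label}"] = len(ids)
        union |= ids
    return {
        "unique_significant_snp": len(union),
        "significant_snp_ids": sorted(union),
        "per_analysis_counts": per_analysis,
    }


def _write_outputs(result: RunResult, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config.hash()}\n"
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write(header)
        result.summary.to_csv(fh, sep="\t", index=False)
    for (r, t, label), eff in result.snp_effects.items():
        df = pd.DataFrame(
            {
                "snp_id": eff.snp_ids,
                "a_hat": eff.a_hat,
                "z": eff.z,
                "significant": [s in set(eff.significant_ids) for s in eff.snp_ids],
            }
        )
        path = out_dir / f"snp_effects_module{r}_t{t:g}_{label}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
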