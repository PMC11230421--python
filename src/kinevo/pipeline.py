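"""End-to-end orchestration: mask -> site-model fits -> LRTs -> BEB ->
branch-site regimes -> ERC -> diversity joins -> summary tables.

Every randomized step draws its stream from one base seed via
``numpy.random.SeedSequence`` spawning, so a run is reproducible
byte-for-byte and per-gene failures never perturb other genes' results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .branch_site import (
    REGIMES,
    SpeciesFeatureConfig,
    branch_site_lrt,
    designate_foreground,
    fit_model_a,
)
from .codon_core import CodonAlignment, apply_column_mask, compute_f3x4
from .phylo import Phylogeny
from .site_models import (
    FitOptions,
    classify_omega_outliers,
    fit_model,
    fit_nested_pair,
    site_posteriors,
)

log = logging.getLogger("kinevo")

CATEGORIES = ("CCAN", "OUTER", "SAC", "Other")


@dataclass
class GeneRecord:
    name: str
    alignment: CodonAlignment
    tree: Phylogeny
    category: str = "Other"
    scores: np.ndarray | None = None  # per-column alignment confidence

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    df: int = 2
    mask_threshold: float = 0.93
    n_perm: int = 1000
    seed: int = 0
    restarts: int = 2
    maxiter: int = 200
    optimize_branch_lengths: bool = False
    beb_threshold: float = 0.95
    species_features: SpeciesFeatureConfig = field(
        default_factory=SpeciesFeatureConfig.default
    )


def _gene_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def run_manifest(config: PipelineConfig) -> dict:
    """Reproducibility record: package versions, seed and a config hash."""
    import hashlib
    import sys

    import scipy

    from . import __version__

    cfg_repr = repr(sorted(
        (k, repr(v)) for k, v in vars(config).items()
        if k != "species_features"
    ))
    return {
        "kinevo": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
    }


def _masked(gene: GeneRecord, cfg: PipelineConfig) -> CodonAlignment:
    if gene.scores is None:
        return gene.alignment
    return apply_column_mask(gene.alignment, gene.scores, cfg.mask_threshold)


def run_site_analysis(
    genes: list[GeneRecord], config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, dict, list[dict]]:
    """Per-gene site-model screen.

    For each gene: mask, fit M0 (estimating kappa), fit M1a/M2a/M7/M8 with
    kappa pinned at the M0 estimate, run both nested LRTs, and run BEB
    site identification for genes significant under M2a.  Returns the
    Table-1-style report, per-gene BEB tables, and isolated error records.
    """
    if not genes:
        raise ValueError("gene list is empty")
    rows, beb_tables, errors = [], {}, []
    for gi, gene in enumerate(genes):
        seed = _gene_seed(config.seed, gi)
        try:
            aln = _masked(gene, config)
            freqs = compute_f3x4(aln)
            base_opts = FitOptions(
                restarts=config.restarts, seed=seed, maxiter=config.maxiter,
                optimize_branch_lengths=config.optimize_branch_lengths,
            )
            m0 = fit_model(aln, gene.tree, "M0", base_opts, freqs=freqs)
            tree = m0.tree  # branch lengths possibly optimized under M0
            opts = FitOptions(
                restarts=config.restarts, seed=seed, maxiter=config.maxiter,
                fix_kappa=m0.kappa,
            )
            m1a, m2a, lrt12 = fit_nested_pair(
                aln, tree, ("M1a", "M2a"), opts, freqs=freqs,
                df=config.df, alpha=config.alpha,
            )
            m7, m8, lrt78 = fit_nested_pair(
                aln, tree, ("M7", "M8"), opts, freqs=freqs,
                df=config.df, alpha=config.alpha,
            )
            fits = {"M1a": m1a, "M2a": m2a, "M7": m7, "M8": m8}
            if lrt12.significant:
                beb_tables[gene.name] = site_posteriors(
                    aln, tree, fits["M2a"], method="BEB",
                    threshold=config.beb_threshold,
                )
            rows.append(
                {
                    "gene": gene.name,
                    "codons": aln.n_unmasked,
                    "n_species": aln.n_taxa,
                    "category": gene.category,
                    "kappa": m0.kappa,
                    "dnds_m0": m0.params["omega"],
                    "dnds_m2": fits["M2a"].mean_omega(),
                    "dnds_m8": fits["M8"].mean_omega(),
                    "m2_vs_m1_stat": lrt12.stat,
                    "m2_vs_m1_p": lrt12.p,
                    "m2_vs_m1_significant": lrt12.significant,
                    "m8_vs_m7_stat": lrt78.stat,
                    "m8_vs_m7_p": lrt78.p,
                    "m8_vs_m7_significant": lrt78.significant,
                }
            )
        except Exception as exc:  # per-gene isolation
            log.warning("gene %s failed: %s", gene.name, exc)
            errors.append({"gene": gene.name, "error": str(exc)})
    report = pd.DataFrame(rows)
    if len(report) >= 3:
        labels = classify_omega_outliers(
            dict(zip(report["gene"], report["dnds_m2"]))
        )
        report["outlier"] = report["gene"].map(labels)
    if len(report):
        for col in ("m2_vs_m1_p", "m8_vs_m7_p"):
            report[col + "_bh"] = stats.false_discovery_control(report[col])
    return report, beb_tables, errors


def run_branch_site_analysis(
    genes: list[GeneRecord],
    regimes: tuple[str, ...] = REGIMES,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, dict, list[dict]]:
    """Branch-site Model A screen over centromere-feature regimes.

    Returns the per-gene-per-regime LRT table, cross-regime overlap counts
    (how many genes are significant in exactly 1, 2, ... regimes), and
    isolated error records.
    """
    unknown = set(regimes) - set(REGIMES)
    if unknown:
        raise ValueError(f"unknown regimes: {sorted(unknown)}")
    rows, errors = [], []
    for gi, gene in enumerate(genes):
        seed = _gene_seed(config.seed, gi)
        try:
            aln = _masked(gene, config)
            freqs = compute_f3x4(aln)
            m0 = fit_model(
                aln, gene.tree, "M0",
                FitOptions(restarts=config.restarts, seed=seed,
                           maxiter=config.maxiter,
                           optimize_branch_lengths=config.optimize_branch_lengths),
                freqs=freqs,
            )
            opts = FitOptions(restarts=config.restarts, seed=seed,
                              maxiter=config.maxiter, fix_kappa=m0.kappa)
            for regime in regimes:
                try:
                    desig = designate_foreground(
                        m0.tree, config.species_features, regime
                    )
                    null = fit_model_a(aln, m0.tree, desig, fix_omega2=True,
                                       options=opts, freqs=freqs)
                    alt = fit_model_a(aln, m0.tree, desig, fix_omega2=False,
                                      options=opts, freqs=freqs)
                    lrt = branch_site_lrt(null, alt, df=config.df,
                                          alpha=config.alpha)
                    rows.append(
                        {
                            "gene": gene.name,
                            "regime": regime,
                            "lnL_null": null.lnL,
                            "lnL_alt": alt.lnL,
                            "stat": lrt.stat,
                            "p": lrt.p,
                            "significant": lrt.significant,
                            "omega2": alt.params["omega2"],
                            "n_foreground": desig.n_foreground,
                        }
                    )
                except Exception as exc:
                    log.warning("gene %s regime %s failed: %s",
                                gene.name, regime, exc)
                    errors.append({"gene": gene.name, "regime": regime,
                                   "error": str(exc)})
        except Exception as exc:
            log.warning("gene %s failed: %s", gene.name, exc)
            errors.append({"gene": gene.name, "regime": "*", "error": str(exc)})
    table = pd.DataFrame(rows)
    overlap: dict[str, int] = {}
    if len(table):
        per_gene = table[table["significant"]].groupby("gene").size()
        overlap = {
            "any": int((per_gene > 0).sum()),
            "1": int((per_gene == 1).sum()),
            "2+": int((per_gene >= 2).sum()),
        }
    return table, overlap, errors


def group_comparison(
    report: pd.DataFrame, grouping: str, value: str = "dnds_m2"
) -> dict:
    """Rank-based comparison of a statistic across gene groups.

    Two groups: Wilcoxon rank-sum; three or more: Kruskal-Wallis.  Groups
    with fewer than 2 members are skipped with a note.
    """
    groups = {
        name: sub[value].dropna().to_numpy()
        for name, sub in report.groupby(grouping)
    }
    kept = {k: v for k, v in groups.items() if len(v) >= 2}
    skipped = sorted(set(groups) - set(kept))
    out = {
        "groups": {k: {"n": len(v), "median": float(np.median(v))}
                   for k, v in kept.items()},
        "skipped": skipped,
    }
    if len(kept) < 2:
        out["note"] = "fewer than 2 usable groups: test skipped"
        return out
    samples = list(kept.values())
    if np.ptp(np.concatenate(samples)) == 0:  # identical constants everywhere
        out["test"], out["p"] = "degenerate", 1.0
        return out
    if len(kept) == 2:
        res = stats.mannwhitneyu(*samples, alternative="two-sided")
        out["test"], out["p"] = "wilcoxon_rank_sum", float(res.pvalue)
    else:
        res = stats.kruskal(*samples)
        out["test"], out["p"] = "kruskal_wallis", float(res.pvalue)
    return out
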