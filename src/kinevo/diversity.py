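"""Population nucleotide diversity (pi) from VCF variant sites over
BED-defined gene intervals, with Z-transformation and diversity vs
divergence comparisons.

Per-site pi is the proportion of chromosome pairs that differ,
2 j (n - j) / (n (n - 1)) for j alternate alleles among n called
chromosomes; per-gene pi averages site pi over the variant sites falling
in the gene interval (the vcftools ``--site-pi`` convention).  Genes with
no variant sites yield a missing value, not zero.  Only biallelic SNPs
are used; missing genotypes reduce n per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats


class DiversityError(ValueError):
    pass


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 1-based
    alt_count: int
    called: int

    def __post_init__(self):
        if not 0 <= self.alt_count <= self.called:
            raise DiversityError("alt_count must lie in [0, called]")


@dataclass
class GeneInterval:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    gene: str
    population: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise DiversityError(f"empty interval for {self.gene}")

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


def site_pi(j: int, n: int) -> float:
    """Proportion of differing chromosome pairs at one biallelic site."""
    if n < 2:
        raise DiversityError("site pi needs >= 2 called chromosomes")
    if not 0 <= j <= n:
        raise DiversityError("alt count out of range")
    return 2.0 * j * (n - j) / (n * (n - 1))


def read_bed(path, population: str = "") -> list[GeneInterval]:
    """BED (0-based half-open) with a name column."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GeneInterval(f[0], int(f[1]), int(f[2]),
                                    f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
                                    population))
    return out


def read_variant_sites(vcf_path, samples: list[str] | None = None) -> list[VariantSite]:
    """Biallelic SNPs from a VCF; multiallelic sites and indels are skipped."""
    vcf = VCF(str(vcf_path), samples=samples)
    sites = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        alt = called = 0
        for g in var.genotypes:
            for allele in g[:-1]:  # last entry is phasing flag
                if allele >= 0:
                    called += 1
                    if allele > 0:
                        alt += 1
        if called >= 2 and 0 < alt < called:  # polymorphic in the sample
            sites.append(VariantSite(var.CHROM, var.POS, alt, called))
    return sites


def gene_pi(sites: list[VariantSite], interval: GeneInterval) -> float:
    """Mean site pi over variant sites in the interval; NaN when none fall in."""
    vals = [
        site_pi(s.alt_count, s.called)
        for s in sites
        if s.chrom == interval.chrom and interval.contains(s.pos) and s.called >= 2
    ]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def gene_pi_table(
    vcf_path, intervals: list[GeneInterval], samples: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene pi for every interval, one population at a time."""
    sites = read_variant_sites(vcf_path, samples)
    rows = []
    for iv in intervals:
        in_gene = [
            s for s in sites if s.chrom == iv.chrom and iv.contains(s.pos)
        ]
        rows.append(
            {
                "gene": iv.gene,
                "population": iv.population,
                "n_sites": len(in_gene),
                "pi": gene_pi(sites, iv),
            }
        )
    return pd.DataFrame(rows)


def z_transform(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD); missing values preserved."""
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        raise DiversityError("Z-transform needs >= 2 non-missing values")
    sd = values[ok].std(ddof=1)
    if sd == 0:
        raise DiversityError("Z-transform undefined for constant values")
    out = np.full_like(values, np.nan)
    out[ok] = (values[ok] - values[ok].mean()) / sd
    return out


def diversity_divergence_report(
    pi_table: pd.DataFrame,
    omegas: dict[str, float],
    adaptive: dict[str, bool],
) -> dict:
    """Compare per-gene pi with divergence-based selection signals.

    Rank-sum test of pi between adaptively and non-adaptively evolving
    genes, plus Pearson and Spearman correlations of pi with the per-gene
    omega; stratified by population.
    """
    report = {}
    for pop, sub in pi_table.groupby("population"):
        sub = sub.dropna(subset=["pi"])
        sub = sub[sub["gene"].isin(omegas)]
        w = np.array([omegas[g] for g in sub["gene"]])
        p = sub["pi"].to_numpy()
        entry = {"n_genes": len(sub)}
        flags = np.array([adaptive.get(g, False) for g in sub["gene"]])
        if flags.sum() >= 2 and (~flags).sum() >= 2:
            u = stats.mannwhitneyu(p[flags], p[~flags], alternative="two-sided")
            entry["ranksum_p"] = float(u.pvalue)
            entry["pi_median_adaptive"] = float(np.median(p[flags]))
            entry["pi_median_other"] = float(np.median(p[~flags]))
        else:
            entry["ranksum_p"] = None
            entry["note"] = "group with < 2 members: rank-sum test skipped"
        if len(sub) >= 3 and np.ptp(p) > 0 and np.ptp(w) > 0:
            entry["pearson_r"], entry["pearson_p"] = map(float, stats.pearsonr(w, p))
            entry["spearman_r"], entry["spearman_p"] = map(float, stats.spearmanr(w, p))
        report[pop or "all"] = entry
    return report
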