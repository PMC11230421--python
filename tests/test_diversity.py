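"""Nucleotide diversity from VCF/BED: per-site pi, per-gene averaging,
Z-transform and diversity-divergence comparisons."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import kinevo as kv
from kinevo.diversity import DiversityError, GeneInterval, VariantSite


def brute_force_site_pi(j: int, n: int) -> float:
    """Fraction of differing chromosome pairs, by explicit enumeration."""
    chroms = [1] * j + [0] * (n - j)
    pairs = list(combinations(range(n), 2))
    diff = sum(chroms[a] != chroms[b] for a, b in pairs)
    return diff / len(pairs)


class TestSitePi:
    def test_pair_enumeration_example(self):
        assert kv.site_pi(1, 4) == pytest.approx(0.5)
        assert brute_force_site_pi(1, 4) == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        assert kv.site_pi(0, 10) == 0.0
        assert kv.site_pi(10, 10) == 0.0

    def test_exhaustive_agreement_up_to_n12(self):
        for n in range(2, 13):
            for j in range(n + 1):
                assert kv.site_pi(j, n) == pytest.approx(
                    brute_force_site_pi(j, n), abs=1e-12
                )

    def test_maximized_at_half(self):
        for n in (4, 8, 12):
            vals = [kv.site_pi(j, n) for j in range(n + 1)]
            assert int(np.argmax(vals)) == n // 2

    def test_too_few_chromosomes(self):
        with pytest.raises(DiversityError):
            kv.site_pi(0, 1)


class TestGenePi:
    def test_mean_of_sites(self):
        sites = [
            VariantSite("c", 150, 1, 4),   # pi 0.5
            VariantSite("c", 200, 1, 10),  # pi 0.2
        ]
        iv = GeneInterval("c", 100, 300, "g")
        assert kv.gene_pi(sites, iv) == pytest.approx(0.35)

    def test_halfopen_boundaries(self):
        """BED [start, end) covers 1-based positions start+1 .. end."""
        iv = GeneInterval("c", 100, 200, "g")
        inside_first = VariantSite("c", 101, 1, 4)
        at_start = VariantSite("c", 100, 1, 4)     # 0-based 99: outside
        at_end = VariantSite("c", 200, 1, 4)       # 0-based 199: last base
        past_end = VariantSite("c", 201, 1, 4)
        assert not np.isnan(kv.gene_pi([inside_first], iv))
        assert np.isnan(kv.gene_pi([at_start], iv))
        assert not np.isnan(kv.gene_pi([at_end], iv))
        assert np.isnan(kv.gene_pi([past_end], iv))

    def test_no_sites_is_missing_not_zero(self):
        iv = GeneInterval("c", 100, 200, "g")
        assert np.isnan(kv.gene_pi([], iv))

    def test_record_order_invariance(self):
        sites = [VariantSite("c", p, 2, 8) for p in (150, 120, 180)]
        iv = GeneInterval("c", 100, 300, "g")
        assert kv.gene_pi(sites, iv) == kv.gene_pi(sites[::-1], iv)


class TestVcfOracle:
    def _write(self, tmp_path, genotypes, positions, chrom="chr1"):
        """genotypes: (n_sites, n_samples) diploid tuples."""
        n_samples = len(genotypes[0])
        names = [f"s{i}" for i in range(n_samples)]
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom},length=100000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names),
        ]
        def allele(a):
            return "." if a < 0 else str(a)

        for pos, row in zip(positions, genotypes):
            gt = "\t".join("/".join(allele(a) for a in g) for g in row)
            lines.append(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gt}")
        p = tmp_path / "toy.vcf"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_gene_pi_matches_pairwise_difference_oracle(self, tmp_path):
        """Toy VCF, 5 sites over 2 genes: per-gene pi equals the average
        over chromosome pairs of their per-site differences."""
        rng = np.random.default_rng(8)
        n_samples = 6
        positions = [110, 140, 190, 1050, 1080]
        genotypes = [
            [tuple(rng.integers(0, 2, 2)) for _ in range(n_samples)]
            for _ in positions
        ]
        vcf = self._write(tmp_path, genotypes, positions)
        bed = tmp_path / "toy.bed"
        bed.write_text("chr1\t100\t1000\tgeneA\nchr1\t1000\t2000\tgeneB\n")
        table = kv.gene_pi_table(vcf, kv.read_bed(bed, "pop"))

        def oracle(site_rows):
            # chromosome-level matrix: 2*n_samples haplotypes per site
            per_site = []
            for row in site_rows:
                chroms = [a for g in row for a in g]
                if len(set(chroms)) < 2:
                    continue  # monomorphic: not a variant site
                pairs = list(combinations(range(len(chroms)), 2))
                per_site.append(
                    sum(chroms[a] != chroms[b] for a, b in pairs) / len(pairs)
                )
            return np.mean(per_site) if per_site else np.nan

        expected_a = oracle(genotypes[:3])
        expected_b = oracle(genotypes[3:])
        got_a = float(table[table.gene == "geneA"].pi.iloc[0])
        got_b = float(table[table.gene == "geneB"].pi.iloc[0])
        assert got_a == pytest.approx(expected_a, abs=1e-12)
        assert got_b == pytest.approx(expected_b, abs=1e-12)

    def test_missing_genotypes_reduce_n(self, tmp_path):
        vcf = self._write(
            tmp_path, [[(0, 1), (-1, -1), (1, 1)]], [150]
        )
        sites = kv.read_variant_sites(vcf)
        assert len(sites) == 1
        assert sites[0].called == 4
        assert sites[0].alt_count == 3

    def test_indels_and_multiallelics_skipped(self, tmp_path):
        p = tmp_path / "mix.vcf"
        p.write_text(
            "\n".join(
                [
                    "##fileformat=VCFv4.2",
                    "##contig=<ID=c,length=1000>",
                    '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
                    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1",
                    "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0",
                    "c\t20\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0",
                    "c\t30\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2",
                ]
            )
            + "\n"
        )
        sites = kv.read_variant_sites(p)
        assert [s.pos for s in sites] == [10]


class TestZTransform:
    def test_symmetric_triple(self):
        assert np.allclose(kv.z_transform([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        z = kv.z_transform(rng.uniform(0, 1, 50))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 20)
        z = kv.z_transform(x)
        assert np.allclose(kv.z_transform(z), z, atol=1e-12)

    def test_missing_preserved(self):
        z = kv.z_transform([1.0, np.nan, 3.0, 5.0])
        assert np.isnan(z[1])
        assert np.isfinite(z[[0, 2, 3]]).all()

    def test_constant_raises(self):
        with pytest.raises(DiversityError):
            kv.z_transform([2.0, 2.0, 2.0])


class TestDiversityDivergence:
    def _table(self, pis, pop="human"):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(pis))],
                "population": pop,
                "n_sites": 10,
                "pi": pis,
            }
        )

    def test_monotone_pi_of_omega_is_significant(self):
        rng = np.random.default_rng(3)
        omegas = {f"g{i}": w for i, w in enumerate(rng.uniform(0.05, 0.9, 40))}
        pis = [omegas[f"g{i}"] * 0.01 + rng.normal(0, 0.0005) for i in range(40)]
        report = kv.diversity_divergence_report(
            self._table(pis), omegas, {f"g{i}": False for i in range(40)}
        )
        entry = report["human"]
        assert entry["pearson_r"] > 0.5
        assert entry["pearson_p"] < 0.01
        assert entry["spearman_p"] < 0.01

    def test_single_adaptive_gene_skips_ranksum(self):
        rng = np.random.default_rng(4)
        omegas = {f"g{i}": w for i, w in enumerate(rng.uniform(0.05, 0.9, 10))}
        pis = list(rng.uniform(0.001, 0.01, 10))
        adaptive = {f"g{i}": i == 0 for i in range(10)}
        report = kv.diversity_divergence_report(self._table(pis), omegas, adaptive)
        entry = report["human"]
        assert entry["ranksum_p"] is None
        assert "pearson_r" in entry

    def test_null_ranksum_calibration(self):
        """Groups drawn from one distribution: rejection near nominal."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            pis = rng.uniform(0.001, 0.01, 30)
            adaptive = dict(
                zip([f"g{i}" for i in range(30)], rng.random(30) < 0.5)
            )
            omegas = {f"g{i}": 0.3 for i in range(30)}
            report = kv.diversity_divergence_report(
                self._table(list(pis)), omegas, adaptive
            )
            p = report["human"]["ranksum_p"]
            if p is not None and p < 0.05:
                rejections += 1
        assert rejections / n_rep < 0.11
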