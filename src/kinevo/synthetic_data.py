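"""Seeded generators for every input the pipeline consumes, with known
ground truth: codon alignments evolved under any fitted model family,
correlated or independent gene-tree pairs, per-column alignment
confidence scores, and toy VCF+BED bundles with analytically known pi.

The built-in ``paper17`` topology is a 17-taxon Euarchontoglires
cladogram (8 primates, 8 rodents, rabbit) with nominal uniform branch
lengths totalling 2.0 substitutions/codon on the unrooted tree — a test
fixture standing in for gene-specific branch lengths, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_core import (
    UNIVERSAL_CODE,
    CodonAlignment,
    CodonFrequencies,
    CodonModelError,
    GY94Params,
    GeneticCode,
    SpectralQ,
    build_rate_matrix,
    rate_linear_components,
    substitution_rate,
)
from .phylo import Phylogeny, read_newick
from .site_models import make_mixture

PAPER17_NEWICK = (
    "(((((((human,(chimpanzee,bonobo)),gorilla),orangutan),macaque),"
    "marmoset),mouse_lemur),"
    "((((((((house_mouse,steppe_mouse),algerian_mouse),ryukyu_mouse),"
    "shrew_mouse),rat),chinese_hamster),naked_mole_rat),rabbit));"
)


def paper17_tree(total_length: float = 2.0) -> Phylogeny:
    """The 17-taxon species cladogram with uniform branch lengths.

    Lengths are set so the unrooted tree (2*17 - 3 = 31 branches) sums to
    ``total_length``; the two root-adjacent branches each get half a unit
    so their merged unrooted branch has the common length.
    """
    t = read_newick(PAPER17_NEWICK)
    per = total_length / 31.0
    for i, nd in enumerate(t.nodes):
        if i == t.root:
            continue
        nd.length = per / 2.0 if nd.parent == t.root else per
    return t


@dataclass
class SimulationSpec:
    """Generative description of one synthetic gene alignment."""

    family: str  # M0 | M1a | M2a | M7 | M8 | ModelA
    params: dict  # natural parameters of the family (incl. kappa)
    n_codons: int
    seed: int
    tree: Phylogeny | None = None  # default: paper17
    freqs: CodonFrequencies | None = None  # default: uniform over sense codons
    foreground_nodes: set[int] = field(default_factory=set)  # ModelA only

    def resolved_tree(self) -> Phylogeny:
        return (self.tree or paper17_tree()).copy()


def _model_a_sim_classes(params: dict):
    from .branch_site import model_a_classes

    return model_a_classes(
        params["p0"], params["p1"], params["omega0"], params["omega2"]
    )


def simulate_alignment(
    spec: SimulationSpec, code: GeneticCode = UNIVERSAL_CODE
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons down the tree; returns (alignment, per-site class labels).

    Per site a class is drawn from the mixture, the root codon from the
    equilibrium frequencies, and each branch applies the transition matrix
    of its class (foreground branches use the class's foreground omega).
    All classes share one time scale — the mixture-average substitution
    rate over background omegas is one per unit branch length — so high-
    omega classes substitute proportionally faster, as under the fitted
    models.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.resolved_tree()
    freqs = spec.freqs or CodonFrequencies.uniform(code)
    if spec.family == "ModelA":
        class_omegas, weights = _model_a_sim_classes(spec.params)
    else:
        mix = make_mixture(spec.family, spec.params)
        class_omegas = [(w, w) for w in mix.omegas]
        weights = mix.weights
    kappa = spec.params["kappa"]

    comps = rate_linear_components(freqs, code)
    ref = float(
        sum(w * substitution_rate(kappa, bg, comps)
            for (bg, _), w in zip(class_omegas, weights))
    )
    spectral, scale = {}, {}
    for pair in class_omegas:
        for w in pair:
            if w not in spectral:
                Q = build_rate_matrix(GY94Params(kappa, w, freqs), code)
                spectral[w] = SpectralQ.decompose(Q, freqs.pi)
                scale[w] = substitution_rate(kappa, w, comps) / ref

    labels = rng.choice(len(class_omegas), size=spec.n_codons, p=weights)
    states = {tree.root: _draw(rng, np.tile(freqs.pi, (spec.n_codons, 1)))}
    order = [i for i in reversed(tree.postorder())]
    for i in order:
        if i == tree.root:
            continue
        nd = tree.nodes[i]
        parent_states = states[nd.parent]
        child = np.empty(spec.n_codons, dtype=np.int64)
        for k, (w_bg, w_fg) in enumerate(class_omegas):
            sel = labels == k
            if not sel.any():
                continue
            w = w_fg if nd.foreground else w_bg
            P = spectral[w].transition(nd.length * scale[w])
            child[sel] = _draw(rng, P[parent_states[sel]])
        states[i] = child
    taxa, rows = [], []
    for i in tree.leaves():
        taxa.append(tree.nodes[i].label)
        rows.append(states[i])
    return CodonAlignment(taxa, np.vstack(rows)), labels


def _draw(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw, one row of probabilities per sample."""
    c = probs.cumsum(axis=1)
    c /= c[:, -1:]
    u = rng.random((probs.shape[0], 1))
    return (u > c).sum(axis=1)


def simulate_column_scores(
    n_codons: int, seed: int, frac_low: float = 0.05, threshold: float = 0.93
) -> np.ndarray:
    """Per-column confidence scores: most near 1, a fraction below threshold."""
    rng = np.random.default_rng(seed)
    scores = 1.0 - rng.beta(1.0, 30.0, size=n_codons) * 0.07
    low = rng.random(n_codons) < frac_low
    scores[low] = rng.uniform(0.5, threshold - 1e-6, size=low.sum())
    return np.clip(scores, 0.0, 1.0)


def simulate_tree_pair(
    base: Phylogeny,
    shared_sigma: float,
    independent_sigma: float,
    seed: int,
) -> tuple[Phylogeny, Phylogeny]:
    """Two gene trees with lognormal branch-rate perturbations.

    Each branch length is multiplied by exp(shared*N + private*N'); the
    shared deviates are common to both trees, so shared_sigma >>
    independent_sigma yields strongly covarying trees.
    """
    rng = np.random.default_rng(seed)
    n = len(base.nodes)
    shared = rng.normal(size=n)
    out = []
    for _ in range(2):
        private = rng.normal(size=n)
        t = base.copy()
        for i, nd in enumerate(t.nodes):
            if i == t.root:
                continue
            nd.length *= float(
                np.exp(shared[i] * shared_sigma + private[i] * independent_sigma)
            )
        out.append(t)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Toy VCF + BED bundles
# ---------------------------------------------------------------------------

def simulate_vcf_bed(
    n_samples: int,
    n_genes: int,
    sites_per_gene: int,
    seed: int,
    freq_spectrum=None,
    chrom: str = "chr1",
    gene_span: int = 10_000,
    population: str = "pop",
) -> tuple[str, str, dict[str, float]]:
    """Emit VCF 4.2 text, BED text and the true per-gene pi.

    Diploid genotypes are drawn binomially at allele frequencies from
    ``freq_spectrum`` (default U(0.05, 0.95)); the recorded truth is the
    realized-genotype pi, so a round trip through the pi pipeline must
    reproduce it exactly.  Monomorphic draws are kept in the VCF but do
    not contribute to pi (truth is NaN for genes with no polymorphic site).
    """
    if n_samples < 1:
        raise CodonModelError("need at least one diploid sample")
    rng = np.random.default_rng(seed)
    if freq_spectrum is None:
        freq_spectrum = lambda r, size: r.uniform(0.05, 0.95, size=size)
    samples = [f"s{i}" for i in range(n_samples)]
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={n_genes * gene_span + 1000}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    vcf_lines, bed_lines = [], []
    truth: dict[str, float] = {}
    n_chrom = 2 * n_samples
    for g in range(n_genes):
        gene = f"gene{g}"
        start = g * gene_span
        end = start + gene_span
        bed_lines.append(f"{chrom}\t{start}\t{end}\t{gene}")
        positions = np.sort(
            rng.choice(np.arange(start + 1, end + 1), size=sites_per_gene, replace=False)
        )
        pis = []
        for pos in positions:
            f = float(freq_spectrum(rng, size=None))
            alleles = rng.random((n_samples, 2)) < f
            j = int(alleles.sum())
            gts = ["/".join(map(str, a.astype(int))) for a in alleles]
            vcf_lines.append(
                f"{chrom}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
            if 0 < j < n_chrom:
                pis.append(2.0 * j * (n_chrom - j) / (n_chrom * (n_chrom - 1)))
        truth[gene] = float(np.mean(pis)) if pis else float("nan")
    vcf_text = "\n".join(header + vcf_lines) + "\n"
    bed_text = "\n".join(bed_lines) + "\n"
    return vcf_text, bed_text, truth
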