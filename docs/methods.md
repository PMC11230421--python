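# Methods

This note documents the models, the numerical choices behind them, what
the synthetic-data generators do and do not emulate, and the package's
known limitations.

## Codon substitution model

The core is a Goldman–Yang-style codon model over the 61 sense codons of
the universal genetic code. Off-diagonal rates between codons differing
at exactly one nucleotide are

    q(i→j) ∝ π_j · κ^[transition] · ω^[nonsynonymous],

all multi-nucleotide changes have rate zero, and diagonals make rows sum
to zero. Equilibrium frequencies π follow the F3x4 construction: the
product of position-specific nucleotide frequencies estimated from the
unmasked alignment columns, renormalized over sense codons. Zero
positional counts receive a pseudocount of 1e-6 before normalization so
the generator stays irreducible. Only the universal nuclear code is
implemented.

The generator is reversible (detailed balance holds by construction), so
transition probabilities are computed by symmetrized eigendecomposition:
B = D^{1/2} Q D^{-1/2} with D = diag(π) is symmetric, `eigh` gives a real
spectrum, and P(t) = D^{-1/2} U e^{Λt} Uᵀ D^{1/2}. Tiny negative entries
from round-off are clamped at zero and rows renormalized. Reversibility
also makes the likelihood invariant to root placement, so rooted input
trees are used as stored (the pulley principle makes explicit unrooting
unnecessary).

### Time scale of site-class mixtures

A single class's generator scaled to one expected substitution per unit
time would make an ω = 4 site look as fast as an ω = 0.2 site. Instead,
all classes in a mixture share one time scale: the unnormalized flux
r(κ, ω) = a + bκ + cω + dκω (coefficients from the synonymous/
nonsynonymous, transition/transversion decomposition of the flux) scales
each class relative to the mixture-average rate Σ_k w_k r(κ, ω_k), which
is pinned to one substitution per codon per unit branch length. High-ω
classes therefore substitute proportionally faster — the property that
gives the site tests their power. For branch-site classes the average is
taken over background omegas, so background branches keep unit scale.

## Likelihood and optimization

Likelihoods use Felsenstein pruning with site-pattern compression; codons
containing gaps or ambiguous nucleotides are treated as missing data
(all-ones partial vectors), as are tree taxa absent from an alignment.
Masked columns (alignment-confidence score below the 0.93 threshold, the
GUIDANCE-style filter) are excluded from pattern construction, which makes
masking exactly equivalent to physically removing the columns.

Model fitting maximizes the likelihood with L-BFGS-B on transformed
coordinates (log κ, logit for proportions and for ω ∈ (0,1),
log(ω₂ − 1) for the positive class, log beta shapes), with bounds
ω ∈ [1e-4, 50], κ ∈ [0.05, 50], beta shapes ∈ [0.005, 99]. Each fit runs
from a family-specific default start plus optional jittered restarts
(seeded); the alternative families (M2a, M8) additionally always try a
near-null start, and `fit_nested_pair` warm-starts the alternative from
the fitted null — together these make lnL(alt) ≥ lnL(null) hold in
practice, not just in theory. Convergence is to ~1e-6 in lnL.

Two speed-relevant protocol choices, both configurable:

- **Branch lengths** are taken from the input gene tree by default.
  `optimize_branch_lengths` refits them once under M0 (coordinate-wise
  bounded Brent sweeps), after which they are frozen for all mixture and
  branch-site fits on that gene — the dominant practical protocol for
  site-model screens.
- **κ** can be pinned to the gene's M0 estimate (`fix_kappa`) for the
  mixture fits. Null and alternative then condition on the same κ, so the
  nested LRT is unaffected, and replicate studies run several-fold
  faster. The pipeline uses this protocol.

### Tests and site identification

Nested models are compared by 2ΔlnL against the χ² critical value at
df = 2 (5.99 at α = 0.05); "significant" means strictly greater. The
branch-site test also defaults to df = 2 with 5.99, with df = 1 (3.84)
available as the field-standard alternative. Per-gene p-values are
reported without multiple-testing correction (matching per-gene cutoff
usage); Benjamini–Hochberg columns are emitted alongside for reference.

M7/M8 discretize Beta(p, q) into 10 equal-probability classes at interval
medians (quantiles (k+0.5)/10) — medians rather than means to avoid
unstable incomplete-beta integrals at extreme shapes.

BEB integrates the class posteriors over a fixed parameter grid with an
equal-mass prior — proportions at triangle midpoints (p0, p1 ∈
{0.05,…,0.95}, p0+p1 ≤ 1), ω₀ over (0,1) and ω₂ over (1,11) at 10
midpoints each — weighting each grid point by its whole-alignment
likelihood with branch lengths, κ and the mixture time scale fixed at the
MLEs. The grid is defined for the three-proportion families, so BEB
covers M2a and branch-site Model A; M8 site identification uses NEB. The
reporting threshold for "selected" sites is posterior > 0.95.

The per-gene dN/dS summary is the mixture-weighted mean ω of the fitted
model (the weights times the class omegas), labelled as such in every
output table. Outlier labels over a gene set use the sample SD: "rapid"
above mean + 2·SD, "constrained" below mean − 1·SD, strict inequalities
(a constant set is all "typical").

## Branch-site Model A

Four site classes on a foreground/background branch partition: ω₀ on all
branches (weight p0), ω = 1 on all (p1), and two classes with ω₂ on the
foreground over ω₀ or 1 on the background, their weights splitting
1 − p0 − p1 in proportion p0 : p1. The null fixes ω₂ = 1; the
alternative frees ω₂ ≥ 1.

Foreground sets come from per-species centromere features (HOR status,
CENP-B-box abundance, clade), shipped as a YAML config for the 17-taxon
Euarchontoglires panel. A regime's foreground is its member species'
terminal branches plus, by default, every internal branch whose entire
descendant leaf set is in the regime (clade closure); a terminal-only
mode exists. Degenerate designations (all branches or none) are
rejected. The shrew mouse (*Mus pahari*) is grouped with the
CENP-B-absent species: only one of its chromosomes carries a high density
of CENP-B repeats.

## Evolutionary rate covariation

For each gene pair the trees are pruned to their shared taxa (≥ 4
required; degree-2 nodes collapse with summed lengths, conserving
leaf-to-leaf path lengths), rescaled to total length 1, and matched
branch-by-branch. Branch correspondence is by the bipartition each branch
induces on the unrooted tree, keyed by the sorted leaf labels of its
smaller side (lexicographic tie-break) — a deterministic, topology-safe
pairing that no published ordering convention pins down. The two
root-adjacent branches of a rooted input merge into one unrooted branch.

The statistic is the Pearson correlation of the matched scaled vectors
(invariant to the rescaling, which is affine per vector). Significance is
a one-sided permutation test — shuffle one tree's scaled lengths, 1000
permutations by default — with the add-one correction
p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1), so p is never zero. The
normalized tree distance is Σ|Δ|/2 ∈ [0, 1]: 0 for identical scaled
trees, approaching 1 at maximal discordance. Vectors with (numerically)
constant branch lengths leave r undefined; such pairs are flagged rather
than dropped silently.

## Nucleotide diversity

Per-site π for j alternate alleles among n called chromosomes is
2j(n−j)/(n(n−1)), the fraction of differing chromosome pairs. Per-gene π
averages site π over the *variant* sites inside the gene interval (the
vcftools `--site-pi` convention; averaging over all interval bases is not
the default). Genes without variant sites get a missing value, never
zero. Only biallelic SNPs are used; indels and multiallelic records are
skipped and missing genotypes reduce n per site. VCF positions are
1-based, BED intervals 0-based half-open, so a variant at 1-based
position p is inside [start, end) iff start < p ≤ end. Z-transformation
uses the sample SD (n−1) and preserves missing values. Populations
(e.g. mouse subspecies) are partitioned before any computation.

## Synthetic data

The generators produce every input the pipeline consumes, with ground
truth: alignments evolved site-by-site down the tree under any fitted
family (per-site class labels returned), correlated tree pairs via
lognormal multiplicative branch perturbations with shared and private
components, per-column confidence scores with a controlled fraction below
the mask threshold, and VCF/BED bundles whose true per-gene π is computed
analytically from the realized genotypes (so the pipeline must round-trip
it exactly). All generators are bitwise-reproducible under a fixed seed.

The built-in 17-taxon species topology carries nominal uniform branch
lengths totalling 2.0 substitutions/codon on the unrooted tree — a test
fixture, not an estimate; real gene trees have gene-specific lengths.
Default study conditions for the replicate experiments: κ = 2, nearly
neutral background (p0 = 0.8, ω₀ = 0.2) for null calibration, and a 10%
class at ω₂ = 4 for power — magnitudes typical of mammalian coding genes
and of strong positive selection respectively.

What the generators do **not** emulate: alignment error and indels (gaps
enter only via masking), recombination and rate variation beyond the
modelled classes, codon usage bias beyond F3x4, linkage between variant
sites, and realistic site-frequency spectra (toy VCFs draw allele
frequencies i.i.d.). Passing tests therefore demonstrate correctness and
statistical behaviour of the methods under their own assumptions, not
robustness to real-data pathologies such as misalignment — the reason
the masking step exists in the first place.

## Problem sizes and runtime

The replicate studies in the test suite run at 17 taxa with 200-codon
genes (null calibration, 200 replicates) and 500-codon genes (power, 100
replicates), with single-restart fits and M0-pinned κ; the model-
concordance panel uses 30 genes of 150 codons. These sizes give stable
rates (binomial SE ≤ ~4 points) while keeping a full run on one core in
the tens of minutes. The acceptance script uses smaller cohorts of the
same shape.

## Known limitations

- No analytic gradients: fits use finite differences, so very large
  gene-by-taxon problems are slower than codeml-class implementations.
- Branch lengths are not co-estimated with mixture parameters (M0
  protocol only); strongly misspecified input lengths bias ω estimates.
- BEB for M8 is not implemented (NEB is used, and flagged in outputs).
- χ²(df=2) for the branch-site test follows the published protocol here;
  the boundary-respecting df=1 mixture null is available but not default.
- The likelihood engine targets tens of taxa; it does not rescale partial
  vectors during pruning, so trees with many hundreds of leaves could
  underflow double precision.
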