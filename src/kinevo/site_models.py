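"""Site-class codon models (M0, M1a, M2a, M7, M8): maximum-likelihood
fitting, nested likelihood-ratio tests and empirical-Bayes identification
of positively selected sites.

Model families
--------------
M0   one omega class for the whole gene.
M1a  "nearly neutral": omega0 in (0,1) with weight p0, omega=1 with 1-p0.
M2a  M1a plus a positive-selection class omega2 >= 1.
M7   10 equal-weight classes at interval medians of Beta(p, q).
M8   the 10 beta classes scaled by p0, plus omega_s >= 1 with weight 1-p0.

Nested pairs (M1a vs M2a, M7 vs M8) are compared by 2*delta-lnL against a
chi-square critical value (df=2, cutoff 5.99 at alpha=0.05 by default);
"significant" means the statistic strictly exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .codon_core import (
    UNIVERSAL_CODE,
    CodonAlignment,
    CodonFrequencies,
    CodonModelError,
    compute_f3x4,
)
from .phylo import LikelihoodEngine, Phylogeny

FAMILIES = ("M0", "M1a", "M2a", "M7", "M8")
N_BETA_CLASSES = 10

OMEGA_MIN, OMEGA_MAX = 1e-4, 50.0
KAPPA_MIN, KAPPA_MAX = 0.05, 50.0
SHAPE_MIN, SHAPE_MAX = 0.005, 99.0


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

@dataclass
class SiteClassMixture:
    family: str
    omegas: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-10 or (self.weights < 0).any():
            raise CodonModelError("mixture weights must be a probability vector")
        expected = {"M0": 1, "M1a": 2, "M2a": 3,
                    "M7": N_BETA_CLASSES, "M8": N_BETA_CLASSES + 1}
        if self.family in expected and len(self.omegas) != expected[self.family]:
            raise CodonModelError(
                f"{self.family} must have {expected[self.family]} site classes"
            )

    @property
    def n_classes(self) -> int:
        return len(self.omegas)

    def mean_omega(self) -> float:
        """Mixture-weighted mean omega (the per-gene dN/dS summary)."""
        return float(self.weights @ self.omegas)


def discretize_beta(p: float, q: float, K: int = N_BETA_CLASSES) -> np.ndarray:
    """K equal-probability Beta(p, q) classes, each at its interval median."""
    if p <= 0 or q <= 0:
        raise CodonModelError("beta shapes must be positive")
    if K < 1:
        raise CodonModelError("K must be >= 1")
    quantiles = (np.arange(K) + 0.5) / K
    vals = stats.beta.ppf(quantiles, p, q)
    # extreme shapes can round the quantile to exactly 0 or 1 in floats;
    # class omegas must stay strictly inside (0, 1)
    return np.clip(vals, 1e-9, 1.0 - 1e-9)


def make_mixture(family: str, params: dict) -> SiteClassMixture:
    """Instantiate a mixture from a family's natural parameter dict."""
    if family == "M0":
        return SiteClassMixture("M0", [params["omega"]], [1.0])
    if family == "M1a":
        p0, w0 = params["p0"], params["omega0"]
        return SiteClassMixture("M1a", [w0, 1.0], [p0, 1.0 - p0])
    if family == "M2a":
        p0, p1 = params["p0"], params["p1"]
        return SiteClassMixture(
            "M2a",
            [params["omega0"], 1.0, params["omega2"]],
            [p0, p1, 1.0 - p0 - p1],
        )
    if family == "M7":
        vals = discretize_beta(params["p"], params["q"])
        return SiteClassMixture("M7", vals, np.full(N_BETA_CLASSES, 1.0 / N_BETA_CLASSES))
    if family == "M8":
        vals = discretize_beta(params["p"], params["q"])
        p0 = params["p0"]
        omegas = np.append(vals, params["omega_s"])
        weights = np.append(np.full(N_BETA_CLASSES, p0 / N_BETA_CLASSES), 1.0 - p0)
        return SiteClassMixture("M8", omegas, weights)
    raise CodonModelError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Knobs for the bounded multi-start optimizer.

    ``fix_kappa`` pins the transition/transversion ratio (e.g. to an M0
    estimate) so mixture fits optimize only their mixture parameters — a
    large speed-up in replicate studies with no effect on nested LRTs,
    since null and alternative then condition on the same kappa.
    """

    restarts: int = 3
    seed: int = 0
    maxiter: int = 200
    fix_kappa: float | None = None
    optimize_branch_lengths: bool = False
    init: dict | None = None


@dataclass
class ModelFit:
    family: str
    lnL: float
    params: dict
    kappa: float
    mixture: SiteClassMixture
    n_free: int
    converged: bool
    n_codons_used: int
    n_species: int
    freqs: CodonFrequencies = field(repr=False, default=None)
    tree: Phylogeny = field(repr=False, default=None)

    def mean_omega(self) -> float:
        return self.mixture.mean_omega()


def _clip01(x, lo=1e-6):
    return np.clip(x, lo, 1.0 - lo)


def _bexp(v):
    """exp with the argument capped: avoids overflow warnings on optimizer
    excursions (results land on the parameter bounds anyway)."""
    return np.exp(np.minimum(v, 100.0))


class _Family:
    """Transform between the optimizer vector and natural parameters."""

    def __init__(self, family: str, fix_kappa: float | None):
        self.family = family
        self.fix_kappa = fix_kappa
        names = {
            "M0": ["omega"],
            "M1a": ["p0", "omega0"],
            "M2a": ["p0", "p1", "omega0", "omega2"],
            "M7": ["p", "q"],
            "M8": ["p0", "p", "q", "omega_s"],
        }[family]
        self.names = (["kappa"] if fix_kappa is None else []) + names

    @property
    def n_free(self) -> int:
        return len(self.names)

    def pack(self, params: dict) -> np.ndarray:
        x = []
        for n in self.names:
            v = params[n]
            if n == "kappa":
                x.append(np.log(v))
            elif n in ("p0", "p1"):
                x.append(logit(_clip01(v)))
            elif n in ("omega0",):
                x.append(logit(_clip01(v)))
            elif n in ("omega2", "omega_s"):
                x.append(np.log(max(v - 1.0, 1e-6)))
            elif n in ("p", "q"):
                x.append(np.log(v))
            elif n == "omega":
                x.append(np.log(v))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> dict:
        out = {}
        for n, v in zip(self.names, x):
            if n == "kappa":
                out[n] = float(np.clip(_bexp(v), KAPPA_MIN, KAPPA_MAX))
            elif n in ("p0", "p1"):
                out[n] = float(expit(v))
            elif n == "omega0":
                out[n] = float(np.clip(expit(v), OMEGA_MIN, 1.0 - 1e-6))
            elif n in ("omega2", "omega_s"):
                out[n] = float(np.clip(1.0 + _bexp(v), 1.0, OMEGA_MAX))
            elif n in ("p", "q"):
                out[n] = float(np.clip(_bexp(v), SHAPE_MIN, SHAPE_MAX))
            elif n == "omega":
                out[n] = float(np.clip(_bexp(v), OMEGA_MIN, OMEGA_MAX))
        if "kappa" not in out:
            out["kappa"] = self.fix_kappa
        if self.family == "M2a":
            # keep the simplex feasible under independent logit coordinates
            s = out["p0"] + out["p1"]
            if s >= 1.0 - 1e-9:
                out["p0"] *= (1.0 - 1e-6) / s
                out["p1"] *= (1.0 - 1e-6) / s
        return out

    def default_start(self) -> dict:
        base = {
            "M0": {"omega": 0.3},
            "M1a": {"p0": 0.7, "omega0": 0.2},
            "M2a": {"p0": 0.65, "p1": 0.3, "omega0": 0.2, "omega2": 2.5},
            "M7": {"p": 0.8, "q": 1.6},
            "M8": {"p0": 0.9, "p": 0.8, "q": 1.6, "omega_s": 2.5},
        }[self.family]
        if self.fix_kappa is None:
            base["kappa"] = 2.0
        return base


def _neg_lnl(engine: LikelihoodEngine, fam: _Family):
    def fn(x):
        params = fam.unpack(x)
        mix = make_mixture(fam.family, params)
        val = engine.log_likelihood(
            params["kappa"], mix.weights, [(w, w) for w in mix.omegas]
        )
        return -val if np.isfinite(val) else 1e12

    return fn


def _optimize_branch_lengths(
    engine: LikelihoodEngine, kappa: float, omega: float, sweeps: int = 2
) -> None:
    """Coordinate-wise Brent optimization of branch lengths under one class."""
    tree = engine.tree
    for _ in range(sweeps):
        for i in range(len(tree.nodes)):
            if i == tree.root:
                continue

            def obj(t):
                tree.nodes[i].length = t
                engine._lengths[i] = t
                engine.invalidate()
                return -engine.log_likelihood(kappa, [1.0], [(omega, omega)])

            res = optimize.minimize_scalar(
                obj, bounds=(1e-8, 10.0), method="bounded",
                options={"xatol": 1e-5},
            )
            tree.nodes[i].length = float(res.x)
            engine._lengths[i] = float(res.x)
    engine.invalidate()


def fit_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    family: str,
    options: FitOptions = FitOptions(),
    freqs: CodonFrequencies | None = None,
) -> ModelFit:
    """Fit one site-model family by bounded multi-start L-BFGS-B.

    Branch lengths are held fixed at the tree's values unless
    ``options.optimize_branch_lengths`` is set, in which case they are
    optimized once under a single-class (M0-style) model and then frozen —
    the dominant practical protocol for site-model screens.
    """
    if family not in FAMILIES:
        raise CodonModelError(f"unknown model family {family!r}")
    if freqs is None:
        freqs = compute_f3x4(aln)
    work_tree = tree.copy()
    engine = LikelihoodEngine(aln, work_tree, freqs)
    if options.optimize_branch_lengths:
        pre = fit_model(
            aln, work_tree, "M0",
            FitOptions(restarts=1, seed=options.seed, fix_kappa=options.fix_kappa),
            freqs=freqs,
        )
        _optimize_branch_lengths(engine, pre.kappa, pre.params["omega"])

    fam = _Family(family, options.fix_kappa)
    fn = _neg_lnl(engine, fam)
    rng = np.random.default_rng(options.seed)
    start = dict(fam.default_start())
    if options.init:
        start.update({k: v for k, v in options.init.items() if k in fam.names})
    starts = [fam.pack(start)]
    # alternative families get a deterministic near-null start so the fit
    # can never land below the nested null optimum
    if family == "M2a":
        near_null = dict(start, p0=start["p0"] * 0.98, p1=(1 - start["p0"]) * 0.98,
                         omega2=1.0 + 1e-4)
        starts.append(fam.pack(near_null))
    elif family == "M8":
        starts.append(fam.pack(dict(start, p0=1 - 1e-4, omega_s=1.0 + 1e-4)))
    for _ in range(max(0, options.restarts - 1)):
        starts.append(starts[0] + rng.normal(0, 0.5, size=starts[0].size))

    best = None
    for xs in starts:
        res = optimize.minimize(
            fn, xs, method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": 1e-10, "eps": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    params = fam.unpack(best.x)
    mixture = make_mixture(family, params)
    converged = bool(np.isfinite(best.fun))
    return ModelFit(
        family=family,
        lnL=-float(best.fun),
        params=params,
        kappa=params["kappa"],
        mixture=mixture,
        n_free=fam.n_free,
        converged=converged,
        n_codons_used=engine.n_sites,
        n_species=aln.n_taxa,
        freqs=freqs,
        tree=work_tree,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

_NESTED = {("M1a", "M2a"), ("M7", "M8"), ("M0", "M1a"), ("M0", "M2a")}


def warm_start(null_fit: ModelFit, alt_family: str) -> dict:
    """Alternative-model starting values seeded from the fitted null.

    The near-boundary configuration guarantees the alternative optimum is
    at least the null's (up to optimizer tolerance).
    """
    p = null_fit.params
    if (null_fit.family, alt_family) == ("M1a", "M2a"):
        return {"p0": p["p0"] * 0.95, "p1": (1 - p["p0"]) * 0.95,
                "omega0": p["omega0"], "omega2": 2.5}
    if (null_fit.family, alt_family) == ("M7", "M8"):
        return {"p": p["p"], "q": p["q"], "p0": 0.95, "omega_s": 2.5}
    raise CodonModelError(f"no warm start for {null_fit.family} -> {alt_family}")


def fit_nested_pair(
    aln: CodonAlignment,
    tree: Phylogeny,
    pair: tuple[str, str] = ("M1a", "M2a"),
    options: FitOptions = FitOptions(),
    freqs: CodonFrequencies | None = None,
    df: int = 2,
    alpha: float = 0.05,
):
    """Fit a nested null/alternative site-model pair and run the LRT.

    The alternative fit is warm-started from the null's estimates (plus
    the family's own default and near-null starts), which both speeds it
    up and enforces lnL monotonicity under nesting in practice.
    """
    from dataclasses import replace

    null_fam, alt_fam = pair
    null_fit = fit_model(aln, tree, null_fam, options, freqs=freqs)
    alt_opts = replace(options, init=warm_start(null_fit, alt_fam))
    alt_fit = fit_model(aln, tree, alt_fam, alt_opts, freqs=freqs)
    lrt = likelihood_ratio_test(null_fit, alt_fit, df=df, alpha=alpha)
    return null_fit, alt_fit, lrt


@dataclass
class LRTResult:
    stat: float
    df: int
    critical: float
    p: float
    significant: bool


def likelihood_ratio_test(
    null_fit: ModelFit,
    alt_fit: ModelFit,
    df: int = 2,
    alpha: float = 0.05,
    families: tuple[str, str] | None = None,
) -> LRTResult:
    """Chi-square LRT of nested site models; significant iff stat > critical."""
    pair = families or (null_fit.family, alt_fit.family)
    if pair not in _NESTED and pair != ("null", "alt"):
        raise CodonModelError(f"models {pair} are not a supported nested pair")
    if not (null_fit.converged and alt_fit.converged):
        raise CodonModelError("LRT requires both fits to have converged")
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(stat, df, critical, p, stat > critical)


# ---------------------------------------------------------------------------
# Site identification (NEB / BEB)
# ---------------------------------------------------------------------------

@dataclass
class SitePosteriorTable:
    """Per-unmasked-codon posterior of the positive-selection class."""

    site_index: np.ndarray  # 1-based index within the unmasked alignment
    posterior: np.ndarray
    method: str  # "NEB" or "BEB"
    threshold: float
    ref_residue: np.ndarray | None = None  # reference-species residue numbers

    @property
    def selected(self) -> np.ndarray:
        return self.posterior > self.threshold


def reference_coordinates(aln: CodonAlignment, ref_taxon: str) -> np.ndarray:
    """Residue number in the reference species for each unmasked column.

    Columns where the reference codon is missing get 0.
    """
    from .codon_core import MISSING

    row = aln.sites[aln.taxa.index(ref_taxon)]
    residue = np.cumsum(row != MISSING)
    out = np.where(row != MISSING, residue, 0)
    return out[aln.mask]


def _neb(engine: LikelihoodEngine, mixture: SiteClassMixture, kappa: float):
    class_omegas = [(w, w) for w in mixture.omegas]
    ref = engine.mixture_rate(kappa, class_omegas, mixture.weights)
    L = engine.class_site_likelihoods(kappa, class_omegas, ref_rate=ref)
    post = mixture.weights[:, None] * L
    post /= post.sum(axis=0, keepdims=True)
    return post


def site_posteriors(
    aln: CodonAlignment,
    tree: Phylogeny,
    alt_fit: ModelFit,
    method: str = "BEB",
    threshold: float = 0.95,
    ref_taxon: str | None = None,
) -> SitePosteriorTable:
    """Posterior probability per site of the omega>1 class (M2a or M8).

    NEB evaluates class posteriors at the MLEs.  BEB (M2a only) averages
    them over a fixed grid on (p0, p1, omega0, omega2) with an equal-mass
    prior, weighting grid points by their data likelihood, which accounts
    for estimation uncertainty in the mixture parameters.
    """
    if alt_fit.family not in ("M2a", "M8"):
        raise CodonModelError("site identification needs a family with an omega>1 class")
    engine = LikelihoodEngine(aln, alt_fit.tree or tree, alt_fit.freqs or compute_f3x4(aln))
    if method == "NEB":
        post = _neb(engine, alt_fit.mixture, alt_fit.kappa)
        pos_post = post[-1] if alt_fit.family == "M8" else post[2]
    elif method == "BEB":
        if alt_fit.family != "M2a":
            raise CodonModelError("the BEB grid is defined for M2a; use NEB for M8")
        mix = alt_fit.mixture
        ref = engine.mixture_rate(
            alt_fit.kappa, [(w, w) for w in mix.omegas], mix.weights
        )
        pos_post = _beb_m2a(engine, alt_fit.kappa, ref)
    else:
        raise CodonModelError(f"unknown method {method!r}")
    per_site = engine.per_site(pos_post)
    ref = reference_coordinates(aln, ref_taxon) if ref_taxon else None
    return SitePosteriorTable(
        site_index=np.arange(1, per_site.size + 1),
        posterior=per_site,
        method=method,
        threshold=threshold,
        ref_residue=ref,
    )


def _beb_m2a(engine: LikelihoodEngine, kappa: float, ref_rate: float) -> np.ndarray:
    """BEB posterior of the positive class under M2a.

    Grid: omega0 and the proportions at midpoints 0.05..0.95 (10 points,
    pairs restricted to p0+p1<=1), omega2 at midpoints of U(1, 11).
    Branch lengths (and the mixture time scale) stay fixed at the MLEs.
    """
    d = 10
    mids = (np.arange(d) + 0.5) / d
    w0_grid = mids
    w2_grid = 1.0 + 10.0 * mids
    L0 = engine.class_site_likelihoods(
        kappa, [(w, w) for w in w0_grid], ref_rate=ref_rate
    )
    L1 = engine.class_site_likelihoods(kappa, [(1.0, 1.0)], ref_rate=ref_rate)[0]
    L2 = engine.class_site_likelihoods(
        kappa, [(w, w) for w in w2_grid], ref_rate=ref_rate
    )

    p_pairs = [(a, b) for a in mids for b in mids if a + b <= 1.0 + 1e-9]
    G = []
    for p0, p1 in p_pairs:
        for i0 in range(d):
            for i2 in range(d):
                G.append((p0, p1, i0, i2))
    p0s = np.array([g[0] for g in G])
    p1s = np.array([g[1] for g in G])
    i0s = np.array([g[2] for g in G])
    i2s = np.array([g[3] for g in G])
    p2s = 1.0 - p0s - p1s

    site = (
        p0s[:, None] * L0[i0s]
        + p1s[:, None] * L1[None, :]
        + p2s[:, None] * L2[i2s]
    )  # (G, n_pat)
    site = np.maximum(site, 1e-300)
    loglik = np.log(site) @ engine.counts
    logw = loglik - loglik.max()
    w = np.exp(logw)
    w /= w.sum()
    class2 = p2s[:, None] * L2[i2s] / site
    return w @ class2


# ---------------------------------------------------------------------------
# Outlier classification
# ---------------------------------------------------------------------------

def classify_omega_outliers(omegas: dict[str, float]) -> dict[str, str]:
    """Label genes rapid / constrained / typical by omega relative to the set.

    rapid: omega strictly above mean + 2 SD; constrained: strictly below
    mean - 1 SD (sample SD over all supplied genes).
    """
    if len(omegas) < 3:
        raise CodonModelError("outlier classification needs >= 3 genes")
    vals = np.array(list(omegas.values()), dtype=float)
    mean, sd = vals.mean(), vals.std(ddof=1)
    out = {}
    for g, w in omegas.items():
        if w > mean + 2 * sd:
            out[g] = "rapid"
        elif w < mean - sd:
            out[g] = "constrained"
        else:
            out[g] = "typical"
    return out
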