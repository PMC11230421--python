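"""Branch-site Model A: positive selection restricted to prespecified
foreground lineages.

Model A has four site classes on a tree whose branches are partitioned
into foreground and background sets:

    class 0   omega0 (<1) on every branch          weight p0
    class 1   omega = 1 on every branch            weight p1
    class 2a  omega0 background / omega2 foreground
    class 2b  1      background / omega2 foreground

with the weights of 2a/2b equal to (1-p0-p1) split in proportion p0:p1.
The null model fixes omega2 = 1; the alternative estimates omega2 >= 1.
The two are compared by a chi-square LRT (df=2, cutoff 5.99 by default,
with the field-standard df=1 available as an option).

Foreground sets are derived from per-species centromere features:
clade membership (rodents / primates), higher-order-repeat (HOR)
satellite structure, and high abundance of functional CENP-B boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import optimize
from scipy.special import expit, logit

from .codon_core import (
    CodonAlignment,
    CodonFrequencies,
    CodonModelError,
    compute_f3x4,
)
from .phylo import LikelihoodEngine, Phylogeny, TreeError
from .site_models import (
    _bexp,
    KAPPA_MAX,
    KAPPA_MIN,
    OMEGA_MAX,
    OMEGA_MIN,
    FitOptions,
    LRTResult,
    likelihood_ratio_test,
    ModelFit,
)

REGIMES = ("rodents", "primates", "cenpb_high", "hor")


# ---------------------------------------------------------------------------
# Species features
# ---------------------------------------------------------------------------

@dataclass
class SpeciesFeatureConfig:
    """Per-species centromere features: HOR status, CENP-B-box status, clade."""

    hor: set[str]
    cenpb_high: set[str]
    clades: dict[str, str]  # species -> primate | rodent | lagomorph

    @classmethod
    def default(cls) -> "SpeciesFeatureConfig":
        text = (
            resources.files("kinevo").joinpath("data/species_features.yaml").read_text()
        )
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml_text(cls, text: str) -> "SpeciesFeatureConfig":
        doc = yaml.safe_load(text)
        return cls(
            hor=set(doc["hor"]),
            cenpb_high=set(doc["cenpb_high"]),
            clades=dict(doc["clades"]),
        )

    def members(self, regime: str) -> set[str]:
        if regime == "rodents":
            return {s for s, c in self.clades.items() if c == "rodent"}
        if regime == "primates":
            return {s for s, c in self.clades.items() if c == "primate"}
        if regime == "cenpb_high":
            return set(self.cenpb_high)
        if regime == "hor":
            return set(self.hor)
        raise CodonModelError(f"unknown regime {regime!r}")


@dataclass
class ForegroundDesignation:
    regime: str
    foreground_nodes: set[int]  # node indices whose parent branch is foreground
    n_foreground: int = 0

    def __post_init__(self):
        self.n_foreground = len(self.foreground_nodes)


def designate_foreground(
    tree: Phylogeny,
    config: SpeciesFeatureConfig,
    regime: str,
    terminal_only: bool = False,
) -> ForegroundDesignation:
    """Mark the branches of a feature regime as foreground.

    Terminal branches of member species are always foreground; by default
    an internal branch is foreground iff every leaf below it is a member
    (clade closure).  ``terminal_only`` restricts to terminal branches.
    """
    members = config.members(regime) & set(tree.leaf_labels())
    if not members:
        raise TreeError(f"regime {regime!r} selects no species on this tree")
    fg: set[int] = set()
    for i in range(len(tree.nodes)):
        if i == tree.root:
            continue
        below = tree.leafset_below(i)
        if tree.is_leaf(i):
            if tree.nodes[i].label in members:
                fg.add(i)
        elif not terminal_only and below <= members:
            fg.add(i)
    n_branches = len(tree.nodes) - 1
    if not fg or len(fg) >= n_branches:
        raise TreeError(
            f"regime {regime!r} designates {len(fg)} of {n_branches} branches: "
            "foreground must be a non-empty proper subset"
        )
    return ForegroundDesignation(regime, fg)


def tag_tree(tree: Phylogeny, designation: ForegroundDesignation) -> Phylogeny:
    t = tree.copy()
    for i in range(len(t.nodes)):
        t.nodes[i].foreground = i in designation.foreground_nodes
    return t


# ---------------------------------------------------------------------------
# Model A
# ---------------------------------------------------------------------------

def model_a_classes(
    p0: float, p1: float, omega0: float, omega2: float
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Model A (background, foreground) omegas and weights for 4 site classes."""
    rest = max(0.0, 1.0 - p0 - p1)
    denom = p0 + p1
    if denom <= 0:
        raise CodonModelError("p0 + p1 must be positive in Model A")
    w = np.array([p0, p1, rest * p0 / denom, rest * p1 / denom])
    omegas = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
    return omegas, w


@dataclass
class BranchSiteFit:
    lnL: float
    params: dict  # p0, p1, omega0, omega2, kappa
    kappa: float
    regime: str
    null: bool  # True when omega2 was fixed at 1
    converged: bool
    n_free: int
    freqs: CodonFrequencies = None
    tree: Phylogeny = None  # tagged tree used for the fit


def _pack_bs(params: dict, fix_omega2: bool, fix_kappa: float | None) -> np.ndarray:
    ptot = np.clip(params["p0"] + params["p1"], 1e-6, 1 - 1e-6)
    frac = np.clip(params["p0"] / max(ptot, 1e-12), 1e-6, 1 - 1e-6)
    x = [logit(ptot), logit(frac), logit(np.clip(params["omega0"], 1e-6, 1 - 1e-6))]
    if not fix_omega2:
        x.append(np.log(max(params["omega2"] - 1.0, 1e-6)))
    if fix_kappa is None:
        x.insert(0, np.log(params.get("kappa", 2.0)))
    return np.array(x)


def _unpack_bs(x: np.ndarray, fix_omega2: bool, fix_kappa: float | None) -> dict:
    i = 0
    if fix_kappa is None:
        kappa = float(np.clip(_bexp(x[0]), KAPPA_MIN, KAPPA_MAX))
        i = 1
    else:
        kappa = fix_kappa
    ptot = float(expit(x[i]))
    frac = float(expit(x[i + 1]))
    omega0 = float(np.clip(expit(x[i + 2]), OMEGA_MIN, 1 - 1e-6))
    omega2 = 1.0 if fix_omega2 else float(np.clip(1.0 + _bexp(x[i + 3]), 1.0, OMEGA_MAX))
    return {
        "kappa": kappa,
        "p0": ptot * frac,
        "p1": ptot * (1 - frac),
        "omega0": omega0,
        "omega2": omega2,
    }


def fit_model_a(
    aln: CodonAlignment,
    tree: Phylogeny,
    designation: ForegroundDesignation,
    fix_omega2: bool = False,
    options: FitOptions = FitOptions(),
    freqs: CodonFrequencies | None = None,
) -> BranchSiteFit:
    """Fit branch-site Model A (null when ``fix_omega2``, else alternative)."""
    if freqs is None:
        freqs = compute_f3x4(aln)
    tagged = tag_tree(tree, designation)
    engine = LikelihoodEngine(aln, tagged, freqs)

    def neg(x):
        p = _unpack_bs(x, fix_omega2, options.fix_kappa)
        omegas, w = model_a_classes(p["p0"], p["p1"], p["omega0"], p["omega2"])
        val = engine.log_likelihood(p["kappa"], w, omegas)
        return -val if np.isfinite(val) else 1e12

    start = {"p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega2": 2.5, "kappa": 2.0}
    if options.init:
        start.update(options.init)
    x0 = _pack_bs(start, fix_omega2, options.fix_kappa)
    rng = np.random.default_rng(options.seed)
    best = None
    for r in range(max(1, options.restarts)):
        xs = x0 if r == 0 else x0 + rng.normal(0, 0.5, size=x0.size)
        res = optimize.minimize(
            neg, xs, method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": 1e-10, "eps": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack_bs(best.x, fix_omega2, options.fix_kappa)
    n_free = len(best.x)
    return BranchSiteFit(
        lnL=-float(best.fun),
        params=params,
        kappa=params["kappa"],
        regime=designation.regime,
        null=fix_omega2,
        converged=bool(np.isfinite(best.fun)),
        n_free=n_free,
        freqs=freqs,
        tree=tagged,
    )


def branch_site_lrt(
    null_fit: BranchSiteFit,
    alt_fit: BranchSiteFit,
    df: int = 2,
    alpha: float = 0.05,
) -> LRTResult:
    """LRT of Model A alternative vs null (omega2 = 1)."""
    null_as = ModelFit("null", null_fit.lnL, null_fit.params, null_fit.kappa,
                       None, null_fit.n_free, null_fit.converged, 0, 0)
    alt_as = ModelFit("alt", alt_fit.lnL, alt_fit.params, alt_fit.kappa,
                      None, alt_fit.n_free, alt_fit.converged, 0, 0)
    return likelihood_ratio_test(null_as, alt_as, df=df, alpha=alpha,
                                 families=("null", "alt"))


# ---------------------------------------------------------------------------
# BEB on foreground lineages
# ---------------------------------------------------------------------------

def model_a_site_posteriors(
    aln: CodonAlignment,
    tree_or_fit,
    alt_fit: BranchSiteFit | None = None,
) -> np.ndarray:
    """BEB posterior, per unmasked site, of the foreground omega>1 classes.

    Averages class posteriors over a fixed grid — proportions (p0, p1) at
    triangle midpoints, omega0 over (0,1), omega2 over (1,11), all at 10
    points — weighting each grid point by its whole-data likelihood.
    Reports P(class 2a) + P(class 2b).
    """
    if alt_fit is None:
        alt_fit = tree_or_fit
        tree = alt_fit.tree
    else:
        tree = tree_or_fit
    engine = LikelihoodEngine(aln, tree, alt_fit.freqs or compute_f3x4(aln))
    kappa = alt_fit.kappa
    mle = alt_fit.params
    mle_omegas, mle_w = model_a_classes(
        mle["p0"], mle["p1"], mle["omega0"], mle["omega2"]
    )
    ref = engine.mixture_rate(kappa, mle_omegas, mle_w)  # time scale at the MLEs
    d = 10
    mids = (np.arange(d) + 0.5) / d
    w0_grid = mids
    w2_grid = 1.0 + 10.0 * mids

    L0 = engine.class_site_likelihoods(kappa, [(w, w) for w in w0_grid], ref_rate=ref)
    L1 = engine.class_site_likelihoods(kappa, [(1.0, 1.0)], ref_rate=ref)[0]
    L2b = engine.class_site_likelihoods(
        kappa, [(1.0, w2) for w2 in w2_grid], ref_rate=ref
    )
    L2a = np.empty((d, d, engine.n_pat))  # [i0, i2]
    for i0, w0 in enumerate(w0_grid):
        L2a[i0] = engine.class_site_likelihoods(
            kappa, [(w0, w2) for w2 in w2_grid], ref_rate=ref
        )

    pairs = [(a, b) for a in mids for b in mids if a + b <= 1.0 + 1e-9]
    total_pos = np.zeros(engine.n_pat)
    logliks, pos_parts = [], []
    for p0, p1 in pairs:
        _, w = model_a_classes(p0, p1, 0.5, 2.0)  # only weights needed
        for i0 in range(d):
            for i2 in range(d):
                site = (
                    w[0] * L0[i0] + w[1] * L1 + w[2] * L2a[i0, i2] + w[3] * L2b[i2]
                )
                site = np.maximum(site, 1e-300)
                logliks.append(np.log(site) @ engine.counts)
                pos_parts.append((w[2] * L2a[i0, i2] + w[3] * L2b[i2]) / site)
    logliks = np.array(logliks)
    wts = np.exp(logliks - logliks.max())
    wts /= wts.sum()
    total_pos = wts @ np.array(pos_parts)
    return engine.per_site(total_pos)
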