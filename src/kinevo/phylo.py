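"""Phylogeny representation, Newick I/O, tree surgery and the pruning
(Felsenstein) likelihood for codon site-class mixtures.

Branch lengths are in expected substitutions per codon site.  The codon
model is time-reversible, so likelihoods are invariant to root placement
(pulley principle) and are computed directly on the stored rooted shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np

from .codon_core import (
    MISSING,
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


class TreeError(ValueError):
    pass


@dataclass
class Node:
    parent: int | None
    children: list[int] = field(default_factory=list)
    label: str | None = None
    length: float = 0.0  # branch length to parent (root: ignored)
    foreground: bool = False  # branch tag used by branch-site models


class Phylogeny:
    """Rooted tree with branch lengths and optional foreground branch tags."""

    def __init__(self, nodes: list[Node], root: int = 0):
        self.nodes = nodes
        self.root = root
        self._validate()

    def _validate(self):
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("leaf labels must be unique")
        for i, nd in enumerate(self.nodes):
            if nd.length < 0:
                raise TreeError(f"negative branch length at node {i}")

    # -- basic queries ---------------------------------------------------

    def is_leaf(self, i: int) -> bool:
        return not self.nodes[i].children

    def leaves(self) -> list[int]:
        return [i for i in range(len(self.nodes)) if self.is_leaf(i)]

    def leaf_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.leaves()]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.nodes[i].children)
        return order[::-1]

    def total_length(self) -> float:
        return sum(nd.length for i, nd in enumerate(self.nodes) if i != self.root)

    def leafset_below(self, i: int) -> frozenset[str]:
        out = []
        stack = [i]
        while stack:
            j = stack.pop()
            if self.is_leaf(j):
                out.append(self.nodes[j].label)
            stack.extend(self.nodes[j].children)
        return frozenset(out)

    def copy(self) -> "Phylogeny":
        nodes = [
            Node(n.parent, list(n.children), n.label, n.length, n.foreground)
            for n in self.nodes
        ]
        return Phylogeny(nodes, self.root)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes: list[Node] = []
        index: dict = {}
        for nd in dtree.preorder_node_iter():
            parent = index[nd.parent_node] if nd.parent_node is not None else None
            label = nd.taxon.label if nd.taxon is not None else nd.label
            length = float(nd.edge.length) if nd.edge.length is not None else 0.0
            index[nd] = len(nodes)
            nodes.append(Node(parent, [], label, length))
            if parent is not None:
                nodes[parent].children.append(index[nd])
        return cls(nodes)

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            nd = self.nodes[i]
            if self.is_leaf(i):
                body = nd.label or ""
            else:
                body = "(" + ",".join(rec(c) for c in nd.children) + ")"
            if i == self.root:
                return body
            return f"{body}:{nd.length:.10g}"

        return rec(self.root) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string; missing branch lengths default to 0."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: Phylogeny, path):
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep: set[str]) -> Phylogeny:
    """Restrict to the given leaf set, collapsing degree-2 nodes (lengths sum).

    Leaf-to-leaf path lengths among retained taxa are conserved.
    """
    keep = set(keep)
    have = set(tree.leaf_labels())
    if not keep <= have:
        raise TreeError(f"taxa not in tree: {sorted(keep - have)}")
    t = tree.copy()
    # iteratively drop unkept leaves and childless internals
    changed = True
    while changed:
        changed = False
        for i in range(len(t.nodes)):
            nd = t.nodes[i]
            if nd.parent is None:
                continue
            alive = i in t.nodes[nd.parent].children
            if not alive:
                continue
            if not nd.children and (nd.label not in keep or nd.label is None):
                t.nodes[nd.parent].children.remove(i)
                changed = True
    # collapse degree-2 internals; reroot if root left with one child
    def collapse():
        nonlocal t
        changed = True
        while changed:
            changed = False
            for i in range(len(t.nodes)):
                nd = t.nodes[i]
                if i == t.root:
                    if len(nd.children) == 1:
                        c = nd.children[0]
                        t.nodes[c].parent = None
                        t.nodes[c].length = 0.0
                        t.root = c
                        changed = True
                    continue
                if nd.parent is None or i not in t.nodes[nd.parent].children:
                    continue
                if len(nd.children) == 1 and nd.label is None:
                    c = nd.children[0]
                    t.nodes[c].length += nd.length
                    t.nodes[c].parent = nd.parent
                    p = t.nodes[nd.parent]
                    p.children[p.children.index(i)] = c
                    changed = True

    collapse()
    # re-index to a compact node list
    return _reindex(t)


def _reindex(t: Phylogeny) -> Phylogeny:
    order = []
    stack = [t.root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(t.nodes[i].children)
    remap = {old: new for new, old in enumerate(order)}
    nodes = []
    for old in order:
        nd = t.nodes[old]
        nodes.append(
            Node(
                remap[nd.parent] if nd.parent is not None else None,
                [remap[c] for c in nd.children],
                nd.label,
                nd.length,
                nd.foreground,
            )
        )
    return Phylogeny(nodes, 0)


def prune_to_shared_taxa(
    t1: Phylogeny, t2: Phylogeny, min_overlap: int = 4
) -> tuple[Phylogeny, Phylogeny]:
    """Prune both trees to their shared taxon set (>= min_overlap required)."""
    shared = set(t1.leaf_labels()) & set(t2.leaf_labels())
    if len(shared) < min_overlap:
        raise TreeError(
            f"only {len(shared)} shared taxa (need >= {min_overlap})"
        )
    return prune_to_taxa(t1, shared), prune_to_taxa(t2, shared)


# ---------------------------------------------------------------------------
# Scaled branch vectors (unit-total length, canonical bipartition order)
# ---------------------------------------------------------------------------

@dataclass
class ScaledBranchVector:
    """Unit-sum branch lengths keyed by leaf-set bipartitions.

    Branches are keyed by the sorted leaf labels on the smaller side of the
    bipartition they induce on the unrooted tree (lexicographic tie-break),
    giving a deterministic, topology-safe correspondence between trees.
    """

    branch_ids: list[tuple[str, ...]]
    lengths: np.ndarray

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if abs(self.lengths.sum() - 1.0) > 1e-10:
            raise TreeError("scaled branch lengths must sum to 1")


def _bipartition_lengths(tree: Phylogeny) -> dict[tuple[str, ...], float]:
    """Unrooted branch lengths keyed by canonical bipartition id."""
    all_leaves = frozenset(tree.leaf_labels())
    root_children = tree.nodes[tree.root].children
    merge_root = len(root_children) == 2  # rooted shape: the two root edges
    out: dict[tuple[str, ...], float] = {}

    def key_of(below: frozenset[str]) -> tuple[str, ...]:
        other = all_leaves - below
        a, b = sorted(below), sorted(other)
        if (len(a), a) <= (len(b), b):
            return tuple(a)
        return tuple(b)

    for i, nd in enumerate(tree.nodes):
        if i == tree.root or nd.parent is None:
            continue
        below = tree.leafset_below(i)
        if below == all_leaves:
            continue
        length = nd.length
        if merge_root and nd.parent == tree.root:
            if i == root_children[0]:
                length = (
                    tree.nodes[root_children[0]].length
                    + tree.nodes[root_children[1]].length
                )
            else:
                continue  # merged into its sibling's entry
        k = key_of(below)
        out[k] = out.get(k, 0.0) + length
    return out


def rescale_to_unit_length(tree: Phylogeny) -> ScaledBranchVector:
    """Branch lengths divided by total tree length, in canonical order."""
    lengths = _bipartition_lengths(tree)
    total = sum(lengths.values())
    if total <= 0:
        raise TreeError("tree has zero total length")
    ids = sorted(lengths)
    return ScaledBranchVector(ids, np.array([lengths[k] / total for k in ids]))


# ---------------------------------------------------------------------------
# Pruning likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Felsenstein-pruning likelihood for site-class codon mixtures.

    Site patterns are compressed once at construction; MISSING states
    contribute all-ones partial vectors.  Site classes may carry distinct
    background/foreground omegas (branch-site models); ordinary site models
    use equal values on every branch.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: Phylogeny,
        freqs: CodonFrequencies,
        code: GeneticCode = UNIVERSAL_CODE,
    ):
        if aln.n_unmasked == 0:
            raise CodonModelError("no usable columns: all sites masked")
        missing_taxa = set(aln.taxa) - set(tree.leaf_labels())
        if missing_taxa:
            raise TreeError(f"alignment taxa absent from tree: {sorted(missing_taxa)}")
        self.code = code
        self.freqs = freqs
        self.S = code.n_sense
        self.tree = tree

        cols = aln.sites[:, aln.mask]
        pats, inverse, counts = np.unique(
            cols, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = pats  # (n_taxa, n_pat)
        self.pattern_of_site = inverse  # unmasked column -> pattern index
        self.counts = counts.astype(float)
        self.n_pat = pats.shape[1]
        self.n_sites = cols.shape[1]

        row_of = {t: r for r, t in enumerate(aln.taxa)}
        self._leaf_states: dict[int, np.ndarray] = {}
        for i in tree.leaves():
            lbl = tree.nodes[i].label
            if lbl in row_of:
                st = pats[row_of[lbl]].copy()
                st[st == MISSING] = self.S  # augmented all-ones column
            else:
                st = np.full(self.n_pat, self.S)  # taxon without data
            self._leaf_states[i] = st
        self._postorder = tree.postorder()
        self._lengths = np.array([tree.nodes[i].length for i in range(len(tree.nodes))])
        self._fg = np.array(
            [tree.nodes[i].foreground for i in range(len(tree.nodes))], dtype=bool
        )
        self._rate_comps = rate_linear_components(freqs, code)
        self._spectral_cache: dict[tuple[float, float], SpectralQ] = {}
        # per-class site-likelihood cache (keyed on kappa, class omegas and
        # the reference rate): grid evaluations such as BEB reuse columns
        self._class_cache: dict[tuple, np.ndarray] = {}

    def invalidate(self):
        """Drop caches after a branch-length change."""
        self._spectral_cache.clear()
        self._class_cache.clear()

    # -- transition matrices --------------------------------------------

    def _spectral(self, kappa: float, omega: float) -> SpectralQ:
        key = (kappa, omega)
        sq = self._spectral_cache.get(key)
        if sq is None:
            Q = build_rate_matrix(GY94Params(kappa, omega, self.freqs), self.code)
            sq = SpectralQ.decompose(Q, self.freqs.pi)
            if len(self._spectral_cache) > 256:
                self._spectral_cache.clear()
            self._spectral_cache[key] = sq
        return sq

    def _branch_mats(
        self,
        kappa: float,
        omega_bg: float,
        omega_fg: float,
        s_bg: float,
        s_fg: float,
    ):
        """Augmented (S+1 columns) transition matrix per node branch.

        ``s_bg``/``s_fg`` multiply branch lengths: the class's relative
        substitution rate on background/foreground branches.
        """
        sq_bg = self._spectral(kappa, omega_bg)
        n = len(self.tree.nodes)
        P = np.empty((n, self.S, self.S + 1))
        if (omega_fg == omega_bg and s_fg == s_bg) or not self._fg.any():
            P[:, :, : self.S] = sq_bg.transition_many(self._lengths * s_bg)
        else:
            sq_fg = self._spectral(kappa, omega_fg)
            bg_idx = np.where(~self._fg)[0]
            fg_idx = np.where(self._fg)[0]
            P[bg_idx, :, : self.S] = sq_bg.transition_many(
                self._lengths[bg_idx] * s_bg
            )
            P[fg_idx, :, : self.S] = sq_fg.transition_many(
                self._lengths[fg_idx] * s_fg
            )
        P[:, :, self.S] = 1.0
        return P

    # -- likelihood ------------------------------------------------------

    def rate(self, kappa: float, omega: float) -> float:
        """Unnormalized expected substitution rate of one omega class."""
        return substitution_rate(kappa, omega, self._rate_comps)

    def mixture_rate(
        self,
        kappa: float,
        class_omegas: list[tuple[float, float]],
        weights: np.ndarray,
    ) -> float:
        """Mixture-average rate over classes (background omegas)."""
        return float(
            sum(w * self.rate(kappa, bg) for (bg, _), w in zip(class_omegas, weights))
        )

    def class_site_likelihoods(
        self,
        kappa: float,
        class_omegas: list[tuple[float, float]],
        ref_rate: float | None = None,
    ) -> np.ndarray:
        """Per-class, per-pattern site likelihoods, shape (K, n_pat).

        With ``ref_rate`` set, class k's branch lengths are multiplied by
        r(kappa, omega_k)/ref_rate so all classes share one time scale;
        without it every class is normalized to one substitution per unit
        length on its own.
        """
        out = np.empty((len(class_omegas), self.n_pat))
        for k, (w_bg, w_fg) in enumerate(class_omegas):
            if ref_rate is None:
                s_bg = s_fg = 1.0
            else:
                s_bg = self.rate(kappa, w_bg) / ref_rate
                s_fg = self.rate(kappa, w_fg) / ref_rate
            key = (kappa, w_bg, w_fg, s_bg, s_fg)
            cached = self._class_cache.get(key)
            if cached is None:
                cached = self._one_class(kappa, w_bg, w_fg, s_bg, s_fg)
                if len(self._class_cache) > 4096:
                    self._class_cache.clear()
                self._class_cache[key] = cached
            out[k] = cached
        return out

    def _one_class(
        self,
        kappa: float,
        omega_bg: float,
        omega_fg: float,
        s_bg: float = 1.0,
        s_fg: float = 1.0,
    ) -> np.ndarray:
        P = self._branch_mats(kappa, omega_bg, omega_fg, s_bg, s_fg)
        partial: dict[int, np.ndarray] = {}
        for i in self._postorder:
            nd = self.tree.nodes[i]
            if not nd.children:
                continue
            prod = None
            for c in self.tree.nodes[i].children:
                if c in self._leaf_states:
                    contrib = P[c][:, self._leaf_states[c]]
                else:
                    contrib = P[c][:, : self.S] @ partial.pop(c)
                prod = contrib if prod is None else prod * contrib
            partial[i] = prod
        root_partial = partial[self._postorder[-1]]
        return self.freqs.pi @ root_partial

    def log_likelihood(
        self,
        kappa: float,
        weights: np.ndarray,
        class_omegas: list[tuple[float, float]],
        rescale: bool = True,
    ) -> float:
        """Mixture log-likelihood; ``rescale`` applies the common time scale
        (mixture-average substitution rate = 1 per unit branch length)."""
        ref = self.mixture_rate(kappa, class_omegas, weights) if rescale else None
        L = self.class_site_likelihoods(kappa, class_omegas, ref_rate=ref)
        site = np.asarray(weights) @ L
        if (site <= 0).any():
            return -np.inf
        return float(self.counts @ np.log(site))

    def per_site(self, values_per_pattern: np.ndarray) -> np.ndarray:
        """Expand a per-pattern vector back to unmasked-site order."""
        return values_per_pattern[..., self.pattern_of_site]


def pruning_log_likelihood(
    aln: CodonAlignment,
    tree: Phylogeny,
    omegas: np.ndarray,
    weights: np.ndarray,
    kappa: float,
    freqs: CodonFrequencies,
    code: GeneticCode = UNIVERSAL_CODE,
) -> tuple[float, np.ndarray]:
    """Total mixture log-likelihood and per-site per-class likelihoods.

    Returns ``(lnL, L)`` where ``L[k, h]`` is the pruning likelihood of
    unmasked site ``h`` under class ``k``'s omega.
    """
    eng = LikelihoodEngine(aln, tree, freqs, code)
    omegas = np.atleast_1d(omegas)
    class_omegas = [(w, w) for w in omegas]
    ref = eng.mixture_rate(kappa, class_omegas, weights)
    Lpat = eng.class_site_likelihoods(kappa, class_omegas, ref_rate=ref)
    site = np.asarray(weights) @ Lpat
    lnL = float(eng.counts @ np.log(site))
    return lnL, eng.per_site(Lpat)
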