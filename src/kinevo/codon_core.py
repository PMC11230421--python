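"""Genetic-code machinery, codon alignments, F3x4 frequencies and the
Goldman-Yang (GY94-style) codon substitution model.

The codon model parameterizes the instantaneous rate of change between
sense codons *i* and *j* as

    q(i->j) = 0                     if i and j differ at >1 position
    q(i->j) ∝ pi_j                  single-position synonymous transversion
    q(i->j) ∝ kappa * pi_j          synonymous transition
    q(i->j) ∝ omega * pi_j          nonsynonymous transversion
    q(i->j) ∝ kappa * omega * pi_j  nonsynonymous transition

with equilibrium codon frequencies pi built from position-specific
nucleotide frequencies (the F3x4 scheme).  The generator is rescaled so
one unit of time equals one expected substitution per codon site, which
makes branch lengths directly interpretable as substitutions/codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

NUCS = "TCAG"
MISSING = -1

F3X4_PSEUDOCOUNT = 1e-6  # added to zero positional counts; keeps Q irreducible


class CodonModelError(ValueError):
    """Raised on invalid sequences, parameters or degenerate inputs."""


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

_UNIVERSAL = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_AA):
    _codon = NUCS[_i // 16] + NUCS[(_i // 4) % 4] + NUCS[_i % 4]
    _UNIVERSAL[_codon] = _aa


@dataclass(frozen=True)
class GeneticCode:
    """Mapping between nucleotide triplets, amino acids and sense-codon indices."""

    table: dict[str, str]
    stops: frozenset[str]
    sense_codons: tuple[str, ...]

    @classmethod
    def universal(cls) -> "GeneticCode":
        stops = frozenset(c for c, a in _UNIVERSAL.items() if a == "*")
        sense = tuple(c for c in sorted(_UNIVERSAL) if c not in stops)
        return cls(table=dict(_UNIVERSAL), stops=stops, sense_codons=sense)

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def index_of(self, codon: str) -> int:
        return self.sense_codons.index(codon)

    def __post_init__(self):
        if len(self.table) != 64:
            raise CodonModelError("genetic code must cover all 64 triplets")
        if set(self.sense_codons) != set(self.table) - set(self.stops):
            raise CodonModelError("sense codons must be exactly the non-stop triplets")

    def aa_of_index(self, idx: int) -> str:
        return self.table[self.sense_codons[idx]]


UNIVERSAL_CODE = GeneticCode.universal()


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon-indexed multiple alignment.

    ``sites`` holds sense-codon indices (``MISSING`` for any triplet with a
    gap or ambiguous nucleotide); ``mask`` marks columns retained for
    likelihood computation.
    """

    taxa: list[str]
    sites: np.ndarray  # (n_taxa, n_codons) int
    mask: np.ndarray = field(default=None)  # (n_codons,) bool

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise CodonModelError("sites matrix must be n_taxa x n_codons")
        if len(set(self.taxa)) != len(self.taxa):
            raise CodonModelError("taxa labels must be unique")
        if self.mask is None:
            self.mask = np.ones(self.n_codons, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_codons,):
            raise CodonModelError("mask length must equal n_codons")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.sites.shape[1]

    @property
    def n_unmasked(self) -> int:
        return int(self.mask.sum())

    def masked_removed(self) -> "CodonAlignment":
        """Physically drop masked columns (identical likelihood by contract)."""
        return CodonAlignment(list(self.taxa), self.sites[:, self.mask].copy())

    def subset_taxa(self, keep: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in keep]
        return CodonAlignment(list(keep), self.sites[idx], self.mask.copy())


def _encode_codon(triplet: str, code: GeneticCode, taxon: str, col: int) -> int:
    t = triplet.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in t):
        return MISSING
    if t in code.stops:
        raise CodonModelError(
            f"internal stop codon {t!r} in {taxon!r} at codon column {col + 1}"
        )
    return code.index_of(t)


def alignment_from_strings(
    seqs: dict[str, str], code: GeneticCode = UNIVERSAL_CODE
) -> CodonAlignment:
    """Build a CodonAlignment from in-memory nucleotide strings."""
    taxa = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise CodonModelError("sequences are not aligned (unequal lengths)")
    (L,) = lengths
    for name, s in seqs.items():
        if len(s) % 3:
            raise CodonModelError(
                f"sequence {name!r} length {len(s)} is not a multiple of 3"
            )
    n_codons = L // 3
    sites = np.empty((len(taxa), n_codons), dtype=np.int64)
    for r, name in enumerate(taxa):
        s = seqs[name]
        for h in range(n_codons):
            sites[r, h] = _encode_codon(s[3 * h : 3 * h + 3], code, name, h)
    return CodonAlignment(taxa, sites)


def read_codon_fasta(path, code: GeneticCode = UNIVERSAL_CODE) -> CodonAlignment:
    """Read a codon-aligned FASTA file; gap/ambiguous codons become MISSING."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise CodonModelError(f"no FASTA records in {path}")
    return alignment_from_strings(seqs, code)


def write_codon_fasta(aln: CodonAlignment, path, code: GeneticCode = UNIVERSAL_CODE):
    with open(path, "w") as fh:
        for r, name in enumerate(aln.taxa):
            seq = "".join(
                code.sense_codons[s] if s != MISSING else "---" for s in aln.sites[r]
            )
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_column_scores(path) -> np.ndarray:
    """Two-column TSV of (1-based column index, confidence score in [0,1])."""
    cols, scores = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, s = line.split("\t")
            cols.append(int(i))
            scores.append(float(s))
    out = np.full(max(cols), np.nan)
    out[np.asarray(cols) - 1] = scores
    if np.isnan(out).any():
        raise CodonModelError("column score file has gaps in its index")
    return out


def write_column_scores(scores: np.ndarray, path):
    with open(path, "w") as fh:
        for i, s in enumerate(scores, 1):
            fh.write(f"{i}\t{s:.6g}\n")


def apply_column_mask(
    aln: CodonAlignment, scores: np.ndarray, threshold: float = 0.93
) -> CodonAlignment:
    """Mask out low-confidence alignment columns (score strictly below threshold)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (aln.n_codons,):
        raise CodonModelError(
            f"scores length {scores.shape[0]} != alignment columns {aln.n_codons}"
        )
    if not 0.0 <= threshold <= 1.0:
        raise CodonModelError("threshold must lie in [0, 1]")
    mask = aln.mask & (scores >= threshold)
    return CodonAlignment(list(aln.taxa), aln.sites.copy(), mask)


# ---------------------------------------------------------------------------
# F3x4 equilibrium frequencies
# ---------------------------------------------------------------------------

@dataclass
class CodonFrequencies:
    pi: np.ndarray  # (S,) sense-codon equilibrium frequencies
    pos_nt: np.ndarray  # (3, 4) positional nucleotide frequencies, NUCS order

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.pos_nt = np.asarray(self.pos_nt, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-10 or (self.pi < 0).any():
            raise CodonModelError("pi must be a probability vector")

    @classmethod
    def uniform(cls, code: GeneticCode = UNIVERSAL_CODE) -> "CodonFrequencies":
        S = code.n_sense
        return cls(np.full(S, 1.0 / S), np.full((3, 4), 0.25))


def compute_f3x4(
    aln: CodonAlignment,
    code: GeneticCode = UNIVERSAL_CODE,
    pseudocount: float = F3X4_PSEUDOCOUNT,
) -> CodonFrequencies:
    """Estimate F3x4 codon frequencies from the unmasked alignment columns."""
    obs = aln.sites[:, aln.mask]
    obs = obs[obs != MISSING]
    if obs.size == 0:
        raise CodonModelError("no usable codons: alignment empty after masking")
    counts = np.zeros((3, 4))
    for idx in obs:
        codon = code.sense_codons[idx]
        for p in range(3):
            counts[p, NUCS.index(codon[p])] += 1
    counts[counts == 0] = pseudocount
    pos_nt = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_nt[0, NUCS.index(c[0])]
            * pos_nt[1, NUCS.index(c[1])]
            * pos_nt[2, NUCS.index(c[2])]
            for c in code.sense_codons
        ]
    )
    pi /= pi.sum()
    return CodonFrequencies(pi, pos_nt)


# ---------------------------------------------------------------------------
# GY94 rate matrix and transition probabilities
# ---------------------------------------------------------------------------

@dataclass
class GY94Params:
    kappa: float
    omega: float
    freqs: CodonFrequencies

    def __post_init__(self):
        if not self.kappa > 0:
            raise CodonModelError("kappa must be > 0")
        if self.omega < 0:
            raise CodonModelError("omega must be >= 0")


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _codon_structure(code: GeneticCode):
    """0/1 masks over codon pairs: (single-step, transition, nonsynonymous)."""
    S = code.n_sense
    single = np.zeros((S, S), dtype=bool)
    transition = np.zeros((S, S), dtype=bool)
    nonsyn = np.zeros((S, S), dtype=bool)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            p = diffs[0]
            if (ci[p], cj[p]) in _TRANSITIONS:
                transition[i, j] = True
            if code.table[ci] != code.table[cj]:
                nonsyn[i, j] = True
    return single, transition, nonsyn


_STRUCT_CACHE: dict[int, tuple] = {}


def _structure(code: GeneticCode):
    key = id(code)
    if key not in _STRUCT_CACHE:
        _STRUCT_CACHE[key] = _codon_structure(code)
    return _STRUCT_CACHE[key]


def build_rate_matrix(params: GY94Params, code: GeneticCode = UNIVERSAL_CODE) -> np.ndarray:
    """GY94 generator, scaled to one expected substitution per codon per unit time."""
    single, transition, nonsyn = _structure(code)
    pi = params.freqs.pi
    factor = np.where(transition, params.kappa, 1.0) * np.where(
        nonsyn, params.omega, 1.0
    )
    Q = np.where(single, factor * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    if rate <= 0:
        raise CodonModelError("degenerate rate matrix (zero total rate)")
    return Q / rate


def rate_linear_components(
    freqs: CodonFrequencies, code: GeneticCode = UNIVERSAL_CODE
) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of the unnormalized substitution rate.

    For the GY94 generator with q(i->j) proportional to
    pi_j * kappa^[transition] * omega^[nonsynonymous], the expected flux
    -sum_i pi_i q(i, i) is linear in kappa and omega:

        r(kappa, omega) = a + b*kappa + c*omega + d*kappa*omega

    (a: synonymous transversions, b: synonymous transitions, c/d their
    nonsynonymous counterparts).  In a site-class mixture all classes
    share one time scale, so class k's generator is scaled by
    r(kappa, omega_k) relative to the mixture-average rate — this is what
    makes omega>1 sites substitute faster, not just differently.
    """
    single, transition, nonsyn = _structure(code)
    pi = freqs.pi
    flux = pi[:, None] * pi[None, :]
    a = float(flux[single & ~transition & ~nonsyn].sum())
    b = float(flux[single & transition & ~nonsyn].sum())
    c = float(flux[single & ~transition & nonsyn].sum())
    d = float(flux[single & transition & nonsyn].sum())
    return a, b, c, d


def substitution_rate(
    kappa: float, omega: float, comps: tuple[float, float, float, float]
) -> float:
    a, b, c, d = comps
    return a + b * kappa + c * omega + d * kappa * omega


@dataclass
class SpectralQ:
    """Eigendecomposition of a reversible generator, for fast P(t)."""

    eigvals: np.ndarray  # (S,)
    left: np.ndarray  # (S, S): P(t) = left @ diag(exp(l t)) @ right
    right: np.ndarray

    @classmethod
    def decompose(cls, Q: np.ndarray, pi: np.ndarray) -> "SpectralQ":
        d = np.sqrt(np.maximum(pi, 1e-300))
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # enforce exact symmetry before eigh
        w, U = np.linalg.eigh(B)
        return cls(w, U / d[:, None], U.T * d[None, :])

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise CodonModelError("branch length must be >= 0")
        P = (self.left * np.exp(self.eigvals * t)[None, :]) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_many(self, ts: np.ndarray) -> np.ndarray:
        """(n_branches, S, S) transition matrices for a vector of lengths."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise CodonModelError("branch lengths must be >= 0")
        E = np.exp(np.outer(ts, self.eigvals))  # (B, S)
        P = np.einsum("ik,bk,kj->bij", self.left, E, self.right, optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def transition_matrix(
    params: GY94Params, t: float, code: GeneticCode = UNIVERSAL_CODE
) -> np.ndarray:
    """P(t) = exp(Q t) for the scaled GY94 generator."""
    Q = build_rate_matrix(params, code)
    return SpectralQ.decompose(Q, params.freqs.pi).transition(t)
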