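"""Goldman-Yang codon substitution models with site- and branch-variable
dN/dS, maximum-likelihood fitting, likelihood-ratio tests, and empirical
Bayes identification of positively selected sites.

Model family
------------
The substitution process runs over the 61 sense codons. Instantaneous rates
between codons differing at one position are

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for codons differing at 2+ positions, diagonal set so rows sum to zero,
and the matrix rescaled to one expected substitution per codon per unit
branch length (-sum_i pi_i q_ii = 1). The chain is time-reversible, so the
matrix exponential is computed through the eigendecomposition of the
symmetrized form diag(sqrt(pi)) Q diag(1/sqrt(pi)).

Site models let omega vary across codons as a finite mixture:
M0 one ratio; M1a nearly-neutral (omega0 < 1, omega1 = 1); M2a adds a class
with omega2 >= 1; M3 has k free discrete classes; M7 draws omega from a
Beta(p, q) discretized into 10 equal-probability categories; M8 adds a point
mass with omega_s >= 1 on top of the beta. The two-ratio branch model gives
a labelled clade its own omega instead.

Likelihoods are computed by Felsenstein pruning over compressed site
patterns with per-node rescaling against underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .seqio import NUCLEOTIDES, STANDARD_CODE, CodonAlignment, GeneticCode, translate

# ---------------------------------------------------------------------------
# Genetic-code structure tables
# ---------------------------------------------------------------------------

_NT_INDEX = {"T": 0, "C": 1, "A": 2, "G": 3}
_PURINES = frozenset("AG")


def _code_structure(code: GeneticCode):
    """Arrays describing single-nucleotide neighbour pairs of sense codons."""
    codons = code.sense_codons
    n = len(codons)
    idx = {c: i for i, c in enumerate(codons)}
    I, J, TS, SYN, POS = [], [], [], [], []
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            (p,) = diff
            I.append(i)
            J.append(j)
            POS.append(p)
            TS.append((ci[p] in _PURINES) == (cj[p] in _PURINES))
            SYN.append(code.codon_to_aa[ci] == code.codon_to_aa[cj])
    return {
        "codons": codons,
        "index": idx,
        "I": np.array(I),
        "J": np.array(J),
        "TS": np.array(TS, dtype=bool),
        "SYN": np.array(SYN, dtype=bool),
        "POS": np.array(POS),
    }


_STRUCTURE_CACHE = {}


def code_structure(code: GeneticCode = STANDARD_CODE):
    key = code.table_id
    if key not in _STRUCTURE_CACHE:
        _STRUCTURE_CACHE[key] = _code_structure(code)
    return _STRUCTURE_CACHE[key]


# ---------------------------------------------------------------------------
# Equilibrium codon frequencies
# ---------------------------------------------------------------------------

def equilibrium_frequencies(aln: CodonAlignment, mode: str = "F3x4",
                            code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Codon frequencies over the 61 sense codons.

    'equal'  uniform 1/61;
    'F1x4'   products of overall nucleotide frequencies;
    'F3x4'   products of position-specific nucleotide frequencies (default,
             the customary CODEML setting).
    Stop-codon mass is dropped and the vector renormalized. Zero entries are
    floored at 1e-10 to keep the chain irreducible.
    """
    codons = code.sense_codons
    if mode == "equal":
        return np.full(len(codons), 1.0 / len(codons))
    counts = np.zeros((3, 4))
    for m in aln.members:
        for i in range(aln.n_codons):
            cod = m.codon(i)
            if any(b not in NUCLEOTIDES for b in cod):
                continue
            for p, b in enumerate(cod):
                counts[p, _NT_INDEX[b]] += 1
    if mode == "F1x4":
        tot = counts.sum(axis=0)
        freq = tot / tot.sum()
        counts = np.tile(freq, (3, 1))
    elif mode == "F3x4":
        counts = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")
    pi = np.array([
        counts[0, _NT_INDEX[c[0]]]
        * counts[1, _NT_INDEX[c[1]]]
        * counts[2, _NT_INDEX[c[2]]]
        for c in codons
    ])
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_q(pi: np.ndarray, kappa: float, omega: float,
            code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """GY94 rate matrix, scaled to mean rate 1 under pi."""
    st = code_structure(code)
    n = len(st["codons"])
    Q = np.zeros((n, n))
    rates = pi[st["J"]] * np.where(st["TS"], kappa, 1.0) \
        * np.where(st["SYN"], 1.0, omega)
    Q[st["I"], st["J"]] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


@dataclass
class QEig:
    """Eigendecomposition of a reversible Q for fast P(t) = exp(Qt)."""

    lam: np.ndarray
    A: np.ndarray   # D^{-1/2} U
    B: np.ndarray   # U.T D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.lam * t)) @ self.B
        return P

    def transition_all(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for a vector of branch lengths: (len(ts), n, n)."""
        E = np.exp(np.outer(ts, self.lam))  # (m, n)
        return np.einsum("ij,mj,jk->mik", self.A, E, self.B)


def q_eigen(Q: np.ndarray, pi: np.ndarray) -> QEig:
    sq = np.sqrt(pi)
    S = Q * sq[:, None] / sq[None, :]
    S = 0.5 * (S + S.T)
    lam, U = np.linalg.eigh(S)
    return QEig(lam=lam, A=U / sq[:, None], B=U.T * sq[None, :])


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) with tiny negative entries clamped and renormalized."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    P = q_eigen(Q, pi).transition(t)
    neg = P.min()
    if neg < -1e-8:
        raise FloatingPointError(f"transition matrix entry {neg} < 0")
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Tree indexing and pattern compression
# ---------------------------------------------------------------------------

@dataclass
class TreeIndex:
    """Postorder-array view of a dendropy tree for pruning."""

    postorder: list          # node ids in postorder (root last)
    children: dict           # node id -> list of child ids
    lengths: np.ndarray      # branch length above each node (root: 0)
    leaf_name: dict          # node id -> taxon label (leaves only)
    n_nodes: int

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TreeIndex":
        nodes = list(tree.postorder_node_iter())
        ids = {id(nd): k for k, nd in enumerate(nodes)}
        children = {}
        lengths = np.zeros(len(nodes))
        leaf_name = {}
        for nd in nodes:
            k = ids[id(nd)]
            children[k] = [ids[id(c)] for c in nd.child_nodes()]
            lengths[k] = nd.edge.length if nd.edge.length else 0.0
            if nd.is_leaf():
                leaf_name[k] = nd.taxon.label
        return cls(
            postorder=[ids[id(nd)] for nd in nodes],
            children=children,
            lengths=lengths,
            leaf_name=leaf_name,
            n_nodes=len(nodes),
        )

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def edge_ids(self) -> list:
        return [k for k in self.postorder if k != self.root]

    def leaf_sets(self):
        """node id -> frozenset of descendant leaf labels."""
        sets = {}
        for k in self.postorder:
            if not self.children[k]:
                sets[k] = frozenset([self.leaf_name[k]])
            else:
                s = frozenset()
                for c in self.children[k]:
                    s |= sets[c]
                sets[k] = s
        return sets


def encode_alignment(aln: CodonAlignment,
                     code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """(n_seqs, n_codons) int matrix of sense-codon state indices."""
    st = code_structure(code)
    idx = st["index"]
    out = np.zeros((len(aln.members), aln.n_codons), dtype=np.int64)
    for r, m in enumerate(aln.members):
        for i in range(aln.n_codons):
            cod = m.codon(i)
            if cod not in idx:
                raise ValueError(
                    f"{m.name}: codon {cod!r} at position {i + 1} is not an "
                    "unambiguous sense codon; apply complete deletion first"
                )
            out[r, i] = idx[cod]
    return out


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class CodonLikelihood:
    """Felsenstein-pruning likelihood for one alignment on one tree."""

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree,
                 pi_mode: str = "F3x4", pi: np.ndarray | None = None,
                 code: GeneticCode = STANDARD_CODE):
        self.aln = aln
        self.code = code
        self.ti = TreeIndex.from_tree(tree)
        names = set(aln.names)
        leaf_names = set(self.ti.leaf_name.values())
        if names != leaf_names:
            raise ValueError(
                f"alignment/tree label mismatch: alignment-only "
                f"{sorted(names - leaf_names)}, tree-only "
                f"{sorted(leaf_names - names)}"
            )
        states = encode_alignment(aln, code)
        row_of = {name: r for r, name in enumerate(aln.names)}
        # order rows by leaf node id for direct lookup during pruning
        self.leaf_rows = {
            k: states[row_of[lbl]] for k, lbl in self.ti.leaf_name.items()
        }
        cols = np.stack([states[:, i] for i in range(aln.n_codons)])
        uniq, inverse = np.unique(cols, axis=0, return_inverse=True)
        self.patterns = uniq            # (n_pat, n_seqs) in aln order
        self.pattern_of_site = inverse  # (n_codons,)
        self.weights = np.bincount(inverse, minlength=len(uniq)).astype(float)
        self.pat_leaf = {
            k: uniq[:, row_of[lbl]] for k, lbl in self.ti.leaf_name.items()
        }
        self.n_states = len(code.sense_codons)
        self.pi = (np.asarray(pi, dtype=float) if pi is not None
                   else equilibrium_frequencies(aln, pi_mode, code))

    @property
    def n_sites(self) -> int:
        return self.aln.n_codons

    @property
    def n_patterns(self) -> int:
        return len(self.weights)

    def _prune(self, P_of_node) -> np.ndarray:
        """Log site-pattern likelihoods given per-node transition matrices."""
        npat = self.n_patterns
        ns = self.n_states
        partial = {}
        logscale = np.zeros(npat)
        for k in self.ti.postorder:
            kids = self.ti.children[k]
            if not kids:
                L = np.zeros((ns, npat))
                L[self.pat_leaf[k], np.arange(npat)] = 1.0
                partial[k] = L
                continue
            L = np.ones((ns, npat))
            for c in kids:
                L *= P_of_node[c] @ partial[c]
                del partial[c]
            m = L.max(axis=0)
            if np.any(m <= 0):
                raise FloatingPointError("zero site likelihood during pruning")
            L /= m
            logscale += np.log(m)
            partial[k] = L
        f = self.pi @ partial[self.ti.root]
        return np.log(f) + logscale

    def class_pattern_logliks(self, kappa: float, omega: float,
                              lengths: np.ndarray) -> np.ndarray:
        """Log pattern likelihoods under a single omega for all sites."""
        Q = build_q(self.pi, kappa, omega, self.code)
        eig = q_eigen(Q, self.pi)
        P = {k: eig.transition(lengths[k]) for k in self.ti.edge_ids}
        return self._prune(P)

    def branch_model_logliks(self, kappa: float, edge_omega: dict,
                             lengths: np.ndarray) -> np.ndarray:
        """Log pattern likelihoods with a per-edge omega (branch models)."""
        eigs = {}
        P = {}
        for k in self.ti.edge_ids:
            w = edge_omega[k]
            if w not in eigs:
                eigs[w] = q_eigen(build_q(self.pi, kappa, w, self.code),
                                  self.pi)
            P[k] = eigs[w].transition(lengths[k])
        return self._prune(P)

    def mixture_lnl(self, kappa: float, props, omegas,
                    lengths: np.ndarray, return_matrix: bool = False):
        """Total lnL of an omega mixture; optionally per-class logliks."""
        props = np.asarray(props, dtype=float)
        logf = np.stack([
            self.class_pattern_logliks(kappa, w, lengths) for w in omegas
        ])  # (n_classes, n_pat)
        site_log = logsumexp(logf + np.log(props)[:, None], axis=0)
        lnl = float(self.weights @ site_log)
        if return_matrix:
            return lnl, logf
        return lnl

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map per-pattern values (last axis) to per-site values."""
        return per_pattern[..., self.pattern_of_site]


# ---------------------------------------------------------------------------
# Site-model specifications
# ---------------------------------------------------------------------------

BETA_CATEGORIES = 10
OMEGA_MAX = 50.0
KAPPA_BOUNDS = (0.1, 30.0)
BETA_SHAPE_BOUNDS = (0.005, 99.0)

MODEL_NAMES = ("M0", "two_ratio", "M1a", "M2a", "M3", "M7", "M8")


@dataclass
class SiteModelSpec:
    """Which omega structure to fit.

    ``k`` applies to M3 (number of discrete classes); ``clade`` names the
    foreground leaf set for the two-ratio branch model.
    """

    name: str
    k: int = 2
    clade: frozenset | None = None

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.name == "two_ratio" and not self.clade:
            raise ValueError("two_ratio requires a foreground clade")
        if self.name == "M3" and self.k < 1:
            raise ValueError("M3 needs k >= 1 classes")

    @property
    def label(self) -> str:
        return f"M3k{self.k}" if self.name == "M3" else self.name

    @property
    def n_free_params(self) -> int:
        """Free parameters of the omega distribution (kappa and branch
        lengths counted separately, as in standard LRT bookkeeping)."""
        return {
            "M0": 1, "two_ratio": 2, "M1a": 2, "M2a": 4,
            "M3": 2 * self.k - 1, "M7": 2, "M8": 4,
        }[self.name]


def beta_category_omegas(p: float, q: float,
                         K: int = BETA_CATEGORIES) -> np.ndarray:
    """Medians of K equal-probability slices of Beta(p, q)."""
    probs = (np.arange(K) + 0.5) / K
    return beta_dist.ppf(probs, p, q)


def _stick_to_props(v: np.ndarray) -> np.ndarray:
    """Stick-breaking fractions -> proportions summing to 1."""
    props = []
    rest = 1.0
    for x in v:
        props.append(rest * x)
        rest *= 1.0 - x
    props.append(rest)
    return np.array(props)


def _props_to_stick(props: np.ndarray) -> np.ndarray:
    v = []
    rest = 1.0
    for p in props[:-1]:
        v.append(min(max(p / rest, 1e-9), 1 - 1e-9))
        rest -= p
        rest = max(rest, 1e-12)
    return np.array(v)


class _Parameterization:
    """Transform between the optimizer vector and model parameters."""

    def __init__(self, spec: SiteModelSpec, n_edges: int,
                 fit_branches: bool):
        self.spec = spec
        self.n_edges = n_edges
        self.fit_branches = fit_branches

    def bounds(self):
        lo_k, hi_k = np.log(KAPPA_BOUNDS)
        lo_w, hi_w = np.log(1e-4), np.log(OMEGA_MAX)
        lo_b, hi_b = np.log(BETA_SHAPE_BOUNDS)
        frac = (1e-6, 1 - 1e-6)
        w01 = (1e-6, 1 - 1e-6)
        wpos = (1.0, OMEGA_MAX)
        name = self.spec.name
        b = [(lo_k, hi_k)]
        if name == "M0":
            b += [(lo_w, hi_w)]
        elif name == "two_ratio":
            b += [(lo_w, hi_w), (lo_w, hi_w)]
        elif name == "M1a":
            b += [frac, w01]
        elif name == "M2a":
            b += [frac, frac, w01, wpos]
        elif name == "M3":
            b += [frac] * (self.spec.k - 1) + [(lo_w, hi_w)] * self.spec.k
        elif name == "M7":
            b += [(lo_b, hi_b), (lo_b, hi_b)]
        elif name == "M8":
            b += [frac, (lo_b, hi_b), (lo_b, hi_b), wpos]
        if self.fit_branches:
            b += [(np.log(1e-6), np.log(20.0))] * self.n_edges
        return b

    def unpack(self, x: np.ndarray) -> dict:
        name = self.spec.name
        kappa = math.exp(x[0])
        i = 1
        out = {"kappa": kappa}
        if name == "M0":
            out["props"], out["omegas"] = [1.0], [math.exp(x[1])]
            i = 2
        elif name == "two_ratio":
            out["omega_background"] = math.exp(x[1])
            out["omega_foreground"] = math.exp(x[2])
            i = 3
        elif name == "M1a":
            p0, w0 = x[1], x[2]
            out["props"], out["omegas"] = [p0, 1 - p0], [w0, 1.0]
            i = 3
        elif name == "M2a":
            props = _stick_to_props(x[1:3])
            out["props"] = list(props)
            out["omegas"] = [x[3], 1.0, x[4]]
            i = 5
        elif name == "M3":
            k = self.spec.k
            props = _stick_to_props(x[1:k]) if k > 1 else np.array([1.0])
            out["props"] = list(props)
            out["omegas"] = list(np.exp(x[k : 2 * k]))
            i = 2 * k
        elif name == "M7":
            p, q = math.exp(x[1]), math.exp(x[2])
            out["beta_p"], out["beta_q"] = p, q
            cats = beta_category_omegas(p, q)
            out["props"] = [1.0 / BETA_CATEGORIES] * BETA_CATEGORIES
            out["omegas"] = list(cats)
            i = 3
        elif name == "M8":
            p0, p, q, ws = x[1], math.exp(x[2]), math.exp(x[3]), x[4]
            out["p0"], out["beta_p"], out["beta_q"], out["omega_s"] = \
                p0, p, q, ws
            cats = beta_category_omegas(p, q)
            out["props"] = [p0 / BETA_CATEGORIES] * BETA_CATEGORIES + [1 - p0]
            out["omegas"] = list(cats) + [ws]
            i = 5
        if self.fit_branches:
            out["lengths_free"] = np.exp(x[i : i + self.n_edges])
        return out

    def default_start(self) -> list:
        name = self.spec.name
        x = [math.log(2.0)]
        if name == "M0":
            x += [math.log(0.2)]
        elif name == "two_ratio":
            x += [math.log(0.2), math.log(0.2)]
        elif name == "M1a":
            x += [0.8, 0.1]
        elif name == "M2a":
            x += [0.8, 0.9, 0.1, 2.0]
        elif name == "M3":
            k = self.spec.k
            sticks = _props_to_stick(np.full(k, 1.0 / k))
            x += list(sticks) + list(np.log(np.linspace(0.05, 1.0, k)))
        elif name == "M7":
            x += [math.log(0.5), math.log(1.5)]
        elif name == "M8":
            x += [0.9, math.log(0.5), math.log(1.5), 2.0]
        return x

    def random_start(self, rng) -> list:
        x = []
        for lo, hi in self.bounds()[: self._n_model_params()]:
            x.append(rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo)))
        return x

    def _n_model_params(self) -> int:
        return len(self.bounds()) - (self.n_edges if self.fit_branches else 0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class SiteModelFit:
    """A fitted codon model: MLEs, log-likelihood, per-site class logliks."""

    spec: SiteModelSpec
    lnL: float
    params: dict                      # kappa, props, omegas, model extras
    branch_lengths: np.ndarray        # per-node (TreeIndex order)
    n_free_params: int
    converged: bool
    site_class_logliks: np.ndarray | None = None   # (n_classes, n_sites)
    engine: CodonLikelihood | None = field(default=None, repr=False)
    trace: list = field(default_factory=list)

    @property
    def class_props(self) -> np.ndarray:
        return np.asarray(self.params["props"])

    @property
    def class_omegas(self) -> np.ndarray:
        return np.asarray(self.params["omegas"])

    def site_posteriors(self) -> np.ndarray:
        """(n_sites, n_classes) NEB posterior class probabilities."""
        logf = self.site_class_logliks
        logpost = logf + np.log(self.class_props)[:, None]
        logpost -= logsumexp(logpost, axis=0)
        return np.exp(logpost).T


def _edge_omega_map(engine: CodonLikelihood, clade: frozenset,
                    omega_bg: float, omega_fg: float) -> dict:
    """Edges whose descendant leaves all fall inside ``clade`` -> foreground."""
    sets = engine.ti.leaf_sets()
    return {
        k: (omega_fg if sets[k] <= clade else omega_bg)
        for k in engine.ti.edge_ids
    }


def _neg_lnl(engine: CodonLikelihood, spec: SiteModelSpec, par,
             fixed_lengths: np.ndarray | None):
    def f(x):
        p = par.unpack(x)
        if par.fit_branches:
            lengths = np.zeros(engine.ti.n_nodes)
            for e, k in enumerate(engine.ti.edge_ids):
                lengths[k] = p["lengths_free"][e]
        else:
            lengths = fixed_lengths
        try:
            if spec.name == "two_ratio":
                eo = _edge_omega_map(engine, spec.clade,
                                     p["omega_background"],
                                     p["omega_foreground"])
                logf = engine.branch_model_logliks(p["kappa"], eo, lengths)
                lnl = float(engine.weights @ logf)
            else:
                lnl = engine.mixture_lnl(p["kappa"], p["props"], p["omegas"],
                                         lengths)
        except FloatingPointError:
            return 1e10
        return -lnl
    return f


def fit_model(aln: CodonAlignment, tree: dendropy.Tree, spec: SiteModelSpec,
              pi_mode: str = "F3x4", seed: int = 0, n_starts: int = 5,
              fix_branch_lengths: np.ndarray | None = None,
              extra_starts: list | None = None,
              engine: CodonLikelihood | None = None,
              gtol: float = 1e-5) -> SiteModelFit:
    """Maximum-likelihood fit of a site/branch model.

    Branch lengths are estimated jointly when ``fix_branch_lengths`` is None
    (the usual protocol is to do that once under M0 and pass the result here
    for every other model). Multi-start L-BFGS-B with seeded stratified
    initializations; ``extra_starts`` allows warm-starting from a nested
    null's MLE. Convergence requires the best two starts to agree within
    0.01 log-units (single-start fits trust the optimizer's own flag).
    """
    engine = engine or CodonLikelihood(aln, tree, pi_mode=pi_mode)
    fit_branches = fix_branch_lengths is None
    par = _Parameterization(spec, len(engine.ti.edge_ids), fit_branches)
    fun = _neg_lnl(engine, spec, par,
                   None if fit_branches else np.asarray(fix_branch_lengths))
    rng = np.random.default_rng(seed)
    starts = [par.default_start()]
    for _ in range(max(0, n_starts - 1)):
        starts.append(par.random_start(rng))
    if extra_starts:
        starts = list(extra_starts) + starts
        starts = starts[: max(n_starts, len(extra_starts) + 1)]
    if fit_branches:
        base_t = math.log(0.1)
        full = []
        for s in starts:
            jitter = rng.normal(0, 0.3, size=par.n_edges)
            full.append(list(s) + list(base_t + jitter))
        starts = full

    bounds = par.bounds()
    results = []
    for x0 in starts:
        res = minimize(fun, np.asarray(x0, dtype=float), method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10, "gtol": gtol})
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    lnls = sorted(-r.fun for r in results)
    converged = bool(best.success) and (
        len(results) < 2 or abs(lnls[-1] - lnls[-2]) < 0.01
    )

    p = par.unpack(best.x)
    if fit_branches:
        lengths = np.zeros(engine.ti.n_nodes)
        for e, k in enumerate(engine.ti.edge_ids):
            lengths[k] = p["lengths_free"][e]
        p.pop("lengths_free")
    else:
        lengths = np.asarray(fix_branch_lengths, dtype=float)

    if spec.name == "two_ratio":
        eo = _edge_omega_map(engine, spec.clade, p["omega_background"],
                             p["omega_foreground"])
        logf = engine.branch_model_logliks(p["kappa"], eo, lengths)
        lnl = float(engine.weights @ logf)
        site_logf = None
        p["props"], p["omegas"] = [1.0], [p["omega_background"]]
    else:
        lnl, logf = engine.mixture_lnl(p["kappa"], p["props"], p["omegas"],
                                       lengths, return_matrix=True)
        site_logf = engine.expand(logf)

    return SiteModelFit(
        spec=spec,
        lnL=lnl,
        params=p,
        branch_lengths=lengths,
        n_free_params=spec.n_free_params,
        converged=converged,
        site_class_logliks=site_logf,
        engine=engine,
        trace=[(-r.fun, bool(r.success)) for r in results],
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    stat_2dl: float
    df: int
    p_value: float
    null_name: str = ""
    alt_name: str = ""


def lrt_pvalue(stat: float, df: int) -> float:
    """Chi-square upper-tail probability of 2*delta-lnL at df."""
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    return float(chi2.sf(max(stat, 0.0), df))


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit,
        df: int | None = None, tol: float = 0.02) -> LRTResult:
    stat = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if stat < -tol:
        raise RuntimeError(
            f"alternative lnL {alt_fit.lnL:.4f} below null {null_fit.lnL:.4f}"
            " beyond tolerance; optimization failure"
        )
    stat = max(stat, 0.0)
    if df is None:
        df = alt_fit.n_free_params - null_fit.n_free_params
    return LRTResult(stat, df, lrt_pvalue(stat, df),
                     null_fit.spec.label, alt_fit.spec.label)


# ---------------------------------------------------------------------------
# Empirical Bayes site identification
# ---------------------------------------------------------------------------

@dataclass
class PositiveSiteReport:
    site: int               # 1-based on the reference sequence
    reference_aa: str
    posterior: float        # P(omega > 1) at this site
    method: str             # 'NEB' or 'BEB'
    significant_95: bool = False
    significant_99: bool = False

    def __str__(self):
        star = "**" if self.significant_99 else ("*" if self.significant_95
                                                 else "")
        return f"{self.site}{self.reference_aa} ({self.posterior:.3f}{star})"


def _reference_aas(fit: SiteModelFit, reference: str | None):
    aln = fit.engine.aln
    ref = aln[reference] if reference else aln.members[0]
    return translate(ref, aln.code).residues


def _reports(post_pos: np.ndarray, fit: SiteModelFit, method: str,
             reference: str | None, threshold: float):
    aas = _reference_aas(fit, reference)
    out = []
    for h, pp in enumerate(post_pos):
        if pp > threshold:
            out.append(PositiveSiteReport(
                site=h + 1,
                reference_aa=aas[h],
                posterior=float(pp),
                method=method,
                significant_95=pp >= 0.95,
                significant_99=pp >= 0.99,
            ))
    return out


def neb_posteriors(fit: SiteModelFit, reference: str | None = None,
                   threshold: float = 0.5) -> list:
    """Naive empirical Bayes: class posteriors at the MLEs; report sites
    whose summed posterior over omega > 1 classes exceeds ``threshold``."""
    if fit.site_class_logliks is None:
        raise ValueError("fit carries no per-site class likelihoods")
    post = fit.site_posteriors()  # (n_sites, n_classes)
    positive = fit.class_omegas > 1.0
    post_pos = post[:, positive].sum(axis=1)
    return _reports(post_pos, fit, "NEB", reference, threshold)


def _cached_class_logliks(fit: SiteModelFit):
    engine = fit.engine
    cache = {}

    def get(omega: float) -> np.ndarray:
        key = round(float(omega), 7)
        if key not in cache:
            logf = engine.class_pattern_logliks(
                fit.params["kappa"], max(key, 1e-6), fit.branch_lengths
            )
            cache[key] = logf  # per pattern
        return cache[key]

    return get


def beb_posteriors(fit: SiteModelFit, grid_points: int = 10,
                   reference: str | None = None,
                   threshold: float = 0.5) -> list:
    """Bayes empirical Bayes positive-site posteriors for M2a or M8.

    The omega-distribution parameters are integrated over a uniform grid
    prior (``grid_points`` per dimension); kappa and branch lengths stay at
    their MLEs. Grid ranges: proportions over the simplex via stick-breaking,
    omega0 in (0,1), the positive-selection omega in (1, 11), beta shapes in
    (0, 2] -- the customary ranges for this integration.
    """
    if fit.spec.name not in ("M2a", "M8"):
        raise ValueError(f"BEB supports M2a and M8, not {fit.spec.label}")
    engine = fit.engine
    g = (np.arange(grid_points) + 0.5) / grid_points
    get_logf = _cached_class_logliks(fit)
    w = engine.weights

    theta_loglik = []   # log f(X | theta), up to a constant
    theta_pos = []      # per-pattern P(positive class | pattern, theta)

    if fit.spec.name == "M2a":
        logf_w0 = [get_logf(w0) for w0 in g]            # omega0 grid
        logf_w1 = get_logf(1.0)
        logf_w2 = [get_logf(1.0 + 10.0 * t) for t in g]  # omega2 grid
        for u in g:
            for v in g:
                p0, p1 = u, (1 - u) * v
                p2 = 1 - p0 - p1
                lp = np.log(np.maximum([p0, p1, p2], 1e-300))
                for a in range(grid_points):
                    for b in range(grid_points):
                        logs = np.stack([
                            lp[0] + logf_w0[a],
                            lp[1] + logf_w1,
                            lp[2] + logf_w2[b],
                        ])
                        site_log = logsumexp(logs, axis=0)
                        theta_loglik.append(float(w @ site_log))
                        theta_pos.append(np.exp(logs[2] - site_log))
    else:  # M8
        # per (p, q): mean class likelihood over the 10 beta categories
        logf_beta = {}
        for p in 2.0 * g:
            for q in 2.0 * g:
                cats = beta_category_omegas(p, q)
                stack = np.stack([get_logf(c) for c in cats])
                logf_beta[(p, q)] = (
                    logsumexp(stack, axis=0) - math.log(len(cats))
                )
        logf_ws = [get_logf(1.0 + 10.0 * t) for t in g]
        for p0 in g:
            lp0, lp1 = math.log(p0), math.log(1 - p0)
            for pq, logf_b in logf_beta.items():
                for b in range(grid_points):
                    logs = np.stack([
                        lp0 + logf_b,
                        lp1 + logf_ws[b],
                    ])
                    site_log = logsumexp(logs, axis=0)
                    theta_loglik.append(float(w @ site_log))
                    theta_pos.append(np.exp(logs[1] - site_log))

    theta_loglik = np.asarray(theta_loglik)
    wt = np.exp(theta_loglik - theta_loglik.max())
    wt /= wt.sum()
    post_pat = wt @ np.stack(theta_pos)       # per pattern
    post_pos = engine.expand(post_pat)        # per site
    return _reports(post_pos, fit, "BEB", reference, threshold)


# ---------------------------------------------------------------------------
# Synonymous-rate bookkeeping (ML pairwise dS from an M0 fit)
# ---------------------------------------------------------------------------

def synonymous_fraction(pi: np.ndarray, kappa: float, omega: float,
                        code: GeneticCode = STANDARD_CODE):
    """(rho_S, c_S): synonymous share of the substitution flux at the given
    omega, and at omega = 1 (the 'mutational opportunity' used to count
    synonymous sites)."""
    st = code_structure(code)

    def flux(w):
        rates = pi[st["I"]] * pi[st["J"]] \
            * np.where(st["TS"], kappa, 1.0) \
            * np.where(st["SYN"], 1.0, w)
        total = rates.sum()
        return rates[st["SYN"]].sum() / total

    Q = build_q(pi, kappa, omega, code)
    rates = pi[st["I"]] * Q[st["I"], st["J"]]
    rho_s = rates[st["SYN"]].sum()
    return float(rho_s), float(flux(1.0))


def m0_pairwise_ds(fit: SiteModelFit) -> float:
    """dS implied by a 2-taxon M0 fit: synonymous substitutions per
    synonymous site, with sites counted from the omega=1 flux."""
    t = float(fit.branch_lengths.sum())
    rho_s, c_s = synonymous_fraction(
        fit.engine.pi, fit.params["kappa"], fit.params["omegas"][0]
    )
    return t * rho_s / (3.0 * c_s)
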