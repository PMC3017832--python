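"""Pairwise evolutionary distances.

Nei-Gojobori (1986) synonymous/nonsynonymous counting with Jukes-Cantor
correction and codon-bootstrap standard errors, plus the p-distance and
Kimura two-parameter nucleotide distances used for tree building.

Pathway averaging for codon pairs differing at 2-3 positions follows the
original unweighted convention: every minimal mutational pathway that avoids
stop codons contributes equally.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .seqio import (
    AMBIGUOUS,
    NUCLEOTIDES,
    STANDARD_CODE,
    CodonAlignment,
    GeneticCode,
    NamedSequence,
)

log = logging.getLogger(__name__)

PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES) == (b in PURINES)


class DistanceError(ValueError):
    pass


@dataclass
class NG86Counts:
    """Synonymous/nonsynonymous site and difference counts for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int

    def __post_init__(self):
        assert min(self.S, self.N, self.Sd, self.Nd) >= -1e-9


@dataclass
class DistanceEstimate:
    """A pairwise distance (substitutions per site) with standard error.

    ``applicable`` is False when the distance correction is undefined
    (log argument non-positive); such estimates carry value NaN and must be
    excluded from averages by the caller.
    """

    value: float
    se: float = 0.0
    n_units: int = 0
    kind: str = "dS"
    applicable: bool = True

    def __str__(self):
        if not self.applicable:
            return f"{self.kind}=inapplicable"
        return f"{self.value:.4f} ± {self.se:.4f}"


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------

def _syn_site_fraction(codon: str, code: GeneticCode):
    """Per-position fraction of single-nt changes that are synonymous.

    Changes to stop codons are excluded from the denominator (NG86).
    """
    fracs = []
    aa = code.codon_to_aa[codon]
    for pos in range(3):
        syn = tot = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if code.is_stop(mut):
                continue
            tot += 1
            if code.codon_to_aa[mut] == aa:
                syn += 1
        fracs.append(syn / tot if tot else 0.0)
    return fracs


def _codon_sites(codon: str, code: GeneticCode) -> float:
    return sum(_syn_site_fraction(codon, code))


def _pathways(c1: str, c2: str):
    """All orderings of the minimal mutational pathway between two codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    for order in itertools.permutations(diff):
        path = [c1]
        cur = c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
            path.append(cur)
        yield path


def _pair_differences(c1: str, c2: str, code: GeneticCode):
    """Pathway-averaged (Sd, Nd) for one codon pair.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, falls back to including them (degenerate, as in NG86 software).
    """
    if c1 == c2:
        return 0.0, 0.0
    usable = []
    blocked = []
    for path in _pathways(c1, c2):
        steps = []
        for a, b in zip(path, path[1:]):
            steps.append(code.codon_to_aa.get(a) == code.codon_to_aa.get(b)
                         and not code.is_stop(a) and not code.is_stop(b))
        if any(code.is_stop(c) for c in path[1:-1]):
            blocked.append(steps)
        else:
            usable.append(steps)
    paths = usable or blocked
    sd = nd = 0.0
    for steps in paths:
        sd += sum(steps)
        nd += len(steps) - sum(steps)
    k = len(paths)
    return sd / k, nd / k


def ng86_counts(seq_a: NamedSequence, seq_b: NamedSequence,
                code: GeneticCode = STANDARD_CODE) -> NG86Counts:
    """NG86 site/difference counts between two gap-free in-frame sequences."""
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise DistanceError("sequences must be equal-length and in-frame")
    n = len(seq_a) // 3
    S = Sd = Nd = 0.0
    used = 0
    for i in range(n):
        ca, cb = seq_a.codon(i), seq_b.codon(i)
        if any(ch not in NUCLEOTIDES for ch in ca + cb):
            continue  # gapped/ambiguous codon: skipped (pairwise deletion)
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        used += 1
        S += 0.5 * (_codon_sites(ca, code) + _codon_sites(cb, code))
        sd, nd = _pair_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    if used == 0:
        raise DistanceError("zero comparable codons")
    return NG86Counts(S=S, N=3 * used - S, Sd=Sd, Nd=Nd, n_codons=used)


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction d = -(3/4) ln(1 - 4p/3); NaN if p >= 3/4."""
    if p < 0:
        raise DistanceError(f"proportion {p} < 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(counts: NG86Counts) -> dict:
    """pS/pN proportions, JC-corrected dS/dN, and omega = dN/dS."""
    pS = counts.Sd / counts.S if counts.S > 0 else 0.0
    pN = counts.Nd / counts.N if counts.N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    out = {
        "pS": pS,
        "pN": pN,
        "dS": DistanceEstimate(dS, 0.0, counts.n_codons, "dS",
                               applicable=not math.isnan(dS)),
        "dN": DistanceEstimate(dN, 0.0, counts.n_codons, "dN",
                               applicable=not math.isnan(dN)),
    }
    out["omega"] = (dN / dS) if (dS and not math.isnan(dS)
                                 and not math.isnan(dN)) else math.nan
    return out


def ng86_pair(seq_a, seq_b, code: GeneticCode = STANDARD_CODE) -> dict:
    return ng86_dnds(ng86_counts(seq_a, seq_b, code))


# ---------------------------------------------------------------------------
# Bootstrap standard errors (codon-column resampling)
# ---------------------------------------------------------------------------

def _codon_arrays(seq_a, seq_b):
    n = len(seq_a) // 3
    return ([seq_a.codon(i) for i in range(n)],
            [seq_b.codon(i) for i in range(n)])


def bootstrap_se(seq_a: NamedSequence, seq_b: NamedSequence,
                 statistic: str = "dS", B: int = 1000, seed: int = 0,
                 code: GeneticCode = STANDARD_CODE) -> float:
    """SE of dS or dN by resampling codon columns with replacement."""
    if B < 100:
        raise DistanceError(f"B must be >= 100, got {B}")
    if statistic not in ("dS", "dN"):
        raise DistanceError(f"statistic must be dS or dN, got {statistic!r}")
    ca, cb = _codon_arrays(seq_a, seq_b)
    n = len(ca)
    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        a = NamedSequence("a", "".join(ca[i] for i in idx))
        b = NamedSequence("b", "".join(cb[i] for i in idx))
        val = ng86_pair(a, b, code)[statistic]
        if val.applicable:
            reps.append(val.value)
        else:
            failed += 1
    if failed > 0.1 * B:
        raise DistanceError(
            f"{statistic} inapplicable in {failed}/{B} bootstrap replicates"
        )
    return float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0


def ng86_with_se(seq_a, seq_b, B: int = 1000, seed: int = 0,
                 code: GeneticCode = STANDARD_CODE) -> dict:
    """NG86 dS/dN point estimates with bootstrap SEs filled in."""
    res = ng86_pair(seq_a, seq_b, code)
    for stat in ("dS", "dN"):
        if res[stat].applicable and res[stat].value > 0:
            res[stat].se = bootstrap_se(seq_a, seq_b, stat, B, seed, code)
    return res


# ---------------------------------------------------------------------------
# Nucleotide distances
# ---------------------------------------------------------------------------

def nucleotide_distance(seq_a: NamedSequence, seq_b: NamedSequence,
                        model: str = "p",
                        deletion: str = "pairwise") -> DistanceEstimate:
    """p-distance or Kimura-2-parameter distance between aligned sequences.

    ``deletion='pairwise'`` skips columns gapped/ambiguous in either member;
    complete deletion across a whole alignment is done upstream in seqio.
    """
    if model not in ("p", "K2P"):
        raise DistanceError(f"model must be 'p' or 'K2P', got {model!r}")
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences must be aligned")
    n = ts = tv = 0
    for x, y in zip(seq_a.residues, seq_b.residues):
        if x in AMBIGUOUS or y in AMBIGUOUS:
            if deletion == "complete":
                raise DistanceError(
                    "gap/ambiguity found; apply complete deletion first"
                )
            continue
        n += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise DistanceError("zero comparable sites")
    if model == "p":
        return DistanceEstimate((ts + tv) / n, 0.0, n, "p")
    P, Q = ts / n, tv / n
    a1, a2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
    if a1 <= 0 or a2 <= 0:
        return DistanceEstimate(math.nan, 0.0, n, "K2P", applicable=False)
    d = -0.5 * math.log(a1) - 0.25 * math.log(a2)
    return DistanceEstimate(d, 0.0, n, "K2P")


# ---------------------------------------------------------------------------
# Pairwise tables
# ---------------------------------------------------------------------------

@dataclass
class PairwiseTable:
    """Symmetric table of pairwise DistanceEstimates."""

    labels: list
    entries: dict  # frozenset({a, b}) -> DistanceEstimate

    def get(self, a: str, b: str) -> DistanceEstimate:
        if a == b:
            return DistanceEstimate(0.0, 0.0, 0, "self")
        return self.entries[frozenset((a, b))]

    def pairs(self):
        for key, est in sorted(self.entries.items(),
                               key=lambda kv: tuple(sorted(kv[0]))):
            a, b = sorted(key)
            yield a, b, est

    def to_matrix(self):
        """Square numpy matrix in label order (for tree building)."""
        k = len(self.labels)
        m = np.zeros((k, k))
        for i, a in enumerate(self.labels):
            for j in range(i + 1, k):
                est = self.get(a, self.labels[j])
                if not est.applicable:
                    raise DistanceError(
                        f"inapplicable distance for pair ({a}, "
                        f"{self.labels[j]}); cannot build a tree"
                    )
                m[i, j] = m[j, i] = est.value
        return m

    def to_tsv(self) -> str:
        lines = ["pair\tvalue\tse"]
        for a, b, est in self.pairs():
            if est.applicable:
                lines.append(f"{a}/{b}\t{est.value:.4f}\t{est.se:.4f}")
            else:
                lines.append(f"{a}/{b}\tNA\tNA")
        return "\n".join(lines) + "\n"


def pairwise_table(aln: CodonAlignment, metric: str = "dS",
                   B: int = 1000, seed: int = 0,
                   model: str = "K2P") -> PairwiseTable:
    """All-pairs distance table over an alignment.

    metric: 'dS' / 'dN' (NG86 + bootstrap SE) or 'nucleotide' (p or K2P per
    ``model``, no SE).
    """
    if len(aln) < 2:
        raise DistanceError("need at least 2 sequences")
    entries = {}
    names = aln.names
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = aln[a], aln[b]
            if metric in ("dS", "dN"):
                pair_seed = (seed + 1_000_003 * (hash((a, b)) % 1000)) % (2**31)
                res = ng86_with_se(sa, sb, B=B, seed=pair_seed, code=aln.code)
                est = res[metric]
            elif metric == "nucleotide":
                est = nucleotide_distance(sa, sb, model=model)
            else:
                raise DistanceError(f"unknown metric {metric!r}")
            if not est.applicable:
                log.warning("distance inapplicable for pair (%s, %s)", a, b)
            entries[frozenset((a, b))] = est
    return PairwiseTable(list(names), entries)
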