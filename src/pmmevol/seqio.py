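"""Sequence and tree I/O, codon-alignment validation and manipulation.

In-frame coding alignments are the substrate of every downstream stage
(distance estimation, tree building, codon-model fitting). This module
enforces the invariants those stages assume: equal lengths, a reading frame
that starts at position 0, no internal stop codons, and -- after complete
deletion -- no gaps or ambiguity characters in any retained column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGT")
GAP = "-"
#: characters treated as deletable under complete deletion (gap + ambiguity)
AMBIGUOUS = frozenset("NRYSWKMBDHV?") | {GAP}


class SeqIOError(ValueError):
    """Malformed sequence input (format, frame, stop codons, duplicates)."""


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide or protein sequence (aligned or not)."""

    name: str
    residues: str

    def __post_init__(self):
        if not self.name:
            raise SeqIOError("sequence name must be non-empty")
        if not self.residues:
            raise SeqIOError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    def codon(self, i: int) -> str:
        return self.residues[3 * i : 3 * i + 3]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with a stable lexicographic ordering of sense codons.

    The ordering of ``sense_codons`` indexes the state space of the codon
    substitution models and must not change across the package.
    """

    table_id: int
    codon_to_aa: dict
    stop_codons: frozenset
    sense_codons: tuple

    @classmethod
    def standard(cls) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(tbl.forward_table)
        stops = frozenset(tbl.stop_codons)
        sense = tuple(sorted(mapping))
        assert len(sense) == 61 and len(stops) == 3
        return cls(1, mapping, stops, sense)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def aa(self, codon: str) -> str:
        """Translate one codon; gaps map to '-', ambiguity to 'X'."""
        if codon == GAP * 3:
            return GAP
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        if codon in self.stop_codons:
            return "*"
        # ambiguous codon: if every compatible resolution agrees, use it
        aas = {
            self.codon_to_aa.get(c, "*")
            for c in _expand_ambiguous(codon)
        }
        return aas.pop() if len(aas) == 1 else "X"


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "?": "ACGT",
}


def _expand_ambiguous(codon: str):
    opts = [_IUPAC.get(b, "") for b in codon]
    if any(not o for o in opts):
        return []
    return [a + b + c for a in opts[0] for b in opts[1] for c in opts[2]]


STANDARD_CODE = GeneticCode.standard()


@dataclass
class CodonAlignment:
    """Equal-length, in-frame aligned coding sequences (no internal stops)."""

    members: list
    code: GeneticCode = field(default=STANDARD_CODE)

    def __post_init__(self):
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SeqIOError(f"duplicate sequence names: {dup}")
        lengths = {len(m) for m in self.members}
        if len(lengths) > 1:
            raise SeqIOError(f"members have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise SeqIOError(f"alignment length {length} not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.members[0]) // 3

    @property
    def names(self) -> list:
        return [m.name for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, name: str) -> NamedSequence:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(name)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a multi-FASTA file into NamedSequences (uppercased, in order)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence name: {rec.id!r}")
        seen.add(rec.id)
        out.append(NamedSequence(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(seqs, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def fasta_string(seqs, width: int = 60) -> str:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs
    ]
    SeqIO.FastaIO.FastaWriter(buf, wrap=width).write_file(records)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Codon-alignment validation
# ---------------------------------------------------------------------------

def find_internal_stops(seq: NamedSequence, code: GeneticCode = STANDARD_CODE):
    """1-based codon indices of internal stop codons (terminal excluded)."""
    n = len(seq) // 3
    return [
        i + 1
        for i in range(n - 1)
        if code.is_stop(seq.codon(i))
    ]


def validate_codon_alignment(seqs, code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    """Check frame and stops; trim a terminal stop shared by all members.

    Raises with the offending sequence names and 1-based codon positions if
    any member carries a premature (internal) stop codon -- the signature of
    a pseudogenized family member.
    """
    aln = CodonAlignment(list(seqs), code)
    offenders = []
    for m in aln.members:
        for idx in find_internal_stops(m, code):
            offenders.append((m.name, idx))
    if offenders:
        desc = "; ".join(f"{n} codon {i}" for n, i in offenders)
        raise SeqIOError(f"internal stop codon(s): {desc}")
    last = [m.codon(aln.n_codons - 1) for m in aln.members]
    if all(code.is_stop(c) for c in last):
        aln = CodonAlignment(
            [NamedSequence(m.name, m.residues[:-3]) for m in aln.members], code
        )
    elif any(code.is_stop(c) for c in last):
        bad = [m.name for m, c in zip(aln.members, last) if code.is_stop(c)]
        raise SeqIOError(
            f"terminal stop present in only some members: {bad}"
        )
    return aln


def complete_deletion(aln: CodonAlignment, unit: str = "codon"):
    """Drop every column (or codon column) gapped/ambiguous in ANY member.

    Returns ``(new_alignment, index_map)`` where ``index_map[old] = new`` for
    surviving columns (codon columns when ``unit == 'codon'``).
    """
    if unit not in ("nucleotide", "codon"):
        raise ValueError(f"unit must be 'nucleotide' or 'codon', got {unit!r}")
    n_col = aln.n_codons if unit == "codon" else aln.n_codons * 3
    keep = []
    for j in range(n_col):
        if unit == "codon":
            chunks = [m.codon(j) for m in aln.members]
            ok = all(all(b in NUCLEOTIDES for b in c) for c in chunks)
        else:
            ok = all(m.residues[j] in NUCLEOTIDES for m in aln.members)
        if ok:
            keep.append(j)
    if not keep:
        raise SeqIOError("complete deletion removed every column")
    if unit == "nucleotide" and len(keep) % 3:
        # nucleotide-level deletion may break frame; keep as plain sequences
        # is not allowed for CodonAlignment, so pad decision: reject.
        raise SeqIOError(
            "nucleotide-level complete deletion broke the reading frame; "
            "use unit='codon' for coding alignments"
        )
    members = []
    for m in aln.members:
        if unit == "codon":
            res = "".join(m.codon(j) for j in keep)
        else:
            res = "".join(m.residues[j] for j in keep)
        members.append(NamedSequence(m.name, res))
    index_map = {old: new for new, old in enumerate(keep)}
    return CodonAlignment(members, aln.code), index_map


def translate(seq: NamedSequence, code: GeneticCode = STANDARD_CODE) -> NamedSequence:
    """Translate an in-frame nucleotide sequence (terminal stop trimmed)."""
    if len(seq) % 3:
        raise SeqIOError(f"{seq.name}: length {len(seq)} not a multiple of 3")
    n = len(seq) // 3
    codons = [seq.codon(i) for i in range(n)]
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    aas = []
    for i, c in enumerate(codons):
        aa = code.aa(c)
        if aa == "*":
            raise SeqIOError(f"{seq.name}: internal stop at codon {i + 1}")
        aas.append(aa)
    return NamedSequence(seq.name, "".join(aas))


def percent_identity(a: NamedSequence, b: NamedSequence,
                     mode: str = "ignore_gap_columns") -> float:
    """Fraction of identical positions among comparable aligned columns."""
    if len(a) != len(b):
        raise SeqIOError("sequences must be aligned (equal length)")
    if mode not in ("ignore_gap_columns", "count_gaps_as_mismatch"):
        raise ValueError(f"unknown mode {mode!r}")
    matches = compared = 0
    for x, y in zip(a.residues, b.residues):
        gap = x in AMBIGUOUS or y in AMBIGUOUS
        if mode == "ignore_gap_columns" and gap:
            continue
        compared += 1
        if x == y and not gap:
            matches += 1
    if compared == 0:
        raise SeqIOError("no comparable positions")
    return matches / compared


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal node labels are read as support."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise SeqIOError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise SeqIOError("duplicate leaf labels in tree")
    return tree


def read_newick(path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
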