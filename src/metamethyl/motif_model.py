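"""IUPAC methylation motifs and strand-specific motif scanning.

A methylation motif is a short degenerate recognition sequence together with
the index of the methylated base within it (the base a methyltransferase
modifies, e.g. the adenine of G[6mA]TC for a Dam-like enzyme).  Scanning is
always strand-specific: a palindromic motif such as GATC has a methylatable
base on each strand, and each strand occurrence is a distinct instance
because each strand carries its own per-site pileup row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

MOD_TYPES = ("5mC", "6mA", "4mC")

#: Degeneracy set of each IUPAC code: the concrete bases the code stands for.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: What a pattern code accepts in an observed k-mer.  Identical to the
#: degeneracy sets except that only pattern code N tolerates an ambiguous N
#: in the sequence (conservative counting: windows containing N never match
#: a specific code).
MATCH_SETS = {code: (bases | {"N"} if code == "N" else bases)
              for code, bases in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

#: Minimal IUPAC code for every non-empty set of concrete bases.
CODE_FOR_SET = {bases: code for code, bases in IUPAC_SETS.items()}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide or IUPAC pattern string."""
    bad = set(seq.upper()) - set(_COMPLEMENT)
    if bad:
        raise ValueError(f"invalid nucleotide/IUPAC character(s): {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT_TABLE)[::-1]


def iupac_match(pattern: str, kmer: str) -> bool:
    """True iff ``kmer`` is an occurrence of the degenerate ``pattern``.

    Each observed base must lie in the degeneracy set of the corresponding
    pattern code; an N in the k-mer is matched only by pattern code N.
    """
    if len(pattern) != len(kmer):
        raise ValueError(
            f"pattern and k-mer lengths differ: {len(pattern)} vs {len(kmer)}")
    for p, b in zip(pattern.upper(), kmer.upper()):
        try:
            allowed = MATCH_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern") from None
        if b not in allowed:
            return False
    return True


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a regex character-class string."""
    parts = []
    for p in pattern.upper():
        if p not in MATCH_SETS:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern")
        parts.append("[" + "".join(sorted(MATCH_SETS[p])) + "]")
    return "".join(parts)


@dataclass(frozen=True)
class Motif:
    """A methylation motif: IUPAC pattern + methylated-base offset + type.

    ``meth_offset`` is the 0-based index of the methylated base within
    ``iupac``; the code at that index must be able to be the modified base
    (a C-compatible code for 5mC/4mC, an A-compatible code for 6mA).
    """

    iupac: str
    meth_offset: int
    mod_type: str

    def __post_init__(self):
        object.__setattr__(self, "iupac", self.iupac.upper())
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"unknown modification type {self.mod_type!r}")
        if not (0 <= self.meth_offset < len(self.iupac)):
            raise ValueError(
                f"meth_offset {self.meth_offset} outside motif {self.iupac!r}")
        for c in self.iupac:
            if c not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC code {c!r} in {self.iupac!r}")
        canonical = "A" if self.mod_type == "6mA" else "C"
        if canonical not in IUPAC_SETS[self.iupac[self.meth_offset]]:
            raise ValueError(
                f"base {self.iupac[self.meth_offset]!r} at offset "
                f"{self.meth_offset} cannot carry {self.mod_type}")

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def bracketed(self) -> str:
        """Report form with the methylated base bracketed, e.g. G[6mA]TC."""
        i = self.meth_offset
        return f"{self.iupac[:i]}[{self.mod_type}]{self.iupac[i + 1:]}"


@dataclass(frozen=True)
class MotifInstance:
    """One strand-specific occurrence of a motif on a contig.

    ``start`` is the 0-based position of the motif's first base in plus-strand
    orientation; ``site_pos`` is the reference coordinate of the methylated
    base: start + offset on the plus strand, start + (len - 1 - offset) on the
    minus strand (the motif reads along the minus strand there).
    """

    contig: str
    strand: str
    start: int
    site_pos: int
    motif: Motif = field(compare=False)


def scan_motif(seq: str, motif: Motif, contig: str = "contig") -> list[MotifInstance]:
    """All strand-specific instances of ``motif`` in ``seq``.

    The plus strand is scanned with the motif and with its reverse
    complement; a reverse-complement match is a minus-strand instance.
    Overlapping occurrences are all reported, and a palindromic motif yields
    one instance per strand at the same window.  Instances are sorted by
    (start, strand) with '+' before '-'.
    """
    seq = seq.upper()
    k = len(motif)
    out: list[MotifInstance] = []
    fwd = re.compile("(?=" + iupac_to_regex(motif.iupac) + ")")
    for m in fwd.finditer(seq):
        s = m.start()
        out.append(MotifInstance(contig, "+", s, s + motif.meth_offset, motif))
    rev = re.compile("(?=" + iupac_to_regex(reverse_complement(motif.iupac)) + ")")
    for m in rev.finditer(seq):
        s = m.start()
        out.append(
            MotifInstance(contig, "-", s, s + k - 1 - motif.meth_offset, motif))
    out.sort(key=lambda inst: (inst.start, 0 if inst.strand == "+" else 1))
    return out


def count_occurrences(seq: str, pattern: str) -> int:
    """Double-strand occurrence count of an IUPAC pattern in ``seq``."""
    seq = seq.upper()
    n = len(re.findall("(?=" + iupac_to_regex(pattern) + ")", seq))
    n += len(re.findall(
        "(?=" + iupac_to_regex(reverse_complement(pattern)) + ")", seq))
    return n


def pattern_subsumes(general: str, specific: str) -> bool:
    """True iff every instance of ``specific`` is an instance of ``general``.

    ``general`` must be no longer than ``specific`` and must align at some
    offset such that each of its positional degeneracy sets contains the
    corresponding set of ``specific``.  Orientation is the caller's concern.
    """
    g, s = general.upper(), specific.upper()
    if len(g) > len(s):
        return False
    for off in range(len(s) - len(g) + 1):
        if all(IUPAC_SETS[s[off + i]] <= IUPAC_SETS[gc]
               for i, gc in enumerate(g)):
            return True
    return False


def motifs_match(a: str, b: str) -> bool:
    """Whether two IUPAC patterns describe the same recognition site.

    True when either pattern subsumes the other, testing ``b`` in both
    orientations (recognition sequences are double-stranded objects).
    """
    for bb in (b, reverse_complement(b)):
        if pattern_subsumes(a, bb) or pattern_subsumes(bb, a):
            return True
    return False


def information_bits(pattern: str) -> float:
    """Information content of a pattern: sum over positions of 2 - log2 |set|."""
    import math
    return sum(2.0 - math.log2(len(IUPAC_SETS[c])) for c in pattern.upper())


def minimal_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of concrete bases."""
    key = frozenset(b.upper() for b in bases)
    try:
        return CODE_FOR_SET[key]
    except KeyError:
        raise ValueError(f"not a concrete base set: {sorted(key)}") from None
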