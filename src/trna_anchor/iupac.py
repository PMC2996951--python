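"""IUPAC nucleotide-code algebra.

Degenerate primers are mixtures of concrete oligos; every operation on them
reduces to set algebra on the 15 IUPAC codes (A, C, G, T plus the 11
ambiguity codes). This module is the single home for that algebra: code/set
lookup, expansion, degeneracy, compatibility and IUPAC-aware reverse
complement. Gaps ('-') are handled only where explicitly stated.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

#: IUPAC code -> set of concrete bases it stands for.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

IUPAC_CODES: str = "".join(CODE_TO_BASES)

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class IUPACError(ValueError):
    """A symbol outside the IUPAC nucleotide alphabet was encountered."""


def bases(code: str) -> frozenset[str]:
    """Return the concrete base set for one IUPAC code."""
    try:
        return CODE_TO_BASES[code.upper()]
    except KeyError:
        raise IUPACError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(base_set) -> str:
    """Return the unique IUPAC code for a non-empty set of concrete bases."""
    key = frozenset(base_set)
    try:
        return BASES_TO_CODE[key]
    except KeyError:
        raise IUPACError(f"no IUPAC code for base set {sorted(key)!r}") from None


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect (symmetric)."""
    return not bases(a).isdisjoint(bases(b))


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate string stands for."""
    d = 1
    for c in seq:
        d *= len(bases(c))
    return d


def expansions(seq: str):
    """Iterate every concrete sequence of a degenerate string (5'->3' order,
    lexicographic per position)."""
    pools = [sorted(bases(c)) for c in seq]
    for combo in itertools.product(*pools):
        yield "".join(combo)


@lru_cache(maxsize=None)
def _complement_code(code: str) -> str:
    return code_for(frozenset(_COMPLEMENT_BASE[b] for b in bases(code)))


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, W<->W, N<->N, ...)."""
    return "".join(_complement_code(c) for c in reversed(seq.upper()))


def validate(seq: str, *, allow_gap: bool = False) -> str:
    """Upper-case and validate a sequence; raise naming the first bad position."""
    out = seq.upper()
    allowed = set(CODE_TO_BASES)
    if allow_gap:
        allowed.add("-")
    for i, c in enumerate(out):
        if c not in allowed:
            raise IUPACError(f"non-IUPAC symbol {c!r} at position {i}")
    return out
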