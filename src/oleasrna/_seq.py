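"""Shared nucleotide-alphabet helpers.

Everything downstream works on the RNA alphabet {A,C,G,U,N}; DNA input
(adapters, 454 reads) is normalized on ingest with T -> U.
"""

from __future__ import annotations

RNA_BASES = "ACGU"
_VALID = set("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: weight of a base pair under the default folding backend
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


class AlphabetError(ValueError):
    """Sequence contains characters outside {A,C,G,U,T,N}."""


def normalize(seq: str) -> str:
    """Upper-case and convert to the RNA alphabet (T -> U)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise AlphabetError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement on the RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def pair_weight(a: str, b: str) -> int:
    """Weighted pairing rule: GC=3, AU=2, GU wobble=1, else 0."""
    return PAIR_WEIGHT.get((a, b), 0)


def is_complement(a: str, b: str) -> bool:
    """Watson-Crick pair on the RNA alphabet (GU wobble excluded)."""
    return PAIR_WEIGHT.get((a, b), 0) >= 2


def is_wobble(a: str, b: str) -> bool:
    return PAIR_WEIGHT.get((a, b), 0) == 1


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
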