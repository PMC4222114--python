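"""IUB/IUPAC consensus alphabet for diploid Sanger sequences.

A single consensus sequence per accession encodes both alleles of a diploid
individual: homozygous positions carry a plain base and heterozygous positions
carry the two-base IUPAC degenerate code (R=A/G, Y=C/T, S=C/G, W=A/T, K=G/T,
M=A/C).  'N' marks an ambiguous base call, '-' an alignment gap; both are kept
at load time so downstream filters can exclude the affected columns
explicitly rather than silently.

Three-/four-base degenerate codes (B, D, H, V) are rejected on input: a
diploid consensus can support at most two alleles at a site.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable

import numpy as np

from .errors import AlphabetError

BASES: tuple[str, ...] = ("A", "C", "G", "T")

HET_CODES: dict[str, FrozenSet[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

#: Symbol -> set of underlying bases. '-' expands to the empty set.
IUB_EXPAND: dict[str, FrozenSet[str]] = (
    {b: frozenset(b) for b in BASES}
    | dict(HET_CODES)
    | {"N": frozenset(BASES), "-": frozenset()}
)

#: The full load-time alphabet: 4 bases, 6 two-base codes, 'N' and '-'.
ALPHABET: FrozenSet[str] = frozenset(IUB_EXPAND)

#: Symbols allowed in a genotype string (valid SNP sites never carry N or -).
GENOTYPE_ALPHABET: FrozenSet[str] = frozenset(BASES) | frozenset(HET_CODES)

_ALLELES_TO_SYMBOL: dict[FrozenSet[str], str] = {frozenset(b): b for b in BASES} | {
    v: k for k, v in HET_CODES.items()
}

# Extra degenerate codes we deliberately reject at load but recognise as
# "ambiguous" when alignments are constructed programmatically.
MULTIBASE_CODES: FrozenSet[str] = frozenset("BDHVN")


def expand_iub(symbol: str) -> FrozenSet[str]:
    """Expand one IUB symbol to its set of underlying bases.

    R->{A,G}, Y->{C,T}, S->{C,G}, W->{A,T}, K->{G,T}, M->{A,C}; plain bases
    map to singletons, 'N' to all four bases and '-' to the empty set.
    """
    try:
        return IUB_EXPAND[symbol]
    except KeyError:
        raise AlphabetError(f"symbol {symbol!r} is not in the IUB consensus alphabet")


def iub_for_alleles(alleles: Iterable[str]) -> str:
    """Return the consensus symbol for a set of one or two alleles."""
    key = frozenset(alleles)
    try:
        return _ALLELES_TO_SYMBOL[key]
    except KeyError:
        raise AlphabetError(f"no single consensus symbol for alleles {sorted(key)}")


def is_heterozygous(symbol: str) -> bool:
    """True iff *symbol* is one of the six two-base degenerate codes."""
    return symbol in HET_CODES


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA 'U' to 'T'. Does not validate the alphabet."""
    return seq.upper().replace("U", "T")


def validate_sequence(seq: str, *, context: str = "") -> None:
    """Raise :class:`AlphabetError` (naming the 1-based position) on any
    symbol outside the load alphabet."""
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            where = f" in {context}" if context else ""
            raise AlphabetError(
                f"invalid symbol {ch!r} at position {i + 1}{where}"
            )


# ---------------------------------------------------------------------------
# numpy lookup tables used by the vectorised column scanner and K2P kernel.

#: byte -> 4-bit allele mask (A=1, C=2, G=4, T=8); N and B/D/H/V get their
#: multi-base masks, '-' and unknown bytes get 0.
MASK_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _bases in IUB_EXPAND.items():
    _m = 0
    for _b in _bases:
        _m |= 1 << BASES.index(_b)
    MASK_LUT[ord(_sym)] = _m
for _sym, _expansion in {"B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG"}.items():
    _m = 0
    for _b in _expansion:
        _m |= 1 << BASES.index(_b)
    MASK_LUT[ord(_sym)] = _m

#: byte -> True for symbols unscorable in a diploid consensus (N, B, D, H, V).
AMBIGUOUS_LUT = np.zeros(256, dtype=bool)
for _sym in MULTIBASE_CODES:
    AMBIGUOUS_LUT[ord(_sym)] = True

#: byte -> base index 0..3 for A/C/G/T, 255 otherwise (gap, het, ambiguous).
CODE4_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    CODE4_LUT[ord(_b)] = _i

#: popcount of a 4-bit mask.
POPCOUNT4 = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


def seq_to_bytes(seq: str) -> np.ndarray:
    """View a sequence string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
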