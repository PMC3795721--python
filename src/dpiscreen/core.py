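"""Double-stranded k-mer arithmetic.

A double-stranded DNA probe presents every window of its forward strand
*and* the reverse complement of every window to a DNA-binding protein.
Throughout this package a "dsDNA motif" is therefore an equivalence class
``{m, revcomp(m)}`` of a k-mer; palindromic k-mers are their own partner.
This module provides the primitives the library designer and the decoder
are built on: reverse complementation, palindrome tests, canonicalization,
window enumeration of a probe's variable region, and IUPAC pattern
matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "DNA_BASES",
    "CanonicalMotif",
    "reverse_complement",
    "is_palindrome",
    "canonicalize",
    "enumerate_motifs",
    "forward_windows",
    "motif_content",
    "iupac_expand",
    "iupac_match",
]

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC one-letter code -> frozenset of plain bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    sym: frozenset(bases) for sym, bases in ambiguous_dna_values.items() if sym != "X"
}

#: Sorted base tuple -> the minimal IUPAC symbol covering exactly that set.
IUPAC_FROM_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}


def _check_seq(s: str) -> str:
    if not s:
        raise ValueError("empty sequence")
    s = s.upper()
    if any(b not in "ACGT" for b in s):
        bad = sorted({b for b in s if b not in "ACGT"})
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick complement of the reversed sequence.

    >>> reverse_complement("TTGACC")
    'GGTCAA'
    """
    return _check_seq(s).translate(_COMPLEMENT)[::-1]


def is_palindrome(s: str) -> bool:
    """True iff ``s`` equals its own reverse complement.

    A dsDNA palindrome reads the same on both strands (e.g. ``TGATCA``);
    odd-length sequences can never be palindromic.
    """
    s = _check_seq(s)
    return s == s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class CanonicalMotif:
    """A double-strand equivalence class of a k-mer.

    ``representative`` is the lexicographically smaller of the k-mer and
    its reverse complement, so ``canonicalize(m) ==
    canonicalize(reverse_complement(m))`` always holds.
    """

    representative: str

    @property
    def k(self) -> int:
        return len(self.representative)

    @property
    def is_palindrome(self) -> bool:
        return is_palindrome(self.representative)

    @property
    def pair(self) -> tuple[str, ...]:
        """Both directed orientations (one entry for palindromes)."""
        rc = reverse_complement(self.representative)
        if rc == self.representative:
            return (self.representative,)
        return (self.representative, rc)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.representative


def canonical_representative(m: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement (fast path)."""
    rc = m.translate(_COMPLEMENT)[::-1]
    return m if m <= rc else rc


def canonicalize(m: str) -> CanonicalMotif:
    """Map a k-mer to its double-strand equivalence class."""
    return CanonicalMotif(canonical_representative(_check_seq(m)))


def enumerate_motifs(k: int) -> list[CanonicalMotif]:
    """All distinct dsDNA motif classes of length ``k``.

    There are ``(4**k - p)/2 + p`` classes, where ``p = 4**(k//2)``
    palindromes for even ``k`` and ``p = 0`` for odd ``k``; for hexamers
    this gives the 2080 classes (64 palindromic) the probe library must
    encode.
    """
    if not 1 <= k <= 12:
        raise ValueError(f"k must be in 1..12, got {k}")
    seen: set[str] = set()
    out: list[CanonicalMotif] = []
    for tup in itertools.product(DNA_BASES, repeat=k):
        m = "".join(tup)
        rep = canonical_representative(m)
        if rep not in seen:
            seen.add(rep)
            out.append(CanonicalMotif(rep))
    return out


def forward_windows(region: str, k: int) -> list[str]:
    """Ordered length-``k`` windows of the forward strand (0-based starts)."""
    region = _check_seq(region)
    if len(region) < k:
        raise ValueError(f"region of {len(region)} bp shorter than k={k}")
    return [region[i : i + k] for i in range(len(region) - k + 1)]


def motif_content(region: str, k: int) -> tuple[set[CanonicalMotif], list[str]]:
    """dsDNA motif classes covered by a probe's variable region.

    Because the reverse strand's windows are exactly the reverse
    complements of the forward windows, canonicalizing the forward windows
    captures the full double-stranded content: a 20 bp region with 15
    pairwise non-equivalent windows covers 30 distinct hexanucleotide
    sequences counting both strands, i.e. 15 classes.

    Returns the class set and the ordered forward-strand window list.
    """
    windows = forward_windows(region, k)
    return {canonicalize(w) for w in windows}, windows


def directed_content(region: str, k: int) -> set[str]:
    """Distinct directed k-mer sequences on both strands of a region."""
    windows = forward_windows(region, k)
    both = set(windows)
    both.update(reverse_complement(w) for w in windows)
    return both


def iupac_expand(symbol: str) -> frozenset[str]:
    """Plain-base subset denoted by one IUPAC symbol."""
    try:
        return IUPAC_SETS[symbol.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol: {symbol!r}") from None


def _check_pattern(pattern: str) -> str:
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    pattern = pattern.upper()
    for sym in pattern:
        if sym not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC symbol: {sym!r}")
    return pattern


def iupac_match(pattern: str, s: str) -> bool:
    """True iff every base of ``s`` lies in the corresponding symbol's set.

    >>> iupac_match("TTGACY", "TTGACC"), iupac_match("TTGACY", "TTGACG")
    (True, False)
    """
    pattern = _check_pattern(pattern)
    s = _check_seq(s)
    if len(pattern) != len(s):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs sequence {len(s)}"
        )
    return all(b in IUPAC_SETS[sym] for sym, b in zip(pattern, s))


def iupac_reverse_complement(pattern: str) -> str:
    """Reverse complement of a degenerate pattern (Y -> R etc.)."""
    pattern = _check_pattern(pattern)
    out = []
    for sym in reversed(pattern):
        comp = frozenset(reverse_complement(b) for b in IUPAC_SETS[sym])
        out.append(IUPAC_FROM_SET[comp])
    return "".join(out)


def minimal_iupac(bases) -> str:
    """Smallest IUPAC symbol covering all observed bases in a column."""
    key = frozenset(bases)
    if not key:
        raise ValueError("no bases observed")
    return IUPAC_FROM_SET[key]
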