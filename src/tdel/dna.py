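"""Elementary DNA sequence operations used across the package.

Only the unambiguous ACGT alphabet is supported: barcodes, anchor strands
and sequencing reads in this workflow never carry IUPAC ambiguity codes,
and rejecting anything else early catches corrupted inputs.
"""

from __future__ import annotations

ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate_dna(seq: str, *, allow_empty: bool = False, name: str = "sequence") -> str:
    """Return *seq* unchanged if it is a plain ACGT string, else raise ValueError."""
    if not isinstance(seq, str):
        raise ValueError(f"{name} must be a string, got {type(seq).__name__}")
    if not seq:
        if allow_empty:
            return seq
        raise ValueError(f"{name} must be non-empty")
    if not _ALPHABET_SET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET_SET)
        raise ValueError(f"{name} contains non-ACGT characters: {bad!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    validate_dna(seq, allow_empty=True)
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring, classic O(len(a)*len(b)) DP."""
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for ch in a:
        cur = [0] * (len(b) + 1)
        for j, ch_b in enumerate(b, start=1):
            if ch == ch_b:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best:
                    best = v
        prev = cur
    return best


def longest_complementary_run(s1: str, s2: str) -> int:
    """Length (bp) of the longest contiguous antiparallel Watson-Crick duplex.

    Two strands can zip up wherever a substring of one is the reverse
    complement of a substring of the other, so this is the longest common
    substring between ``s1`` and ``reverse_complement(s2)``. Symmetric in
    its arguments.
    """
    validate_dna(s1, name="s1")
    validate_dna(s2, name="s2")
    return _longest_common_substring(s1, reverse_complement(s2))
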