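"""DNA barcode (code) sets with a guaranteed minimum pairwise Hamming distance.

A codebook maps a fixed-length DNA code to the identifier of the building
block it encodes. Keeping every pair of codes at Hamming distance >= d
makes single-base sequencing errors correctable whenever the per-read
mismatch budget is < d/2.
"""

from __future__ import annotations

from functools import cached_property
from typing import Iterable, Mapping

import numpy as np

from .dna import ALPHABET, hamming, validate_dna
from .errors import ConfigError, DesignError

#: sentinel id for corrupted codes equidistant from two codebook entries
_AMBIGUOUS = object()

# assignment outcome labels
ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"
NO_CODE = "no_code"


def build_codebook(
    n_codes: int,
    code_length: int = 12,
    min_distance: int = 3,
    seed: int = 0,
    max_attempts: int | None = None,
) -> list[str]:
    """Draw ``n_codes`` ACGT codes with all pairwise Hamming distances >= ``min_distance``.

    Seeded rejection sampling: candidates are drawn uniformly and kept when
    they clear the distance bound against every accepted code. For the code
    counts used here (up to ~1000 codes of length 12) the accepted fraction
    stays near 1, so the search is cheap and reproducible.

    Raises
    ------
    DesignError
        If the request is impossible (``min_distance`` > ``code_length`` or
        more codes than 4**length) or the bounded search fails.
    """
    if n_codes < 0:
        raise DesignError("n_codes must be >= 0")
    if code_length < 1:
        raise DesignError("code_length must be >= 1")
    if min_distance < 1:
        raise DesignError("min_distance must be >= 1")
    if min_distance > code_length:
        raise DesignError(
            f"min_distance {min_distance} exceeds code_length {code_length}: impossible"
        )
    if n_codes > 4**code_length:
        raise DesignError(f"cannot draw {n_codes} distinct codes of length {code_length}")

    rng = np.random.default_rng(seed)
    limit = max_attempts if max_attempts is not None else max(10_000, 500 * n_codes)
    codes: list[str] = []
    attempts = 0
    while len(codes) < n_codes:
        attempts += 1
        if attempts > limit:
            raise DesignError(
                f"codebook search failed: {len(codes)}/{n_codes} codes after "
                f"{limit} attempts (length={code_length}, min_distance={min_distance})"
            )
        cand = "".join(ALPHABET[i] for i in rng.integers(0, 4, code_length))
        if all(hamming(cand, c) >= min_distance for c in codes):
            codes.append(cand)
    return codes


class Codebook:
    """Immutable code -> building-block-id map with error-tolerant assignment."""

    def __init__(self, code_to_id: Mapping[str, str]):
        if not code_to_id:
            raise ConfigError("codebook must contain at least one code")
        lengths = {len(c) for c in code_to_id}
        if len(lengths) != 1:
            raise ConfigError(f"codebook codes must share one length, got {sorted(lengths)}")
        ids = list(code_to_id.values())
        if len(set(ids)) != len(ids):
            raise ConfigError("codebook ids must be unique")
        for code in code_to_id:
            validate_dna(code, name="code")
        self._code_to_id = dict(code_to_id)
        self.code_length = lengths.pop()

    def __len__(self) -> int:
        return len(self._code_to_id)

    def __contains__(self, code: str) -> bool:
        return code in self._code_to_id

    @property
    def codes(self) -> list[str]:
        return list(self._code_to_id)

    @property
    def ids(self) -> list[str]:
        return list(self._code_to_id.values())

    def id_of(self, code: str) -> str:
        return self._code_to_id[code]

    def code_of(self, bb_id: str) -> str:
        return self._id_to_code[bb_id]

    @cached_property
    def _id_to_code(self) -> dict[str, str]:
        return {v: k for k, v in self._code_to_id.items()}

    @cached_property
    def min_distance(self) -> int:
        """Smallest pairwise Hamming distance; equals code_length for one code."""
        codes = self.codes
        if len(codes) == 1:
            return self.code_length
        mat = np.frombuffer("".join(codes).encode(), dtype=np.uint8)
        mat = mat.reshape(len(codes), self.code_length)
        best = self.code_length
        # blockwise pairwise distances keep memory bounded for large codebooks
        for i in range(0, len(codes), 256):
            block = mat[i : i + 256]
            d = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
            # mask self-comparisons
            rows = np.arange(block.shape[0]) + i
            d[np.arange(block.shape[0]), rows] = self.code_length
            best = min(best, int(d.min()))
        return best

    @cached_property
    def _one_error_neighbors(self) -> dict[str, object]:
        """Map every single-substitution variant of every code to its id.

        Variants reachable from two different codes are marked ambiguous
        (impossible when min_distance >= 3). Exact codes are excluded: the
        exact-match path takes precedence.
        """
        table: dict[str, object] = {}
        for code, bb_id in self._code_to_id.items():
            for pos in range(self.code_length):
                for base in ALPHABET:
                    if base == code[pos]:
                        continue
                    variant = code[:pos] + base + code[pos + 1 :]
                    if variant in self._code_to_id:
                        continue
                    if variant in table and table[variant] != bb_id:
                        table[variant] = _AMBIGUOUS
                    else:
                        table[variant] = bb_id
        return table

    def assign(self, code: str, max_mismatch: int = 1) -> tuple[str | None, str]:
        """Assign ``code`` to the unique nearest codebook entry within ``max_mismatch``.

        Returns ``(id, "assigned")`` on success; otherwise ``(None, reason)``
        with reason ``"no_code"`` (wrong length), ``"ambiguous"`` (tie) or
        ``"unassigned"`` (no entry close enough). When
        ``max_mismatch < min_distance / 2`` the assignment is provably unique.
        """
        if len(code) != self.code_length:
            return None, NO_CODE
        exact = self._code_to_id.get(code)
        if exact is not None:
            return exact, ASSIGNED
        if max_mismatch == 0:
            return None, UNASSIGNED
        if max_mismatch == 1:
            hit = self._one_error_neighbors.get(code)
            if hit is None:
                return None, UNASSIGNED
            if hit is _AMBIGUOUS:
                return None, AMBIGUOUS
            return hit, ASSIGNED
        # general (rare) path: full scan
        best_d = self.code_length + 1
        best_id: str | None = None
        tie = False
        for cand, bb_id in self._code_to_id.items():
            d = hamming(code, cand)
            if d < best_d:
                best_d, best_id, tie = d, bb_id, False
            elif d == best_d:
                tie = True
        if best_d > max_mismatch:
            return None, UNASSIGNED
        if tie:
            return None, AMBIGUOUS
        return best_id, ASSIGNED

    def to_mapping(self) -> dict[str, str]:
        return dict(self._code_to_id)

    @classmethod
    def from_codes(cls, codes: Iterable[str], id_prefix: str) -> "Codebook":
        return cls({code: f"{id_prefix}{i + 1:03d}" for i, code in enumerate(codes)})


def build_index_table(
    sample_names: Iterable[str],
    index_length: int = 8,
    min_distance: int = 3,
    seed: int = 0,
) -> dict[str, str]:
    """Assign each selection sample a distinct index sequence for demultiplexing."""
    names = list(sample_names)
    if len(set(names)) != len(names):
        raise ConfigError("sample names must be unique")
    seqs = build_codebook(len(names), index_length, min_distance, seed=seed)
    return dict(zip(names, seqs))
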