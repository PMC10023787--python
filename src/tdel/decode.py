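"""Decode selection FASTQ files into per-code count tables.

Mirrors the decoding procedure of a DEL selection run: each read is
assigned to its selection sample by the sample index, classified to a
sub-library channel by its constant flank, its code region is extracted
and matched against that channel's codebook, and code occurrences are
counted in a single streaming pass. All matching is Hamming-based
(substitution-only); ambiguity always resolves to an explicit unassigned
tally, never an arbitrary choice, and every rejection reason is reported.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .codes import AMBIGUOUS, ASSIGNED, NO_CODE, UNASSIGNED, Codebook
from .dna import hamming
from .encoding import CHANNEL_ROLES, EncodingScheme
from .errors import ConfigError, FastqFormatError

NO_INDEX = "no_index"
AMBIGUOUS_INDEX = "ambiguous_index"


@dataclass
class CountTable:
    """Per-sample, per-channel code counts plus unassigned tallies.

    Conservation holds by construction: every read seen increments exactly
    one of (an assigned code count, a per-sample no_code/ambiguous tally,
    a global no_index/ambiguous_index tally).
    """

    counts: dict = field(default_factory=lambda: defaultdict(lambda: defaultdict(lambda: defaultdict(int))))
    no_code: dict = field(default_factory=lambda: defaultdict(int))
    ambiguous: dict = field(default_factory=lambda: defaultdict(int))
    no_index: int = 0
    ambiguous_index: int = 0
    total_reads: int = 0

    def channel(self, sample: str, role: str) -> dict[str, int]:
        return dict(self.counts[sample][role])

    def assigned_total(self) -> int:
        return sum(
            k
            for roles in self.counts.values()
            for ch in roles.values()
            for k in ch.values()
        )

    def is_conserved(self) -> bool:
        rejected = self.no_index + self.ambiguous_index
        rejected += sum(self.no_code.values()) + sum(self.ambiguous.values())
        return self.assigned_total() + rejected == self.total_reads

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": sample, "sublibrary": role, "code_id": code_id, "count": k}
            for sample, roles in sorted(self.counts.items())
            for role, ch in sorted(roles.items())
            for code_id, k in sorted(ch.items())
        ]
        return pd.DataFrame(rows, columns=["sample", "sublibrary", "code_id", "count"])

    def qc_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "total_reads", "sample": "", "value": self.total_reads},
            {"metric": "assigned", "sample": "", "value": self.assigned_total()},
            {"metric": NO_INDEX, "sample": "", "value": self.no_index},
            {"metric": AMBIGUOUS_INDEX, "sample": "", "value": self.ambiguous_index},
        ]
        for sample in sorted(set(self.no_code) | set(self.ambiguous) | set(self.counts)):
            rows.append({"metric": NO_CODE, "sample": sample, "value": self.no_code.get(sample, 0)})
            rows.append(
                {"metric": AMBIGUOUS, "sample": sample, "value": self.ambiguous.get(sample, 0)}
            )
        return pd.DataFrame(rows, columns=["metric", "sample", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _nearest_unique(seq: str, candidates: Mapping[str, str], max_mismatch: int):
    """Unique nearest key of ``candidates`` within ``max_mismatch`` Hamming distance."""
    best_d = len(seq) + 1
    best = None
    tie = False
    for cand, value in candidates.items():
        d = hamming(seq, cand)
        if d < best_d:
            best_d, best, tie = d, value, False
        elif d == best_d:
            tie = True
    if best_d > max_mismatch:
        return None, UNASSIGNED
    if tie:
        return None, AMBIGUOUS
    return best, ASSIGNED


def demultiplex(
    read_seq: str,
    index_table: Mapping[str, str],
    max_mismatch: int = 1,
    region: tuple[int, int] = (0, 8),
) -> tuple[str | None, str]:
    """Assign a read to the unique sample index within ``max_mismatch``.

    Returns ``(sample, "assigned")`` or ``(None, reason)`` with reason
    ``"no_index"`` (no index close enough, or read too short) or
    ``"ambiguous"`` (equidistant from two indexes).
    """
    seq_to_sample = _index_lookup(index_table)
    start, end = region
    if len(read_seq) < end:
        return None, NO_INDEX
    observed = read_seq[start:end]
    exact = seq_to_sample.get(observed)
    if exact is not None:
        return exact, ASSIGNED
    if max_mismatch == 0:
        return None, NO_INDEX
    hit, reason = _nearest_unique(observed, seq_to_sample, max_mismatch)
    if reason == UNASSIGNED:
        return None, NO_INDEX
    return hit, reason


def _index_lookup(index_table: Mapping[str, str]) -> dict[str, str]:
    seqs = list(index_table.values())
    if len(set(seqs)) != len(seqs):
        raise ConfigError("index table contains duplicate sequences")
    if len({len(s) for s in seqs} or {0}) > 1:
        raise ConfigError("index sequences must share one length")
    return {seq: sample for sample, seq in index_table.items()}


def extract_code(
    read_seq: str,
    scheme: EncodingScheme,
    channel: str,
    anchored: bool = False,
    flank_mismatch: int = 1,
) -> tuple[str | None, str]:
    """Extract the code region of a read.

    Fixed-coordinate mode slices the scheme's code interval. Anchored mode
    locates the channel's constant flank anywhere in the read (within a
    ``flank_mismatch`` budget) and takes the adjacent window, tolerating
    shifted layouts. Returns ``(code, "assigned")`` or ``(None, "no_code")``.
    """
    code_len = scheme.code_length
    if not anchored:
        start, end = scheme.code_region
        if len(read_seq) < end:
            return None, NO_CODE
        return read_seq[start:end], ASSIGNED
    flank = scheme.flanks[channel]
    flen = len(flank)
    best_pos = None
    best_d = flank_mismatch + 1
    for pos in range(0, len(read_seq) - flen - code_len + 1):
        d = hamming(read_seq[pos : pos + flen], flank)
        if d < best_d:
            best_d, best_pos = d, pos
            if d == 0:
                break
    if best_pos is None:
        return None, NO_CODE
    start = best_pos + flen
    return read_seq[start : start + code_len], ASSIGNED


def assign_code(code: str, codebook: Codebook, max_mismatch: int = 1) -> tuple[str | None, str]:
    """Match a code against a codebook; see :meth:`Codebook.assign`."""
    return codebook.assign(code, max_mismatch)


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (name, seq, qual) from FASTQ or gzipped FASTQ, failing fast on damage."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    record = 0
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                name, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record {record + 1} in {path}: {exc}", record + 1
                ) from exc
            record += 1
            yield name, seq, qual


def iter_reads(source) -> Iterator[tuple[str, str, str]]:
    """Normalize a read source: path(s), or iterables of records / raw sequences."""
    if isinstance(source, (str, Path)):
        yield from _iter_fastq(source)
        return
    for item in source:
        if isinstance(item, (str, Path)) and Path(str(item)).suffix in {".fastq", ".fq", ".gz"}:
            yield from _iter_fastq(item)
        elif isinstance(item, str):
            yield "", item, ""
        else:
            yield item


def count_reads(
    source,
    scheme: EncodingScheme,
    index_table: Mapping[str, str] | None = None,
    max_mm_index: int = 1,
    max_mm_code: int = 1,
    flank_mismatch: int = 1,
) -> CountTable:
    """Single streaming pass: demultiplex, classify channel, assign and count codes.

    ``source`` may be FASTQ path(s) (gzip transparent) or any iterable of
    (name, seq, qual) records. ``index_table`` defaults to the scheme's.
    Memory is constant in the number of reads; only per-code counters are held.
    """
    index_table = scheme.index_table if index_table is None else index_table
    seq_to_sample = _index_lookup(index_table)
    flank_to_role = {scheme.flanks[r]: r for r in CHANNEL_ROLES if r in scheme.flanks}
    if len(flank_to_role) != len(scheme.flanks):
        raise ConfigError("channel flanks are not distinct")
    codebooks = scheme.codebooks
    i0, i1 = scheme.index_region
    f0, f1 = scheme.flank_region
    c0, c1 = scheme.code_region

    table = CountTable()
    counts = table.counts
    for _, seq, _ in iter_reads(source):
        table.total_reads += 1
        if scheme.reverse_complemented:
            from .dna import reverse_complement

            seq = reverse_complement(seq)
        if len(seq) < c1:
            # cannot even demultiplex reliably; treat as index failure if the
            # index region itself is truncated, else as a code failure
            if len(seq) < i1:
                table.no_index += 1
                continue
        # --- sample index ---
        sample = seq_to_sample.get(seq[i0:i1])
        if sample is None:
            if max_mm_index > 0:
                sample, reason = _nearest_unique(seq[i0:i1], seq_to_sample, max_mm_index)
            else:
                reason = UNASSIGNED
            if sample is None:
                if reason == AMBIGUOUS:
                    table.ambiguous_index += 1
                else:
                    table.no_index += 1
                continue
        # --- channel via constant flank ---
        role = flank_to_role.get(seq[f0:f1])
        if role is None:
            role, reason = _nearest_unique(seq[f0:f1], flank_to_role, flank_mismatch)
            if role is None:
                if reason == AMBIGUOUS:
                    table.ambiguous[sample] += 1
                else:
                    table.no_code[sample] += 1
                continue
        # --- code ---
        if len(seq) < c1:
            table.no_code[sample] += 1
            continue
        code_id, reason = codebooks[role].assign(seq[c0:c1], max_mm_code)
        if code_id is None:
            if reason == AMBIGUOUS:
                table.ambiguous[sample] += 1
            else:
                table.no_code[sample] += 1
            continue
        counts[sample][role][code_id] += 1
    return table
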