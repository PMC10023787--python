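"""DNA architecture of the trio-pharmacophore library and its NGS read layout.

The assembled library is held together purely by hybridization: the SL-A
strand and the left SL-B strand share a long (33 bp) complementary region,
the right SL-B strand and the SL-C strand share a shorter (13 bp) region,
and SL-A/SL-C share only a 6 bp overlap that is too short to form a stable
duplex on its own. The two SL-B strands are internally bridged by 6 + 12
complementary base pairs. This module generates anchor-strand sets that
realize a declared duplex specification, validates which sub-library
mixtures assemble at a given stability threshold, and defines the layout
(sample index, constant flank, code) of the sequencing reads used to
decode selections.

Hybridization is deliberately modeled as the longest contiguous perfect
duplex compared against a base-pair threshold — no nearest-neighbor
thermodynamics. The assembly evidence this mirrors is qualitative (a 6 bp
overlap fails to hold a complex together while 13 bp suffices), and a
contiguity cutoff reproduces that with a single parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .codes import Codebook, build_codebook, build_index_table
from .dna import ALPHABET, hamming, longest_complementary_run, reverse_complement, validate_dna
from .errors import ConfigError, DesignError

#: declared duplex lengths (bp) of the default architecture
DEFAULT_DUPLEX_SPEC: dict[str, int] = {
    "B_internal_short": 6,
    "B_internal_long": 12,
    "A_B": 33,
    "B_C": 13,
    "A_C": 6,
}

#: default anchor strand lengths (nt); each must accommodate its declared segments
DEFAULT_STRAND_LENGTHS: dict[str, int] = {"A": 48, "B_left": 57, "B_right": 37, "C": 27}

ANCHOR_NAMES = ("A", "B_left", "B_right", "C")

#: roles of the three read channels; each sub-library is decoded independently
CHANNEL_ROLES = ("A", "B", "C")

#: anchor strand whose ends provide the constant read flank for each channel
_CHANNEL_ANCHOR = {"A": "A", "B": "B_left", "C": "C"}

DEFAULT_INDEX_LENGTH = 8
DEFAULT_FLANK_LENGTH = 10
DEFAULT_CODE_LENGTH = 12
DEFAULT_STABILITY_THRESHOLD = 10
#: unintended cross-pair duplexes must stay strictly below this length
DEFAULT_SPOILER_THRESHOLD = 6


@dataclass
class EncodingScheme:
    """Anchor strands, read layout, codebooks and sample indexes of one design.

    ``region_map`` holds 0-based half-open intervals on the sequenced strand
    (sequencing orientation); set ``reverse_complemented`` for layouts read
    from the opposite strand.
    """

    anchors: dict[str, str]
    duplex_spec: dict[str, int]
    read_length: int
    region_map: dict[str, tuple[int, int]]
    flanks: dict[str, str]
    tails: dict[str, str]
    codebooks: dict[str, Codebook] = field(default_factory=dict)
    index_table: dict[str, str] = field(default_factory=dict)
    reverse_complemented: bool = False

    def __post_init__(self):
        for name in ANCHOR_NAMES:
            if name not in self.anchors:
                raise ConfigError(f"anchor strand {name!r} missing from scheme")
            validate_dna(self.anchors[name], name=f"anchor {name}")
        intervals = sorted(self.region_map.values())
        for start, end in intervals:
            if not (0 <= start < end <= self.read_length):
                raise ConfigError(f"region ({start}, {end}) outside read of length {self.read_length}")
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ConfigError("read layout regions overlap")
        index_seqs = list(self.index_table.values())
        if len(set(index_seqs)) != len(index_seqs):
            raise ConfigError("duplicate index sequences in index table")
        for name, seq in self.index_table.items():
            validate_dna(seq, name=f"index {name}")

    # -- derived layout accessors -------------------------------------------------

    @property
    def index_region(self) -> tuple[int, int]:
        return self.region_map["sample_index"]

    @property
    def flank_region(self) -> tuple[int, int]:
        return self.region_map["flank"]

    @property
    def code_region(self) -> tuple[int, int]:
        return self.region_map["code"]

    @property
    def code_length(self) -> int:
        start, end = self.code_region
        return end - start

    def read_template(self, sample: str, channel: str, code: str) -> str:
        """Assemble the error-free read for one code on one channel."""
        index = self.index_table[sample]
        return index + self.flanks[channel] + code + self.tails[channel]

    # -- serialization ------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "anchors": dict(self.anchors),
            "duplex_spec": dict(self.duplex_spec),
            "read_length": self.read_length,
            "region_map": {k: list(v) for k, v in self.region_map.items()},
            "flanks": dict(self.flanks),
            "tails": dict(self.tails),
            "codebooks": {r: cb.to_mapping() for r, cb in self.codebooks.items()},
            "index_table": dict(self.index_table),
            "reverse_complemented": self.reverse_complemented,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncodingScheme":
        return cls(
            anchors=dict(d["anchors"]),
            duplex_spec={k: int(v) for k, v in d["duplex_spec"].items()},
            read_length=int(d["read_length"]),
            region_map={k: tuple(v) for k, v in d["region_map"].items()},
            flanks=dict(d["flanks"]),
            tails=dict(d["tails"]),
            codebooks={r: Codebook(m) for r, m in d.get("codebooks", {}).items()},
            index_table=dict(d.get("index_table", {})),
            reverse_complemented=bool(d.get("reverse_complemented", False)),
        )

    def save(self, path: str | Path) -> None:
        """Write the design file (JSON or YAML by extension)."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "EncodingScheme":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(data)

    def anchors_to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        records = [
            SeqRecord(Seq(seq), id=f"anchor_{name}", description="")
            for name, seq in self.anchors.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def anchors_from_fasta(cls, path: str | Path) -> dict[str, str]:
        """Read anchor strands from FASTA records named ``anchor_<name>``."""
        from Bio import SeqIO

        anchors = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id.removeprefix("anchor_")
            anchors[name] = str(rec.seq).upper()
        return anchors


@dataclass
class PairingReport:
    """Which sub-library mixtures assemble at a duplex-length threshold."""

    threshold: int
    duplex_lengths: dict[str, int]
    stable: dict[str, bool]

    def is_stable(self, pair: str) -> bool:
        return self.stable[pair]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, n))


def _place(segments: list[str], total_length: int, rng: np.random.Generator) -> str:
    """Concatenate segments with random spacer bases distributed between/around them."""
    core = sum(map(len, segments))
    pad_total = total_length - core
    n_gaps = len(segments) + 1
    cuts = np.sort(rng.integers(0, pad_total + 1, n_gaps - 1))
    pads = np.diff(np.concatenate(([0], cuts, [pad_total])))
    parts = []
    for pad, seg in zip(pads, segments + [""]):
        parts.append(_random_seq(rng, int(pad)))
        parts.append(seg)
    return "".join(parts)


def design_anchor_set(
    duplex_spec: Mapping[str, int] | None = None,
    strand_lengths: Mapping[str, int] | None = None,
    seed: int = 0,
    spoiler_threshold: int = DEFAULT_SPOILER_THRESHOLD,
    max_attempts: int = 500,
) -> dict[str, str]:
    """Design four anchor strands realizing the declared duplex lengths exactly.

    Seeded rejection sampling: complementary segments of the declared
    lengths are embedded in otherwise random strands, and a candidate set
    is accepted only if every declared pair reproduces its length exactly
    under :func:`longest_complementary_run`, the short internal SL-B duplex
    is present as a separate run, unintended cross-pairs stay below
    ``spoiler_threshold``, and the per-channel read flanks derived from the
    strand ends are mutually distinguishable (Hamming distance >= 4).
    Deterministic for a fixed seed.
    """
    spec = dict(DEFAULT_DUPLEX_SPEC if duplex_spec is None else duplex_spec)
    lengths = dict(DEFAULT_STRAND_LENGTHS if strand_lengths is None else strand_lengths)
    missing = set(DEFAULT_DUPLEX_SPEC) - set(spec)
    if missing:
        raise DesignError(f"duplex_spec lacks entries {sorted(missing)}")

    need = {
        "A": spec["A_B"] + spec["A_C"],
        "B_left": spec["A_B"] + spec["B_internal_short"] + spec["B_internal_long"],
        "B_right": spec["B_internal_short"] + spec["B_internal_long"] + spec["B_C"],
        "C": spec["B_C"] + spec["A_C"],
    }
    for name, n in need.items():
        if n > lengths.get(name, 0):
            raise DesignError(
                f"infeasible design: strand {name} of length {lengths.get(name)} cannot "
                f"hold {n} nt of declared duplex segments"
            )

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        seg_ab = _random_seq(rng, spec["A_B"])
        seg_ac = _random_seq(rng, spec["A_C"])
        seg_bc = _random_seq(rng, spec["B_C"])
        seg_s = _random_seq(rng, spec["B_internal_short"])
        seg_l = _random_seq(rng, spec["B_internal_long"])

        anchors = {
            "A": _place([seg_ab, seg_ac], lengths["A"], rng),
            "B_left": _place([reverse_complement(seg_ab), seg_s, seg_l], lengths["B_left"], rng),
            "B_right": _place(
                [reverse_complement(seg_l), reverse_complement(seg_s), seg_bc],
                lengths["B_right"],
                rng,
            ),
            "C": _place([reverse_complement(seg_bc), reverse_complement(seg_ac)], lengths["C"], rng),
        }
        if _anchor_set_valid(anchors, spec, seg_s, spoiler_threshold):
            return anchors
    raise DesignError(
        f"anchor design failed after {max_attempts} attempts "
        f"(spec={spec}, lengths={lengths}, spoiler_threshold={spoiler_threshold})"
    )


def _anchor_set_valid(
    anchors: Mapping[str, str],
    spec: Mapping[str, int],
    internal_short_segment: str,
    spoiler_threshold: int,
) -> bool:
    lcr = longest_complementary_run
    if lcr(anchors["A"], anchors["B_left"]) != spec["A_B"]:
        return False
    if lcr(anchors["B_right"], anchors["C"]) != spec["B_C"]:
        return False
    if lcr(anchors["A"], anchors["C"]) != spec["A_C"]:
        return False
    if lcr(anchors["B_left"], anchors["B_right"]) != max(
        spec["B_internal_long"], spec["B_internal_short"]
    ):
        return False
    # the short internal duplex must exist as its own run
    if lcr(internal_short_segment, anchors["B_right"]) != spec["B_internal_short"]:
        return False
    # unintended cross-pairs must not hybridize
    if lcr(anchors["A"], anchors["B_right"]) >= spoiler_threshold:
        return False
    if lcr(anchors["B_left"], anchors["C"]) >= spoiler_threshold:
        return False
    # read flanks (strand ends) must be distinguishable between channels
    flanks = [anchors[_CHANNEL_ANCHOR[r]][:DEFAULT_FLANK_LENGTH] for r in CHANNEL_ROLES]
    for i in range(len(flanks)):
        for j in range(i + 1, len(flanks)):
            if hamming(flanks[i], flanks[j]) < 4:
                return False
    return True


def design_scheme(
    sublibrary_sizes: Mapping[str, int],
    sample_names: Iterable[str],
    seed: int = 0,
    duplex_spec: Mapping[str, int] | None = None,
    strand_lengths: Mapping[str, int] | None = None,
    code_length: int = DEFAULT_CODE_LENGTH,
    code_min_distance: int = 3,
    index_length: int = DEFAULT_INDEX_LENGTH,
    flank_length: int = DEFAULT_FLANK_LENGTH,
) -> EncodingScheme:
    """Design a complete encoding scheme: anchors, read layout, codebooks, indexes.

    The read layout is ``[sample_index][constant flank][code][tail]``; the
    constant flank and tail of each channel are the ends of that channel's
    anchor strand, so a read identifies its sub-library by its flank.
    """
    anchors = design_anchor_set(duplex_spec, strand_lengths, seed=seed)
    spec = dict(DEFAULT_DUPLEX_SPEC if duplex_spec is None else duplex_spec)
    flanks = {r: anchors[_CHANNEL_ANCHOR[r]][:flank_length] for r in CHANNEL_ROLES}
    tails = {r: anchors[_CHANNEL_ANCHOR[r]][-flank_length:] for r in CHANNEL_ROLES}
    read_length = index_length + flank_length + code_length + flank_length
    region_map = {
        "sample_index": (0, index_length),
        "flank": (index_length, index_length + flank_length),
        "code": (index_length + flank_length, index_length + flank_length + code_length),
    }
    codebooks = {}
    for offset, role in enumerate(CHANNEL_ROLES):
        n = int(sublibrary_sizes[role])
        codes = build_codebook(n, code_length, code_min_distance, seed=seed + 1000 + offset)
        codebooks[role] = Codebook.from_codes(codes, id_prefix=role)
    index_table = build_index_table(
        sample_names, index_length=index_length, min_distance=3, seed=seed + 2000
    )
    return EncodingScheme(
        anchors=anchors,
        duplex_spec=spec,
        read_length=read_length,
        region_map=region_map,
        flanks=flanks,
        tails=tails,
        codebooks=codebooks,
        index_table=index_table,
    )


def validate_assembly(
    scheme: EncodingScheme,
    stability_threshold: int = DEFAULT_STABILITY_THRESHOLD,
    present: Iterable[str] = CHANNEL_ROLES,
) -> PairingReport:
    """Predict which sub-library mixtures form stable complexes.

    A pair is stable when its longest contiguous duplex reaches the
    threshold; the full trimer is stable iff both the A-B and B-C contacts
    are. With the default architecture (A-B 33 bp, B-C 13 bp, A-C 6 bp)
    any threshold in 7..13 bp gives the native-PAGE pattern: A-B, B-C and
    A-B-C assemble while A+C alone does not.
    """
    present = set(present)
    unknown = present - set(CHANNEL_ROLES)
    if unknown:
        raise ConfigError(f"unknown sub-library roles {sorted(unknown)}")
    a = scheme.anchors["A"]
    b_left, b_right = scheme.anchors["B_left"], scheme.anchors["B_right"]
    c = scheme.anchors["C"]
    pair_lengths = {}
    if {"A", "B"} <= present:
        pair_lengths["A-B"] = max(
            longest_complementary_run(a, b_left), longest_complementary_run(a, b_right)
        )
    if {"A", "C"} <= present:
        pair_lengths["A-C"] = longest_complementary_run(a, c)
    if {"B", "C"} <= present:
        pair_lengths["B-C"] = max(
            longest_complementary_run(b_left, c), longest_complementary_run(b_right, c)
        )
    stable = {pair: length >= stability_threshold for pair, length in pair_lengths.items()}
    if present == {"A", "B", "C"}:
        stable["A-B-C"] = stable["A-B"] and stable["B-C"]
    return PairingReport(threshold=stability_threshold, duplex_lengths=pair_lengths, stable=stable)
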