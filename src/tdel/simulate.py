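"""Synthetic affinity selections with full ground truth.

Everything downstream of the wet lab — demultiplexing, code assignment,
counting, enrichment, qPCR quantification — is testable against simulated
selections whose true capture weights are known. One selection is modeled
as a single probabilistic capture round: the post-selection pool is one
multinomial draw of ``pool_size`` members with probabilities proportional
to pre-selection abundance times a per-member capture weight.

The capture weight encodes avidity between the two flanking fragments
modulated by the linker:

    target:    W(a, b, c) = beta + w_a[a] * w_c[c] * l_b[b]
    no_target: W = beta                      (blank support: background only)
    no_ligand: W = beta + eps_direct * l_b[b] (linker may touch the target weakly)

where ``beta > 0`` is non-specific background capture. The multiplicative
form is a declared modeling choice kept behind the BindingModel interface.

Sequencing is strand-wise: the three sub-libraries are decoded
independently, so each read carries exactly one sub-library's code and
each pool member contributes one read per channel per pool copy (before
optional depth resampling). Sequencing errors are substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .encoding import CHANNEL_ROLES, EncodingScheme
from .errors import ConfigError
from .library import BuildingBlock, SubLibrary, TDELibrary
from .qpcr import StandardCurve

MODES = ("target", "no_target", "no_ligand")

_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class BindingModel:
    """Per-building-block capture weights for one selection mode."""

    w_a: np.ndarray
    w_c: np.ndarray
    l_b: np.ndarray
    beta: float = 1.0
    mode: str = "target"
    epsilon_direct: float = 0.1

    def __post_init__(self):
        self.w_a = np.asarray(self.w_a, dtype=float)
        self.w_c = np.asarray(self.w_c, dtype=float)
        self.l_b = np.asarray(self.l_b, dtype=float)
        for name, arr in (("w_a", self.w_a), ("w_c", self.w_c), ("l_b", self.l_b)):
            if arr.ndim != 1:
                raise ConfigError(f"{name} must be 1-dimensional")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ConfigError(f"{name} must be finite and >= 0")
        if not self.beta > 0:
            raise ConfigError(f"beta must be > 0, got {self.beta}")
        if self.epsilon_direct < 0:
            raise ConfigError("epsilon_direct must be >= 0")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.w_a), len(self.l_b), len(self.w_c)

    def with_mode(self, mode: str) -> "BindingModel":
        return BindingModel(self.w_a, self.w_c, self.l_b, self.beta, mode, self.epsilon_direct)

    def channel_truth(self, role: str) -> np.ndarray:
        """The true per-building-block weight vector of one channel."""
        return {"A": self.w_a, "B": self.l_b, "C": self.w_c}[role]


def capture_weight(member_index: tuple[int, int, int], model: BindingModel) -> float:
    """Capture weight of one (a, b, c) member under the model's mode."""
    ia, ib, ic = member_index
    na, nb, nc = model.shape
    if not (0 <= ia < na and 0 <= ib < nb and 0 <= ic < nc):
        raise ConfigError(f"member index {member_index} outside library shape {model.shape}")
    if model.mode == "no_target":
        return float(model.beta)
    if model.mode == "no_ligand":
        return float(model.beta + model.epsilon_direct * model.l_b[ib])
    return float(model.beta + model.w_a[ia] * model.w_c[ic] * model.l_b[ib])


def capture_weights(model: BindingModel) -> np.ndarray:
    """Dense (n_a, n_b, n_c) array of capture weights. Desk-scale libraries only."""
    na, nb, nc = model.shape
    if model.mode == "no_target":
        return np.full((na, nb, nc), model.beta)
    if model.mode == "no_ligand":
        w = model.beta + model.epsilon_direct * model.l_b
        return np.broadcast_to(w[None, :, None], (na, nb, nc)).copy()
    synergy = np.einsum("a,b,c->abc", model.w_a, model.l_b, model.w_c)
    return model.beta + synergy


@dataclass
class SelectionTruth:
    """Ground truth of one simulated selection (member-level counts and weights)."""

    shape: tuple[int, int, int]
    weights: np.ndarray
    pre_counts: np.ndarray
    post_counts: np.ndarray
    pool_size: int
    seed: int
    mode: str

    def marginal(self, role: str, which: str = "post") -> np.ndarray:
        """Per-building-block read counts of one channel (sum over the other axes)."""
        counts = {"pre": self.pre_counts, "post": self.post_counts}[which]
        cube = counts.reshape(self.shape)
        axis_keep = {"A": 0, "B": 1, "C": 2}[role]
        axes = tuple(i for i in range(3) if i != axis_keep)
        return cube.sum(axis=axes)

    def to_frame(self, library: TDELibrary) -> pd.DataFrame:
        """Member-level truth table (a_id, b_id, c_id, W, pre_count, post_count)."""
        na, nb, nc = self.shape
        ia, ib, ic = np.unravel_index(np.arange(na * nb * nc), self.shape)
        ids_a = np.asarray(library.sub("A").ids)
        ids_b = np.asarray(library.sub("B").ids)
        ids_c = np.asarray(library.sub("C").ids)
        return pd.DataFrame(
            {
                "a_id": ids_a[ia],
                "b_id": ids_b[ib],
                "c_id": ids_c[ic],
                "weight": self.weights.ravel(),
                "pre_count": self.pre_counts.ravel(),
                "post_count": self.post_counts.ravel(),
            }
        )


def simulate_selection(
    pre_abundances: np.ndarray,
    model: BindingModel,
    pool_size: int,
    seed: int,
) -> SelectionTruth:
    """One capture round: multinomial resampling weighted by capture weights.

    ``pre_abundances`` is a (n_a, n_b, n_c) array (or flat vector) of
    relative member abundances in the naive assembled pool. The pre pool
    is itself sampled (``pre_counts``) so that the pre-selection sequencing
    channel carries realistic sampling noise.
    """
    if pool_size <= 0:
        raise ConfigError(f"pool_size must be > 0, got {pool_size}")
    shape = model.shape
    ab = np.asarray(pre_abundances, dtype=float).reshape(shape)
    if np.any(ab < 0) or not np.all(np.isfinite(ab)):
        raise ConfigError("abundances must be finite and >= 0")
    total = ab.sum()
    if total <= 0:
        raise ConfigError("abundances must not be all zero")
    rng = np.random.default_rng(seed)
    p_pre = (ab / total).ravel()
    pre_counts = rng.multinomial(pool_size, p_pre)
    weights = capture_weights(model)
    cap = ab.ravel() * weights.ravel()
    cap_total = cap.sum()
    if cap_total <= 0:
        raise ConfigError("all capture probabilities are zero")
    post_counts = rng.multinomial(pool_size, cap / cap_total)
    return SelectionTruth(
        shape=shape,
        weights=weights,
        pre_counts=pre_counts.reshape(shape),
        post_counts=post_counts.reshape(shape),
        pool_size=pool_size,
        seed=seed,
        mode=model.mode,
    )


def simulate_capture(
    input_counts: np.ndarray,
    model: BindingModel,
    seed: int,
    capture_rate: float = 0.01,
) -> np.ndarray:
    """Absolute capture yields: each input copy is retained independently.

    Retention probability of a member is ``capture_rate * W`` (clipped at 1),
    so unlike :func:`simulate_selection` — which models the *composition* of
    a fixed-size sequenced pool — the total recovered material differs
    between selection modes. This is the quantity a qPCR readout sees: with
    ligand-bearing flanks the whole linker sub-library elutes in larger
    amounts than in a no-ligand selection, which in turn exceeds background.
    """
    if not 0 < capture_rate:
        raise ConfigError("capture_rate must be > 0")
    counts = np.asarray(input_counts, dtype=np.int64).reshape(model.shape)
    if np.any(counts < 0):
        raise ConfigError("input counts must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.clip(capture_rate * capture_weights(model), 0.0, 1.0)
    return rng.binomial(counts, p)


def random_binding_model(
    shape: tuple[int, int, int],
    seed: int,
    sigma_fragment: float = 1.0,
    sigma_linker: float = 0.5,
    beta: float = 1.0,
    epsilon_direct: float = 0.1,
    mode: str = "target",
) -> BindingModel:
    """Draw log-normal fragment and linker weights (median 1, declared spreads).

    Fragment affinities in a diverse library span orders of magnitude, so a
    log-normal with sigma 1 is used for the flanking fragments; linkers
    modulate rather than dominate binding, hence the tighter sigma 0.5.
    """
    na, nb, nc = shape
    rng = np.random.default_rng(seed)
    return BindingModel(
        w_a=rng.lognormal(0.0, sigma_fragment, na),
        w_c=rng.lognormal(0.0, sigma_fragment, nc),
        l_b=rng.lognormal(0.0, sigma_linker, nb),
        beta=beta,
        mode=mode,
        epsilon_direct=epsilon_direct,
    )


def synthetic_library(scheme: EncodingScheme, seed: int = 0) -> TDELibrary:
    """Build a library whose members carry the scheme's codes and random masses.

    Masses emulate typical fragment sizes: flanking fragments uniform in
    120-280 Da, linkers in 80-220 Da.
    """
    rng = np.random.default_rng(seed)
    subs = {}
    ranges = {"A": (120.0, 280.0), "B": (80.0, 220.0), "C": (120.0, 280.0)}
    for role in CHANNEL_ROLES:
        cb = scheme.codebooks[role]
        lo, hi = ranges[role]
        masses = rng.uniform(lo, hi, len(cb))
        members = [
            BuildingBlock(id=bb_id, sublibrary=role, code=code, mass=float(m))
            for (code, bb_id), m in zip(cb.to_mapping().items(), masses)
        ]
        subs[role] = SubLibrary(name=f"SL-{role}", role=role, members=members)
    return TDELibrary(subs["A"], subs["B"], subs["C"])


def resample_depth(member_counts: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Subsample a pool to a sequencing depth (multinomial over pool fractions)."""
    counts = np.asarray(member_counts)
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    rng = np.random.default_rng(seed)
    flat = rng.multinomial(depth, counts.ravel() / total)
    return flat.reshape(counts.shape)


def _channel_code_counts(
    member_counts: np.ndarray,
    library: TDELibrary,
    role: str,
) -> list[tuple[str, str, int]]:
    """Per-channel (code, id, count) triples from member-level pool counts."""
    shape = library.shape
    cube = np.asarray(member_counts).reshape(shape)
    axis_keep = {"A": 0, "B": 1, "C": 2}[role]
    axes = tuple(i for i in range(3) if i != axis_keep)
    marg = cube.sum(axis=axes)
    sub = library.sub(role)
    return [(m.code, m.id, int(k)) for m, k in zip(sub.members, marg)]


def generate_fastq(
    member_counts: np.ndarray | Mapping[tuple[str, str, str], int],
    scheme: EncodingScheme,
    library: TDELibrary,
    sample_name: str,
    error_rate: float = 0.0,
    seed: int = 0,
    channels: Iterable[str] = CHANNEL_ROLES,
) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) FASTQ records for one selection sample.

    Each member contributes, per channel, one read per pool copy; a read is
    ``index + flank + code + tail`` with independent per-base substitution
    probability ``error_rate``. Read names carry the channel and the true
    source id (``sample:channel:true_id:serial``) so per-read decoding
    accuracy can be audited. Reads are emitted in seeded shuffled order
    within each channel. Quality is constant Phred 40 ('I').
    """
    if sample_name not in scheme.index_table:
        raise ConfigError(f"unknown sample {sample_name!r}: not in index table")
    if not 0 <= error_rate < 1:
        raise ConfigError(f"error_rate must be in [0, 1), got {error_rate}")
    if isinstance(member_counts, Mapping):
        counts = np.zeros(library.shape, dtype=np.int64)
        idx = {
            role: {bb_id: i for i, bb_id in enumerate(library.sub(role).ids)}
            for role in CHANNEL_ROLES
        }
        for (a_id, b_id, c_id), k in member_counts.items():
            if k < 0:
                raise ConfigError("member counts must be >= 0")
            counts[idx["A"][a_id], idx["B"][b_id], idx["C"][c_id]] += int(k)
    else:
        counts = np.asarray(member_counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ConfigError("member counts must be >= 0")

    rng = np.random.default_rng(seed)
    qual = "I" * scheme.read_length
    for role in channels:
        triples = _channel_code_counts(counts, library, role)
        n_reads = sum(k for _, _, k in triples)
        if n_reads == 0:
            continue
        templates = np.zeros((len(triples), scheme.read_length), dtype=np.uint8)
        for row, (code, _, _) in enumerate(triples):
            templates[row] = np.frombuffer(
                scheme.read_template(sample_name, role, code).encode(), dtype=np.uint8
            )
        reps = np.array([k for _, _, k in triples])
        reads = np.repeat(templates, reps, axis=0)
        source = np.repeat(np.array([bb_id for _, bb_id, _ in triples]), reps)
        order = rng.permutation(n_reads)
        reads = reads[order]
        source = source[order]
        if error_rate > 0:
            mask = rng.random(reads.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                shift = rng.integers(1, 4, n_err).astype(np.uint8)
                reads[mask] = _BASES_U8[(_BASE_INDEX[reads[mask]] + shift) % 4]
        for i in range(n_reads):
            name = f"{sample_name}:{role}:{source[i]}:{i}"
            yield name, bytes(reads[i]).decode("ascii"), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (name, seq, qual) records as 4-line FASTQ; gzip when path ends in .gz."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


BELOW_DETECTION = "below_detection"


def simulate_qpcr(
    true_amounts: Mapping[str, float],
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct values from a log-linear standard-curve model with Gaussian noise.

    Ct = slope * log10(amount) + intercept + Normal(0, noise_sd). Codes with
    non-positive amounts are flagged ``below_detection`` (Ct left empty)
    rather than producing silent NaN arithmetic downstream.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for code_id, amount in true_amounts.items():
        if amount <= 0:
            rows.append({"code_id": code_id, "ct": np.nan, BELOW_DETECTION: True})
            continue
        ct = curve.slope * np.log10(amount) + curve.intercept
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        rows.append({"code_id": code_id, "ct": float(ct), BELOW_DETECTION: False})
    return pd.DataFrame(rows, columns=["code_id", "ct", BELOW_DETECTION])
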