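"""Building blocks, sub-libraries and the assembled combinatorial library.

A trio-pharmacophore DNA-encoded library (T-DEL) is the self-assembly
product of three independently synthesized, purified sub-libraries: two
fragment collections (roles A and C) displayed at the ends of a DNA
complex, bridged by a linker collection (role B). Each building block
carries a DNA code; the assembled library is the full factorial of the
three member sets, so an 883 x 30 x 890 design yields 23,576,100 members
without any member ever being synthesized individually.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .dna import validate_dna
from .errors import ConfigError, MassUnavailableError

ROLES = ("A", "B", "C")


@dataclass(frozen=True)
class BuildingBlock:
    """One chemical fragment or linker together with its DNA code."""

    id: str
    sublibrary: str
    code: str
    smiles: str | None = None
    mass: float | None = None

    def __post_init__(self):
        if not self.id:
            raise ConfigError("building block id must be non-empty")
        if self.sublibrary not in ROLES:
            raise ConfigError(f"sublibrary role must be one of {ROLES}, got {self.sublibrary!r}")
        validate_dna(self.code, name=f"code of {self.id}")
        if self.mass is not None and not self.mass > 0:
            raise ConfigError(f"mass of {self.id} must be > 0, got {self.mass}")


@dataclass
class SubLibrary:
    """A named, ordered collection of building blocks sharing one anchor role."""

    name: str
    role: str
    members: list[BuildingBlock] = field(default_factory=list)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigError(f"role must be one of {ROLES}, got {self.role!r}")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate building block ids in sub-library {self.name}")
        codes = [m.code for m in self.members]
        if len(set(codes)) != len(codes):
            raise ConfigError(f"duplicate codes in sub-library {self.name}")
        if len({len(c) for c in codes} or {0}) > 1:
            raise ConfigError(f"codes in sub-library {self.name} must share one length")
        for m in self.members:
            if m.sublibrary != self.role:
                raise ConfigError(
                    f"building block {m.id} has role {m.sublibrary}, expected {self.role}"
                )
        self._by_id = {m.id: m for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i: int) -> BuildingBlock:
        return self.members[i]

    def get(self, bb_id: str) -> BuildingBlock:
        try:
            return self._by_id[bb_id]
        except KeyError:
            raise KeyError(f"unknown building block {bb_id!r} in sub-library {self.name}") from None

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def codes(self) -> list[str]:
        return [m.code for m in self.members]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.members],
                "sublibrary": [m.sublibrary for m in self.members],
                "code": [m.code for m in self.members],
                "smiles": [m.smiles for m in self.members],
                "mass": [m.mass for m in self.members],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        name: str | None = None,
        compute_mass_from_smiles: bool = False,
    ) -> "SubLibrary":
        """Load a building-block table (required columns id, sublibrary, code).

        Optional columns ``smiles`` and ``mass``; with
        ``compute_mass_from_smiles`` missing masses are filled from SMILES
        via RDKit.
        """
        df = pd.read_csv(path, dtype={"id": str, "sublibrary": str, "code": str})
        required = {"id", "sublibrary", "code"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"building-block table {path} lacks columns {sorted(missing)}")
        roles = df["sublibrary"].unique()
        if len(roles) != 1:
            raise ConfigError(f"building-block table {path} mixes roles {sorted(roles)}")
        members = []
        for row in df.itertuples(index=False):
            smiles = getattr(row, "smiles", None)
            if pd.isna(smiles):
                smiles = None
            mass = getattr(row, "mass", None)
            if mass is None or pd.isna(mass):
                mass = None
            else:
                mass = float(mass)
            if mass is None and smiles is not None and compute_mass_from_smiles:
                mass = mass_from_smiles(smiles)
            members.append(
                BuildingBlock(
                    id=str(row.id), sublibrary=str(row.sublibrary), code=str(row.code),
                    smiles=smiles, mass=mass,
                )
            )
        return cls(name=name or str(Path(path).stem), role=str(roles[0]), members=members)


def mass_from_smiles(smiles: str) -> float:
    """Molecular weight (Da) from a SMILES string. Requires the ``chem`` extra (RDKit)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise ConfigError("computing masses from SMILES requires rdkit (tdel[chem])") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConfigError(f"unparseable SMILES: {smiles!r}")
    return float(Descriptors.MolWt(mol))


@dataclass(frozen=True)
class TDELMember:
    """One assembled library member, identified by its three building-block ids."""

    a_id: str
    b_id: str
    c_id: str
    combined_mass: float | None = None


class TDELibrary:
    """Three sub-libraries (A: fragment, B: linker, C: fragment) viewed as one library."""

    def __init__(self, a: SubLibrary, b: SubLibrary, c: SubLibrary):
        for sl, role in ((a, "A"), (b, "B"), (c, "C")):
            if sl.role != role:
                raise ConfigError(f"sub-library {sl.name} has role {sl.role}, expected {role}")
        self.sublibraries = {"A": a, "B": b, "C": c}

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(self.sublibraries[r]) for r in ROLES)

    @property
    def size(self) -> int:
        na, nb, nc = self.shape
        return na * nb * nc

    def sub(self, role: str) -> SubLibrary:
        return self.sublibraries[role]

    def member(self, ia: int, ib: int, ic: int) -> TDELMember:
        return TDELMember(
            a_id=self.sublibraries["A"][ia].id,
            b_id=self.sublibraries["B"][ib].id,
            c_id=self.sublibraries["C"][ic].id,
        )

    def __iter__(self) -> Iterator[TDELMember]:
        count, triples = enumerate_members(*self.shape)
        for ia, ib, ic in triples:
            yield self.member(ia, ib, ic)


def enumerate_members(size_a: int, size_b: int, size_c: int) -> tuple[int, Iterator[tuple[int, int, int]]]:
    """Total member count plus a lazy iterator over (a, b, c) index triples.

    The count is the plain product of the three sub-library sizes — the
    883 x 30 x 890 design enumerates to 23,576,100 members. The iterator
    yields every triple exactly once in lexicographic order and never
    materializes the full library.
    """
    for label, n in (("size_a", size_a), ("size_b", size_b), ("size_c", size_c)):
        if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
            raise ConfigError(f"{label} must be an integer, got {n!r}")
        if n < 0:
            raise ConfigError(f"{label} must be >= 0, got {n}")
    count = int(size_a) * int(size_b) * int(size_c)
    triples = itertools.product(range(size_a), range(size_b), range(size_c))
    return count, triples


def mw_statistics(masses: Iterable[float], percentile: float = 90.0) -> dict[str, float]:
    """Mean and a percentile of a molecular-weight distribution.

    Percentiles use linear interpolation between closest ranks (numpy's
    default "linear" method), so reported upper percentiles depend mildly
    on this convention for small compound sets.
    """
    arr = np.asarray(list(masses), dtype=float)
    if arr.size == 0:
        raise ConfigError("mw_statistics requires a non-empty mass list")
    if not np.all(arr > 0):
        raise ConfigError("all masses must be > 0")
    if not 0 <= percentile <= 100:
        raise ConfigError(f"percentile must be in [0, 100], got {percentile}")
    return {
        "mean": float(arr.mean()),
        "percentile": float(percentile),
        "percentile_value": float(np.percentile(arr, percentile, method="linear")),
        "n": int(arr.size),
    }


def combined_mass(
    member: TDELMember, library: TDELibrary, linkage_correction: float = 0.0
) -> float:
    """Additive mass of an assembled member: sum of the three fragment masses
    minus ``linkage_correction`` (e.g. water losses on bond formation).

    Raises :class:`MassUnavailableError` when any fragment mass is missing
    rather than silently returning a partial sum.
    """
    blocks = (
        library.sub("A").get(member.a_id),
        library.sub("B").get(member.b_id),
        library.sub("C").get(member.c_id),
    )
    missing = [bb.id for bb in blocks if bb.mass is None]
    if missing:
        raise MassUnavailableError(f"mass unavailable for building block(s) {missing}")
    total = sum(bb.mass for bb in blocks) - linkage_correction
    if total < 0:
        raise ConfigError(
            f"linkage correction {linkage_correction} exceeds fragment mass sum "
            f"{total + linkage_correction}"
        )
    return float(total)
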