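"""Atomic structure container, selections, and coordinate file IO.

The in-memory model is a thin, immutable-ish wrapper around a pandas
DataFrame with one row per heavy atom.  File parsing goes through gemmi
(PDB and mmCIF); writing emits fixed-width PDB ``ATOM`` records.  Only the
highest-occupancy alternate conformer is kept and waters are dropped on
read; heteroatoms are excluded by default but can be retained for surface
calculations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "ResidueSelection",
    "read_structure",
    "write_pdb",
]

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]

#: residues treated as water on read
_WATER_NAMES = {"HOH", "DOD", "WAT"}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine: kept, treated as MET-like
}


@dataclass(frozen=True)
class StructureModel:
    """Heavy-atom coordinates with chain / residue / atom identity.

    Parameters
    ----------
    atoms
        DataFrame with columns ``chain, resnum, resname, atom, element,
        x, y, z``.  The key ``(chain, resnum, atom)`` must be unique.
    label
        Free-text provenance tag (file stem, synthetic generator name, ...).
    """

    atoms: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.atoms
        missing = [c for c in ATOM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        coords = df[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in structure")
        if df.duplicated(subset=["chain", "resnum", "atom"]).any():
            dups = df[df.duplicated(subset=["chain", "resnum", "atom"], keep=False)]
            raise ValueError(
                "duplicate (chain, residue, atom) keys: "
                f"{dups[['chain', 'resnum', 'atom']].head(5).to_dict('records')}"
            )

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates in Å."""
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def residues(self, chain: str | None = None) -> pd.DataFrame:
        """Unique (chain, resnum, resname) rows in file order."""
        df = self.atoms
        if chain is not None:
            df = df[df["chain"] == chain]
        return df[["chain", "resnum", "resname"]].drop_duplicates().reset_index(drop=True)

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        return StructureModel(self.atoms[mask].reset_index(drop=True),
                              label=label if label is not None else self.label)

    def select_chains(self, chains: Iterable[str]) -> "StructureModel":
        chains = set(chains)
        return self.subset(self.atoms["chain"].isin(chains).to_numpy())

    def select(self, selection: "ResidueSelection") -> "StructureModel":
        return self.subset(selection.mask(self))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped through ``R x + t``."""
        xyz = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        df = self.atoms.copy()
        df[["x", "y", "z"]] = xyz
        return StructureModel(df, label=self.label)

    def atom_coord(self, chain: str, resnum: int, atom: str) -> np.ndarray:
        df = self.atoms
        hit = df[(df["chain"] == chain) & (df["resnum"] == resnum) & (df["atom"] == atom)]
        if len(hit) != 1:
            raise KeyError(f"atom {chain}:{resnum}:{atom} not found")
        return hit[["x", "y", "z"]].to_numpy(float)[0]


_RANGE_RE = re.compile(r"^([^:]+):(-?\d+)(?:-(-?\d+))?$")


@dataclass(frozen=True)
class ResidueSelection:
    """Chain / residue-range selection with an optional atom-name filter.

    Ranges are 1-based inclusive.  The string form is
    ``"A:15-40,A:300-335"`` (single residues as ``"A:241"``); the default
    atom filter keeps Cα only, ``atoms=None`` keeps every atom.
    """

    ranges: tuple[tuple[str, int, int], ...]
    atoms: tuple[str, ...] | None = ("CA",)

    @classmethod
    def parse(cls, text: str, atoms: Sequence[str] | None = ("CA",)) -> "ResidueSelection":
        ranges = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            m = _RANGE_RE.match(part)
            if not m:
                raise ValueError(f"cannot parse selection term {part!r}")
            chain, lo, hi = m.group(1), int(m.group(2)), m.group(3)
            hi = int(hi) if hi is not None else lo
            if hi < lo:
                raise ValueError(f"empty range in selection term {part!r}")
            ranges.append((chain, lo, hi))
        if not ranges:
            raise ValueError("empty selection string")
        return cls(tuple(ranges), tuple(atoms) if atoms is not None else None)

    def with_atoms(self, atoms: Sequence[str] | None) -> "ResidueSelection":
        return replace(self, atoms=tuple(atoms) if atoms is not None else None)

    def mask(self, structure: StructureModel) -> np.ndarray:
        """Boolean atom mask; raises if any range matches nothing."""
        df = structure.atoms
        total = np.zeros(len(df), dtype=bool)
        for chain, lo, hi in self.ranges:
            m = (df["chain"] == chain) & df["resnum"].between(lo, hi)
            if self.atoms is not None:
                m &= df["atom"].isin(self.atoms)
            if not m.any():
                raise ValueError(
                    f"selection {chain}:{lo}-{hi} (atoms={self.atoms}) matches no atoms "
                    f"in structure {structure.label!r}"
                )
            total |= m.to_numpy()
        return total

    def residue_keys(self) -> list[tuple[str, int]]:
        keys: list[tuple[str, int]] = []
        for chain, lo, hi in self.ranges:
            keys.extend((chain, r) for r in range(lo, hi + 1))
        return keys


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, *, keep_hetero: bool = False,
                   model_index: int = 0) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Waters and hydrogens are always dropped; non-polymer heteroatoms are
    dropped unless ``keep_hetero``.  Of alternate conformers only the
    highest-occupancy one is retained.
    """
    import gemmi

    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps the highest-occupancy altloc
    st.remove_hydrogens()
    st.remove_waters()
    model = st[model_index]
    rows = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            is_polymer = res.name in _STANDARD_AA
            if not is_polymer and not keep_hetero:
                continue
            for atom in res:
                el = atom.element.name
                if el == "H" or el == "D":
                    continue
                rows.append((chain.name, res.seqid.num, res.name, atom.name, el,
                             atom.pos.x, atom.pos.y, atom.pos.z))
    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    if df.empty:
        raise ValueError(f"no atoms read from {path}")
    return StructureModel(df, label=path.stem)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write fixed-width ``ATOM`` records (one model, TER per chain)."""
    path = Path(path)
    lines = []
    serial = 0
    last_chain = None
    for row in structure.atoms.itertuples(index=False):
        if last_chain is not None and row.chain != last_chain:
            lines.append("TER")
        last_chain = row.chain
        serial += 1
        name = row.atom
        # PDB column convention: 1-3 char names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {serial:5d} {name_field}{'':1s}{row.resname:<3s} "
            f"{row.chain[:1]}{row.resnum:4d}    "
            f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {row.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
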