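"""Macromolecular structure I/O with a uniform polymer model.

Structures are read through gemmi (PDB and mmCIF) and flattened into a
small chain -> residue -> atom model with sequential 1-based ``label_id``
numbering per chain, independent of author numbering gaps or insertion
codes.  Waters and non-polymer ligands are dropped; only residues that
carry at least a C-alpha atom survive, so every residue can participate
in superposition.  Alternate locations are resolved to the
highest-occupancy conformer (ties broken by file order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "read_structure",
    "write_structure",
    "chain_sequence",
    "find_subsequence",
    "NOT_FOUND",
]

#: Sentinel returned by :func:`find_subsequence` when the query is absent.
NOT_FOUND = -1

# Three-letter -> one-letter mapping. Norleucine (NLE) maps to 'Z', the
# convention used for synthesized methionine-bioisostere scaffolds; other
# non-standard residues map to 'X'.
_NLE = "NLE"


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed or has no polymer."""


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    name: str
    seq_id: int  # author residue number
    label_id: int  # sequential 1-based index within the chain
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = ""

    @property
    def one_letter(self) -> str:
        if self.name == _NLE:
            return "Z"
        info = gemmi.find_tabulated_residue(self.name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            return code if code.isalpha() else "X"
        return "X"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray | None:
        a = self.atom("CA")
        return None if a is None else a.position


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("structure must contain at least one chain")

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.id!r} "
                f"(available: {', '.join(self.chains)})"
            ) from None

    def ca_coords(self, chain_id: str, label_ids: list[int] | None = None) -> np.ndarray:
        """C-alpha coordinates for a chain, optionally restricted to label_ids."""
        residues = self.chain(chain_id)
        if label_ids is not None:
            by_id = {r.label_id: r for r in residues}
            residues = [by_id[i] for i in label_ids]
        coords = []
        for r in residues:
            ca = r.ca
            if ca is None:
                raise ValueError(f"residue {r.name}{r.seq_id} has no CA atom")
            coords.append(ca)
        return np.array(coords, dtype=float)

    def __iter__(self) -> Iterator[tuple[str, list[Residue]]]:
        return iter(self.chains.items())


def _resolve_altlocs(raw_atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by file order."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the polymer model.

    Only amino-acid residues with at least a C-alpha atom are kept; waters
    and ligands are dropped.  ``label_id`` is assigned 1..n per chain in
    file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no model in file")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = (info is not None and info.is_amino_acid()) or res.name == _NLE
            if not is_aa:
                continue
            raw = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\0" else "",
                )
                for a in res
            ]
            atoms = _resolve_altlocs(raw)
            if not any(a.name == "CA" for a in atoms):
                continue
            residues.append(
                Residue(
                    name=res.name,
                    seq_id=res.seqid.num,
                    label_id=len(residues) + 1,
                    atoms=atoms,
                    icode=res.seqid.icode.strip(),
                )
            )
        if residues:
            chains[ch.name] = residues

    if not chains:
        raise StructureParseError(f"{path}: no polymer residues with CA atoms")
    return Structure(id=path.stem.upper() if st.name in ("", "XXXX") else st.name,
                     chains=chains)


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write the polymer model as a PDB file.

    Raises on inputs the fixed-width PDB format cannot represent
    (>99999 atoms, coordinates outside (-1000, 10000) Angstrom).
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported output format {format!r}")
    n_atoms = sum(len(r.atoms) for ch in s.chains.values() for r in ch)
    if n_atoms > 99999:
        raise ValueError(f"{n_atoms} atoms exceed PDB format capacity (99999)")
    for ch in s.chains.values():
        for r in ch:
            for a in r.atoms:
                if np.any(np.abs(a.position) >= 10000) or np.any(a.position <= -1000):
                    raise ValueError(
                        f"coordinate {a.position} of {a.name} exceeds PDB field width"
                    )

    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for r in residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_id, r.icode or " ")
            gres.het_flag = "A"
            for a in r.atoms:
                gatom = gemmi.Atom()
                gatom.name = a.name
                gatom.element = gemmi.Element(a.element)
                gatom.pos = gemmi.Position(*a.position)
                gatom.occ = a.occupancy
                gres.add_atom(gatom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(s: Structure, chain: str) -> str:
    """One-letter sequence of a chain in label_id order ('X' unknown, 'Z' Nle)."""
    return "".join(r.one_letter for r in s.chain(chain))


def find_subsequence(parent: str, query: str) -> int:
    """1-based start of the first occurrence of query in parent, or NOT_FOUND.

    When ``parent`` came from :func:`chain_sequence`, convert the returned
    index to author numbering via the chain's residues if needed.
    """
    if not parent or not query:
        raise ValueError("parent and query must be non-empty")
    idx = parent.find(query)
    return NOT_FOUND if idx < 0 else idx + 1


def find_subsequence_author(s: Structure, chain: str, query: str) -> int:
    """Author seq_id of the first residue of query within a chain, or NOT_FOUND."""
    seq = chain_sequence(s, chain)
    pos = find_subsequence(seq, query)
    if pos == NOT_FOUND:
        return NOT_FOUND
    return s.chain(chain)[pos - 1].seq_id
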