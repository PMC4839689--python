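"""Structure data model and PDB input/output.

The in-memory model is deliberately small: atoms carry PDB-file numbering
verbatim (1-based ``res_seq``, insertion codes preserved) so that residue
labels used in engineering work (e.g. N31, T187) match the file. Parsing
and writing go through gemmi; only the first MODEL of a multi-model file
becomes a :class:`Structure` (multi-model files are trajectories and are
read by :mod:`cystforge.flexibility`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "ResidueKey",
    "Atom",
    "Residue",
    "Structure",
    "ResiduePair",
    "read_pdb",
    "write_pdb",
]

#: (chain_id, res_seq, insertion_code) — the residue identity used throughout.
ResidueKey = tuple[str, int, str]


def residue_key(chain_id: str, res_seq: int, icode: str = "") -> ResidueKey:
    return (chain_id, int(res_seq), icode or "")


@dataclass
class Atom:
    """A single atom with PDB-style identity and Å coordinates."""

    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coordinates must be a finite 3-vector")

    @property
    def residue_id(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.insertion_code, self.atom_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue: shared identity plus its atoms (hydrogens retained)."""

    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(f"residue {self.res_name}{self.res_seq}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.res_seq}{self.insertion_code}"


@dataclass(frozen=True, order=True)
class ResiduePair:
    """Unordered residue pair in canonical order (lower residue first).

    Canonical order sorts by chain, then sequence number, then insertion
    code, so the pair is stable under swapping its members.
    """

    a: ResidueKey
    b: ResidueKey

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("a residue cannot pair with itself")
        if self.b < self.a:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @staticmethod
    def of(a: ResidueKey, b: ResidueKey) -> "ResiduePair":
        return ResiduePair(a, b)

    def __contains__(self, key: ResidueKey) -> bool:
        return key == self.a or key == self.b

    @property
    def members(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.a, self.b)

    @property
    def sequence_separation(self) -> int | None:
        """|Δ res_seq| for same-chain pairs, None across chains."""
        if self.a[0] != self.b[0]:
            return None
        return abs(self.a[1] - self.b[1])

    @property
    def label(self) -> str:
        return f"{self.a[0]}:{self.a[1]}{self.a[2]}-{self.b[0]}:{self.b[1]}{self.b[2]}"


class Structure:
    """An ordered collection of residues plus native disulfide records.

    Residue order follows the source file. ``ssbonds`` lists the native
    cystine pairs (from SSBOND records or supplied at construction).
    """

    def __init__(
        self,
        identifier: str,
        residues: Iterable[Residue],
        ssbonds: Iterable[ResiduePair] = (),
    ) -> None:
        self.identifier = identifier
        self.residues: list[Residue] = list(residues)
        self._index: dict[ResidueKey, Residue] = {}
        seen_atoms: set[tuple] = set()
        for res in self.residues:
            if res.key in self._index:
                raise ValueError(f"duplicate residue {res.key}")
            self._index[res.key] = res
            for atom in res.atoms:
                if atom.key in seen_atoms:
                    raise ValueError(f"duplicate atom {atom.key}")
                seen_atoms.add(atom.key)
        self.ssbonds: list[ResiduePair] = list(ssbonds)
        for pair in self.ssbonds:
            for k in pair.members:
                if k not in self._index:
                    raise ValueError(f"ssbond references missing residue {k}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    def get(self, key: ResidueKey) -> Residue | None:
        return self._index.get(key)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.heavy_atoms]

    def coords(self, atom_name: str | None = None, heavy_only: bool = False) -> np.ndarray:
        """Stacked coordinates, optionally restricted to one atom name."""
        if atom_name is not None:
            pts = [r.atom(atom_name).coords for r in self.residues if r.has_atom(atom_name)]
        elif heavy_only:
            pts = [a.coords for a in self.heavy_atoms]
        else:
            pts = [a.coords for a in self.atoms]
        return np.array(pts, float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with a rigid transform applied to every atom."""
        new_residues = []
        for res in self.residues:
            new_atoms = [
                Atom(
                    a.chain_id,
                    a.res_seq,
                    a.insertion_code,
                    a.res_name,
                    a.atom_name,
                    a.element,
                    np.asarray(rotation, float) @ a.coords + np.asarray(translation, float),
                    a.b_factor,
                    a.occupancy,
                )
                for a in res.atoms
            ]
            new_residues.append(
                Residue(res.chain_id, res.res_seq, res.insertion_code, res.res_name, new_atoms)
            )
        return Structure(self.identifier, new_residues, self.ssbonds)


def _from_gemmi_model(identifier: str, model: gemmi.Model) -> list[Residue]:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            our = Residue(chain.name, res.seqid.num, icode, res.name)
            # resolve alternate locations: keep the highest-occupancy copy
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            for atom in res:
                chosen = by_name[atom.name]
                if atom is not chosen:
                    continue
                our.atoms.append(
                    Atom(
                        chain.name,
                        res.seqid.num,
                        icode,
                        res.name,
                        atom.name,
                        atom.element.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        atom.b_iso,
                        atom.occ,
                    )
                )
            residues.append(our)
    return residues


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first MODEL is read. SSBOND records become ``ssbonds``.
    Alternate locations are resolved to the highest-occupancy conformer.

    Raises FileNotFoundError for a missing file and ValueError for a file
    with no ATOM records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError(f"{path}: no ATOM records")
    residues = _from_gemmi_model(st.name or path.stem, st[0])
    structure = Structure(st.name or path.stem, residues)
    ssbonds: list[ResiduePair] = []
    for conn in st.connections:
        if conn.type != gemmi.ConnectionType.Disulf:
            continue
        p1, p2 = conn.partner1, conn.partner2
        k1 = residue_key(p1.chain_name, p1.res_id.seqid.num, p1.res_id.seqid.icode.strip())
        k2 = residue_key(p2.chain_name, p2.res_id.seqid.num, p2.res_id.seqid.icode.strip())
        if k1 in structure and k2 in structure and k1 != k2:
            ssbonds.append(ResiduePair.of(k1, k2))
    structure.ssbonds = ssbonds
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.identifier
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        chain = chains.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = chain
            model.add_chain(chain)
            chain = model[len(model) - 1]
            chains[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.res_seq, res.insertion_code or " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.b_iso = atom.b_factor
            ga.occ = atom.occupancy
            gres.add_atom(ga)
        chain.add_residue(gres)
    st.add_model(model)
    for pair in structure.ssbonds:
        conn = gemmi.Connection()
        conn.type = gemmi.ConnectionType.Disulf
        conn.name = f"disulf_{pair.a[1]}_{pair.b[1]}"
        a1 = gemmi.AtomAddress()
        a1.chain_name = pair.a[0]
        a1.res_id = gemmi.ResidueId()
        a1.res_id.seqid = gemmi.SeqId(pair.a[1], pair.a[2] or " ")
        a1.res_id.name = structure[pair.a].res_name
        a1.atom_name = "SG"
        a2 = gemmi.AtomAddress()
        a2.chain_name = pair.b[0]
        a2.res_id = gemmi.ResidueId()
        a2.res_id.seqid = gemmi.SeqId(pair.b[1], pair.b[2] or " ")
        a2.res_id.name = structure[pair.b].res_name
        a2.atom_name = "SG"
        conn.partner1 = a1
        conn.partner2 = a2
        st.connections.append(conn)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file, including SSBOND records."""
    st = _to_gemmi(structure)
    st.write_pdb(str(path))
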