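"""Interaction auditing around engineered sites.

Hydrogen-bond detection (with a heavy-atom proxy criterion for structures
that lack hydrogens, as homology models typically do), hydrogen-bond
network differencing between two structures, salt-bridge detection with
the conventional charged-atom 6 Å criterion, and free-thiol bookkeeping
mirroring an Ellman (DTNB) titration under reducing and native
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import angle, distance
from .structure import Atom, ResidueKey, ResiduePair, Structure

__all__ = [
    "HBond",
    "SaltBridge",
    "ThiolCount",
    "detect_hbonds",
    "diff_hbonds",
    "detect_salt_bridges",
    "count_free_thiols",
]

_POLAR = ("N", "O", "S")
_BASIC_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
_H_COVALENT = 1.25  # Å, H considered attached to a donor below this
_ANTECEDENT_MAX = 1.8  # Å, heavy-atom covalent neighbor search


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str, str]
    acceptor: tuple[str, int, str, str]
    d_a_distance: float
    angle: float | None  # D-H...A if H present, else heavy-atom proxy; None if no frame

    @property
    def donor_residue(self) -> ResidueKey:
        return self.donor[:3]

    @property
    def acceptor_residue(self) -> ResidueKey:
        return self.acceptor[:3]


@dataclass(frozen=True)
class SaltBridge:
    basic: ResidueKey
    acidic: ResidueKey
    min_charged_atom_distance: float


@dataclass(frozen=True)
class ThiolCount:
    """DTNB-style sulfhydryl bookkeeping for one protein variant."""

    label: str
    total_cys: int
    bonded_cys: int

    def __post_init__(self) -> None:
        if self.bonded_cys > self.total_cys:
            raise ValueError("more bonded Cys than total Cys")
        if self.total_cys < 0 or self.bonded_cys < 0:
            raise ValueError("counts must be non-negative")

    @property
    def free_thiols_reduced(self) -> int:
        """Free SH after full reduction: every Cys titrates."""
        return self.total_cys

    @property
    def free_thiols_native(self) -> int:
        """Free SH under native (non-reducing) conditions."""
        return self.total_cys - self.bonded_cys


def _attached_hydrogens(structure: Structure, donor: Atom) -> list[Atom]:
    res = structure[donor.residue_id]
    return [
        a
        for a in res.atoms
        if a.is_hydrogen and distance(a.coords, donor.coords) < _H_COVALENT
    ]


def _antecedent(structure: Structure, donor: Atom) -> Atom | None:
    """Nearest covalently-bonded heavy neighbor of the donor atom."""
    res = structure[donor.residue_id]
    best = None
    best_d = _ANTECEDENT_MAX
    for a in res.heavy_atoms:
        if a.key == donor.key:
            continue
        d = distance(a.coords, donor.coords)
        if d < best_d:
            best, best_d = a, d
    return best


def detect_hbonds(
    structure: Structure,
    region: set[ResidueKey] | None = None,
    d_a_cutoff: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Hydrogen bonds by donor-acceptor distance and angle criteria.

    Donors and acceptors are N/O/S heavy atoms. A pair qualifies when the
    donor-acceptor distance is within ``d_a_cutoff`` and the angle
    criterion holds: D-H...A >= ``angle_min`` when the donor carries a
    hydrogen, otherwise the heavy-atom proxy angle (donor's covalent
    neighbor, donor, acceptor) >= ``angle_min``. Same-residue pairs are
    skipped. When ``region`` is given, a bond is reported if either
    endpoint's residue belongs to the region. Output is sorted by
    (donor key, acceptor key).
    """
    polar = [a for a in structure.heavy_atoms if a.element.upper() in _POLAR]
    bonds: list[HBond] = []
    for donor in polar:
        for acceptor in polar:
            if donor.key == acceptor.key:
                continue
            if donor.residue_id == acceptor.residue_id:
                continue
            if region is not None and (
                donor.residue_id not in region and acceptor.residue_id not in region
            ):
                continue
            d = distance(donor.coords, acceptor.coords)
            if d > d_a_cutoff:
                continue
            hydrogens = _attached_hydrogens(structure, donor)
            if hydrogens:
                ang = max(
                    angle(donor.coords, h.coords, acceptor.coords) for h in hydrogens
                )
            else:
                ante = _antecedent(structure, donor)
                ang = (
                    angle(ante.coords, donor.coords, acceptor.coords)
                    if ante is not None
                    else None
                )
            if ang is not None and ang < angle_min:
                continue
            bonds.append(HBond(donor.key, acceptor.key, d, ang))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def diff_hbonds(
    structure_a: Structure,
    structure_b: Structure,
    region: set[ResidueKey] | None = None,
    d_a_cutoff: float = 3.5,
    angle_min: float = 120.0,
) -> tuple[list[tuple[ResidueKey, ResidueKey]], list[tuple[ResidueKey, ResidueKey]]]:
    """Hydrogen-bond network difference keyed on residue pairs.

    Returns ``(lost, gained)``: donor/acceptor residue pairs present only
    in ``structure_a`` (lost) or only in ``structure_b`` (gained). Both
    structures must share residue numbering over the region.
    """
    if region is not None:
        for key in region:
            if key not in structure_a or key not in structure_b:
                raise ValueError(f"residue {key} missing from one structure over the region")
    keyed_a = {
        (b.donor_residue, b.acceptor_residue)
        for b in detect_hbonds(structure_a, region, d_a_cutoff, angle_min)
    }
    keyed_b = {
        (b.donor_residue, b.acceptor_residue)
        for b in detect_hbonds(structure_b, region, d_a_cutoff, angle_min)
    }
    lost = sorted(keyed_a - keyed_b)
    gained = sorted(keyed_b - keyed_a)
    return lost, gained


def detect_salt_bridges(
    structure: Structure,
    cutoff: float = 6.0,
    include_histidine: bool = True,
) -> list[SaltBridge]:
    """Salt bridges: charged side-chain atoms within the cutoff.

    Basic nitrogens (Lys NZ; Arg NH1/NH2/NE; His ND1/NE2 when included)
    against acidic carboxylate oxygens (Asp OD1/OD2; Glu OE1/OE2); the
    minimum charged-atom distance must not exceed ``cutoff`` (6 Å is the
    usual ionic-interaction convention).
    """
    basics: list[tuple[ResidueKey, np.ndarray]] = []
    acidics: list[tuple[ResidueKey, np.ndarray]] = []
    for res in structure.residues:
        if res.res_name in _BASIC_ATOMS:
            if res.res_name == "HIS" and not include_histidine:
                continue
            pts = [res.atom(n).coords for n in _BASIC_ATOMS[res.res_name] if res.has_atom(n)]
            if pts:
                basics.append((res.key, np.array(pts)))
        if res.res_name in _ACIDIC_ATOMS:
            pts = [res.atom(n).coords for n in _ACIDIC_ATOMS[res.res_name] if res.has_atom(n)]
            if pts:
                acidics.append((res.key, np.array(pts)))
    bridges = []
    for bkey, bpts in basics:
        for akey, apts in acidics:
            dmin = float(
                np.min(np.linalg.norm(bpts[:, None, :] - apts[None, :, :], axis=2))
            )
            if dmin <= cutoff:
                bridges.append(SaltBridge(bkey, akey, dmin))
    bridges.sort(key=lambda b: (b.basic, b.acidic))
    return bridges


def count_free_thiols(
    sequence: str | Sequence[int],
    native_disulfides: Iterable[tuple[int, int]] = (),
    introduced_cys_pairs: Iterable[tuple[int, int]] = (),
    introduced_formed: bool = True,
    label: str = "",
) -> ThiolCount:
    """Free-sulfhydryl count for a variant, as a DTNB titration would see.

    Parameters
    ----------
    sequence : a 1-letter protein sequence (1-based Cys positions are read
        from it), or directly an iterable of Cys positions.
    native_disulfides : position pairs bonded in the wild type.
    introduced_cys_pairs : engineered double-Cys substitutions; the two
        positions become Cys if they are not already.
    introduced_formed : whether the engineered bonds are assumed formed
        (native conditions). Under full reduction the flag is irrelevant.

    Under reducing conditions every Cys titrates; under native conditions
    only cysteines outside formed disulfides do.
    """
    if isinstance(sequence, str):
        cys_positions = {i + 1 for i, aa in enumerate(sequence.upper()) if aa == "C"}
    else:
        cys_positions = {int(p) for p in sequence}
    introduced = [tuple(sorted(p)) for p in introduced_cys_pairs]
    for pair in introduced:
        cys_positions.update(pair)
    bonded: set[int] = set()
    for i, j in native_disulfides:
        for p in (i, j):
            if p not in cys_positions:
                raise ValueError(f"disulfide position {p} is not a Cys")
        bonded.update((i, j))
    if introduced_formed:
        for i, j in introduced:
            bonded.update((i, j))
    return ThiolCount(label=label, total_cys=len(cys_positions), bonded_cys=len(bonded & cys_positions))
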