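"""Geometric scanning for engineerable disulfide bonds.

Every residue pair of a structure is evaluated for compatibility with an
in-silico double-Cys substitution: the Cβ-Cβ distance must fall in a
window compatible with a Sγ-Sγ bond, some combination of χ1 rotamers must
bring the two modelled Sγ atoms to bonding distance with a native-like χ3
torsion (cystines cluster near χ3 ≈ -87° or +97°), and the modelled Sγ
atoms must not clash with surrounding heavy atoms.

Side chains are modelled at ideal covalent geometry (Cβ-Sγ 1.81 Å,
Cα-Cβ-Sγ 114.6°) over the three staggered χ1 rotamers; glycine first
receives an idealized Cβ constructed from its backbone.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral, distance, ideal_cb, place_atom
from .structure import Residue, ResiduePair, Structure

__all__ = ["DesignParams", "DisulfideCandidate", "place_sg", "scan_candidates"]

CB_SG_LENGTH = 1.81  # Å, ideal Cβ-Sγ bond
CA_CB_SG_ANGLE = 114.6  # degrees


@dataclass(frozen=True)
class DesignParams:
    """Geometric thresholds for the candidate scan.

    Defaults follow the conventional disulfide-design criteria: Cβ-Cβ
    within 3-5 Å, Sγ-Sγ near the 2.05 Å bond length, χ3 within 30° of the
    two native cystine torsion clusters, and a 2 Å steric clash limit.
    All are exposed because the passing count on any given model is
    sensitive to them.
    """

    cb_cb_window: tuple[float, float] = (3.0, 5.0)
    ss_bond_length: float = 2.05
    ss_length_tolerance: float = 0.5
    chi3_targets: tuple[float, ...] = (-87.0, 97.0)
    chi3_tolerance: float = 30.0
    clash_distance: float = 2.0
    chi1_rotamers: tuple[float, ...] = (-60.0, 60.0, 180.0)

    def __post_init__(self) -> None:
        lo, hi = self.cb_cb_window
        if not lo < hi:
            raise ValueError("cb_cb_window lower bound must be below upper bound")
        if self.chi3_tolerance <= 0:
            raise ValueError("chi3_tolerance must be positive")


@dataclass
class DisulfideCandidate:
    """One evaluated residue pair with its best achievable geometry."""

    pair: ResiduePair
    cb_cb_distance: float
    best_chi3: float | None
    best_ss_length: float | None
    sg_coords_a: np.ndarray | None
    sg_coords_b: np.ndarray | None
    passes_geometry: bool
    clash_count: int

    @property
    def label(self) -> str:
        return self.pair.label


def _backbone(residue: Residue) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for name in ("N", "CA"):
        if not residue.has_atom(name):
            raise ValueError(f"residue {residue.label}: missing backbone atom {name}")
    n = residue.atom("N").coords
    ca = residue.atom("CA").coords
    if residue.has_atom("CB"):
        cb = residue.atom("CB").coords
    else:
        if not residue.has_atom("C"):
            raise ValueError(
                f"residue {residue.label}: no CB and no C to construct an ideal CB"
            )
        cb = ideal_cb(n, ca, residue.atom("C").coords)
    return n, ca, cb


def resolve_cb(residue: Residue) -> np.ndarray:
    """Cβ coordinates, constructing an idealized Cβ for glycine."""
    return _backbone(residue)[2]


def place_sg(residue: Residue, params: DesignParams = DesignParams()) -> list[np.ndarray]:
    """Candidate Sγ positions for an in-silico Cys substitution.

    One position per χ1 rotamer, each at the ideal Cβ-Sγ bond length and
    Cα-Cβ-Sγ angle. For glycine an idealized Cβ is constructed first.
    """
    n, ca, cb = _backbone(residue)
    return [
        place_atom(n, ca, cb, CB_SG_LENGTH, CA_CB_SG_ANGLE, chi1)
        for chi1 in params.chi1_rotamers
    ]


def _chi3_deviation(chi3: float, targets: tuple[float, ...]) -> float:
    def circ(a: float, b: float) -> float:
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)

    return min(circ(chi3, t) for t in targets)


def scan_candidates(
    structure: Structure, params: DesignParams = DesignParams()
) -> list[DisulfideCandidate]:
    """Scan all residue pairs for disulfide-compatible geometry.

    A pair passes when some (χ1_a, χ1_b) rotamer combination places the two
    modelled Sγ atoms within ``ss_length_tolerance`` of the Sγ-Sγ bond
    length with a χ3 torsion within tolerance of a target, and that
    combination's Sγ atoms have no heavy-atom clash outside the pair
    itself. Results are sorted by Cβ-Cβ distance, then canonical pair
    order, and include only pairs inside the Cβ-Cβ window (others cannot
    bond regardless of rotamer).
    """
    workable: list[tuple[Residue, np.ndarray, list[np.ndarray]]] = []
    for res in structure.residues:
        try:
            n, ca, cb = _backbone(res)
        except ValueError:
            continue
        sgs = [
            place_atom(n, ca, cb, CB_SG_LENGTH, CA_CB_SG_ANGLE, chi1)
            for chi1 in params.chi1_rotamers
        ]
        workable.append((res, cb, sgs))
    if len(workable) < 2:
        warnings.warn("no residue pairs with resolvable CB; empty scan")
        return []

    # heavy atoms indexed once for clash checks
    heavy = structure.heavy_atoms
    heavy_coords = np.array([a.coords for a in heavy]).reshape(-1, 3)
    heavy_res = [a.residue_id for a in heavy]
    tree = cKDTree(heavy_coords) if len(heavy) else None

    lo, hi = params.cb_cb_window
    cb_coords = np.array([cb for _, cb, _ in workable])
    pair_tree = cKDTree(cb_coords)
    candidates: list[DisulfideCandidate] = []
    for i, j in sorted(pair_tree.query_pairs(hi)):
        res_a, cb_a, sgs_a = workable[i]
        res_b, cb_b, sgs_b = workable[j]
        d_cb = distance(cb_a, cb_b)
        if d_cb < lo:
            continue
        pair = ResiduePair.of(res_a.key, res_b.key)
        exclude = {res_a.key, res_b.key}
        best: tuple[tuple, float, float, np.ndarray, np.ndarray, int] | None = None
        for sg_a, sg_b in itertools.product(sgs_a, sgs_b):
            ss_len = distance(sg_a, sg_b)
            len_dev = abs(ss_len - params.ss_bond_length)
            try:
                chi3 = dihedral(cb_a, sg_a, sg_b, cb_b)
            except ValueError:
                continue
            chi3_dev = _chi3_deviation(chi3, params.chi3_targets)
            clashes = 0
            if tree is not None:
                for sg in (sg_a, sg_b):
                    for idx in tree.query_ball_point(sg, params.clash_distance):
                        if heavy_res[idx] not in exclude:
                            clashes += 1
            meets = (
                len_dev <= params.ss_length_tolerance
                and chi3_dev <= params.chi3_tolerance
                and clashes == 0
            )
            # rank combos: geometry-satisfying first, then by (length dev, chi3 dev)
            score = (not meets, round(len_dev, 9), round(chi3_dev, 9))
            if best is None or score < best[0]:
                best = (score, chi3, ss_len, sg_a, sg_b, clashes)
        if best is None:
            continue
        score, chi3, ss_len, sg_a, sg_b, clashes = best
        candidates.append(
            DisulfideCandidate(
                pair=pair,
                cb_cb_distance=d_cb,
                best_chi3=chi3,
                best_ss_length=ss_len,
                sg_coords_a=sg_a,
                sg_coords_b=sg_b,
                passes_geometry=not score[0],
                clash_count=clashes,
            )
        )
    candidates.sort(key=lambda c: (round(c.cb_cb_distance, 9), c.pair))
    return candidates
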