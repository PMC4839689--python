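"""Spatial-configuration exclusion cascade for disulfide candidates.

Geometric candidates are reduced to a flexibility-analysis shortlist by
three exclusion stages applied in a fixed order:

1. **conflict** — the pair would disturb a native cystine (either member
   belongs to a native disulfide, or a modelled Sγ clashes with one);
2. **separation** — the two residues are fewer than a minimum number of
   positions apart in the primary sequence, risking strain in the local
   secondary structure;
3. **catalytic** — either residue lies within a cutoff radius of a
   catalytic residue, so mutating it risks the integrity of the active
   site.

Each pair is attributed to the first stage that rejects it, so stage
counts partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .design import DisulfideCandidate
from .structure import ResidueKey, ResiduePair, Structure

__all__ = [
    "CascadeConfig",
    "ScreenVerdict",
    "ScreenReport",
    "filter_conflict",
    "filter_separation",
    "filter_catalytic",
    "run_cascade",
]

ACCEPTED = "accepted"
EXCLUDED_CONFLICT = "excluded_conflict"
EXCLUDED_SEPARATION = "excluded_separation"
EXCLUDED_CATALYTIC = "excluded_catalytic"
STATUSES = (ACCEPTED, EXCLUDED_CONFLICT, EXCLUDED_SEPARATION, EXCLUDED_CATALYTIC)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and reference residues for the exclusion cascade.

    ``catalytic_measurement`` selects how residue-to-catalytic-center
    distance is measured: minimum heavy-atom distance (default), Cβ-Cβ
    distance, or residue-centroid distance. ``catalytic_proximal_residues``
    optionally supplies a precomputed set of residues known to sit within
    the radius, so the cascade can be replayed on published candidate
    lists without the source coordinates.
    """

    min_sequence_separation: int = 10
    catalytic_residues: tuple[ResidueKey, ...] = ()
    catalytic_radius: float = 5.0
    native_cystines: tuple[ResiduePair, ...] = ()
    clash_distance: float = 2.0
    catalytic_measurement: str = "heavy_atom"  # heavy_atom | cb | centroid
    catalytic_proximal_residues: frozenset[ResidueKey] = frozenset()

    def __post_init__(self) -> None:
        if self.catalytic_radius <= 0:
            raise ValueError("catalytic_radius must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("min_sequence_separation must be >= 1")
        if self.catalytic_measurement not in ("heavy_atom", "cb", "centroid"):
            raise ValueError(f"unknown measurement {self.catalytic_measurement!r}")


@dataclass
class ScreenVerdict:
    pair: ResiduePair
    status: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class ScreenReport:
    """Cascade outcome: one verdict per input pair plus stage bookkeeping."""

    verdicts: list[ScreenVerdict]
    input_count: int

    @property
    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in STATUSES}
        for v in self.verdicts:
            c[v.status] += 1
        return c

    @property
    def accepted(self) -> list[ResiduePair]:
        return [v.pair for v in self.verdicts if v.status == ACCEPTED]

    def summary(self) -> str:
        c = self.counts
        lines = [f"screened {self.input_count} candidate pairs"]
        lines.append(f"  excluded, native-cystine conflict: {c[EXCLUDED_CONFLICT]}")
        lines.append(f"  excluded, sequence separation:     {c[EXCLUDED_SEPARATION]}")
        lines.append(f"  excluded, catalytic proximity:     {c[EXCLUDED_CATALYTIC]}")
        lines.append(f"  accepted:                          {c[ACCEPTED]}")
        return "\n".join(lines)


def _as_pair(item: ResiduePair | DisulfideCandidate) -> ResiduePair:
    return item.pair if isinstance(item, DisulfideCandidate) else item


def _candidate(item: ResiduePair | DisulfideCandidate) -> DisulfideCandidate | None:
    return item if isinstance(item, DisulfideCandidate) else None


def _conflict_detail(
    item: ResiduePair | DisulfideCandidate,
    structure: Structure | None,
    config: CascadeConfig,
) -> str | None:
    pair = _as_pair(item)
    native_members = set()
    for cystine in config.native_cystines:
        if structure is not None:
            for key in cystine.members:
                res = structure.get(key)
                if res is not None and res.res_name not in ("CYS", "CYX"):
                    raise ValueError(f"native cystine references non-Cys residue {key}")
        native_members.update(cystine.members)
    for key in pair.members:
        if key in native_members:
            return f"residue {key[0]}:{key[1]} belongs to a native disulfide"
    cand = _candidate(item)
    if cand is not None and structure is not None:
        for cystine in config.native_cystines:
            for key in cystine.members:
                res = structure.get(key)
                if res is None:
                    continue
                for atom in res.heavy_atoms:
                    for sg in (cand.sg_coords_a, cand.sg_coords_b):
                        if sg is None:
                            continue
                        if float(np.linalg.norm(sg - atom.coords)) < config.clash_distance:
                            return (
                                f"modelled SG clashes with native cystine atom "
                                f"{key[0]}:{key[1]}:{atom.atom_name}"
                            )
    return None


def filter_conflict(
    pairs: Sequence[ResiduePair | DisulfideCandidate],
    structure: Structure | None,
    config: CascadeConfig,
) -> list[ScreenVerdict]:
    """Flag pairs conflicting with a native disulfide bond."""
    out = []
    for item in pairs:
        detail = _conflict_detail(item, structure, config)
        status = EXCLUDED_CONFLICT if detail else ACCEPTED
        out.append(ScreenVerdict(_as_pair(item), status, detail or ""))
    return out


def _separation_detail(pair: ResiduePair, config: CascadeConfig) -> str | None:
    sep = pair.sequence_separation
    if sep is not None and sep < config.min_sequence_separation:
        return f"sequence separation {sep} < {config.min_sequence_separation}"
    return None


def filter_separation(
    pairs: Sequence[ResiduePair | DisulfideCandidate], config: CascadeConfig
) -> list[ScreenVerdict]:
    """Flag same-chain pairs closer than the minimum sequence separation.

    Cross-chain pairs pass by definition (separation is undefined).
    """
    out = []
    for item in pairs:
        pair = _as_pair(item)
        detail = _separation_detail(pair, config)
        out.append(
            ScreenVerdict(pair, EXCLUDED_SEPARATION if detail else ACCEPTED, detail or "")
        )
    return out


def _residue_points(structure: Structure, key: ResidueKey, mode: str) -> np.ndarray:
    res = structure[key]
    if mode == "heavy_atom":
        pts = [a.coords for a in res.heavy_atoms]
    elif mode == "cb":
        name = "CB" if res.has_atom("CB") else "CA"
        pts = [res.atom(name).coords]
    else:  # centroid
        pts = [np.mean([a.coords for a in res.heavy_atoms], axis=0)]
    return np.array(pts).reshape(-1, 3)


def _catalytic_detail(
    pair: ResiduePair, structure: Structure | None, config: CascadeConfig
) -> str | None:
    for key in pair.members:
        if key in config.catalytic_proximal_residues:
            return f"residue {key[0]}:{key[1]} is within {config.catalytic_radius} Å of the catalytic center"
    if structure is None or not config.catalytic_residues:
        return None
    cat_points = []
    for ck in config.catalytic_residues:
        if ck not in structure:
            raise KeyError(f"catalytic residue {ck} not found in structure")
        cat_points.append(_residue_points(structure, ck, config.catalytic_measurement))
    cat_tree = cKDTree(np.vstack(cat_points))
    for key in pair.members:
        if key not in structure:
            continue
        pts = _residue_points(structure, key, config.catalytic_measurement)
        dmin = float(np.min(cat_tree.query(pts)[0]))
        if dmin <= config.catalytic_radius:
            return (
                f"residue {key[0]}:{key[1]} at {dmin:.2f} Å from the catalytic center"
            )
    return None


def filter_catalytic(
    pairs: Sequence[ResiduePair | DisulfideCandidate],
    structure: Structure | None,
    config: CascadeConfig,
) -> list[ScreenVerdict]:
    """Flag pairs with a residue within the catalytic-center radius."""
    out = []
    for item in pairs:
        pair = _as_pair(item)
        detail = _catalytic_detail(pair, structure, config)
        out.append(
            ScreenVerdict(pair, EXCLUDED_CATALYTIC if detail else ACCEPTED, detail or "")
        )
    return out


def run_cascade(
    pairs: Iterable[ResiduePair | DisulfideCandidate],
    structure: Structure | None,
    config: CascadeConfig,
) -> ScreenReport:
    """Run the full exclusion cascade; first failing stage wins.

    The verdict order follows the canonical pair order so the report is
    independent of input order.
    """
    items = sorted(pairs, key=lambda it: _as_pair(it))
    verdicts: list[ScreenVerdict] = []
    for item in items:
        pair = _as_pair(item)
        detail = _conflict_detail(item, structure, config)
        if detail:
            verdicts.append(ScreenVerdict(pair, EXCLUDED_CONFLICT, detail))
            continue
        detail = _separation_detail(pair, config)
        if detail:
            verdicts.append(ScreenVerdict(pair, EXCLUDED_SEPARATION, detail))
            continue
        detail = _catalytic_detail(pair, structure, config)
        if detail:
            verdicts.append(ScreenVerdict(pair, EXCLUDED_CATALYTIC, detail))
            continue
        verdicts.append(ScreenVerdict(pair, ACCEPTED))
    return ScreenReport(verdicts=verdicts, input_count=len(items))
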