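"""Trajectory flexibility statistics and the dual-decrease selection rule.

Given unfolding-simulation trajectories of a wild-type protein and of
candidate double-Cys mutants, this module computes per-residue RMSF,
overall Cα RMSD against a reference, and local RMSD restricted to the
residues within a radius of an engineered pair. Candidate pairs are then
ranked by the mutant-minus-wild-type change and the dual-decrease rule
keeps pairs that rigidify both the local region and the overall fold.

All internal values are Å; reports can be rendered in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import apply_transform, kabsch_superpose
from .structure import ResidueKey, ResiduePair, Structure, _from_gemmi_model

__all__ = [
    "Trajectory",
    "FlexibilityReport",
    "DeltaRanking",
    "RankRow",
    "read_trajectory_pdb",
    "read_trajectory_table",
    "write_trajectory_table",
    "local_region",
    "compute_rmsf",
    "compute_rmsd",
    "RmsdSeries",
    "analyze_flexibility",
    "rank_pairs",
    "select_dual_decrease",
]

AtomKey = tuple[str, int, str, str]


@dataclass
class Trajectory:
    """Frames of coordinates plus the atom identity of each column.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``atom_index`` maps
    each column to an atom key of the reference structure.
    """

    atom_index: list[AtomKey]
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atom_index):
            raise ValueError("atom_index must cover every coordinate column")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def columns_for(
        self,
        atom_name: str | None = "CA",
        residues: set[ResidueKey] | None = None,
    ) -> np.ndarray:
        """Column indices matching an atom name and/or residue subset."""
        idx = []
        for i, (ch, seq, ic, name) in enumerate(self.atom_index):
            if atom_name is not None and name != atom_name:
                continue
            if residues is not None and (ch, seq, ic) not in residues:
                continue
            idx.append(i)
        return np.array(idx, int)


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one MODEL per frame)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    frames = []
    atom_index: list[AtomKey] | None = None
    for model in st:
        residues = _from_gemmi_model(st.name, model)
        keys = [a.key for r in residues for a in r.atoms]
        coords = np.array([a.coords for r in residues for a in r.atoms])
        if atom_index is None:
            atom_index = keys
        elif keys != atom_index:
            raise ValueError(f"{path}: models have inconsistent atoms")
        frames.append(coords)
    return Trajectory(atom_index=atom_index, frames=np.array(frames))


def write_trajectory_table(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a plain whitespace-delimited frame table.

    Header lines name the atoms; each subsequent line is one frame of
    x y z triples.
    """
    with open(path, "w") as fh:
        fh.write("# atoms: " + " ".join(
            f"{ch}:{seq}{ic}:{name}" for ch, seq, ic, name in traj.atom_index
        ) + "\n")
        for frame in traj.frames:
            fh.write(" ".join(f"{v:.4f}" for v in frame.ravel()) + "\n")


def read_trajectory_table(path: str | Path) -> Trajectory:
    """Read the plain-text frame table written by :func:`write_trajectory_table`."""
    atom_index: list[AtomKey] = []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# atoms:"):
                for tok in line[len("# atoms:"):].split():
                    ch, resid, name = tok.split(":")
                    seq = ""
                    ic = ""
                    for c in resid:
                        if c.isdigit() or (c == "-" and not seq):
                            seq += c
                        else:
                            ic += c
                    atom_index.append((ch, int(seq), ic, name))
                continue
            if line.startswith("#"):
                continue
            rows.append(np.fromstring(line, sep=" "))
    if not atom_index or not rows:
        raise ValueError(f"{path}: not a trajectory table")
    frames = np.array(rows).reshape(len(rows), len(atom_index), 3)
    return Trajectory(atom_index=atom_index, frames=frames)


def local_region(
    structure: Structure, pair: ResiduePair, radius: float = 5.0
) -> set[ResidueKey]:
    """Residues with any heavy atom within `radius` Å of either pair residue.

    The pair residues themselves are always included. Determined on the
    reference structure and intended to be held fixed across frames and
    across the wild-type/mutant comparison.
    """
    for key in pair.members:
        if key not in structure:
            raise KeyError(f"pair residue {key} not in structure")
    region = set(pair.members)
    if radius <= 0:
        return region
    seed_pts = np.array(
        [a.coords for key in pair.members for a in structure[key].heavy_atoms]
    ).reshape(-1, 3)
    tree = cKDTree(seed_pts)
    for res in structure.residues:
        if res.key in region:
            continue
        pts = np.array([a.coords for a in res.heavy_atoms]).reshape(-1, 3)
        if len(pts) and float(np.min(tree.query(pts)[0])) <= radius:
            region.add(res.key)
    return region


def _iterative_mean(coords: np.ndarray, fit: bool, passes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames onto an iteratively refined mean.

    Returns (aligned frames, mean structure). With ``fit=False`` the frames
    are used as-is.
    """
    if not fit:
        return coords, coords.mean(axis=0)
    aligned = coords
    mean = coords.mean(axis=0)
    for _ in range(passes):
        out = np.empty_like(coords)
        for t in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[t], mean)
            out[t] = apply_transform(coords[t], rot, trans)
        aligned = out
        mean = aligned.mean(axis=0)
    return aligned, mean


def compute_rmsf(
    trajectory: Trajectory,
    selection: str | None = "CA",
    residues: set[ResidueKey] | None = None,
    fit: bool = True,
) -> dict[ResidueKey, float]:
    """Per-residue RMSF about the trajectory mean, in Å.

    Each frame is superposed (Kabsch) onto the mean structure, which is
    recomputed after superposition (two passes); the fluctuation of
    residue *i* is sqrt(mean_t |x_i(t) - <x_i>|^2). With several selected
    atoms per residue the per-atom fluctuations are averaged.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    cols = trajectory.columns_for(selection, residues)
    if len(cols) == 0:
        raise ValueError("selection matches no atoms")
    coords = trajectory.frames[:, cols, :]
    aligned, mean = _iterative_mean(coords, fit)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    out: dict[ResidueKey, list[float]] = {}
    for value, col in zip(per_atom, cols):
        ch, seq, ic, _ = trajectory.atom_index[col]
        out.setdefault((ch, seq, ic), []).append(float(value))
    return {k: float(np.mean(v)) for k, v in out.items()}


@dataclass
class RmsdSeries:
    """Per-frame RMSD values plus the tail-window ("stabilized") average."""

    series: np.ndarray
    average: float
    window: tuple[int, int]


def compute_rmsd(
    trajectory: Trajectory,
    reference: Structure,
    fit_selection: str | None = "CA",
    compute_selection: str | None = "CA",
    compute_residues: set[ResidueKey] | None = None,
    fit: bool = True,
    tail_fraction: float = 0.5,
) -> RmsdSeries:
    """Cα RMSD of each frame against a reference structure.

    Each frame is rigid-body fitted on ``fit_selection`` atoms, then the
    RMSD is evaluated over ``compute_selection`` (optionally restricted to
    ``compute_residues``, e.g. a local region). The reported average is
    taken over the final ``tail_fraction`` of frames, where an unfolding
    trajectory's RMSD has typically leveled off.
    """
    ref_lookup = {a.key: a.coords for r in reference.residues for a in r.atoms}
    fit_cols = trajectory.columns_for(fit_selection) if fit else np.array([], int)
    comp_cols = trajectory.columns_for(compute_selection, compute_residues)
    if len(comp_cols) == 0:
        raise ValueError("compute selection matches no atoms")
    missing = [
        trajectory.atom_index[c]
        for c in list(fit_cols) + list(comp_cols)
        if trajectory.atom_index[c] not in ref_lookup
    ]
    if missing:
        raise ValueError(f"reference lacks atoms needed for RMSD: {missing[:3]}...")
    ref_fit = np.array([ref_lookup[trajectory.atom_index[c]] for c in fit_cols]).reshape(-1, 3)
    ref_comp = np.array([ref_lookup[trajectory.atom_index[c]] for c in comp_cols]).reshape(-1, 3)
    values = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        frame = trajectory.frames[t]
        if fit and len(fit_cols) >= 3:
            rot, trans, _ = kabsch_superpose(frame[fit_cols], ref_fit)
            comp = apply_transform(frame[comp_cols], rot, trans)
        else:
            comp = frame[comp_cols]
        values[t] = np.sqrt(np.mean(np.sum((comp - ref_comp) ** 2, axis=1)))
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    start = trajectory.n_frames - max(1, int(round(tail_fraction * trajectory.n_frames)))
    return RmsdSeries(
        series=values,
        average=float(values[start:].mean()),
        window=(start, trajectory.n_frames),
    )


@dataclass
class FlexibilityReport:
    """Flexibility summary for one trajectory (wild-type or one mutant)."""

    label: str
    rmsf_per_residue: dict[ResidueKey, float] = field(default_factory=dict)
    overall_rmsd_series: np.ndarray | None = None
    overall_rmsd_avg: float | None = None
    local_rmsd_avg: dict[ResiduePair, float] = field(default_factory=dict)
    window: tuple[int, int] | None = None

    def rmsf_sum(self, pair: ResiduePair) -> float:
        """Sum of the two pair residues' Cα RMSF (a mobility score)."""
        return self.rmsf_per_residue[pair.a] + self.rmsf_per_residue[pair.b]


def analyze_flexibility(
    reference: Structure,
    trajectory: Trajectory,
    pairs: Sequence[ResiduePair] = (),
    label: str = "",
    radius: float = 5.0,
    region_source: Structure | None = None,
    tail_fraction: float = 0.5,
) -> FlexibilityReport:
    """Full flexibility workup: RMSF, overall RMSD, per-pair local RMSD.

    Local regions are determined on ``region_source`` (default: the
    reference itself) so wild-type and mutants can share the same region
    definition.
    """
    region_src = region_source if region_source is not None else reference
    overall = compute_rmsd(trajectory, reference, tail_fraction=tail_fraction)
    report = FlexibilityReport(
        label=label or reference.identifier,
        rmsf_per_residue=compute_rmsf(trajectory),
        overall_rmsd_series=overall.series,
        overall_rmsd_avg=overall.average,
        window=overall.window,
    )
    for pair in pairs:
        region = local_region(region_src, pair, radius)
        local = compute_rmsd(
            trajectory, reference, compute_residues=region, tail_fraction=tail_fraction
        )
        report.local_rmsd_avg[pair] = local.average
    return report


@dataclass
class RankRow:
    pair: ResiduePair
    wt_value: float
    mutant_value: float

    @property
    def delta(self) -> float:
        return self.mutant_value - self.wt_value


@dataclass
class DeltaRanking:
    """Pairs ranked ascending by mutant-minus-wild-type change.

    Rank 1 is the most negative delta — the strongest rigidification.
    Ties break on canonical pair order.
    """

    mode: str
    rows: list[RankRow]

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (r.delta, r.pair))

    @property
    def pairs(self) -> list[ResiduePair]:
        return [r.pair for r in self.rows]

    def top(self, k: int) -> list[RankRow]:
        return self.rows[:k]

    def row(self, pair: ResiduePair) -> RankRow:
        for r in self.rows:
            if r.pair == pair:
                return r
        raise KeyError(f"pair {pair.label} not in ranking")


def rank_pairs(
    wt_report: FlexibilityReport,
    mutant_reports: Mapping[ResiduePair, FlexibilityReport],
    mode: str = "local",
) -> DeltaRanking:
    """Rank candidate pairs by their flexibility change versus wild type.

    ``mode='local'`` compares the pair's local-region RMSD average;
    ``mode='overall'`` compares the overall RMSD average.
    """
    if mode not in ("local", "overall"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for pair, mreport in mutant_reports.items():
        if mode == "local":
            try:
                wt = wt_report.local_rmsd_avg[pair]
                mut = mreport.local_rmsd_avg[pair]
            except KeyError as exc:
                raise KeyError(f"missing local RMSD entry for pair {pair.label}") from exc
        else:
            if wt_report.overall_rmsd_avg is None or mreport.overall_rmsd_avg is None:
                raise KeyError(f"missing overall RMSD for pair {pair.label}")
            wt = wt_report.overall_rmsd_avg
            mut = mreport.overall_rmsd_avg
        rows.append(RankRow(pair=pair, wt_value=wt, mutant_value=mut))
    return DeltaRanking(mode=mode, rows=rows)


def select_dual_decrease(
    local_ranking: DeltaRanking,
    overall_ranking: DeltaRanking,
    top_k: int = 4,
) -> set[ResiduePair]:
    """Keep pairs that rigidify both locally and overall.

    A pair is selected when it (a) sits within the top ``top_k`` of the
    local ranking with a negative local delta, and (b) also has a negative
    overall delta. The result is therefore always a subset of the top-k
    local pairs.
    """
    if set(local_ranking.pairs) != set(overall_ranking.pairs):
        raise ValueError("local and overall rankings cover different pair sets")
    selected = set()
    for row in local_ranking.top(top_k):
        if row.delta >= 0:
            continue
        if overall_ranking.row(row.pair).delta < 0:
            selected.add(row.pair)
    return selected
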