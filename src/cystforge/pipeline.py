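"""End-to-end pipeline: scan -> screen -> flexibility -> selection.

The flexibility stage accepts either raw trajectories (wild type plus one
per accepted candidate) or a precomputed table of tail-average RMSD
values, so a screening campaign whose simulations were run elsewhere can
still be ranked and selected here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignParams, DisulfideCandidate, scan_candidates
from .flexibility import (
    DeltaRanking,
    FlexibilityReport,
    Trajectory,
    analyze_flexibility,
    rank_pairs,
    read_trajectory_pdb,
    read_trajectory_table,
    select_dual_decrease,
)
from .screening import CascadeConfig, run_cascade
from .structure import ResidueKey, ResiduePair, Structure, read_pdb, write_pdb

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "parse_residue_spec",
    "parse_pair_spec",
]

log = logging.getLogger("cystforge")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def parse_residue_spec(spec: str) -> ResidueKey:
    """Parse ``"A:105"`` into a residue key."""
    chain, _, seq = spec.partition(":")
    if not seq:
        chain, seq = "A", chain
    return (chain, int(seq), "")


def parse_pair_spec(spec: str) -> ResiduePair:
    """Parse ``"A:31-A:187"`` (or ``"A:31,A:187"``) into a ResiduePair."""
    sep = "-" if "-" in spec else ","
    a, b = spec.split(sep)
    return ResiduePair.of(parse_residue_spec(a.strip()), parse_residue_spec(b.strip()))


@dataclass
class RunConfig:
    """Flat, YAML-loadable configuration of the whole pipeline."""

    pdb: str = ""
    out_dir: str = "cystforge_out"
    units: str = "A"  # A | nm
    seed: int = 0
    # design thresholds
    cb_cb_window: tuple[float, float] = (3.0, 5.0)
    chi3_tolerance: float = 30.0
    clash_distance: float = 2.0
    # cascade
    min_sequence_separation: int = 10
    catalytic_residues: tuple[str, ...] = ()
    catalytic_radius: float = 5.0
    native_cystines: tuple[str, ...] = ()  # default: SSBOND records of the input
    # flexibility
    flex_enabled: bool = True
    local_radius: float = 5.0
    tail_fraction: float = 0.5
    wt_trajectory: str = ""
    mutant_trajectories: dict[str, str] = field(default_factory=dict)  # pair spec -> path
    precomputed_rmsd: str = ""  # TSV alternative to trajectories
    top_k: int = 4

    def __post_init__(self) -> None:
        if self.units not in ("A", "nm"):
            raise ValueError("units must be 'A' or 'nm'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def design_params(self) -> DesignParams:
        return DesignParams(
            cb_cb_window=tuple(self.cb_cb_window),
            chi3_tolerance=self.chi3_tolerance,
            clash_distance=self.clash_distance,
        )

    def cascade_config(self, structure: Structure) -> CascadeConfig:
        if self.native_cystines:
            native = tuple(parse_pair_spec(s) for s in self.native_cystines)
        else:
            native = tuple(structure.ssbonds)
        return CascadeConfig(
            min_sequence_separation=self.min_sequence_separation,
            catalytic_residues=tuple(
                parse_residue_spec(s) for s in self.catalytic_residues
            ),
            catalytic_radius=self.catalytic_radius,
            native_cystines=native,
            clash_distance=self.clash_distance,
        )


def _read_traj(path: str) -> Trajectory:
    if str(path).endswith(".pdb"):
        return read_trajectory_pdb(path)
    return read_trajectory_table(path)


def _scale(value: float | None, units: str) -> float | None:
    if value is None:
        return None
    return value / 10.0 if units == "nm" else value


def candidates_frame(candidates: list[DisulfideCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain_a": c.pair.a[0],
                "res_a": c.pair.a[1],
                "chain_b": c.pair.b[0],
                "res_b": c.pair.b[1],
                "cb_cb": round(c.cb_cb_distance, 3),
                "chi3": round(c.best_chi3, 2) if c.best_chi3 is not None else float("nan"),
                "ss_length": round(c.best_ss_length, 3)
                if c.best_ss_length is not None
                else float("nan"),
                "clashes": c.clash_count,
                "passes": c.passes_geometry,
            }
            for c in candidates
        ]
    )


def ranking_frame(ranking: DeltaRanking, units: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "pair": row.pair.label,
                "wt": _scale(row.wt_value, units),
                "mutant": _scale(row.mutant_value, units),
                "delta": _scale(row.delta, units),
            }
            for i, row in enumerate(ranking.rows)
        ]
    )


def _rankings_from_table(path: str, accepted: list[ResiduePair]) -> tuple[DeltaRanking, DeltaRanking]:
    """Build rankings from a precomputed TSV.

    Columns: pair (``A:31-A:187``), wt_local, mut_local, wt_overall,
    mut_overall — values in the pipeline's internal unit (Å).
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"pair", "wt_local", "mut_local", "wt_overall", "mut_overall"}
    if not needed.issubset(df.columns):
        raise ValueError(f"precomputed RMSD table must have columns {sorted(needed)}")
    pairs = {parse_pair_spec(p): row for p, row in zip(df["pair"], df.itertuples())}
    missing = [p.label for p in accepted if p not in pairs]
    if missing:
        raise ValueError(f"precomputed table lacks accepted pairs: {missing}")
    wt = FlexibilityReport(label="WT")
    mutants: dict[ResiduePair, FlexibilityReport] = {}
    for pair in accepted:
        row = pairs[pair]
        wt.local_rmsd_avg[pair] = float(row.wt_local)
        wt.overall_rmsd_avg = float(row.wt_overall)
        mutants[pair] = FlexibilityReport(
            label=pair.label,
            overall_rmsd_avg=float(row.mut_overall),
            local_rmsd_avg={pair: float(row.mut_local)},
        )
    return rank_pairs(wt, mutants, "local"), rank_pairs(wt, mutants, "overall")


def _apply_design(
    structure: Structure,
    selected: list[ResiduePair],
    candidates: list[DisulfideCandidate],
) -> Structure:
    """In-silico mutation: selected residues become Cys with modelled Sγ.

    The new cystines are recorded as SSBOND entries alongside any native
    ones.
    """
    from .structure import Atom, Residue

    by_pair = {c.pair: c for c in candidates}
    sg_for: dict[ResidueKey, np.ndarray] = {}
    for pair in selected:
        cand = by_pair.get(pair)
        if cand is None or cand.sg_coords_a is None:
            continue
        sg_for[pair.a] = cand.sg_coords_a
        sg_for[pair.b] = cand.sg_coords_b
    mutate = {k for pair in selected for k in pair.members}
    residues = []
    for res in structure.residues:
        if res.key not in mutate:
            residues.append(res)
            continue
        atoms = [
            Atom(a.chain_id, a.res_seq, a.insertion_code, "CYS", a.atom_name,
                 a.element, a.coords, a.b_factor, a.occupancy)
            for a in res.atoms
            # drop side-chain atoms beyond CB of the replaced residue
            if a.atom_name in ("N", "CA", "C", "O", "CB")
        ]
        if res.key in sg_for and not any(a.atom_name == "SG" for a in atoms):
            atoms.append(
                Atom(res.chain_id, res.res_seq, res.insertion_code, "CYS", "SG",
                     "S", sg_for[res.key])
            )
        residues.append(Residue(res.chain_id, res.res_seq, res.insertion_code, "CYS", atoms))
    return Structure(
        structure.identifier + "_designed",
        residues,
        list(structure.ssbonds) + list(selected),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run scan -> screen -> flexibility -> selection and write reports.

    Returns the machine-readable summary (also written as
    ``summary.json`` in the output directory). Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        structure = read_pdb(config.pdb)
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    log.info("scan: %d residues, window %s", len(structure), config.cb_cb_window)
    try:
        candidates = scan_candidates(structure, config.design_params())
        passing = [c for c in candidates if c.passes_geometry]
        candidates_frame(candidates).to_csv(out / "candidates.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("scan", exc) from exc

    try:
        cascade_cfg = config.cascade_config(structure)
        screen = run_cascade(passing, structure, cascade_cfg)
        pd.DataFrame(
            [
                {"pair": v.pair.label, "status": v.status, "detail": v.detail}
                for v in screen.verdicts
            ]
        ).to_csv(out / "screen.tsv", sep="\t", index=False)
        (out / "screen_summary.txt").write_text(screen.summary() + "\n")
    except Exception as exc:
        raise PipelineError("screen", exc) from exc
    accepted = screen.accepted

    summary: dict = {
        "input": str(config.pdb),
        "units": config.units,
        "seed": config.seed,
        "thresholds": {
            "cb_cb_window": list(config.cb_cb_window),
            "chi3_tolerance": config.chi3_tolerance,
            "clash_distance": config.clash_distance,
            "min_sequence_separation": config.min_sequence_separation,
            "catalytic_radius": config.catalytic_radius,
            "local_radius": config.local_radius,
            "tail_fraction": config.tail_fraction,
            "top_k": config.top_k,
        },
        "counts": {
            "scanned": len(candidates),
            "geometric": len(passing),
            **screen.counts,
        },
        "accepted_pairs": [p.label for p in accepted],
    }

    if not config.flex_enabled or not accepted:
        summary["selected_pairs"] = []
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    try:
        if config.precomputed_rmsd:
            local_rank, overall_rank = _rankings_from_table(
                config.precomputed_rmsd, accepted
            )
        else:
            if not config.wt_trajectory:
                raise ValueError("flexibility stage needs wt_trajectory or precomputed_rmsd")
            wt_traj = _read_traj(config.wt_trajectory)
            wt_report = analyze_flexibility(
                structure,
                wt_traj,
                accepted,
                label="WT",
                radius=config.local_radius,
                tail_fraction=config.tail_fraction,
            )
            mutant_reports: dict[ResiduePair, FlexibilityReport] = {}
            for pair in accepted:
                path = config.mutant_trajectories.get(pair.label)
                if path is None:
                    raise ValueError(f"missing mutant trajectory for pair {pair.label}")
                mtraj = _read_traj(path)
                mutant_reports[pair] = analyze_flexibility(
                    structure,
                    mtraj,
                    [pair],
                    label=pair.label,
                    radius=config.local_radius,
                    region_source=structure,
                    tail_fraction=config.tail_fraction,
                )
            local_rank = rank_pairs(wt_report, mutant_reports, "local")
            overall_rank = rank_pairs(wt_report, mutant_reports, "overall")
        ranking_frame(local_rank, config.units).to_csv(
            out / "ranking_local.tsv", sep="\t", index=False
        )
        ranking_frame(overall_rank, config.units).to_csv(
            out / "ranking_overall.tsv", sep="\t", index=False
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("flexibility", exc) from exc

    try:
        selected = select_dual_decrease(local_rank, overall_rank, config.top_k)
        selected_sorted = sorted(selected)
        design = _apply_design(structure, selected_sorted, passing)
        write_pdb(design, out / "designed.pdb")
    except Exception as exc:
        raise PipelineError("select", exc) from exc

    summary["selected_pairs"] = [p.label for p in selected_sorted]
    summary["ranking_local"] = ranking_frame(local_rank, config.units).to_dict("records")
    summary["ranking_overall"] = ranking_frame(overall_rank, config.units).to_dict(
        "records"
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
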