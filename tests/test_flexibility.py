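"""Trajectory statistics: RMSF, RMSD, ranking, dual-decrease selection."""

import numpy as np
import pytest

from cystforge import datasets as ds
from cystforge.fixtures import FixtureSpec, make_structure, make_trajectory
from cystforge.flexibility import (
    DeltaRanking,
    FlexibilityReport,
    RankRow,
    Trajectory,
    compute_rmsd,
    compute_rmsf,
    local_region,
    rank_pairs,
    read_trajectory_pdb,
    read_trajectory_table,
    select_dual_decrease,
    write_trajectory_table,
)
from cystforge.geometry import random_rotation
from cystforge.structure import ResiduePair, write_pdb

from .conftest import build_residue, build_structure
from .oracles import quaternion_rmsd


def pair(a, b, chain="A"):
    return ResiduePair.of((chain, a, ""), (chain, b, ""))


def sparse_structure(positions):
    """One-atom (CA) residues at prescribed coordinates."""
    residues = [
        build_residue(seq, "ALA", {"CA": ("C", xyz)}) for seq, xyz in positions.items()
    ]
    return build_structure(*residues)


class TestLocalRegion:
    def test_isolated_pair_is_just_the_pair(self):
        s = sparse_structure({1: (0, 0, 0), 10: (3, 0, 0), 50: (100, 0, 0)})
        assert local_region(s, pair(1, 10), radius=1.0) == {
            ("A", 1, ""),
            ("A", 10, ""),
        }

    def test_neighbor_at_4A_included_at_radius_5(self):
        s = sparse_structure({1: (0, 0, 0), 10: (3, 0, 0), 20: (0, 4.0, 0)})
        region = local_region(s, pair(1, 10), radius=5.0)
        assert region == {("A", 1, ""), ("A", 10, ""), ("A", 20, "")}

    def test_radius_zero_degenerate(self):
        s = sparse_structure({1: (0, 0, 0), 10: (0.5, 0, 0), 20: (0.6, 0, 0)})
        assert local_region(s, pair(1, 10), radius=0.0) == {("A", 1, ""), ("A", 10, "")}

    def test_missing_residue_raises(self):
        s = sparse_structure({1: (0, 0, 0), 10: (3, 0, 0)})
        with pytest.raises(KeyError):
            local_region(s, pair(1, 99))


class TestRmsf:
    def test_static_trajectory_zero(self, helix20):
        spec = FixtureSpec(n_frames=10, fluctuation_amplitudes=np.zeros(20))
        traj = make_trajectory(helix20, spec)
        rmsf = compute_rmsf(traj)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rmsf.values())

    def test_isotropic_gaussian_closed_form(self, helix20):
        # per-coordinate sigma = 0.2 A -> E[RMSF] = 0.2 * sqrt(3)
        spec = FixtureSpec(
            seed=5, n_frames=5000, fluctuation_amplitudes=np.full(20, 0.2)
        )
        traj = make_trajectory(helix20, spec)
        rmsf = compute_rmsf(traj, fit=False)
        expected = 0.2 * np.sqrt(3.0)
        mean_rmsf = np.mean(list(rmsf.values()))
        assert mean_rmsf == pytest.approx(expected, rel=0.03)

    def test_two_frames_single_displaced_atom(self):
        # many anchor atoms fixed, one atom displaced by d between two
        # frames, no fitting: its RMSF is d/2 (distance to the midpoint)
        n_atoms = 20
        base = np.random.default_rng(0).uniform(0, 10, (n_atoms, 3))
        frames = np.stack([base, base.copy()])
        d = 1.6
        frames[1, 0, 2] += d
        atom_index = [("A", i + 1, "", "CA") for i in range(n_atoms)]
        traj = Trajectory(atom_index=atom_index, frames=frames)
        rmsf = compute_rmsf(traj, fit=False)
        assert rmsf[("A", 1, "")] == pytest.approx(d / 2, abs=1e-12)
        assert rmsf[("A", 2, "")] == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_rejected(self, helix20):
        spec = FixtureSpec(n_frames=1, fluctuation_amplitudes=np.zeros(20))
        with pytest.raises(ValueError):
            compute_rmsf(make_trajectory(helix20, spec))

    def test_fitting_removes_rigid_motion(self, helix20):
        amps = np.full(20, 0.2)
        plain = make_trajectory(helix20, FixtureSpec(seed=9, n_frames=800, fluctuation_amplitudes=amps))
        moved = make_trajectory(
            helix20,
            FixtureSpec(seed=9, n_frames=800, fluctuation_amplitudes=amps),
            rigid_motion=True,
        )
        r_plain = compute_rmsf(plain, fit=True)
        r_moved = compute_rmsf(moved, fit=True)
        for key in r_plain:
            assert r_moved[key] == pytest.approx(r_plain[key], rel=0.05)

    def test_amplitude_profile_recovered(self, helix20):
        amps = np.linspace(0.05, 0.5, 20)
        traj = make_trajectory(
            helix20, FixtureSpec(seed=3, n_frames=2000, fluctuation_amplitudes=amps)
        )
        rmsf = compute_rmsf(traj)
        profile = np.array([rmsf[r.key] for r in helix20.residues])
        corr = np.corrcoef(profile, amps)[0, 1]
        assert corr > 0.95


class TestRmsd:
    def test_reference_vs_itself_zero(self, helix20):
        traj = make_trajectory(
            helix20, FixtureSpec(n_frames=2, fluctuation_amplitudes=np.zeros(20))
        )
        out = compute_rmsd(traj, helix20)
        np.testing.assert_allclose(out.series, 0.0, atol=1e-12)

    def test_rigidly_moved_trajectory_fits_to_zero(self, helix20):
        spec = FixtureSpec(seed=2, n_frames=5, fluctuation_amplitudes=np.zeros(20))
        traj = make_trajectory(helix20, spec, rigid_motion=True)
        out = compute_rmsd(traj, helix20)
        assert np.all(out.series <= 1e-6)

    def test_against_quaternion_oracle(self, helix20):
        spec = FixtureSpec(seed=4, n_frames=5, fluctuation_amplitudes=np.full(20, 0.8))
        traj = make_trajectory(helix20, spec)
        out = compute_rmsd(traj, helix20, tail_fraction=1.0)
        ref_ca = helix20.coords("CA")
        cols = traj.columns_for("CA")
        for t in range(traj.n_frames):
            expected = quaternion_rmsd(traj.frames[t][cols], ref_ca)
            assert out.series[t] == pytest.approx(expected, abs=1e-9)
        assert out.average == pytest.approx(out.series.mean(), abs=1e-12)

    def test_window_consistent_under_frame_duplication(self, helix20):
        spec = FixtureSpec(seed=6, n_frames=8, fluctuation_amplitudes=np.full(20, 0.4))
        traj = make_trajectory(helix20, spec)
        doubled = Trajectory(
            atom_index=traj.atom_index,
            frames=np.repeat(traj.frames, 2, axis=0),
        )
        a = compute_rmsd(traj, helix20, tail_fraction=0.5).average
        b = compute_rmsd(doubled, helix20, tail_fraction=0.5).average
        assert b == pytest.approx(a, abs=1e-12)

    def test_empty_selection_rejected(self, helix20):
        traj = make_trajectory(
            helix20, FixtureSpec(n_frames=2, fluctuation_amplitudes=np.zeros(20))
        )
        with pytest.raises(ValueError):
            compute_rmsd(traj, helix20, compute_selection="SG")


class TestTrajectoryIO:
    def test_multimodel_pdb_roundtrip(self, helix20, tmp_path):
        spec = FixtureSpec(seed=1, n_frames=3, fluctuation_amplitudes=np.full(20, 0.3))
        traj = make_trajectory(helix20, spec)
        # write frames as a multi-model PDB by hand through the writer
        path = tmp_path / "traj.pdb"
        with open(path, "w") as fh:
            for t in range(traj.n_frames):
                fh.write(f"MODEL     {t+1}\n")
                moved = helix20.transformed(np.eye(3), np.zeros(3))
                i = 0
                for res in moved.residues:
                    for atom in res.atoms:
                        atom.coords = traj.frames[t][i]
                        i += 1
                for res in moved.residues:
                    for atom in res.atoms:
                        x, y, z = atom.coords
                        fh.write(
                            f"ATOM  {i:5d} {atom.atom_name:<4s}{atom.res_name:>3s} "
                            f"{atom.chain_id}{atom.res_seq:4d}    "
                            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                            f"{atom.element:>2s}\n"
                        )
                fh.write("ENDMDL\n")
        back = read_trajectory_pdb(path)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.frames, traj.frames, atol=2e-3)

    def test_table_roundtrip(self, helix20, tmp_path):
        spec = FixtureSpec(seed=1, n_frames=4, fluctuation_amplitudes=np.full(20, 0.3))
        traj = make_trajectory(helix20, spec)
        path = tmp_path / "traj.dat"
        write_trajectory_table(traj, path)
        back = read_trajectory_table(path)
        assert back.atom_index == traj.atom_index
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)


class TestRanking:
    def test_published_local_ranking(self):
        local, _ = ds.published_rankings()
        top = local.rows[0]
        assert top.pair == ds.pair_from_label("N31C-T187C")
        assert top.delta == pytest.approx(-0.242, abs=1e-9)

    def test_published_overall_ranking(self):
        _, overall = ds.published_rankings()
        assert overall.rows[0].pair == ds.pair_from_label("N31C-T187C")
        assert overall.rows[0].delta == pytest.approx(-0.103, abs=1e-9)
        assert overall.rows[-1].pair == ds.pair_from_label("E63C-N182C")
        assert overall.rows[-1].delta == pytest.approx(0.076, abs=1e-9)

    def test_tie_break_by_canonical_pair_order(self):
        rows = [
            RankRow(pair(50, 60), 1.0, 0.9),
            RankRow(pair(10, 20), 1.0, 0.9),
        ]
        ranking = DeltaRanking(mode="local", rows=rows)
        assert ranking.rows[0].pair == pair(10, 20)

    def test_missing_pair_entry_raises(self):
        wt = FlexibilityReport(label="WT", local_rmsd_avg={})
        mut = {pair(1, 20): FlexibilityReport(label="m", local_rmsd_avg={})}
        with pytest.raises(KeyError):
            rank_pairs(wt, mut, "local")


class TestDualDecrease:
    def test_published_selection(self):
        local, overall = ds.published_rankings()
        chosen = select_dual_decrease(local, overall, top_k=4)
        assert chosen == {
            ds.pair_from_label("N31C-T187C"),
            ds.pair_from_label("P102C-N125C"),
        }

    def test_all_positive_deltas_empty(self):
        rows = [RankRow(pair(1, 20), 1.0, 1.1), RankRow(pair(2, 30), 1.0, 1.2)]
        local = DeltaRanking("local", list(rows))
        overall = DeltaRanking("overall", list(rows))
        assert select_dual_decrease(local, overall) == set()

    def test_single_dual_negative_pair(self):
        local = DeltaRanking(
            "local", [RankRow(pair(1, 20), 1.0, 0.8), RankRow(pair(2, 30), 1.0, 1.2)]
        )
        overall = DeltaRanking(
            "overall", [RankRow(pair(1, 20), 2.0, 1.9), RankRow(pair(2, 30), 2.0, 2.2)]
        )
        assert select_dual_decrease(local, overall) == {pair(1, 20)}

    def test_selection_is_subset_of_top_k_local(self):
        local, overall = ds.published_rankings()
        for k in (1, 2, 4, 8):
            chosen = select_dual_decrease(local, overall, top_k=k)
            assert chosen <= {r.pair for r in local.top(k)}

    def test_inconsistent_pair_sets_rejected(self):
        local = DeltaRanking("local", [RankRow(pair(1, 20), 1.0, 0.8)])
        overall = DeltaRanking("overall", [RankRow(pair(2, 30), 1.0, 0.8)])
        with pytest.raises(ValueError):
            select_dual_decrease(local, overall)
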