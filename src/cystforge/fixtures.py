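"""Deterministic synthetic inputs for testing and examples.

Everything a full analysis needs can be generated here without any
download: toy poly-Ala structures with prescribed backbone geometry,
residue pairs forged with textbook disulfide geometry (so the geometric
scanner has a known positive), trajectories with prescribed per-residue
fluctuation amplitudes (so RMSF/RMSD estimators have closed-form
expectations), and assay curves generated from known kinetic parameters.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral, ideal_cb, place_atom, random_rotation
from .stability import AssaySeries
from .structure import Atom, Residue, ResiduePair, Structure
from .flexibility import Trajectory

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_disulfide_pair",
    "merge_structures",
    "make_trajectory",
    "make_assay",
]

# ideal backbone internal coordinates (Engh-Huber-like)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7


@dataclass
class FixtureSpec:
    """Parameters of the synthetic generators.

    ``fluctuation_amplitudes`` is the per-residue per-coordinate standard
    deviation (Å) of the isotropic Gaussian displacement used by
    :func:`make_trajectory`.
    """

    seed: int = 0
    n_residues: int = 20
    geometry: str = "ideal_helix"  # ideal_helix | extended
    fluctuation_amplitudes: np.ndarray | None = None
    n_frames: int = 100
    noise_model: str = "isotropic_gaussian"

    def __post_init__(self) -> None:
        if self.noise_model != "isotropic_gaussian":
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.fluctuation_amplitudes is not None:
            self.fluctuation_amplitudes = np.asarray(self.fluctuation_amplitudes, float)
            if np.any(self.fluctuation_amplitudes < 0):
                raise ValueError("amplitudes must be non-negative")


_TORSIONS = {
    # (phi, psi) backbone torsions
    "ideal_helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}


def make_structure(
    spec: FixtureSpec, chain_id: str = "A", start_seq: int = 1, identifier: str = "fixture"
) -> Structure:
    """Poly-Ala backbone with ideal internal coordinates.

    ``ideal_helix`` uses the canonical α-helix torsions (φ=-57°, ψ=-47°);
    ``extended`` an antiparallel-β-like strand. Atoms per residue:
    N, CA, C, O, CB.
    """
    if spec.n_residues < 1:
        raise ValueError("need at least one residue")
    if spec.geometry not in _TORSIONS:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    phi, psi = _TORSIONS[spec.geometry]
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_N_CA, 0.0, 0.0])
    c = place_atom(np.array([-0.5, 1.0, 0.0]), n, ca, _CA_C, _ANG_N_CA_C, -55.0)
    residues = []
    seq = start_seq
    prev_n, prev_ca, prev_c = n, ca, c
    for i in range(spec.n_residues):
        if i > 0:
            n = place_atom(prev_n, prev_ca, prev_c, _C_N, _ANG_CA_C_N, psi)
            ca = place_atom(prev_ca, prev_c, n, _N_CA, _ANG_C_N_CA, 180.0)
            c = place_atom(prev_c, n, ca, _CA_C, _ANG_N_CA_C, phi)
        o = place_atom(n, ca, c, _C_O, 120.5, psi - 180.0)
        cb = ideal_cb(n, ca, c)
        atoms = [
            Atom(chain_id, seq, "", "ALA", "N", "N", n),
            Atom(chain_id, seq, "", "ALA", "CA", "C", ca),
            Atom(chain_id, seq, "", "ALA", "C", "C", c),
            Atom(chain_id, seq, "", "ALA", "O", "O", o),
            Atom(chain_id, seq, "", "ALA", "CB", "C", cb),
        ]
        residues.append(Residue(chain_id, seq, "", "ALA", atoms))
        prev_n, prev_ca, prev_c = n, ca, c
        seq += 1
    return Structure(identifier, residues)


def make_disulfide_pair(
    seq_a: int = 10,
    seq_b: int = 30,
    chain_id: str = "A",
    chi1_a: float = -60.0,
    chi1_b: float = -60.0,
    chi3: float = -87.0,
    offset: np.ndarray | None = None,
    as_cys: bool = True,
    identifier: str = "forged-pair",
) -> Structure:
    """Two residues forged with textbook disulfide geometry.

    Residue ``seq_a`` is built first; the partner's Cβ/Cα/N are grown
    outward from the Sγ-Sγ bond so that the pair realizes exactly the
    requested χ1 rotamers and χ3 torsion at ideal bond lengths (Cβ-Sγ
    1.81 Å, Sγ-Sγ 2.05 Å). Re-deriving the Sγ positions from the
    backbones with the same ideal geometry therefore reproduces them
    bit-for-bit, which makes this the forward-constructed ground truth
    for the geometric scanner.
    """
    n_a = np.array([0.0, 0.0, 0.0])
    ca_a = np.array([_N_CA, 0.0, 0.0])
    c_a = place_atom(np.array([-0.5, 1.0, 0.0]), n_a, ca_a, _CA_C, _ANG_N_CA_C, -55.0)
    cb_a = ideal_cb(n_a, ca_a, c_a)
    sg_a = place_atom(n_a, ca_a, cb_a, 1.81, 114.6, chi1_a)
    sg_b = place_atom(ca_a, cb_a, sg_a, 2.05, 104.2, -80.0)
    cb_b = place_atom(cb_a, sg_a, sg_b, 1.81, 104.2, chi3)
    ca_b = place_atom(sg_a, sg_b, cb_b, 1.53, 114.6, -75.0)
    n_b = place_atom(sg_b, cb_b, ca_b, _N_CA, 110.5, chi1_b)
    c_b = place_atom(cb_b, n_b, ca_b, _CA_C, _ANG_N_CA_C, -120.0)
    shift = np.zeros(3) if offset is None else np.asarray(offset, float)
    res_name = "CYS" if as_cys else "ALA"

    def _res(seq: int, coords: dict[str, np.ndarray]) -> Residue:
        atoms = [
            Atom(chain_id, seq, "", res_name, name, name[0], xyz + shift)
            for name, xyz in coords.items()
        ]
        return Residue(chain_id, seq, "", res_name, atoms)

    coords_a = {"N": n_a, "CA": ca_a, "C": c_a, "CB": cb_a}
    coords_b = {"N": n_b, "CA": ca_b, "C": c_b, "CB": cb_b}
    if as_cys:
        coords_a["SG"] = sg_a
        coords_b["SG"] = sg_b
    ssbonds = (
        [ResiduePair.of((chain_id, seq_a, ""), (chain_id, seq_b, ""))] if as_cys else []
    )
    return Structure(identifier, [_res(seq_a, coords_a), _res(seq_b, coords_b)], ssbonds)


def merge_structures(identifier: str, *parts: Structure) -> Structure:
    """Combine disjoint structures into one (residue keys must not collide)."""
    residues = [r for p in parts for r in p.residues]
    ssbonds = [b for p in parts for b in p.ssbonds]
    return Structure(identifier, residues, ssbonds)


def make_trajectory(
    structure: Structure,
    spec: FixtureSpec,
    rigid_motion: bool = False,
) -> Trajectory:
    """Synthetic trajectory: base coordinates plus per-residue noise.

    Every atom of residue *i* receives an independent isotropic Gaussian
    displacement with that residue's amplitude (per coordinate, Å) in
    each frame. With ``rigid_motion`` each frame is additionally rotated
    and translated randomly, to exercise superposition fitting. At large
    frame counts the per-coordinate amplitude σ gives an expected RMSF of
    σ·√3.
    """
    amps = spec.fluctuation_amplitudes
    if amps is None:
        amps = np.zeros(len(structure))
    amps = np.asarray(amps, float)
    if len(amps) != len(structure):
        raise ValueError(
            f"amplitude count {len(amps)} != residue count {len(structure)}"
        )
    rng = np.random.default_rng(spec.seed)
    atom_index = []
    base = []
    atom_amp = []
    for amp, res in zip(amps, structure.residues):
        for atom in res.atoms:
            atom_index.append(atom.key)
            base.append(atom.coords)
            atom_amp.append(amp)
    base = np.array(base)
    atom_amp = np.array(atom_amp)[None, :, None]
    noise = rng.standard_normal((spec.n_frames, len(base), 3)) * atom_amp
    frames = base[None, :, :] + noise
    if rigid_motion:
        for t in range(spec.n_frames):
            rot = random_rotation(rng)
            trans = rng.uniform(-20.0, 20.0, 3)
            frames[t] = frames[t] @ rot.T + trans
    times = np.arange(spec.n_frames, dtype=float) * 4.0  # ps, conventional save interval
    return Trajectory(atom_index=atom_index, frames=frames, frame_times=times)


def make_assay(kind: str, params: dict, seed: int = 0) -> AssaySeries:
    """Assay curve from a known generating model, optionally with noise.

    Parameters by kind (σ is multiplicative Gaussian noise, default 0):

    - ``inactivation_time``: t_half (min), a0, t (array, default 0..120
      by 15), sigma — a(t) = a0·2^(−t/t_half).
    - ``thermal_T50``: T50 (°C), slope (°C), T (array), sigma — logistic
      residual activity 1/(1+exp((T−T50)/slope)).
    - ``profile_temperature`` / ``profile_pH``: optimum, width, x (array),
      peak (default 100), sigma — Gaussian bump.
    - ``kinetics_substrate``: Km, Vmax, S (array of concentrations),
      sigma — Michaelis-Menten v = Vmax·S/(Km+S).
    """
    rng = np.random.default_rng(seed)
    sigma = float(params.get("sigma", 0.0))
    if kind == "inactivation_time":
        t_half = float(params["t_half"])
        if t_half <= 0:
            raise ValueError("t_half must be positive")
        t = np.asarray(params.get("t", np.arange(0.0, 121.0, 15.0)), float)
        a0 = float(params.get("a0", 1.0))
        y = a0 * np.power(2.0, -t / t_half)
        x = t
    elif kind == "thermal_T50":
        t50 = float(params["T50"])
        slope = float(params.get("slope", 2.0))
        x = np.asarray(params.get("T", np.arange(40.0, 81.0, 5.0)), float)
        y = 1.0 / (1.0 + np.exp((x - t50) / slope))
    elif kind in ("profile_temperature", "profile_pH"):
        opt = float(params["optimum"])
        width = float(params.get("width", 10.0))
        x = np.asarray(params["x"], float)
        peak = float(params.get("peak", 100.0))
        y = peak * np.exp(-0.5 * ((x - opt) / width) ** 2)
    elif kind == "kinetics_substrate":
        km = float(params["Km"])
        vmax = float(params["Vmax"])
        if km <= 0 or vmax <= 0:
            raise ValueError("Km and Vmax must be positive")
        x = np.asarray(params.get("S", np.array([50, 100, 200, 400, 800, 1600.0])), float)
        y = vmax * x / (km + x)
    else:
        raise ValueError(f"unknown assay kind {kind!r}")
    if sigma > 0:
        y = y * (1.0 + sigma * rng.standard_normal(len(y)))
        y = np.clip(y, 1e-12, None)
    return AssaySeries(kind=kind, x=x, y=y, label=params.get("label", ""))
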