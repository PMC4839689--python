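# Methods

This note documents the models and procedures behind `cystforge`, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions.

## Geometric model of an engineered disulfide

An engineered cystine is evaluated purely geometrically, before any
simulation. For each residue of the input structure a cysteine side
chain is modelled at ideal covalent geometry: Cβ–Sγ bond 1.81 Å,
Cα–Cβ–Sγ angle 114.6°, with the Sγ position sampled over the three
staggered χ1 rotamers (−60°, +60°, 180°). Glycine first receives an
idealized Cβ constructed from its backbone N/Cα/C by the standard
fixed-coefficient construction (|Cα–Cβ| ≈ 1.52 Å, N–Cα–Cβ ≈ 110°,
L-chirality). A residue pair is a candidate when:

- the Cβ–Cβ distance lies in `cb_cb_window` (default **3.0–5.0 Å** —
  the range over which two ideal side chains can reach the Sγ–Sγ bond
  length);
- some (χ1ᵃ, χ1ᵇ) rotamer combination puts the two Sγ atoms within
  **0.5 Å** of the **2.05 Å** Sγ–Sγ bond length;
- that combination's χ3 torsion (Cβ–Sγ–Sγ′–Cβ′) is within
  **30°** of one of the native cystine clusters at **−87°/+97°**;
- neither modelled Sγ comes within **2.0 Å** of any heavy atom outside
  the pair itself.

Discrete 3×3 rotamer sampling, rather than continuous χ1 optimization,
keeps the scan deterministic and cheap; the grid is configurable. All
thresholds are exposed in `DesignParams` because the passing count on
any given model is sensitive to them, and because the homology models
such campaigns start from are themselves uncertain: a structure-specific
candidate count is not a portable constant.

The best rotamer combination per pair is chosen by (geometry satisfied,
smallest bond-length deviation, smallest χ3 deviation), with values
rounded to 1e-9 before comparison so the choice is stable under global
rigid motion of the input.

## Exclusion cascade

Candidates are excluded in a fixed stage order — native-cystine
conflict, sequence separation, catalytic proximity — and each pair is
attributed to the first stage that rejects it, so the stage counts
partition the input exactly.

- *Conflict*: a pair is rejected when either member already belongs to a
  native cystine, or when a modelled Sγ clashes (< 2 Å) with a native
  cystine's atoms. Membership is the primary criterion; the clash term
  catches near-bond interference.
- *Separation*: same-chain pairs with |Δresidue| **< 10** are rejected
  (strictly less than: a pair exactly 10 apart is kept). Cross-chain
  pairs pass by definition.
- *Catalytic proximity*: a pair is rejected when either residue has any
  heavy atom within **5 Å** of any heavy atom of a catalytic residue.
  Minimum heavy-atom distance is the default measurement; Cβ-based and
  centroid-based variants are config options since the choice is a
  genuine modelling decision. When the source coordinates are not
  available (as for the shipped BglTM case study, whose homology model
  was never deposited), `CascadeConfig.catalytic_proximal_residues`
  accepts a precomputed set of residues known to sit inside the radius,
  so the cascade bookkeeping can still be replayed and audited.

## Flexibility statistics

Trajectories are consumed, not produced: the package reads multi-model
PDB files or a plain whitespace-delimited frame table (one line per
frame). High-temperature unfolding simulations are the intended source.

- **RMSF**: frames are superposed (Kabsch, proper rotations only) onto
  the mean structure, which is recomputed after superposition (two
  passes); RMSFᵢ = √⟨|xᵢ(t) − ⟨xᵢ⟩|²⟩ per Cα, averaged per residue.
- **RMSD**: each frame is rigid-body fitted on all Cα atoms, then the
  RMSD is evaluated over the compute selection — all Cα for the overall
  value, or the Cα of the local region for a candidate pair. The
  *local region* is all residues with any heavy atom within 5 Å of the
  pair, determined once on the wild-type reference structure and held
  fixed, so wild type and mutant are compared over the same residue
  set. A global Cα fit is used for local RMSD too (fitting on a small
  region is numerically unstable); a local-fit variant is a config
  option.
- The reported "stabilized" average is the mean over the final **50%**
  of frames, where an unfolding trajectory's RMSD has typically leveled
  off. The window fraction is configurable; duplicated-frame inputs
  give identical averages by construction.
- Internal unit is Å throughout; reports can be rendered in nm.

Candidates are ranked ascending by Δ = value(mutant) − value(wild
type); rank 1 is the strongest rigidification; ties break on canonical
pair order. The **dual-decrease rule** selects pairs that are within the
top-k (default 4) of the local ranking with negative local Δ *and* have
negative overall Δ — rigidifying a loop while destabilizing the fold is
a known failure mode, which this rule filters out.

## Interaction audits

- Hydrogen bonds: donor/acceptor are N/O/S heavy atoms; criteria are
  donor–acceptor distance ≤ **3.5 Å** and angle ≥ **120°** — the D–H⋯A
  angle when the donor carries a hydrogen, otherwise the heavy-atom
  proxy angle (covalent neighbor–donor–acceptor). The proxy exists
  because homology models typically carry no hydrogens. Network
  differences between two structures are keyed on (donor residue,
  acceptor residue) pairs.
- Salt bridges: Lys NZ / Arg NH1,NH2,NE / His ND1,NE2 versus Asp
  OD1,OD2 / Glu OE1,OE2, minimum charged-atom distance ≤ **6 Å** (the
  usual ionic-interaction-server convention). Histidine is included by
  default and can be excluded.
- Free thiols: a variant's cysteine inventory is counted as a DTNB
  titration would see it — every Cys under full reduction, only
  unbonded Cys under native conditions.

## Stability and kinetics estimators

- **Half-life**: the primary estimator fits a(t) = a₀e^(−kt) by linear
  regression on log-activity and reports t½ = ln 2 / k plus r². A
  crossing-based estimator (interpolated time of the 50%-of-initial
  crossing) is provided for comparison; for clean first-order decay the
  two coincide, and the fit uses all points rather than two.
- **T50**: linear interpolation of the first downward crossing of 50%
  residual activity, with an optional untreated-control normalization;
  non-monotone series warn and use the first crossing.
- **Profiles**: scaled so the maximum is 100%; the optimum is the x of
  the maximum, ties resolve to the lower x and are flagged.
- **Kinetics**: Km and Vmax by least squares on the double-reciprocal
  (Lineweaver–Burk) line, kcat = Vmax/[E]; the specificity constant is
  reported as kcat/Km with a μM→mM conversion by default. On noiseless
  Michaelis–Menten data the fit is exact, matching a direct nonlinear
  least-squares fit; on noisy data the double-reciprocal transform
  overweights low-substrate points — it is kept because it is the
  standard graphical method for this assay class.
- **Comparisons**: percent changes are rounded to one decimal (the
  reporting convention of the case-study tables); differences are
  exact.

Thermodynamic parameters (Tm, ΔH, ΔG) are treated as measured DSC
inputs; only comparisons are computed. ΔS is deliberately not modelled.

## Synthetic data

The generators in `cystforge.fixtures` are pure functions of their
arguments and seed (a single `numpy` Generator per call; no global
state):

- *Structures*: poly-Ala backbones at ideal internal coordinates
  (α-helix φ=−57°, ψ=−47°, or extended), and two-residue pairs forged
  with exact textbook disulfide geometry by growing the partner's
  backbone outward from the Sγ–Sγ bond — re-deriving Sγ from the
  backbones reproduces the forged positions bit-for-bit, making the
  pair a ground-truth positive for the scanner.
- *Trajectories*: base coordinates plus independent isotropic Gaussian
  displacement per atom with a prescribed per-residue amplitude σ
  (per coordinate, Å), optionally composed with a random rigid motion
  per frame to exercise the superposition fitting. The closed form
  E[RMSF] → σ√3 anchors the estimator tests.
- *Assays*: exponential decay, logistic residual-activity,
  Gaussian-bump profiles and Michaelis–Menten curves with optional
  multiplicative Gaussian noise.

What this validates — and what it does not: the isotropic Gaussian
model has no correlated motions, no anharmonicity and no actual
unfolding, so passing tests demonstrate that the *estimators* (RMSF,
RMSD, rankings, fits) are correct on data with known ground truth, not
that any particular simulation protocol reproduces the case study's
absolute RMSD values. Those absolute values depend on an undeposited
homology model and a specific high-temperature simulation protocol;
the package therefore ships them as reference tables
(`cystforge.datasets`) and reproduces all *derived* bookkeeping —
cascade counts, delta columns, rankings, selection, percent changes —
exactly from those inputs.

## Problem sizes and numerical choices

Test problem sizes were chosen so the whole suite runs in seconds while
keeping sampling error well inside the asserted tolerances: 5 000
frames for the σ√3 RMSF check (±3%), 2 000 frames for amplitude-profile
recovery (r > 0.95), 40-frame trajectories for the end-to-end pipeline
fixture, 9-point assay curves with 2% noise for half-life recovery
(±5%). Superposition uses SVD with a determinant correction so
reflections are never returned; torsions are reported in (−180°, 180°]
with collinear frames rejected rather than silently returning 0.

## Known limitations

- No force-field scoring or energy minimization of the mutant: the scan
  is purely geometric, by design.
- PDB only (first MODEL as structure, models as frames); no mmCIF, no
  symmetry/assembly handling, no compressed MD formats without an
  external conversion step.
- Alternate locations resolve to the highest-occupancy conformer only.
- Hydrogen-bond and salt-bridge criteria are distance/angle
  conventions, not energy models; counts on real structures depend on
  the criteria chosen and on model quality.
- The Lineweaver–Burk estimator inherits the known bias of reciprocal
  transforms under noise; use the nonlinear fit in `scipy` directly if
  unbiased estimates matter more than convention.
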