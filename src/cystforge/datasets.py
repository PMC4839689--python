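"""Reference values from the BglTM β-glucanase disulfide-engineering case study.

BglTM is a mesophilic 1,3-1,4-β-glucanase (*Bacillus terquilensis*) with
one native cystine (C32-C61) and catalytic glutamates E105/E109. A
disulfide-design campaign on its homology model produced 28 geometric
candidate pairs, reduced by the spatial-configuration cascade to 14,
which were then ranked by unfolding-simulation flexibility changes; the
dual-decrease rule selected N31C-T187C and P102C-N125C. This module
ships those published screening lists, the local/overall RMSD averages
(in nm), the DSC thermodynamic table and the Michaelis-Menten kinetics
table, so the screening bookkeeping and ranking arithmetic can be
replayed and audited without the (undeposited) model coordinates.
"""

from __future__ import annotations

import re

import pandas as pd

from .flexibility import DeltaRanking, FlexibilityReport, rank_pairs
from .screening import CascadeConfig
from .stability import ThermoRecord
from .structure import ResidueKey, ResiduePair

__all__ = [
    "pair_from_label",
    "CHAIN",
    "NATIVE_CYSTINE",
    "CATALYTIC_RESIDUES",
    "CONFLICT_EXCLUDED",
    "SEPARATION_EXCLUDED",
    "CATALYTIC_EXCLUDED",
    "ACCEPTED_PAIRS",
    "all_candidate_pairs",
    "replay_cascade_config",
    "LOCAL_RMSD_NM",
    "OVERALL_RMSD_NM",
    "local_rmsd_table",
    "overall_rmsd_table",
    "published_rankings",
    "THERMO_RECORDS",
    "KINETICS_TABLE",
    "HALF_LIVES_60C_MIN",
    "T50_C",
    "WT_SEQUENCE_CYS_POSITIONS",
]

CHAIN = "A"

_LABEL_RE = re.compile(r"^[A-Z](\d+)C?$")


def _key(seq: int) -> ResidueKey:
    return (CHAIN, seq, "")


def pair_from_label(label: str) -> ResiduePair:
    """Parse a mutation-style pair label like ``"N31C-T187C"`` or ``"C32-F59C"``."""
    left, right = label.split("-")
    seqs = []
    for token in (left, right):
        m = _LABEL_RE.match(token.strip())
        if not m:
            raise ValueError(f"cannot parse residue token {token!r}")
        seqs.append(int(m.group(1)))
    return ResiduePair.of(_key(seqs[0]), _key(seqs[1]))


NATIVE_CYSTINE = pair_from_label("C32-C61")
CATALYTIC_RESIDUES: tuple[ResidueKey, ...] = (_key(105), _key(109))
WT_SEQUENCE_CYS_POSITIONS = (32, 61)

# Screening-cascade bookkeeping: 28 geometric candidates -> 14 accepted.
CONFLICT_EXCLUDED = tuple(pair_from_label(s) for s in ("C32-F59C",))
SEPARATION_EXCLUDED = tuple(
    pair_from_label(s)
    for s in (
        "G23C-Y24C",
        "S55C-K58C",
        "P81C-S89C",
        "G96C-W103C",
        "D150C-K157C",
        "G159C-L164C",
    )
)
CATALYTIC_EXCLUDED = tuple(
    pair_from_label(s)
    for s in (
        "Y72C-W151C",
        "P81C-F110C",
        "S89C-F110C",
        "S89C-A204C",
        "S90C-E109C",
        "T93C-G177C",
        "D104C-P173C",
    )
)

# Residues known to sit within the 5 Å catalytic-center radius; every
# catalytic-proximity exclusion involves at least one of them, and none
# of the accepted pairs involves any (G177 itself is clear — it also
# appears in the accepted pair T95C-G177C; T93 is the proximal member).
CATALYTIC_PROXIMAL_RESIDUES = frozenset(_key(s) for s in (72, 89, 93, 104, 109, 110))

# Flexibility shortlist with tail-average RMSD values (nm): local = Cα
# within 5 Å of the engineered pair, overall = all Cα. One shared
# wild-type trajectory underlies every overall value.
LOCAL_RMSD_NM: dict[str, tuple[float, float]] = {
    # label: (wild-type, mutant)
    "N31C-T187C": (0.676, 0.434),
    "K83C-A141C": (0.710, 0.519),
    "P102C-N125C": (0.528, 0.389),
    "G3C-Q68C": (0.784, 0.650),
    "A82C-L202C": (0.671, 0.585),
    "L49C-G62C": (0.542, 0.462),
    "R65C-M180C": (0.562, 0.489),
    "I87C-N185C": (0.756, 0.710),
    "E76C-R210C": (0.641, 0.597),
    "G86C-T196C": (0.751, 0.718),
    "R78C-T146C": (0.772, 0.768),
    "T95C-G177C": (0.524, 0.534),
    "D22C-A36C": (0.527, 0.555),
    "E63C-N182C": (0.541, 0.575),
}

OVERALL_RMSD_WT_NM = 1.214
OVERALL_RMSD_NM: dict[str, float] = {
    # label: mutant overall average (wild-type is OVERALL_RMSD_WT_NM)
    "N31C-T187C": 1.111,
    "P102C-N125C": 1.116,
    "R65C-M180C": 1.191,
    "R78C-T146C": 1.196,
    "L49C-G62C": 1.197,
    "G86C-T196C": 1.200,
    "A82C-L202C": 1.203,
    "I87C-N185C": 1.207,
    "E76C-R210C": 1.234,
    "G3C-Q68C": 1.236,
    "T95C-G177C": 1.242,
    "D22C-A36C": 1.260,
    "K83C-A141C": 1.277,
    "E63C-N182C": 1.290,
}

ACCEPTED_PAIRS = tuple(pair_from_label(s) for s in LOCAL_RMSD_NM)


def all_candidate_pairs() -> list[ResiduePair]:
    """The full 28-pair geometric candidate list (accepted + excluded)."""
    return list(ACCEPTED_PAIRS) + list(CONFLICT_EXCLUDED) + list(
        SEPARATION_EXCLUDED
    ) + list(CATALYTIC_EXCLUDED)


def replay_cascade_config() -> CascadeConfig:
    """Cascade configuration replaying the published screen without coordinates."""
    return CascadeConfig(
        min_sequence_separation=10,
        catalytic_residues=CATALYTIC_RESIDUES,
        catalytic_radius=5.0,
        native_cystines=(NATIVE_CYSTINE,),
        catalytic_proximal_residues=CATALYTIC_PROXIMAL_RESIDUES,
    )


def local_rmsd_table() -> pd.DataFrame:
    rows = [
        {"pair": label, "wt_nm": wt, "mutant_nm": mut, "delta_nm": round(mut - wt, 3)}
        for label, (wt, mut) in LOCAL_RMSD_NM.items()
    ]
    return pd.DataFrame(rows).sort_values("delta_nm").reset_index(drop=True)


def overall_rmsd_table() -> pd.DataFrame:
    rows = [
        {
            "pair": label,
            "wt_nm": OVERALL_RMSD_WT_NM,
            "mutant_nm": mut,
            "delta_nm": round(mut - OVERALL_RMSD_WT_NM, 3),
        }
        for label, mut in OVERALL_RMSD_NM.items()
    ]
    return pd.DataFrame(rows).sort_values("delta_nm").reset_index(drop=True)


def published_rankings() -> tuple[DeltaRanking, DeltaRanking]:
    """(local, overall) rankings built from the published averages.

    The values are loaded into :class:`FlexibilityReport` objects and run
    through :func:`cystforge.flexibility.rank_pairs`, so the ranking code
    path is the one exercised on raw trajectories. Values stay in nm.
    """
    pairs = {label: pair_from_label(label) for label in LOCAL_RMSD_NM}
    wt = FlexibilityReport(
        label="WT",
        overall_rmsd_avg=OVERALL_RMSD_WT_NM,
        local_rmsd_avg={pairs[l]: wt_mut[0] for l, wt_mut in LOCAL_RMSD_NM.items()},
    )
    mutants = {
        pairs[l]: FlexibilityReport(
            label=l,
            overall_rmsd_avg=OVERALL_RMSD_NM[l],
            local_rmsd_avg={pairs[l]: LOCAL_RMSD_NM[l][1]},
        )
        for l in LOCAL_RMSD_NM
    }
    return (
        rank_pairs(wt, mutants, mode="local"),
        rank_pairs(wt, mutants, mode="overall"),
    )


# DSC thermodynamics: melting temperature, unfolding enthalpy, stability
# free energy per variant.
THERMO_RECORDS: dict[str, ThermoRecord] = {
    "WT": ThermoRecord("WT", Tm=50.8, dH=189.4, dG=8.8),
    "G3C-Q68C": ThermoRecord("G3C-Q68C", Tm=48.7, dH=187.6, dG=8.4),
    "N31C-T187C": ThermoRecord("N31C-T187C", Tm=52.2, dH=201.9, dG=9.3),
    "K83C-A141C": ThermoRecord("K83C-A141C", Tm=46.9, dH=167.2, dG=8.1),
    "P102C-N125C": ThermoRecord("P102C-N125C", Tm=53.1, dH=197.3, dG=9.5),
    "N31C-T187C/P102C-N125C": ThermoRecord(
        "N31C-T187C/P102C-N125C", Tm=54.9, dH=207.6, dG=10.3
    ),
}

# Measured half-lives at 60 °C (min) and half-inactivation temperatures (°C).
HALF_LIVES_60C_MIN: dict[str, float] = {
    "WT": 59.0,
    "N31C-T187C": 81.4,
    "P102C-N125C": 81.2,
    "N31C-T187C/P102C-N125C": 87.5,
}
T50_C: dict[str, float] = {
    "WT": 76.0,
    "N31C-T187C": 77.1,
    "P102C-N125C": 76.8,
    "N31C-T187C/P102C-N125C": 77.5,
}

# Michaelis-Menten kinetics (substrate: barley β-glucan; 40 °C, pH 6.5).
KINETICS_TABLE = pd.DataFrame(
    [
        {"variant": "WT", "specific_activity_U_mg": 3936.4, "Km_uM": 277.8, "kcat_s": 184.9, "kcat_over_Km_s_mM": 665.1},
        {"variant": "N31C-T187C", "specific_activity_U_mg": 4013.4, "Km_uM": 277.3, "kcat_s": 187.6, "kcat_over_Km_s_mM": 677.3},
        {"variant": "P102C-N125C", "specific_activity_U_mg": 3998.0, "Km_uM": 277.7, "kcat_s": 183.6, "kcat_over_Km_s_mM": 660.4},
        {"variant": "N31C-T187C/P102C-N125C", "specific_activity_U_mg": 4045.4, "Km_uM": 277.5, "kcat_s": 186.3, "kcat_over_Km_s_mM": 672.6},
    ]
)
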