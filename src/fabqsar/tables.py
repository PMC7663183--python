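"""Packaged per-residue property tables and amino-acid scales.

All tables are keyed by the 20 canonical one-letter codes. Scales are
dimensionless unless noted. The registry at the bottom backs
:func:`fabqsar.seq_descriptors.residue_property_sum` and is pluggable:
users may register their own tables (e.g. exported from ProtDCal) without
touching the workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AmbiguousSequence, UnknownResidue

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte–Doolittle hydropathy (dimensionless).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Theoretical maximum ASA (Å²) of residue X in an extended Gly-X-Gly
#: tripeptide (Tien et al. 2013, "theoretical" column). Denominator of the
#: relative solvent accessibility RSA_i = SASA_i / MaxASA_i.
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Non-polar residue group used by the surface-property descriptors.
NPR = frozenset("AGILMFPWV")
#: Polar residue group (complement of NPR over the 20 canonical residues).
PLR = frozenset("RNDCQEHKSTY")

#: Average residue (monomer minus water) masses, Da.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Side-chain / terminal pKa values (EMBOSS defaults).
PKA = {"Nterm": 8.6, "Cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1,
       "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}

# EMBOSS pepstats residue categories (canonical residues only).
TINY = frozenset("ACGST")
SMALL = frozenset("ACDGNPSTV")
AROMATIC = frozenset("FHWY")
POLAR_CLASS = frozenset("CDEHKNQRST")
NONPOLAR_CLASS = frozenset("AFGILMPVWY")

# --- amino-acid scales ----------------------------------------------------

#: Extended 5-component Z-scale (Sandberg et al. 1998): lipophilicity,
#: steric/polarisability, polarity, and two electronic components.
Z_SCALE = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

#: Topological 5-component T-scale (Tian et al. 2007).
T_SCALE = {
    "A": (-9.11, -1.63, 0.63, 1.04, 2.26),
    "R": (0.23, 3.89, -1.16, -0.39, -0.06),
    "N": (-4.62, 0.66, 1.16, -0.22, 0.93),
    "D": (-4.65, 0.75, 1.39, -0.40, 1.05),
    "C": (-7.35, -0.86, -0.33, 0.80, 0.98),
    "Q": (-3.00, 1.72, 0.28, -0.39, 0.33),
    "E": (-3.03, 1.82, 0.51, -0.58, 0.43),
    "G": (-10.61, -1.21, -0.12, 0.75, 3.25),
    "H": (-1.01, -1.31, 0.01, -1.81, -0.21),
    "I": (-4.25, -0.28, -0.15, 1.40, -0.21),
    "L": (-4.38, 0.28, -0.49, 1.45, 0.02),
    "K": (-2.59, 2.34, -1.69, 0.41, -0.21),
    "M": (-4.08, 0.98, -2.34, 1.64, -0.79),
    "F": (0.49, -0.94, -0.63, -1.27, -0.44),
    "P": (-5.11, -3.54, -0.53, -0.36, -0.29),
    "S": (-7.44, -0.65, 0.68, -0.17, 1.58),
    "T": (-5.97, -0.62, 1.11, 0.31, 0.95),
    "W": (5.73, -2.67, -0.07, -1.96, -0.54),
    "Y": (2.08, -0.47, -0.01, -2.26, -0.48),
    "V": (-5.87, -0.94, 0.28, 1.10, 0.48),
}

#: 3-component MS-WHIM scale (Zaliani & Gancia 1999), derived from
#: molecular-surface electrostatic potentials.
MSWHIM = {
    "A": (-0.73, 0.20, -0.62),
    "R": (-0.22, 0.27, 1.00),
    "N": (0.14, 0.20, -0.66),
    "D": (0.11, -1.00, -0.96),
    "C": (-0.66, 0.26, -0.27),
    "Q": (0.30, 1.00, -0.30),
    "E": (0.24, -0.39, -0.04),
    "G": (-0.31, -0.28, -0.75),
    "H": (0.84, 0.67, -0.78),
    "I": (-0.91, 0.83, -0.25),
    "L": (-0.74, 0.72, -0.16),
    "K": (-0.51, 0.08, 0.60),
    "M": (-0.70, 1.00, -0.32),
    "F": (0.76, 0.85, -0.34),
    "P": (-0.43, 0.73, -0.60),
    "S": (-0.80, 0.61, -1.00),
    "T": (-0.58, 0.85, -0.89),
    "W": (1.00, 0.98, -0.47),
    "Y": (0.97, 0.66, -0.16),
    "V": (-1.00, 0.79, -0.58),
}

# --- thermodynamic-style per-residue tables -------------------------------
# Registry defaults standing in for energy-based descriptor providers:
#   Gc  — side-chain conformational entropy cost TΔS, kcal/mol
#         (Pickett & Sternberg 1993), a stability proxy;
#   dGw — hydration potential, kcal/mol (Wolfenden et al. 1981), the
#         water-shell interaction energy of the side chain;
#   W   — estimated count of first-shell water molecules around a fully
#         exposed residue, MaxASA / 9.65 Å² per water.

GC_CONF_ENTROPY = {
    "A": 0.0, "R": 2.03, "N": 1.57, "D": 1.25, "C": 0.55,
    "Q": 2.11, "E": 1.81, "G": 0.0, "H": 0.96, "I": 0.89,
    "L": 0.78, "K": 1.94, "M": 1.61, "F": 0.58, "P": 0.0,
    "S": 1.71, "T": 1.63, "W": 0.97, "Y": 0.99, "V": 0.51,
}

DGW_HYDRATION = {
    "A": 1.94, "R": -19.92, "N": -9.68, "D": -10.95, "C": -1.24,
    "Q": -9.38, "E": -10.20, "G": 2.39, "H": -10.27, "I": 2.15,
    "L": 2.28, "K": -9.52, "M": -1.48, "F": -0.76, "P": 0.0,
    "S": -5.06, "T": -4.88, "W": -5.88, "Y": -6.11, "V": 1.99,
}

W_FIRST_SHELL = {aa: MAX_ASA_TIEN[aa] / 9.65 for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class PropertyScale:
    """A multi-component amino-acid scale.

    ``table[residue]`` holds one value per component; every canonical
    residue must be present with the full component tuple.
    """

    name: str
    components: tuple[str, ...]
    table: dict[str, tuple[float, ...]]

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.table)
        if missing:
            raise ValueError(f"scale {self.name} missing residues {sorted(missing)}")
        for aa, vals in self.table.items():
            if len(vals) != len(self.components):
                raise ValueError(f"scale {self.name}: residue {aa} has "
                                 f"{len(vals)} values, expected {len(self.components)}")


SCALES: dict[str, PropertyScale] = {
    "z5": PropertyScale("z5", ("z1", "z2", "z3", "z4", "z5"), Z_SCALE),
    "t5": PropertyScale("t5", ("t1", "t2", "t3", "t4", "t5"), T_SCALE),
    "mswhim": PropertyScale("mswhim", ("m1", "m2", "m3"), MSWHIM),
}

#: Scalar per-residue tables addressable by residue_property_sum.
RESIDUE_TABLES: dict[str, dict[str, float]] = {
    "kd": KYTE_DOOLITTLE,
    "Gc": GC_CONF_ENTROPY,
    "W": W_FIRST_SHELL,
    "dGw": DGW_HYDRATION,
}


def register_residue_table(name: str, table: dict[str, float]) -> None:
    """Register a user-supplied scalar per-residue table (20 entries)."""
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"table {name} missing residues {sorted(missing)}")
    RESIDUE_TABLES[name] = dict(table)


def validate_sequence(seq: str, allow_empty: bool = False) -> str:
    """Normalise (upper-case, strip) and validate a peptide sequence.

    Ambiguity codes (B, Z, X) and anything outside the 20 canonical
    letters are rejected: every packaged property table is defined only
    for the canonical residues.
    """
    seq = seq.strip().upper()
    if not seq and not allow_empty:
        raise UnknownResidue("empty sequence")
    for ch in seq:
        if ch in "BZX":
            raise AmbiguousSequence(f"ambiguity code {ch!r} not supported")
        if ch not in AMINO_ACIDS:
            raise UnknownResidue(f"unknown residue {ch!r}")
    return seq
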