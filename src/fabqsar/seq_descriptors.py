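"""Primary-sequence (Seq2D) descriptor generation.

Descriptors are per-region sums of amino-acid scale components (Z-scale,
T-scale, MS-WHIM), per-region scalar property-table sums (Kyte–Doolittle
hydropathy and thermodynamic-style increments), and a pepstats-like set
of global physicochemical properties (molecular weight, net charge at pH
7, isoelectric point, aliphatic index, composition fractions).

Only the 14 variable-domain regions contribute: with a single constant
allele per chain, constant-domain sequence descriptors are static across
samples and carry no information.

Summed descriptors weight every residue equally and are invariant to
residue order within a region — a known representational limitation of
sequence-level descriptors for surface-driven behaviour such as HIC
binding.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .descriptor_table import DescriptorTable
from .errors import EmptyRegion, UnknownTable
from .imgt import FabAnnotation
from .tables import (AROMATIC, NONPOLAR_CLASS, PKA, POLAR_CLASS,
                     RESIDUE_MASS, RESIDUE_TABLES, SCALES, SMALL, TINY,
                     WATER_MASS, PropertyScale, validate_sequence)

DEFAULT_SCALES = ("z5", "t5", "mswhim")
DEFAULT_TABLES = ("kd", "Gc", "W", "dGw")

PEPSTATS_NAMES = ("molecular_weight", "net_charge", "isoelectric_point",
                  "aliphatic_index", "tiny_fraction", "small_fraction",
                  "aromatic_fraction", "polar_fraction", "nonpolar_fraction")


def scale_region_sum(region_seq: str, scale: PropertyScale) -> np.ndarray:
    """Sum each scale component over the residues of a region."""
    region_seq = validate_sequence(region_seq, allow_empty=True)
    out = np.zeros(len(scale.components))
    for aa in region_seq:
        out += scale.table[aa]
    return out


def residue_property_sum(region_seq: str, table_name: str) -> float:
    """Sum a registered scalar per-residue table over a region."""
    if table_name not in RESIDUE_TABLES:
        raise UnknownTable(
            f"{table_name!r}; registered: {sorted(RESIDUE_TABLES)}")
    region_seq = validate_sequence(region_seq, allow_empty=True)
    table = RESIDUE_TABLES[table_name]
    return float(sum(table[aa] for aa in region_seq))


def _charge_at_ph(seq: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    pos = 1.0 / (1.0 + 10 ** (ph - PKA["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (PKA["Cterm"] - ph))
    for aa in seq:
        if aa in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10 ** (ph - PKA[aa]))
        elif aa in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (PKA[aa] - ph))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pI solved by bisection on the net-charge function."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _charge_at_ph(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pepstats_like(region_seq: str) -> dict[str, float]:
    """EMBOSS-pepstats-style global properties of a peptide.

    Molecular weight in Da (average residue masses + one water), net
    charge in elementary charges at pH 7, pI in pH units, Ikai aliphatic
    index, and residue-class mole fractions in [0, 1].
    """
    seq = validate_sequence(region_seq, allow_empty=True)
    if not seq:
        raise EmptyRegion("pepstats properties undefined for empty sequence")
    n = len(seq)
    frac = lambda group: sum(aa in group for aa in seq) / n
    fa = seq.count("A") / n
    fv = seq.count("V") / n
    fil = (seq.count("I") + seq.count("L")) / n
    return {
        "molecular_weight": sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS,
        "net_charge": _charge_at_ph(seq, 7.0),
        "isoelectric_point": isoelectric_point(seq),
        "aliphatic_index": 100.0 * (fa + 2.9 * fv + 3.9 * fil),
        "tiny_fraction": frac(TINY),
        "small_fraction": frac(SMALL),
        "aromatic_fraction": frac(AROMATIC),
        "polar_fraction": frac(POLAR_CLASS),
        "nonpolar_fraction": frac(NONPOLAR_CLASS),
    }


def build_seq2d(annotations: dict[str, FabAnnotation],
                scales: tuple[str, ...] = DEFAULT_SCALES,
                residue_tables: tuple[str, ...] = DEFAULT_TABLES,
                include_pepstats: bool = True) -> DescriptorTable:
    """Assemble the Seq2D descriptor matrix over variable-domain regions.

    One row per Fab; columns are "<region>.<scale>.<component>",
    "<region>.<table>" and "<region>.pepstats.<property>" for each of the
    14 variable-domain regions. Empty regions contribute zeros (with a
    warning for pepstats properties, which are undefined there).
    """
    rows = {}
    for sample, fab in annotations.items():
        row: dict[str, float] = {}
        for region in fab.variable_regions():
            seq = fab.region_sequence(region)
            for scale_name in scales:
                scale = SCALES[scale_name]
                sums = scale_region_sum(seq, scale)
                for comp, val in zip(scale.components, sums):
                    row[f"{region.name}.{scale_name}.{comp}"] = val
            for table_name in residue_tables:
                row[f"{region.name}.{table_name}"] = residue_property_sum(
                    seq, table_name)
            if include_pepstats:
                if seq:
                    props = pepstats_like(seq)
                else:
                    warnings.warn(f"{sample}: empty region {region.name}; "
                                  "pepstats descriptors set to 0")
                    props = {name: 0.0 for name in PEPSTATS_NAMES}
                for name in PEPSTATS_NAMES:
                    row[f"{region.name}.pepstats.{name}"] = props[name]
        rows[sample] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample"
    return DescriptorTable(frame, provenance="Seq2D")
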