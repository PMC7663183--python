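"""SASA-based structural descriptors (Hom3D / MD3D).

The solvent-accessible surface area is computed with the Shrake–Rupley
rolling-probe algorithm on a deterministic Fibonacci-lattice point set.
Per-residue SASA is normalised by the theoretical Gly-X-Gly maximum
(Tien et al. 2013) to give the relative solvent accessibility

    RSA_i = SASA_i / MaxASA_i,  clamped to [0, 1],

and region surface-property descriptors weight accessibility with the
Kyte–Doolittle hydropathy C_i^KD over the non-polar (NPR) and polar (PLR)
residue groups:

    SP_nonpolar = Σ_{i ∈ NPR} RSA_i · C_i^KD
    SP_polar    = Σ_{i ∈ PLR} RSA_i · C_i^KD

Raw cumulative region SASA (total / polar / non-polar) is emitted
alongside the weighted descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptor_table import DescriptorTable
from .errors import UnknownResidue
from .imgt import FabAnnotation, RegionAnnotation
from .seq_descriptors import residue_property_sum
from .structure import Structure
from .tables import KYTE_DOOLITTLE, MAX_ASA_TIEN, NPR, PLR

DEFAULT_STRUCT_TABLES = ("kd", "Gc", "W", "dGw")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation-covariant orthonormal frame from the coordinate cloud.

    Principal axes of the centred coordinates, with each axis sign fixed
    by the third central moment of the projections (falling back to the
    raw eigenvector when the cloud is symmetric along an axis), and the
    third axis completed by a cross product. Attaching the sphere
    lattice to this frame makes SASA exactly invariant under rigid
    motion for non-degenerate geometries.
    """
    centred = coords - coords.mean(0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    axes = []
    for k in (2, 1):  # two largest principal axes
        v = vecs[:, k]
        skew = float(((centred @ v) ** 3).sum())
        if abs(skew) > 1e-8:
            v = v * np.sign(skew)
        axes.append(v)
    axes.append(np.cross(axes[0], axes[1]))
    return np.column_stack(axes)


def shrake_rupley(structure: Structure, probe_radius: float = 1.4,
                  n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom SASA (Å²) by the Shrake–Rupley algorithm.

    Test points are placed on each atom's solvent-extended sphere
    (r_atom + probe) and counted as accessible when outside every
    neighbour's extended sphere. The quasi-uniform lattice is expressed
    in the structure's canonical principal-axes frame, so results are
    deterministic and invariant under rigid motion of the input.
    """
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be >= 92")
    frame = _canonical_frame(structure.coords)
    unit = fibonacci_sphere(n_sphere_points) @ frame.T
    coords = structure.coords
    radii = structure.radii + probe_radius
    n = structure.n_atoms
    out = np.zeros(n)
    # pairwise distances once; structures here are small (Fab-scale)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    for i in range(n):
        neighbours = np.where((dist[i] < radii[i] + radii) &
                              (np.arange(n) != i))[0]
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        out[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return out


@dataclass(frozen=True)
class ResidueSurface:
    """Per-residue surface summary used by the region descriptors."""

    chain_id: str
    res_id: int
    letter: str
    sasa: float           # Å²
    rsa: float            # dimensionless, clamped to [0, 1]
    kd: float             # Kyte–Doolittle hydropathy
    polarity_class: str   # "NPR" | "PLR"


def residue_rsa(structure: Structure,
                max_asa: dict[str, float] | None = None,
                atom_sasa: np.ndarray | None = None,
                probe_radius: float = 1.4,
                n_sphere_points: int = 960) -> list[ResidueSurface]:
    """Aggregate atom SASA per residue and normalise to RSA.

    ``max_asa`` defaults to the packaged Tien et al. theoretical table;
    a fixture-specific table may be supplied (e.g. one derived from the
    generating geometry of a toy structure).
    """
    table = MAX_ASA_TIEN if max_asa is None else max_asa
    if atom_sasa is None:
        atom_sasa = shrake_rupley(structure, probe_radius, n_sphere_points)
    out = []
    for chain_id, res_id, letter in structure.residues():
        if letter not in table:
            raise UnknownResidue(f"no MaxASA for residue {letter!r}")
        mask = (structure.chain_ids == chain_id) & (structure.res_ids == res_id)
        sasa = float(atom_sasa[mask].sum())
        raw = sasa / table[letter]
        if raw > 1.0:
            warnings.warn(f"RSA {raw:.2f} > 1 for {chain_id}:{res_id} "
                          f"({letter}); clamped")
        out.append(ResidueSurface(
            chain_id=chain_id, res_id=res_id, letter=letter, sasa=sasa,
            rsa=min(max(raw, 0.0), 1.0), kd=KYTE_DOOLITTLE[letter],
            polarity_class="NPR" if letter in NPR else "PLR"))
    return out


def _in_region(res: ResidueSurface, region: RegionAnnotation) -> bool:
    return (res.chain_id == region.chain_id
            and region.start <= res.res_id < region.end)


def sp_nonpolar(residues: list[ResidueSurface],
                region: RegionAnnotation) -> float:
    """Hydrophobic surface-property descriptor Σ_{i∈NPR} RSA_i · KD_i."""
    return float(sum(r.rsa * r.kd for r in residues
                     if _in_region(r, region) and r.polarity_class == "NPR"))


def sp_polar(residues: list[ResidueSurface],
             region: RegionAnnotation) -> float:
    """Polar surface-property descriptor Σ_{i∈PLR} RSA_i · KD_i."""
    return float(sum(r.rsa * r.kd for r in residues
                     if _in_region(r, region) and r.polarity_class == "PLR"))


def region_sasa(residues: list[ResidueSurface], region: RegionAnnotation,
                class_filter: str = "all") -> float:
    """Cumulative residue SASA (Å²) over a region, optionally restricted
    to the polar (PLR) or nonpolar (NPR) residue group."""
    wanted = {"all": ("NPR", "PLR"), "polar": ("PLR",),
              "nonpolar": ("NPR",)}[class_filter]
    return float(sum(r.sasa for r in residues
                     if _in_region(r, region) and r.polarity_class in wanted))


def build_struct_table(structures: dict[str, Structure],
                       annotations: dict[str, FabAnnotation],
                       provenance: str,
                       residue_tables: tuple[str, ...] = DEFAULT_STRUCT_TABLES,
                       max_asa: dict[str, float] | None = None,
                       probe_radius: float = 1.4,
                       n_sphere_points: int = 960) -> DescriptorTable:
    """Structural descriptor matrix over all 28 regions per Fab.

    Per region: SP_polar, SP_nonpolar, SASA_all, SASA_polar,
    SASA_nonpolar, plus registered per-residue table sums over the
    region sequence. Provenance tags the structural representation
    (Hom3D for static homology-model frames, MD3D for MD-relaxed ones).
    """
    rows = {}
    for sample, structure in structures.items():
        fab = annotations[sample]
        surfaces = residue_rsa(structure, max_asa=max_asa,
                               probe_radius=probe_radius,
                               n_sphere_points=n_sphere_points)
        row: dict[str, float] = {}
        for region in fab.regions:
            row[f"{region.name}.SP_polar"] = sp_polar(surfaces, region)
            row[f"{region.name}.SP_nonpolar"] = sp_nonpolar(surfaces, region)
            row[f"{region.name}.SASA_all"] = region_sasa(surfaces, region, "all")
            row[f"{region.name}.SASA_polar"] = region_sasa(
                surfaces, region, "polar")
            row[f"{region.name}.SASA_nonpolar"] = region_sasa(
                surfaces, region, "nonpolar")
            seq = fab.region_sequence(region)
            for table_name in residue_tables:
                row[f"{region.name}.{table_name}"] = residue_property_sum(
                    seq, table_name)
        rows[sample] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample"
    return DescriptorTable(frame, provenance=provenance)
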