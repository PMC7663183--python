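"""Synthetic fixture generation.

Every input the workflow consumes can be generated here, fully
reproducible from (spec, seed): IMGT-valid Fab sequence pairs built on
germline-like frameworks with randomised CDRs, chemically naive but
geometrically valid toy structures, multi-frame trajectories with
controlled noise and drift, and descriptor matrices with planted sparse
linear signal, collinear blocks and an optional class-correlated
confounder block.

Defaults mirror the study conditions the workflow targets: CDR-H3
lengths 6–20 and a fixed 3-residue CDR-L2; trajectory frames every
40 ps over 50 ns; regression matrices of 80 samples × 50 descriptors
with 5 informative descriptors and noise sd 0.1. Ground truth (support,
coefficients, drift) is returned machine-readable so tests never
hard-code derived numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import germline
from .chemometrics.scaling import Dataset
from .descriptor_table import DescriptorTable
from .imgt import ChainSequence, FabAnnotation, annotate_fab
from .structure import Structure, Trajectory
from .tables import AMINO_ACIDS

#: CDR alphabet excludes C/W/F so randomised loops can never spoof the
#: conserved anchors the numbering algorithm scans for.
CDR_ALPHABET = "".join(a for a in AMINO_ACIDS if a not in "CWF")


@dataclass
class TrajectorySpec:
    n_frames: int = 1250          # 50 ns at 40 ps/frame
    dt_ps: float = 40.0
    drift_start_frame: int = 125  # drift begins at 5 ns
    drift_magnitude: float = 0.0  # Å reached at the final frame
    drift_mode: str = "linear"    # "linear" ramp or instantaneous "step"
    noise_sd: float = 0.1         # Å isotropic per-atom noise
    drift_fraction: float = 0.3   # leading fraction of atoms that drift


@dataclass
class FixtureSpec:
    n_samples: int = 20
    cdr_length_ranges: dict = field(default_factory=lambda: {
        "H1": (5, 12), "H2": (5, 10), "H3": (6, 20),
        "L1": (5, 12), "L2": (3, 3), "L3": (5, 12),
    })
    noise_sd: float = 0.1
    n_descriptors: int = 50
    n_informative: int = 5
    beta_scale: float = 1.0
    collinear_blocks: int = 0      # extra near-duplicate columns
    collinear_r: float = 0.98
    confounder_block: int = 0      # class-correlated nuisance descriptors
    n_classes: int = 3
    skewed_response: bool = False
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    seed: int = 0


# --- sequences ------------------------------------------------------------

def _random_cdr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CDR_ALPHABET), size=length))


def make_fab_sequences(spec: FixtureSpec
                       ) -> list[tuple[ChainSequence, ChainSequence]]:
    """Generate (heavy, light) chain pairs that annotate to 28 regions.

    Frameworks are fixed germline-like templates carrying the conserved
    anchors; CDRs are randomised within the configured length ranges;
    constant domains are the packaged IGHG1*01 / IGLK1*01 alleles.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for _ in range(spec.n_samples):
        lr = spec.cdr_length_ranges
        h_cdrs = [_random_cdr(rng, rng.integers(lo, hi + 1))
                  for lo, hi in (lr["H1"], lr["H2"], lr["H3"])]
        l_cdrs = [_random_cdr(rng, rng.integers(lo, hi + 1))
                  for lo, hi in (lr["L1"], lr["L2"], lr["L3"])]
        hf, lf = germline.HEAVY_FRAMEWORKS, germline.KAPPA_FRAMEWORKS
        vh = (hf["FR1"] + h_cdrs[0] + hf["FR2"] + h_cdrs[1] + hf["FR3"]
              + h_cdrs[2] + hf["FR4"])
        vl = (lf["FR1"] + l_cdrs[0] + lf["FR2"] + l_cdrs[1] + lf["FR3"]
              + l_cdrs[2] + lf["FR4"])
        heavy = ChainSequence("heavy", vh + germline.IGHG1_CH1, len(vh))
        light = ChainSequence("light", vl + germline.IGLK1_CL, len(vl))
        pairs.append((heavy, light))
    return pairs


def make_fab_annotations(spec: FixtureSpec) -> dict[str, FabAnnotation]:
    return {f"mab{i:03d}": annotate_fab(h, l)
            for i, (h, l) in enumerate(make_fab_sequences(spec))}


# --- structures -----------------------------------------------------------

def make_toy_structure(heavy: ChainSequence | str,
                       light: ChainSequence | None = None,
                       geometry: str = "extended",
                       spacing: float = 3.8,
                       radius: float = 2.0) -> Structure:
    """Chemically naive C-alpha structure with pseudo-radii.

    Geometries: "extended" (residues along x at ``spacing`` Å), "helix"
    (ideal alpha-helix trace), "sphere_cluster" (residues on a Fibonacci
    sphere shell), "ellipsoid" (anisotropic shell with non-degenerate
    principal axes) and "globule" (seeded random packing). Two chains are
    laid out in parallel, offset in y. Deterministic.
    """
    chains = []
    if isinstance(heavy, ChainSequence):
        chains.append(("heavy", heavy.residues))
    else:
        chains.append(("heavy", str(heavy)))
    if light is not None:
        chains.append(("light", light.residues))

    coords, elements, chain_ids, res_ids, letters, names = \
        [], [], [], [], [], []
    for c_idx, (chain_id, seq) in enumerate(chains):
        n = len(seq)
        if geometry == "extended":
            xyz = np.column_stack([np.arange(n) * spacing,
                                   np.zeros(n), np.zeros(n)])
        elif geometry == "helix":
            t = np.arange(n) * (2 * np.pi / 3.6)
            xyz = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t),
                                   np.arange(n) * 1.5])
        elif geometry in ("sphere_cluster", "ellipsoid"):
            from .struct_descriptors import fibonacci_sphere
            shell = max(spacing * np.sqrt(n) / 2.0, spacing)
            xyz = fibonacci_sphere(n) * shell
            if geometry == "ellipsoid":
                # anisotropic shell: non-degenerate principal axes
                xyz = xyz * np.array([1.0, 0.75, 0.55])
        elif geometry == "globule":
            import zlib
            grng = np.random.default_rng(zlib.crc32(seq.encode()) % (2 ** 31))
            radius_g = spacing * max(n, 2) ** (1 / 3)
            xyz = grng.normal(0.0, radius_g / 2.0, size=(n, 3))
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        xyz = xyz + np.array([0.0, 20.0 * c_idx, 0.0])
        coords.append(xyz)
        elements.extend(["C"] * n)
        chain_ids.extend([chain_id] * n)
        res_ids.extend(range(n))
        letters.extend(seq)
        names.extend(["CA"] * n)
    return Structure(
        coords=np.vstack(coords), elements=np.array(elements, dtype=object),
        radii=np.full(sum(len(s) for _, s in chains), radius),
        chain_ids=np.array(chain_ids, dtype=object),
        res_ids=np.array(res_ids, dtype=int),
        res_letters=np.array(letters, dtype=object),
        atom_names=np.array(names, dtype=object))


def toy_max_asa(structure: Structure, geometry: str = "extended",
                **kwargs) -> dict[str, float]:
    """MaxASA table consistent with the toy geometry: the SASA of the
    central residue of an extended Gly-X-Gly built the same way."""
    from .struct_descriptors import residue_rsa, shrake_rupley
    from .tables import AMINO_ACIDS

    out = {}
    for aa in AMINO_ACIDS:
        tri = make_toy_structure(f"G{aa}G", geometry=geometry, **kwargs)
        sasa = shrake_rupley(tri)
        mask = tri.res_ids == 1
        out[aa] = float(sasa[mask].sum())
    return out


def make_trajectory(structure: Structure, spec: TrajectorySpec,
                    seed: int = 0) -> tuple[Trajectory, dict]:
    """Base structure + Gaussian noise, with optional linear drift.

    A leading fraction of atoms drifts along +x from
    ``drift_start_frame``: either a linear ramp reaching
    ``drift_magnitude`` Å at the final frame (a slow domain shift) or an
    instantaneous step of the full magnitude (a sharp conformational
    transition, giving SASA series a programmed two-level step). Returns
    (trajectory, ground truth dict with the drifting atom indices and
    programmed magnitude).
    """
    rng = np.random.default_rng(seed)
    n_atoms = structure.n_atoms
    n_drift = int(round(spec.drift_fraction * n_atoms))
    drift_atoms = np.arange(n_drift)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        frame = structure.coords + rng.normal(0.0, spec.noise_sd,
                                              size=(n_atoms, 3))
        if spec.drift_magnitude and f >= spec.drift_start_frame:
            if spec.drift_mode == "step":
                shift = spec.drift_magnitude
            else:
                span = max(spec.n_frames - 1 - spec.drift_start_frame, 1)
                shift = (spec.drift_magnitude
                         * (f - spec.drift_start_frame) / span)
            frame[drift_atoms, 0] += shift
        frames[f] = frame
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ps
    truth = {"drift_atoms": drift_atoms, "drift_magnitude": spec.drift_magnitude,
             "drift_start_frame": spec.drift_start_frame,
             "drift_mode": spec.drift_mode, "noise_sd": spec.noise_sd}
    return Trajectory(frames=frames, times=times, template=structure), truth


# --- regression fixtures --------------------------------------------------

def make_regression_dataset(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Descriptor matrix with planted sparse linear signal.

    X is standard normal with optional collinear columns (pairwise
    r >= collinear_r with their parents) and an optional class-correlated
    confounder block that carries species information but none about the
    response. y = X·β + ε with β supported on ``n_informative`` leading
    descriptors. Returns (dataset, ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_descriptors
    x = rng.standard_normal((n, p))

    collinear_pairs = []
    for b in range(spec.collinear_blocks):
        parent = rng.integers(p)
        noise_sd = np.sqrt(1.0 / spec.collinear_r ** 2 - 1.0)
        col = x[:, parent] + rng.normal(0.0, noise_sd, size=n)
        x = np.column_stack([x, col])
        collinear_pairs.append((parent, p + b))

    support = np.arange(spec.n_informative)
    beta = np.zeros(x.shape[1])
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    beta[support] = spec.beta_scale * signs * rng.uniform(
        0.5, 1.5, size=spec.n_informative)

    labels = None
    if spec.confounder_block:
        labels = pd.Series(
            rng.integers(spec.n_classes, size=n),
            index=range(n)).map(lambda k: f"species{k}")
        class_means = rng.normal(0.0, 2.0,
                                 size=(spec.n_classes, spec.confounder_block))
        codes = labels.str.removeprefix("species").astype(int).to_numpy()
        block = class_means[codes] + rng.normal(
            0.0, 0.5, size=(n, spec.confounder_block))
        x = np.column_stack([x, block])
        beta = np.concatenate([beta, np.zeros(spec.confounder_block)])

    eps = rng.normal(0.0, spec.noise_sd, size=n)
    y = x @ beta + eps
    if spec.skewed_response:
        y = np.exp(y / max(y.std(), 1e-9))  # right-skewed, positive

    names = ([f"d{j:03d}" for j in range(p)]
             + [f"c{j:03d}" for j in range(len(collinear_pairs))]
             + [f"conf{j:03d}" for j in range(spec.confounder_block)])
    ids = [f"s{i:03d}" for i in range(n)]
    frame = pd.DataFrame(x, index=ids, columns=names)
    frame.index.name = "sample"
    response = pd.Series(y, index=ids, name="rt_minutes")
    meta = {}
    if labels is not None:
        labels.index = ids
        meta["species"] = labels
    dataset = Dataset(DescriptorTable(frame, provenance="Seq2D"),
                      response, meta)
    truth = {"support": [names[j] for j in support], "beta": beta,
             "noise_sd": spec.noise_sd, "collinear_pairs": collinear_pairs,
             "species": labels}
    return dataset, truth
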