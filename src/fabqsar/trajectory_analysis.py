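"""Multi-frame trajectory analytics.

Quantifies the structural-relaxation phenomenology of Fab MD runs:
RMSD of each frame against a reference (after optimal superposition),
per-atom/per-residue RMSF about the mean structure, the magnitude of the
dominant essential motion from coordinate-covariance PCA, per-region
SASA time series, and the absolute difference of SASA averages between
the early (pre-split) and late (post-split) simulation intervals.

Superposition uses the Kabsch least-squares algorithm on a C-alpha
selection by default; the coordinate covariance for the essential-motion
PCA is unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSelection, EmptyInterval
from .imgt import FabAnnotation, RegionAnnotation
from .struct_descriptors import region_sasa, residue_rsa
from .structure import Structure, Trajectory


def _default_selection(traj_or_struct) -> np.ndarray:
    template = (traj_or_struct.template
                if isinstance(traj_or_struct, Trajectory) else traj_or_struct)
    mask = template.atom_names == "CA"
    if not mask.any():  # toy structures without named backbone atoms
        mask = np.ones(template.n_atoms, dtype=bool)
    return np.where(mask)[0]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the
    selected atoms; the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise DegenerateSelection("need at least 3 atoms")
    m, r = mobile[sel], reference[sel]
    mc, rc = m.mean(0), r.mean(0)
    h = (m - mc).T @ (r - rc)
    u, s, vt = np.linalg.svd(h)
    # collinear selections leave the rotation about the axis undetermined
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise DegenerateSelection("selection is (nearly) collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - r) ** 2).sum(1).mean()))
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, reference: np.ndarray | None = None,
                selection: np.ndarray | None = None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) versus a reference frame (default: frame 0).

    With ``superpose=False`` the raw coordinate RMSD is reported (no
    rigid-body fit) — useful to read off an absolute programmed drift.
    """
    if reference is None:
        reference = traj.frames[0]
    if selection is None:
        selection = _default_selection(traj)
    if not superpose:
        d = traj.frames[:, selection, :] - reference[selection]
        return np.sqrt((d ** 2).sum(-1).mean(-1))
    return np.array([kabsch_superpose(f, reference, selection)[2]
                     for f in traj.frames])


def superpose_frames(traj: Trajectory, reference: np.ndarray,
                     selection: np.ndarray) -> np.ndarray:
    out = np.empty_like(traj.frames)
    for i, f in enumerate(traj.frames):
        rot, trans, _ = kabsch_superpose(f, reference, selection)
        out[i] = f @ rot.T + trans
    return out


def _mean_aligned_frames(traj: Trajectory,
                         selection: np.ndarray,
                         n_passes: int = 2) -> np.ndarray:
    """Iterated mean-structure alignment (fit to mean, recompute mean)."""
    frames = traj.frames
    mean = frames[0]
    for _ in range(n_passes):
        aligned = np.empty_like(frames)
        for i, f in enumerate(frames):
            rot, trans, _ = kabsch_superpose(f, mean, selection)
            aligned[i] = f @ rot.T + trans
        mean = aligned.mean(0)
        frames = aligned
    return frames


def rmsf(traj: Trajectory, selection: np.ndarray | None = None,
         per_residue: bool = False,
         align_selection: np.ndarray | None = None) -> np.ndarray:
    """Root-mean-square fluctuation about the mean structure (Å).

    Frames are superposed to their mean structure first (two alignment
    passes, fit on ``align_selection``, defaulting to ``selection``);
    per_residue averages atom RMSF within each residue of the selection.
    """
    if selection is None:
        selection = _default_selection(traj)
    if align_selection is None:
        align_selection = selection
    aligned = _mean_aligned_frames(traj, align_selection)
    sub = aligned[:, selection, :]
    mean = sub.mean(0)
    per_atom = np.sqrt(((sub - mean) ** 2).sum(-1).mean(0))
    if not per_residue:
        return per_atom
    res_keys = [(c, int(r)) for c, r in
                zip(traj.template.chain_ids[selection],
                    traj.template.res_ids[selection])]
    order, groups = [], {}
    for k, v in zip(res_keys, per_atom):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(v)
    return np.array([np.mean(groups[k]) for k in order])


def essential_motion_magnitude(traj: Trajectory,
                               selection: np.ndarray | None = None
                               ) -> tuple[np.ndarray, float]:
    """Essential-dynamics eigenvalues and dominant-motion magnitude.

    PCA of the 3N coordinate covariance of the superposed frames;
    returns (eigenvalues in Å², descending) and sqrt(largest eigenvalue)
    in Å. The eigenvalue sum equals the total coordinate variance.
    """
    if selection is None:
        selection = _default_selection(traj)
    aligned = _mean_aligned_frames(traj, selection)
    flat = aligned[:, selection, :].reshape(traj.n_frames, -1)
    centred = flat - flat.mean(0)
    # SVD of the frame matrix gives the covariance eigenvalues directly
    s = np.linalg.svd(centred, compute_uv=False)
    eigvals = np.zeros(flat.shape[1])
    k = min(len(s), flat.shape[1])
    eigvals[:k] = (s ** 2) / traj.n_frames
    eigvals = np.sort(eigvals)[::-1]
    return eigvals, float(np.sqrt(eigvals[0]))


@dataclass
class SasaSeries:
    """Cumulative region SASA per frame."""

    region: str
    times: np.ndarray   # ps
    values: np.ndarray  # Å²

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")
        if (self.values < 0).any():
            raise ValueError("SASA values must be >= 0")


def region_sasa_series(traj: Trajectory, annotation: FabAnnotation,
                       region: RegionAnnotation,
                       max_asa: dict[str, float] | None = None,
                       n_sphere_points: int = 960,
                       frame_stride: int = 1) -> SasaSeries:
    """Per-frame cumulative residue SASA for one region.

    ``frame_stride`` subsamples frames to bound the SASA cost on long
    trajectories.
    """
    idx = range(0, traj.n_frames, frame_stride)
    values, times = [], []
    for i in idx:
        surfaces = residue_rsa(traj.frame_structure(i), max_asa=max_asa,
                               n_sphere_points=n_sphere_points)
        values.append(region_sasa(surfaces, region, "all"))
        times.append(traj.times[i])
    return SasaSeries(region=region.name, times=np.array(times),
                      values=np.array(values))


def sasa_interval_diff(series: SasaSeries,
                       split_time: float = 5000.0) -> float:
    """|mean SASA before split − mean SASA from split on| (Å²).

    The default split at 5 ns separates the initial relaxation phase
    from the stabilised remainder of a 50 ns production run.
    """
    early = series.values[series.times < split_time]
    late = series.values[series.times >= split_time]
    if len(early) == 0 or len(late) == 0:
        raise EmptyInterval(f"series does not span split at {split_time} ps")
    return float(abs(early.mean() - late.mean()))
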