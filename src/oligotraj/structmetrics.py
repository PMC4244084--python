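"""Rigid-body superposition (Kabsch), RMSD time series and per-residue RMSF.

The RMSF reference is the iteratively aligned mean structure (two
align/average iterations) by default; a fixed native reference is also
supported.  The default atom selection for both metrics is Cα.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import Frame, SystemModel, Trajectory

__all__ = [
    "Superposition",
    "kabsch",
    "rmsd_series",
    "rmsf_per_residue",
]


@dataclass
class Superposition:
    rotation: np.ndarray          # (3, 3), proper (det = +1)
    translation: np.ndarray       # (3,), Å
    rmsd: float                   # Å, after alignment

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(reference: np.ndarray, mobile: np.ndarray,
           weights: np.ndarray | None = None) -> Superposition:
    """Least-squares optimal proper rotation + translation of *mobile* onto
    *reference*, via SVD of the weighted covariance matrix."""
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValidationError("point sets must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() == 0:
            raise ValidationError("weights must be n non-negative values")
        w = w / w.sum()

    ref_c = ref - w @ ref
    mob_c = mob - w @ mob
    H = (mob_c * w[:, None]).T @ ref_c
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-8 * max(s[0], 1e-300):
        warnings.warn("near-degenerate (collinear) point set: rotation is "
                      "ill-conditioned", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = mob_c @ R.T
    rmsd = float(np.sqrt((w * ((aligned - ref_c) ** 2).sum(axis=1)).sum()))
    t = (w @ ref) - (w @ mob) @ R.T
    return Superposition(R, t, rmsd)


def _selection(model: SystemModel, selection: np.ndarray | None,
               chain_ids: list[str] | None) -> np.ndarray:
    if selection is not None:
        sel = np.asarray(selection, dtype=np.intp)
    else:
        sel = model.calpha_atom_indices(chain_ids)
    if sel.size == 0:
        raise ValidationError("empty atom selection")
    return sel


def rmsd_series(traj: Trajectory, reference: Frame,
                selection: np.ndarray | None = None,
                chain_ids: list[str] | None = None) -> np.ndarray:
    """Per-frame Kabsch-aligned RMSD (Å) over the selection (default: Cα)."""
    sel = _selection(traj.model, selection, chain_ids)
    ref = reference.coords[sel]
    return np.array([kabsch(ref, f.coords[sel]).rmsd for f in traj.frames])


def rmsf_per_residue(traj: Trajectory, selection: np.ndarray | None = None,
                     chain_ids: list[str] | None = None,
                     reference: Frame | None = None,
                     n_iterations: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (Å) about the aligned average structure.

    Every frame is aligned to the current reference, the aligned mean is
    taken as the new reference, and the cycle repeats *n_iterations* times
    (starting from the supplied native *reference*, or from frame 0).
    Returns (global residue indices, rmsf values).
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    sel = _selection(traj.model, selection, chain_ids)
    coords = np.stack([f.coords[sel] for f in traj.frames])
    ref = (reference.coords[sel] if reference is not None else coords[0]).copy()
    aligned = coords
    for _ in range(max(1, n_iterations)):
        aligned = np.stack([kabsch(ref, c).apply(c) for c in coords])
        ref = aligned.mean(axis=0)
    mean = aligned.mean(axis=0)
    msd_atom = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # per selected atom

    res_of_sel = traj.model.atom_residue[sel]
    residues = np.unique(res_of_sel)
    rmsf = np.array([np.sqrt(msd_atom[res_of_sel == r].mean()) for r in residues])
    return residues, rmsf
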