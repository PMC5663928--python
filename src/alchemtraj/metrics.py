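"""Least-squares superposition and positional deviation statistics.

Superposition uses the Kabsch algorithm (SVD with reflection correction),
optionally mass-weighted.  RMSD series and per-atom RMSF follow the common
MD-analysis pattern: align each frame on one selection (e.g. protein
backbone), report the deviation over another (e.g. ligand heavy atoms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Trajectory

__all__ = ["SuperpositionResult", "superpose", "apply_transform", "rmsd", "rmsd_series", "rmsf"]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    Apply as ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray  # (3, 3), proper rotation, det = +1
    translation: np.ndarray  # (3,)
    rmsd_after: float  # over the fitted selection, Angstrom


def _as_coords(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected (n_atoms, 3) coordinates, got {x.shape}")
    return x


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> SuperpositionResult:
    """Weighted least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The fit is computed over ``selection`` (all atoms when ``None``); the
    returned transform can then be applied to the full coordinate set.
    Selections of fewer than 3 non-collinear atoms leave the rotation
    under-determined; the returned transform is still a valid least-squares
    minimiser (the RMSD is unique) and a warning is emitted.
    """
    mobile = _as_coords(mobile)
    reference = _as_coords(reference)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if selection.size < 2:
        raise ValueError("superposition requires at least 2 selected atoms")
    x = mobile[selection]
    y = reference[selection]
    if weights is None:
        w = np.ones(selection.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (selection.size,):
            raise ValueError("weights must match the selection size")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    xc = x - w @ x
    yc = y - w @ y
    # rank of the centred reference tells us whether the rotation is unique
    if np.linalg.matrix_rank(yc, tol=1e-8) < 2:
        warnings.warn(
            "selection is collinear or coincident; rotation under-determined "
            "(returned transform is still a least-squares minimiser)",
            stacklevel=2,
        )
    h = (w[:, None] * xc).T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = (w @ y) - rot @ (w @ x)
    fitted = x @ rot.T + trans
    rmsd_after = float(np.sqrt(np.sum(w * np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd_after=rmsd_after)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def rmsd(a: np.ndarray, b: np.ndarray, selection: Optional[np.ndarray] = None) -> float:
    """Plain (unfitted) RMSD between two conformations over a selection."""
    a = _as_coords(a)
    b = _as_coords(b)
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise ValueError("empty selection")
        a = a[selection]
        b = b[selection]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection: Optional[np.ndarray] = None,
    align_selection: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after per-frame superposition.

    Each frame is superposed onto ``reference`` over ``align_selection``
    (defaults to ``selection``), then the RMSD is evaluated over
    ``selection``.  This supports the usual pattern of aligning on the
    protein backbone while reporting ligand heavy-atom deviation.
    """
    reference = _as_coords(reference)
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    fit_sel = selection if align_selection is None else np.asarray(align_selection, dtype=int)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        res = superpose(traj.coordinates[f], reference, fit_sel, weights)
        moved = apply_transform(traj.coordinates[f], res)
        out[f] = rmsd(moved, reference, selection)
    return out


def rmsf(
    traj: Trajectory,
    selection: Optional[np.ndarray] = None,
    align_selection: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean position (A).

    Frames are first superposed (over ``align_selection``, defaulting to
    ``selection``) onto the first frame to remove rigid-body motion, then
    the fluctuation of each selected atom about its time-average position
    is reported.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    fit_sel = selection if align_selection is None else np.asarray(align_selection, dtype=int)
    ref = traj.coordinates[0]
    aligned = np.empty((traj.n_frames, selection.size, 3))
    for f in range(traj.n_frames):
        res = superpose(traj.coordinates[f], ref, fit_sel)
        aligned[f] = apply_transform(traj.coordinates[f], res)[selection]
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
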