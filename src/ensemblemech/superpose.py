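"""Least-squares superposition (Kabsch), RMSD, pairwise matrices, RMSF.

The metric kernel used by every analysis stage.  All quantities are
unweighted over the selected atoms and expressed in Å.  The optimal proper
rotation is obtained from the SVD of the 3×3 cross-covariance with the
reflection branch corrected by the sign of ``det(V Wᵀ)`` (Kabsch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import (
    AtomSelection,
    ConformationalEnsemble,
    SelectionError,
)

__all__ = [
    "FitResult",
    "DegenerateFitError",
    "kabsch_fit",
    "rmsd",
    "pairwise_rmsd_matrix",
    "pairwise_rmsd_cross",
    "rmsf",
]


class DegenerateFitError(ValueError):
    """Fewer than 3 non-collinear atoms available for fitting."""


@dataclass
class FitResult:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    ``rotation`` is a proper 3×3 rotation (det = +1); the fitted coordinates
    are ``(mobile - mobile_centroid) @ rotation.T + target_centroid``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after_fit: float


def _check_fit_geometry(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError(
            f"need at least 3 fit atoms, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    # rank < 2 means the points are collinear (or coincident)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear; rotation is underdetermined")


def _kabsch_rotation(mobile_c: np.ndarray, target_c: np.ndarray) -> np.ndarray:
    h = mobile_c.T @ target_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    return vt.T @ np.diag(diag) @ u.T


def kabsch_fit(
    mobile: np.ndarray,
    target: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[FitResult, np.ndarray]:
    """Superpose ``mobile`` onto ``target``, fitting over ``fit_indices``.

    The optimal transform is determined on the fit atoms and applied to all
    atoms of ``mobile``.  Returns the :class:`FitResult` (with RMSD evaluated
    over the fit atoms) and the fully transformed mobile coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {target.shape}")
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    fit_indices = np.asarray(fit_indices, dtype=int)
    if fit_indices.size == 0:
        raise ValueError("fit_indices is empty")
    m_fit = mobile[fit_indices]
    t_fit = target[fit_indices]
    _check_fit_geometry(m_fit)
    m_cent = m_fit.mean(axis=0)
    t_cent = t_fit.mean(axis=0)
    rot = _kabsch_rotation(m_fit - m_cent, t_fit - t_cent)
    transformed = (mobile - m_cent) @ rot.T + t_cent
    diff = transformed[fit_indices] - t_fit
    value = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    translation = t_cent - rot @ m_cent
    return FitResult(rotation=rot, translation=translation, rmsd_after_fit=value), transformed


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    indices: np.ndarray | None = None,
    prefit: bool = True,
    fit_indices: np.ndarray | None = None,
) -> float:
    """RMSD between two conformations over ``indices``.

    With ``prefit`` the Kabsch superposition is applied first, fitting on
    ``fit_indices`` (defaulting to ``indices`` — the same atoms used for the
    RMSD, the standard convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if indices is None:
        indices = np.arange(a.shape[0])
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty index list for RMSD")
    if prefit:
        if fit_indices is None:
            fit_indices = indices
        _, b_fitted = kabsch_fit(b, a, fit_indices=fit_indices)
    else:
        b_fitted = b
    diff = a[indices] - b_fitted[indices]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _batched_fitted_rmsd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form Kabsch RMSD for matched coordinate batches.

    ``a``, ``b``: (batch, n_atoms, 3) already centered per conformation.
    Uses rmsd² = (|a|² + |b|² − 2(σ₁+σ₂±σ₃))/n with the sign of the smallest
    singular value set by det(H).
    """
    n = a.shape[1]
    h = np.einsum("bik,bil->bkl", a, b)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    s_sum = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
    sq = (np.sum(a * a, axis=(1, 2)) + np.sum(b * b, axis=(1, 2)) - 2.0 * s_sum) / n
    return np.sqrt(np.clip(sq, 0.0, None))


def fitted_rmsd_pairs(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Per-pair Kabsch-fitted RMSD for two matched frame batches.

    ``coords_a``, ``coords_b``: (n_pairs, n_atoms, 3); each pair is fitted on
    its own atoms.  Vectorized over pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    return _batched_fitted_rmsd(a, b)


def unfitted_rmsd_pairs(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Per-pair RMSD without superposition for matched frame batches."""
    diff = np.asarray(coords_a, float) - np.asarray(coords_b, float)
    return np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))


def pairwise_rmsd_matrix(
    ensemble: ConformationalEnsemble,
    selection: AtomSelection,
    prefit: bool = True,
    block: int = 256,
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix over a resolved selection.

    Every pair is superposed independently on the selection atoms (matching
    the per-pair fit convention) unless ``prefit`` is off.  Computed in
    blocks with the batched closed-form Kabsch RMSD.
    """
    if not selection.resolved:
        raise SelectionError(f"selection {selection.name!r} must be resolved")
    x = ensemble.coords[:, selection.indices, :].astype(float)
    f = x.shape[0]
    if prefit:
        x = x - x.mean(axis=1, keepdims=True)
    out = np.zeros((f, f), dtype=float)
    for i0 in range(0, f, block):
        i1 = min(i0 + block, f)
        for j0 in range(i0, f, block):
            j1 = min(j0 + block, f)
            ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
            mask = jj > ii
            if not mask.any():
                continue
            ai, bj = ii[mask], jj[mask]
            if prefit:
                vals = _batched_fitted_rmsd(x[ai], x[bj])
            else:
                vals = unfitted_rmsd_pairs(x[ai], x[bj])
            out[ai, bj] = vals
            out[bj, ai] = vals
    return out


def pairwise_rmsd_cross(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    prefit: bool = True,
    block: int = 512,
) -> np.ndarray:
    """All-pairs RMSD between two frame stacks (n_a, n_atoms, 3) x (n_b, ...)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if prefit:
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
    na, nb = a.shape[0], b.shape[0]
    out = np.empty((na, nb), dtype=float)
    for i0 in range(0, na, block):
        i1 = min(i0 + block, na)
        for j0 in range(0, nb, block):
            j1 = min(j0 + block, nb)
            ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
            ai, bj = ii.ravel(), jj.ravel()
            if prefit:
                vals = _batched_fitted_rmsd(a[ai], b[bj])
            else:
                vals = unfitted_rmsd_pairs(a[ai], b[bj])
            out[i0:i1, j0:j1] = vals.reshape(i1 - i0, j1 - j0)
    return out


def fit_frames_to_reference(
    coords: np.ndarray, reference: np.ndarray, fit_indices: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto a reference on ``fit_indices`` (all atoms moved)."""
    out = np.empty_like(coords, dtype=float)
    for i, frame in enumerate(coords):
        _, out[i] = kabsch_fit(frame, reference, fit_indices=fit_indices)
    return out


def rmsf(
    ensemble: ConformationalEnsemble,
    selection: AtomSelection,
    fit_selection: AtomSelection | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation over the ensemble, Å.

    Frames are superposed onto the ensemble-mean structure on
    ``fit_selection`` (default: the analysis selection), with the mean
    structure iterated once: fit to the naive mean, recompute the mean,
    refit.  RMSF is √⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩ per selected atom.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if fit_selection is None:
        fit_selection = selection
    for sel in (selection, fit_selection):
        if not sel.resolved:
            raise SelectionError(f"selection {sel.name!r} must be resolved")
    coords = ensemble.coords.astype(float)
    fit_idx = fit_selection.indices
    mean = coords.mean(axis=0)
    fitted = fit_frames_to_reference(coords, mean, fit_idx)
    mean = fitted.mean(axis=0)
    fitted = fit_frames_to_reference(fitted, mean, fit_idx)
    mean = fitted.mean(axis=0)
    dev = fitted[:, selection.indices, :] - mean[selection.indices]
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
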