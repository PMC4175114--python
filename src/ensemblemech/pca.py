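"""Essential-dynamics PCA of Cartesian fluctuations on a combined ensemble.

The unbound and bound ensembles are concatenated, every frame is superposed
onto a common reference, and the covariance matrix of the selected Cartesian
coordinates is eigendecomposed.  Each ensemble is then projected separately
onto the shared eigenvectors; ensemble overlap in PC space and
nearest-neighbour cross-ensemble pairs are derived from those projections.

Projections are in Å (raw Cartesian units along each principal mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomSelection, ConformationalEnsemble, SelectionError
from .superpose import fit_frames_to_reference

__all__ = [
    "PCModel",
    "PCProjection",
    "fit_pc_model",
    "project",
    "variance_fractions",
    "overlap_fraction",
    "nearest_cross_pairs",
]


@dataclass
class PCModel:
    """Eigendecomposition of the Cartesian covariance of a combined ensemble.

    ``eigenvectors`` has orthonormal columns of length 3·n_sel; eigenvalues
    (Å², descending) use the 1/(F−1) covariance normalization.
    """

    mean_structure: np.ndarray          # (n_sel, 3) Å
    eigenvectors: np.ndarray            # (3*n_sel, m)
    eigenvalues: np.ndarray             # (m,) Å², descending
    fit_selection: str
    analysis_selection: str
    n_frames_total: int


@dataclass
class PCProjection:
    """Scores of one ensemble on the combined principal modes."""

    provenance: str
    scores: np.ndarray                  # (n_frames, k) Å
    pc_ranks: np.ndarray                # 1-based component ranks


def _fitted_selected_coords(
    ensemble: ConformationalEnsemble,
    analysis_selection: AtomSelection,
    fit_selection: AtomSelection,
    reference: np.ndarray,
) -> np.ndarray:
    fitted = fit_frames_to_reference(
        ensemble.coords.astype(float), np.asarray(reference, float), fit_selection.indices
    )
    sel = fitted[:, analysis_selection.indices, :]
    return sel.reshape(sel.shape[0], -1)


def fit_pc_model(
    unbound: ConformationalEnsemble,
    bound: ConformationalEnsemble,
    analysis_selection: AtomSelection,
    fit_selection: AtomSelection | None = None,
    reference: np.ndarray | None = None,
) -> PCModel:
    """PCA of the concatenated unbound+bound ensemble over a selection.

    Every frame of both ensembles is superposed onto ``reference`` (default:
    the first unbound frame) on ``fit_selection`` (default: the analysis
    selection itself).  When 3·n_sel exceeds the frame count the spectrum is
    obtained from the frame-frame Gram matrix — mathematically identical,
    cheaper.
    """
    for sel in (analysis_selection, fit_selection):
        if sel is not None and not sel.resolved:
            raise SelectionError(f"selection {sel.name!r} must be resolved")
    if fit_selection is None:
        fit_selection = analysis_selection
    if reference is None:
        reference = unbound.coords[0]
    if unbound.n_atoms != bound.n_atoms:
        raise SelectionError("ensembles differ in atom count; selections cannot match")

    xu = _fitted_selected_coords(unbound, analysis_selection, fit_selection, reference)
    xb = _fitted_selected_coords(bound, analysis_selection, fit_selection, reference)
    x = np.concatenate([xu, xb], axis=0)
    f, d = x.shape
    if f < 2:
        raise ValueError("PCA requires at least 2 frames in total")
    mean = x.mean(axis=0)
    y = x - mean

    if d <= f:
        cov = (y.T @ y) / (f - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
    else:
        gram = (y @ y.T) / (f - 1)
        gvals, gvecs = np.linalg.eigh(gram)
        order = np.argsort(gvals)[::-1]
        gvals = gvals[order]
        gvecs = gvecs[:, order]
        keep = gvals > 1e-12 * max(gvals[0], 1.0)
        gvals, gvecs = gvals[keep], gvecs[:, keep]
        evecs = (y.T @ gvecs) / np.sqrt(gvals * (f - 1))
        evals = gvals

    if np.any(evals < -1e-8):
        raise ValueError("covariance eigenvalues substantially negative")
    evals = np.clip(evals, 0.0, None)
    return PCModel(
        mean_structure=mean.reshape(-1, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
        fit_selection=fit_selection.name,
        analysis_selection=analysis_selection.name,
        n_frames_total=f,
    )


def project(
    model: PCModel,
    ensemble: ConformationalEnsemble,
    analysis_selection: AtomSelection,
    fit_selection: AtomSelection,
    reference: np.ndarray,
    k: int | None = None,
) -> PCProjection:
    """Project an ensemble onto the first ``k`` combined principal modes.

    The ensemble is fitted exactly as during model building; scores are
    ``(x − mean) · eigenvectors[:, :k]``.
    """
    m = model.eigenvectors.shape[1]
    if k is None:
        k = m
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} available components")
    x = _fitted_selected_coords(ensemble, analysis_selection, fit_selection, reference)
    scores = (x - model.mean_structure.ravel()) @ model.eigenvectors[:, :k]
    return PCProjection(
        provenance=ensemble.provenance,
        scores=scores,
        pc_ranks=np.arange(1, k + 1),
    )


def project_coords(model: PCModel, flat_coords: np.ndarray, k: int) -> np.ndarray:
    """Scores for already-fitted flattened coordinates (rows of 3·n_sel)."""
    return (np.atleast_2d(flat_coords) - model.mean_structure.ravel()) @ model.eigenvectors[:, :k]


def variance_fractions(model: PCModel, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode variance fractions and their cumulative sum, first ``k`` modes."""
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("total variance is zero; no fluctuations to decompose")
    if k is None:
        k = len(model.eigenvalues)
    if k > len(model.eigenvalues):
        raise ValueError(f"k={k} exceeds the {len(model.eigenvalues)} available components")
    fr = model.eigenvalues[:k] / total
    return fr, np.cumsum(fr)


def _cells(scores: np.ndarray, origin: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor((scores - origin) / bin_width).astype(np.int64)


def overlap_fraction(
    proj_unbound: PCProjection,
    proj_bound: PCProjection,
    k: int = 2,
    bin_width: float | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fraction of frames falling in PC-space grid cells occupied by both ensembles.

    A k-dimensional uniform grid with cell edge ``bin_width`` is anchored at
    the combined minimum; a cell is shared when at least one frame of each
    ensemble lands in it.  Default ``bin_width`` is 1/20 of the combined PC1
    range.  Returns the shared-frame fraction plus per-frame overlap flags
    for each ensemble.  Symmetric in its two arguments.
    """
    su = np.atleast_2d(proj_unbound.scores)[:, :k]
    sb = np.atleast_2d(proj_bound.scores)[:, :k]
    allsc = np.concatenate([su, sb], axis=0)
    if bin_width is None:
        span = allsc[:, 0].max() - allsc[:, 0].min()
        bin_width = span / 20.0 if span > 0 else 1.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    origin = allsc.min(axis=0)
    cu = _cells(su, origin, bin_width)
    cb = _cells(sb, origin, bin_width)
    set_u = {tuple(c) for c in cu}
    set_b = {tuple(c) for c in cb}
    shared = set_u & set_b
    flags_u = np.array([tuple(c) in shared for c in cu], dtype=bool)
    flags_b = np.array([tuple(c) in shared for c in cb], dtype=bool)
    frac = (flags_u.sum() + flags_b.sum()) / (len(flags_u) + len(flags_b))
    return float(frac), flags_u, flags_b


def nearest_cross_pairs(
    proj_unbound: PCProjection,
    proj_bound: PCProjection,
    cutoff: float,
    k: int = 3,
) -> list[tuple[int, int, float]]:
    """For each bound frame, its nearest unbound frame in the first k PCs.

    Pairs with Euclidean distance ≤ ``cutoff`` are kept; an unbound frame may
    partner several bound frames.  Returns ``(bound_index, unbound_index,
    distance)`` triples; empty list (with no error) when nothing is within
    the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    su = np.atleast_2d(proj_unbound.scores)[:, :k]
    sb = np.atleast_2d(proj_bound.scores)[:, :k]
    tree = cKDTree(su)
    dist, idx = tree.query(sb, k=1)
    pairs = [
        (int(b), int(u), float(d))
        for b, (u, d) in enumerate(zip(idx, dist))
        if d <= cutoff
    ]
    return pairs
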