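"""Standard trajectory descriptors: RMSD, RMSF, Cartesian PCA, distances.

These are the conventional companions of a correlation analysis: per-frame
RMSD from a reference structure, per-atom RMSF about the trajectory mean,
principal component analysis of the flattened 3N Cartesian coordinate vector
of a selection, interatomic distance time series, and density-based
clustering of conformations on the PC1-PC2 plane.

Conventions: PCA covariance uses the 1/n_frames (population) normalization,
so contribution rates are invariant and eigenvalues reproducible; RMSF is
computed on the trajectory as given — apply the superposition convention you
want (per-molecule or global) before calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .errors import AtomLookupError, ParameterError, SelectionError, ShapeError
from .trajio import Trajectory, _resolve_selection, superpose

__all__ = [
    "PCAResult",
    "rmsd_series",
    "rmsf",
    "pca_cartesian",
    "distance_series",
    "density_cluster_2d",
]


@dataclass
class PCAResult:
    """Cartesian PCA of a selection.

    ``components`` rows are orthonormal 3N directions, eigenvalues (A^2)
    non-increasing; ``projections[f, k]`` is the score of frame ``f`` on
    component ``k``; recombining all components reproduces the centered data.
    """

    mean_structure: np.ndarray  # (n_sel, 3)
    components: np.ndarray  # (n_comp, 3 * n_sel)
    eigenvalues: np.ndarray  # (n_comp,)
    contribution_rates: np.ndarray  # (n_comp,)
    projections: np.ndarray  # (n_frames, n_comp)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Centered coordinates rebuilt from all components, (n_frames, 3*n_sel)."""
        return self.projections @ self.components


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection=None,
    fit: bool = False,
    fit_selection=None,
) -> np.ndarray:
    """Per-frame RMSD (A) of ``selection`` from ``reference`` (n_atoms, 3).

    With ``fit=True`` each frame is first rigidly superposed onto the
    reference using ``fit_selection`` (default: the same selection).
    """
    sel = _resolve_selection(traj.topology, selection)
    if sel.size == 0:
        raise SelectionError("empty selection for RMSD")
    if fit:
        traj = superpose(traj, reference, fit_selection if fit_selection is not None else sel)
    diff = traj.coords[:, sel, :] - np.asarray(reference, dtype=float)[sel]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def rmsf(traj: Trajectory, selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (A) about the trajectory mean.

    RMSF_i = sqrt(<||r_i(t) - <r_i>||^2>_t).  Superpose the trajectory with
    the convention of your choice beforehand.
    """
    if traj.n_frames < 2:
        raise ShapeError("RMSF needs at least 2 frames")
    sel = _resolve_selection(traj.topology, selection)
    x = traj.coords[:, sel, :]
    dev = x - x.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def pca_cartesian(traj: Trajectory, selection=None) -> PCAResult:
    """PCA of the flattened 3N Cartesian coordinates of ``selection``.

    Eigendecomposition of the population covariance of the centered
    (n_frames, 3N) matrix via SVD; contribution rates are eigenvalue
    fractions.  The trajectory should be superposed first; a warning is
    issued when n_frames <= 3 * n_selected (poor sampling).
    """
    sel = _resolve_selection(traj.topology, selection)
    if sel.size == 0:
        raise SelectionError("empty selection for PCA")
    if traj.n_frames <= 3 * sel.size:
        warnings.warn(
            f"only {traj.n_frames} frames for {3 * sel.size} coordinates; "
            "PCA may be undersampled",
            stacklevel=2,
        )
    x = traj.coords[:, sel, :].reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / traj.n_frames
    total = eigenvalues.sum()
    if total <= 0:
        raise ParameterError("zero total variance; PCA undefined")
    return PCAResult(
        mean_structure=mean.reshape(-1, 3),
        components=vt,
        eigenvalues=eigenvalues,
        contribution_rates=eigenvalues / total,
        projections=u * s,
    )


def distance_series(traj: Trajectory, atom_a: int, atom_b: int) -> np.ndarray:
    """Euclidean distance (A) between two atoms per frame; no superposition."""
    for idx in (atom_a, atom_b):
        if not 0 <= idx < traj.n_atoms:
            raise AtomLookupError(f"atom index {idx} out of range")
    diff = traj.coords[:, atom_a, :] - traj.coords[:, atom_b, :]
    return np.sqrt(np.sum(diff**2, axis=1))


def density_cluster_2d(
    projections: np.ndarray,
    grid_size: int = 100,
    bandwidth=None,
    level: float = 0.1,
) -> np.ndarray:
    """Label clusters of a 2-D score cloud by density contouring.

    A Gaussian KDE is evaluated on a ``grid_size`` x ``grid_size`` grid,
    thresholded at ``level`` x max density, and connected super-threshold
    regions become clusters (labels 0, 1, ... by decreasing population).
    Every point is assigned the label of its nearest super-threshold grid
    cell, so no point is left unlabelled.  Degenerate input (all points
    identical) is a single cluster.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ShapeError(f"projections must be (n, 2); got {pts.shape}")
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 points")
    if np.allclose(pts, pts[0]):
        return np.zeros(pts.shape[0], dtype=int)

    try:
        kde = gaussian_kde(pts.T, bw_method=bandwidth)
    except np.linalg.LinAlgError:
        # collapsed to a line: jitter minimally to regularize the KDE
        jitter = 1e-9 * (pts.std() + 1.0)
        rng = np.random.default_rng(0)
        kde = gaussian_kde((pts + rng.normal(0, jitter, pts.shape)).T, bw_method=bandwidth)

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = 0.1 * np.maximum(hi - lo, 1e-6)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)

    mask = dens >= level * dens.max()
    labelled, n_regions = ndimage.label(mask)
    if n_regions == 0:
        return np.zeros(pts.shape[0], dtype=int)

    cell_idx = np.nonzero(mask)
    cell_xy = np.column_stack([xx[cell_idx], yy[cell_idx]])
    cell_lab = labelled[cell_idx]
    tree = cKDTree(cell_xy)
    _, nearest = tree.query(pts)
    raw = cell_lab[nearest]

    # relabel by decreasing population
    order = np.argsort([-np.sum(raw == r) for r in range(1, n_regions + 1)], kind="stable")
    remap = {int(region + 1): rank for rank, region in enumerate(order)}
    return np.array([remap[int(r)] for r in raw], dtype=int)
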