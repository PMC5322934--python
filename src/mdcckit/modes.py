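"""Gaussian-mixture decomposition of per-atom coordinate distributions.

Over a long trajectory an atom's sampled positions are often multi-modal —
the classic example is a side chain flipping between rotamers, which puts a
terminal atom in two well-separated spatial basins.  Each basin is modelled
as one Gaussian component ("mode") of a mixture over the atom's 3-D
coordinates: a weight pi_k (the fraction of time spent in the mode), a
center mu_k, and a full 3x3 covariance.

Fitting is expectation-maximization with seeded restarts; the number of
modes K is chosen by the Bayesian information criterion over K = 1..max_modes
(the criterion is pluggable, AIC is also available).  Components whose
converged weight falls below a floor are pruned and the remainder
renormalized.  Modes are ordered by non-increasing weight (ties broken by
lexicographic center comparison) so mode indices are stable across runs.

Per-frame mode membership is the standard mixture responsibility
p_k(r_i(t)), recomputed from the stored (pruned) mixture.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .errors import AtomLookupError, ParameterError
from .trajio import Trajectory

__all__ = [
    "AtomModes",
    "ModePosterior",
    "fit_modes",
    "fit_all_modes",
    "mode_posterior",
    "mode_center_distance",
    "modes_to_json",
    "modes_from_json",
]

COVARIANCE_FLOOR = 1e-6  # A^2, added to covariance diagonals
WEIGHT_PRUNE_FLOOR = 0.01


@dataclass
class AtomModes:
    """Gaussian-mixture description of one atom's coordinate distribution."""

    atom_index: int
    weights: np.ndarray  # (K,)
    centers: np.ndarray  # (K, 3) A
    covariances: np.ndarray  # (K, 3, 3) A^2
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ParameterError(f"mode weights sum to {self.weights.sum()}, not 1")
        if np.any(self.weights <= 0):
            raise ParameterError("all mode weights must be positive")
        for cov in self.covariances:
            if not np.allclose(cov, cov.T):
                raise ParameterError("mode covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() < 0.5 * COVARIANCE_FLOOR:
                raise ParameterError("mode covariance below regularization floor")

    @property
    def n_modes(self) -> int:
        return len(self.weights)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Per-mode log of weight * N(x | mu_k, Sigma_k); x is (n, 3)."""
        x = np.atleast_2d(x)
        cols = [
            np.log(w) + multivariate_normal(mu, cov, allow_singular=True).logpdf(x)
            for w, mu, cov in zip(self.weights, self.centers, self.covariances)
        ]
        return np.column_stack(cols)


@dataclass
class ModePosterior:
    """Per-frame mode-membership probabilities p_k(r_i(t)) for one atom."""

    atom_index: int
    probs: np.ndarray  # (n_frames, K), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("posterior rows must sum to 1")

    @property
    def n_modes(self) -> int:
        return self.probs.shape[1]


def _sorted_mode_order(weights: np.ndarray, centers: np.ndarray) -> list[int]:
    return sorted(
        range(len(weights)), key=lambda k: (-weights[k], tuple(centers[k]))
    )


def fit_modes(
    traj: Trajectory,
    atom_index: int,
    max_modes: int = 6,
    seed: int = 0,
    n_init: int = 5,
    criterion: str = "bic",
    prune_weight: float = WEIGHT_PRUNE_FLOOR,
    reg_covar: float = COVARIANCE_FLOOR,
) -> AtomModes:
    """Fit a Gaussian mixture to one atom's coordinates, selecting K by BIC.

    Deterministic given ``seed``.  Degenerate (frozen) atoms yield a single
    mode centered at the fixed point with floor covariance.  After model
    selection, components with weight < ``prune_weight`` are dropped and the
    remaining weights renormalized.
    """
    if not 0 <= atom_index < traj.n_atoms:
        raise AtomLookupError(f"atom index {atom_index} out of range")
    if max_modes < 1:
        raise ParameterError("max_modes must be >= 1")
    x = traj.coords[:, atom_index, :]
    if traj.n_frames < 50:
        warnings.warn(
            f"only {traj.n_frames} frames; mode fitting may be unreliable",
            stacklevel=2,
        )
    if np.allclose(x, x[0]):
        return AtomModes(
            atom_index,
            np.array([1.0]),
            x[:1].copy(),
            np.array([np.eye(3) * reg_covar]),
            {"criterion": criterion, "seed": seed, "constant": True},
        )

    crit_values: dict[int, float] = {}
    best = None
    best_crit = np.inf
    for k in range(1, max_modes + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=reg_covar,
            n_init=n_init,
            random_state=seed % (2**31),
            max_iter=500,
        )
        try:
            gm.fit(x)
        except ValueError:
            continue
        value = gm.bic(x) if criterion == "bic" else gm.aic(x)
        crit_values[k] = float(value)
        if value < best_crit:
            best_crit = value
            best = gm
    if best is None:
        raise ParameterError("no mixture could be fitted")

    weights = best.weights_.copy()
    centers = best.means_.copy()
    covs = best.covariances_.copy()
    keep = weights >= prune_weight
    pruned = int((~keep).sum())
    if not keep.any():
        keep[np.argmax(weights)] = True
    weights, centers, covs = weights[keep], centers[keep], covs[keep]
    weights = weights / weights.sum()
    order = _sorted_mode_order(weights, centers)
    return AtomModes(
        atom_index,
        weights[order],
        centers[order],
        covs[order],
        {
            "criterion": criterion,
            "criterion_values": crit_values,
            "k_range": [1, max_modes],
            "seed": seed,
            "n_init": n_init,
            "n_frames": traj.n_frames,
            "pruned_components": pruned,
        },
    )


def fit_all_modes(
    traj: Trajectory,
    selection=None,
    max_modes: int = 6,
    seed: int = 0,
    **kwargs,
) -> dict[int, AtomModes]:
    """Fit modes for every selected atom (default: all heavy atoms).

    Per-atom seeds are derived from ``seed`` and the atom index so results do
    not depend on selection order.
    """
    from .trajio import _resolve_selection

    if selection is None:
        sel = np.nonzero(traj.topology.heavy_mask())[0]
    else:
        sel = _resolve_selection(traj.topology, selection)
    out: dict[int, AtomModes] = {}
    for i in sel:
        atom_seed = (seed * 1000003 + int(i)) % (2**31)
        out[int(i)] = fit_modes(traj, int(i), max_modes=max_modes, seed=atom_seed, **kwargs)
    return out


def mode_posterior(modes: AtomModes, traj: Trajectory) -> ModePosterior:
    """Mixture responsibilities of every frame for one atom's modes."""
    x = traj.coords[:, modes.atom_index, :]
    if modes.n_modes == 1:
        return ModePosterior(modes.atom_index, np.ones((traj.n_frames, 1)))
    logp = modes.log_density(x)
    probs = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    return ModePosterior(modes.atom_index, probs)


def mode_center_distance(modes_i: AtomModes, k: int, modes_j: AtomModes, l: int) -> float:
    """Euclidean distance (A) between mode centers mu_k of atom i and mu_l of atom j."""
    if not 0 <= k < modes_i.n_modes:
        raise AtomLookupError(f"mode index {k} out of range for atom {modes_i.atom_index}")
    if not 0 <= l < modes_j.n_modes:
        raise AtomLookupError(f"mode index {l} out of range for atom {modes_j.atom_index}")
    return float(np.linalg.norm(modes_i.centers[k] - modes_j.centers[l]))


def modes_to_json(all_modes: dict[int, AtomModes], path) -> None:
    payload = {
        str(i): {
            "atom_index": m.atom_index,
            "weights": m.weights.tolist(),
            "centers": m.centers.tolist(),
            "covariances": m.covariances.tolist(),
            "fit_info": m.fit_info,
        }
        for i, m in all_modes.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def modes_from_json(path) -> dict[int, AtomModes]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        int(i): AtomModes(
            rec["atom_index"],
            np.array(rec["weights"]),
            np.array(rec["centers"]),
            np.array(rec["covariances"]),
            rec.get("fit_info", {}),
        )
        for i, rec in payload.items()
    }
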