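"""Dynamic cross-correlation, conventional and multi-modal (mDCC).

The conventional DCC between atoms i and j is the normalized time average

    DCC(i,j) = <dr_i(t) . dr_j(t)>_t
               / sqrt(<||dr_i||^2>_t <||dr_j||^2>_t),

with dr_i(t) = r_i(t) - <r_i>_t.  When an atom's distribution is
multi-modal (a flipping side chain, a transiently formed contact), the
deviation from the global mean conflates the switch between basins with the
motion inside a basin, and genuine within-basin correlation is diluted or
cancelled.

The multi-modal variant measures correlation per pair of Gaussian modes
(k of atom i, l of atom j): deviations are taken from the mode centers,
dr_{i,k}(t) = r_i(t) - mu_k, and every frame is weighted by the joint
membership probability w_{i,j;k,l}(t) = p_k(r_i(t)) p_l(r_j(t)):

    mDCC(i,j;k,l) = <w dr_{i,k} . dr_{j,l}>_t
                    / sqrt(<w ||dr_{i,k}||^2>_t <w ||dr_{j,l}||^2>_t).

Both quantities lie in [-1, 1] (Cauchy-Schwarz with the non-negative frame
weights).  When both atoms are uni-modal, w = 1 and the mode center is the
mean, so mDCC collapses exactly to DCC.

Residue-level summary: the representative mDCC of a residue pair (a, b) is
the largest mDCC over all atom pairs (i in a, j in b) and mode pairs (k, l),
after omitting mode pairs that only rarely coexist — those whose
time-averaged joint probability <w>_t is <= ``weight_floor`` (default 0.1).
A companion residue DCC (max of conventional DCC over the atom pairs) is
kept for detecting transient interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedCorrelationError
from .modes import AtomModes, ModePosterior
from .trajio import Topology, Trajectory

__all__ = [
    "ModePairCorrelation",
    "ResidueCorrelationMatrix",
    "dcc",
    "mdcc_mode_pair",
    "atom_pair_mode_correlations",
    "residue_matrix",
]

DEFAULT_WEIGHT_FLOOR = 0.1


@dataclass
class ModePairCorrelation:
    """mDCC of one mode pair, with its joint weight and center distance.

    ``mdcc_value`` is NaN when the weighted variances vanish (the pair is
    never jointly occupied, or an atom is frozen within the mode).
    """

    atom_i: int
    atom_j: int
    mode_k: int
    mode_l: int
    mdcc_value: float
    mean_weight: float
    center_distance: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mdcc_value)


@dataclass
class ResidueCorrelationMatrix:
    """Symmetric residue-level representative mDCC and companion DCC.

    ``residue_indices`` are topology residue indices in topology order;
    ``provenance[(a, b)]`` records the maximizing atom/mode pair of cell
    (a, b) (a < b, positions within this matrix).  ``mdcc_min`` keeps the
    signed minimum over the same candidate set, for diagnostics.  Cells with
    no analyzable atom pair are NaN and flagged in ``missing``.
    """

    residue_indices: list[int]
    labels: list[str]
    molecules: list[str]
    mdcc: np.ndarray
    dcc: np.ndarray
    mdcc_min: np.ndarray
    provenance: dict[tuple[int, int], ModePairCorrelation]
    missing: np.ndarray
    weight_floor: float
    candidates: dict[tuple[int, int], list[ModePairCorrelation]] | None = None

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mdcc, index=self.labels, columns=self.labels)

    def to_tsv(self, path, which: str = "mdcc") -> None:
        mat = {"mdcc": self.mdcc, "dcc": self.dcc, "mdcc_min": self.mdcc_min}[which]
        pd.DataFrame(mat, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


def _deviations(traj: Trajectory, atom: int) -> np.ndarray:
    x = traj.coords[:, atom, :]
    return x - x.mean(axis=0)


def dcc(traj: Trajectory, atom_i: int, atom_j: int) -> float:
    """Conventional dynamic cross-correlation of two atoms; symmetric in arguments."""
    di = _deviations(traj, atom_i)
    dj = _deviations(traj, atom_j)
    vi = np.mean(np.sum(di**2, axis=1))
    vj = np.mean(np.sum(dj**2, axis=1))
    if vi == 0 or vj == 0:
        raise UndefinedCorrelationError(
            f"zero-variance atom in pair ({atom_i}, {atom_j}); DCC undefined"
        )
    return float(np.mean(np.sum(di * dj, axis=1)) / np.sqrt(vi * vj))


def mdcc_mode_pair(
    traj: Trajectory,
    modes_i: AtomModes,
    modes_j: AtomModes,
    posterior_i: ModePosterior,
    posterior_j: ModePosterior,
    k: int,
    l: int,
) -> ModePairCorrelation:
    """mDCC of mode k of atom i against mode l of atom j.

    Frames are weighted by the joint membership probability; deviations are
    taken from the two mode centers.  If either weighted variance is zero
    (e.g. the modes are never jointly occupied) the value is NaN.
    """
    if posterior_i.n_modes != modes_i.n_modes or posterior_j.n_modes != modes_j.n_modes:
        raise ParameterError("posterior and modes disagree on mode count")
    w = posterior_i.probs[:, k] * posterior_j.probs[:, l]
    di = traj.coords[:, modes_i.atom_index, :] - modes_i.centers[k]
    dj = traj.coords[:, modes_j.atom_index, :] - modes_j.centers[l]
    num = np.mean(w * np.sum(di * dj, axis=1))
    vi = np.mean(w * np.sum(di**2, axis=1))
    vj = np.mean(w * np.sum(dj**2, axis=1))
    value = num / np.sqrt(vi * vj) if vi > 0 and vj > 0 else np.nan
    return ModePairCorrelation(
        atom_i=modes_i.atom_index,
        atom_j=modes_j.atom_index,
        mode_k=k,
        mode_l=l,
        mdcc_value=float(value),
        mean_weight=float(np.mean(w)),
        center_distance=float(np.linalg.norm(modes_i.centers[k] - modes_j.centers[l])),
    )


def atom_pair_mode_correlations(
    traj: Trajectory,
    modes_i: AtomModes,
    modes_j: AtomModes,
    posterior_i: ModePosterior,
    posterior_j: ModePosterior,
) -> list[ModePairCorrelation]:
    """All mode-pair mDCC values for one atom pair, vectorized over frames."""
    T = traj.n_frames
    A = traj.coords[:, modes_i.atom_index, :]
    B = traj.coords[:, modes_j.atom_index, :]
    Mi = modes_i.centers  # (K, 3)
    Mj = modes_j.centers  # (L, 3)
    Pi = posterior_i.probs  # (T, K)
    Pj = posterior_j.probs  # (T, L)

    # dot[t,k,l] = (A[t]-Mi[k]).(B[t]-Mj[l]) expanded into four separable terms
    s0 = np.sum(A * B, axis=1)  # (T,)
    s1 = A @ Mj.T  # (T, L)
    s2 = B @ Mi.T  # (T, K)
    s3 = Mi @ Mj.T  # (K, L)
    qi = np.sum((A[:, None, :] - Mi[None, :, :]) ** 2, axis=2)  # (T, K)
    qj = np.sum((B[:, None, :] - Mj[None, :, :]) ** 2, axis=2)  # (T, L)

    mean_w = (Pi.T @ Pj) / T  # (K, L)
    num = (
        np.einsum("tk,tl,t->kl", Pi, Pj, s0)
        - np.einsum("tk,tl->kl", Pi, Pj * s1)
        - np.einsum("tk,tl->kl", Pi * s2, Pj)
    ) / T + mean_w * s3
    vi = np.einsum("tk,tl->kl", Pi * qi, Pj) / T
    vj = np.einsum("tk,tl->kl", Pi, Pj * qj) / T

    out = []
    for k in range(modes_i.n_modes):
        for l in range(modes_j.n_modes):
            value = (
                num[k, l] / np.sqrt(vi[k, l] * vj[k, l])
                if vi[k, l] > 0 and vj[k, l] > 0
                else np.nan
            )
            out.append(
                ModePairCorrelation(
                    atom_i=modes_i.atom_index,
                    atom_j=modes_j.atom_index,
                    mode_k=k,
                    mode_l=l,
                    mdcc_value=float(value),
                    mean_weight=float(mean_w[k, l]),
                    center_distance=float(np.linalg.norm(Mi[k] - Mj[l])),
                )
            )
    return out


def _better(cand: ModePairCorrelation, incumbent: ModePairCorrelation | None) -> bool:
    """Max with deterministic tie-breaking: larger mean weight, then closer centers."""
    if incumbent is None:
        return True
    if cand.mdcc_value != incumbent.mdcc_value:
        return cand.mdcc_value > incumbent.mdcc_value
    if cand.mean_weight != incumbent.mean_weight:
        return cand.mean_weight > incumbent.mean_weight
    return cand.center_distance < incumbent.center_distance


def residue_matrix(
    traj: Trajectory,
    all_modes: dict[int, AtomModes],
    all_posteriors: dict[int, ModePosterior],
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    store_candidates: bool = False,
) -> ResidueCorrelationMatrix:
    """Residue-level representative mDCC and companion DCC matrices.

    For each residue pair, the representative mDCC is the maximum over all
    atom pairs and mode pairs whose time-averaged joint probability exceeds
    ``weight_floor``; the provenance of the argmax is retained.  The
    companion DCC is the maximum conventional DCC over the same atom pairs.
    Atoms must appear in both ``all_modes`` and ``all_posteriors``; frozen
    (zero-variance) atoms are skipped for DCC.  With ``store_candidates``
    every floor-passing candidate is kept per cell (needed for the
    "any mode pair" network edge rule).
    """
    topology = traj.topology
    atom_ids = sorted(set(all_modes) & set(all_posteriors))
    if not atom_ids:
        raise ParameterError("no atoms with both modes and posteriors")

    by_residue: dict[int, list[int]] = {}
    for i in atom_ids:
        by_residue.setdefault(topology.atoms[i].residue_index, []).append(i)
    residue_indices = sorted(by_residue)
    pos = {r: p for p, r in enumerate(residue_indices)}
    R = len(residue_indices)

    mdcc_mat = np.full((R, R), np.nan)
    dcc_mat = np.full((R, R), np.nan)
    min_mat = np.full((R, R), np.nan)
    provenance: dict[tuple[int, int], ModePairCorrelation] = {}
    candidates: dict[tuple[int, int], list[ModePairCorrelation]] = {}

    devs: dict[int, np.ndarray] = {}
    variances: dict[int, float] = {}
    for i in atom_ids:
        d = _deviations(traj, i)
        devs[i] = d
        variances[i] = float(np.mean(np.sum(d**2, axis=1)))

    for a_pos, a in enumerate(residue_indices):
        for b_pos in range(a_pos, R):
            b = residue_indices[b_pos]
            best: ModePairCorrelation | None = None
            worst: ModePairCorrelation | None = None
            best_dcc = np.nan
            cell_cands: list[ModePairCorrelation] = []
            for i in by_residue[a]:
                for j in by_residue[b]:
                    if a_pos == b_pos and j <= i:
                        continue
                    if variances[i] > 0 and variances[j] > 0:
                        v = float(
                            np.mean(np.sum(devs[i] * devs[j], axis=1))
                            / np.sqrt(variances[i] * variances[j])
                        )
                        if np.isnan(best_dcc) or v > best_dcc:
                            best_dcc = v
                    for cand in atom_pair_mode_correlations(
                        traj,
                        all_modes[i],
                        all_modes[j],
                        all_posteriors[i],
                        all_posteriors[j],
                    ):
                        if cand.mean_weight <= weight_floor or not cand.defined:
                            continue
                        cell_cands.append(cand)
                        if _better(cand, best):
                            best = cand
                        if worst is None or cand.mdcc_value < worst.mdcc_value:
                            worst = cand
            if a_pos == b_pos:
                # self-pair: representative value 1 when the residue moves at all
                moving = any(variances[i] > 0 for i in by_residue[a])
                mdcc_mat[a_pos, a_pos] = 1.0 if moving else np.nan
                dcc_mat[a_pos, a_pos] = 1.0 if moving else np.nan
                min_mat[a_pos, a_pos] = 1.0 if moving else np.nan
                continue
            if best is not None:
                mdcc_mat[a_pos, b_pos] = mdcc_mat[b_pos, a_pos] = best.mdcc_value
                min_mat[a_pos, b_pos] = min_mat[b_pos, a_pos] = worst.mdcc_value
                provenance[(a_pos, b_pos)] = best
            if not np.isnan(best_dcc):
                dcc_mat[a_pos, b_pos] = dcc_mat[b_pos, a_pos] = best_dcc
            if store_candidates and cell_cands:
                candidates[(a_pos, b_pos)] = cell_cands

    return ResidueCorrelationMatrix(
        residue_indices=residue_indices,
        labels=[topology.residue_label(r) for r in residue_indices],
        molecules=[topology.molecule_of(r) for r in residue_indices],
        mdcc=mdcc_mat,
        dcc=dcc_mat,
        mdcc_min=min_mat,
        provenance=provenance,
        missing=np.isnan(mdcc_mat),
        weight_floor=weight_floor,
        candidates=candidates if store_candidates else None,
    )
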