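"""Conventional DCC, mode-pair mDCC and the residue-level summary."""

import numpy as np
import pytest

from mdcckit.errors import UndefinedCorrelationError
from mdcckit.mdcc import (
    atom_pair_mode_correlations,
    dcc,
    mdcc_mode_pair,
    residue_matrix,
)
from mdcckit.modes import AtomModes, ModePosterior, fit_all_modes, fit_modes, mode_posterior
from mdcckit.synth import generate_two_state_pair, generate_unimodal_system

from conftest import make_trajectory


class TestDcc:
    def test_self_pair_is_one(self):
        rng = np.random.default_rng(0)
        traj = make_trajectory(rng.normal(0, 1, (100, 1, 3)))
        assert np.isclose(dcc(traj, 0, 0), 1.0)

    def test_point_reflection_is_minus_one(self):
        rng = np.random.default_rng(1)
        coords = np.empty((100, 2, 3))
        coords[:, 0, :] = rng.normal(0, 1, (100, 3))
        coords[:, 1, :] = -coords[:, 0, :]  # reflection through the origin
        assert np.isclose(dcc(make_trajectory(coords), 0, 1), -1.0)

    def test_orthogonal_deviation_patterns_give_zero(self):
        # per-frame dot products [1, -1, -1, 1] average to 0
        coords = np.zeros((4, 2, 3))
        coords[:, 0, 0] = [1.0, -1.0, 1.0, -1.0]
        coords[:, 1, 0] = [1.0, 1.0, -1.0, -1.0]
        assert np.isclose(dcc(make_trajectory(coords), 0, 1), 0.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        traj = make_trajectory(rng.normal(0, 1, (200, 2, 3)))
        assert dcc(traj, 0, 1) == dcc(traj, 1, 0)

    def test_zero_variance_reported(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 0, 0] = np.arange(10.0)
        with pytest.raises(UndefinedCorrelationError):
            dcc(make_trajectory(coords), 0, 1)


class TestMdccModePair:
    def test_unimodal_pair_collapses_to_dcc(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 1, (500, 2, 3))
        coords[:, 1, :] = 0.6 * coords[:, 0, :] + 0.8 * rng.normal(0, 1, (500, 3))
        traj = make_trajectory(coords)
        modes = {i: fit_modes(traj, i, max_modes=1, seed=0) for i in (0, 1)}
        post = {i: mode_posterior(modes[i], traj) for i in (0, 1)}
        pair = mdcc_mode_pair(traj, modes[0], modes[1], post[0], post[1], 0, 0)
        assert np.isclose(pair.mdcc_value, dcc(traj, 0, 1), atol=1e-9)
        assert np.isclose(pair.mean_weight, 1.0)

    def test_matched_modes_agree_with_true_assignment_oracle(self):
        """Fitted mDCC reproduces the oracle computed from the planted states
        and centers, and recovers the planted within-mode correlation."""
        traj, truth = generate_two_state_pair(20_000, rho=0.9, seed=4)
        states = truth.switch_schedule["pair"]
        modes = {i: fit_modes(traj, i, max_modes=3, seed=4) for i in (0, 1)}
        post = {i: mode_posterior(modes[i], traj) for i in (0, 1)}

        for state in (0, 1):
            # oracle: hard true assignments, planted centers
            w = (states == state).astype(float)
            di = traj.coords[:, 0, :] - truth.modes[0][state].center
            dj = traj.coords[:, 1, :] - truth.modes[1][state].center
            num = np.mean(w * np.sum(di * dj, axis=1))
            den = np.sqrt(
                np.mean(w * np.sum(di**2, axis=1))
                * np.mean(w * np.sum(dj**2, axis=1))
            )
            oracle = num / den

            # fitted mode whose center is nearest the planted center
            k = int(
                np.argmin(
                    np.linalg.norm(
                        modes[0].centers - truth.modes[0][state].center, axis=1
                    )
                )
            )
            l = int(
                np.argmin(
                    np.linalg.norm(
                        modes[1].centers - truth.modes[1][state].center, axis=1
                    )
                )
            )
            pair = mdcc_mode_pair(traj, modes[0], modes[1], post[0], post[1], k, l)
            assert np.isclose(pair.mdcc_value, oracle, atol=0.02)
            assert np.isclose(pair.mdcc_value, 0.9, atol=0.05)

    def test_never_jointly_occupied_pair_is_undefined(self):
        # hard, complementary posteriors: w(t) = 0 for the crossed mode pair
        coords = np.zeros((10, 2, 3))
        coords[:5, 0, 0] = 1.0
        coords[5:, 1, 0] = 1.0
        traj = make_trajectory(coords)
        m = AtomModes(
            0,
            np.array([0.5, 0.5]),
            np.array([[1.0, 0, 0], [0.0, 0, 0]]),
            np.array([np.eye(3) * 0.01] * 2),
        )
        m2 = AtomModes(
            1,
            np.array([0.5, 0.5]),
            np.array([[1.0, 0, 0], [0.0, 0, 0]]),
            np.array([np.eye(3) * 0.01] * 2),
        )
        p0 = np.zeros((10, 2))
        p0[:5, 0] = 1.0
        p0[5:, 1] = 1.0
        p1 = np.zeros((10, 2))
        p1[:5, 1] = 1.0
        p1[5:, 0] = 1.0
        pair = mdcc_mode_pair(
            traj, m, m2, ModePosterior(0, p0), ModePosterior(1, p1), 0, 0
        )
        assert pair.mean_weight == 0.0
        assert not pair.defined


def _fit_posteriors(traj, max_modes, seed):
    modes = fit_all_modes(traj, max_modes=max_modes, seed=seed)
    post = {i: mode_posterior(m, traj) for i, m in modes.items()}
    return modes, post


class TestResidueMatrix:
    def test_unimodal_residues_reduce_to_dcc(self):
        traj, _ = generate_unimodal_system(5, 800, sigma=1.0, seed=5)
        modes, post = _fit_posteriors(traj, 1, 5)
        mat = residue_matrix(traj, modes, post)
        assert np.allclose(mat.mdcc, mat.dcc, atol=1e-9, equal_nan=True)

    def test_rare_pair_floor_excludes_and_next_best_retained(self):
        """A mode pair with mean joint weight 0.05 is omitted even when it has
        the largest mDCC; the best well-populated pair becomes representative."""
        rng = np.random.default_rng(6)
        T = 40
        rare = np.zeros(T, dtype=bool)
        rare[-2:] = True  # 2/40 frames -> mean weight 0.05
        coords = np.zeros((T, 2, 3))
        # common mode: weakly correlated jitter about the origin centers
        a = rng.normal(0, 1, (T, 3))
        b = 0.3 * a + np.sqrt(1 - 0.09) * rng.normal(0, 1, (T, 3))
        coords[:, 0, :] = a
        coords[:, 1, :] = b + [5.0, 0, 0]
        # rare mode: perfectly correlated motion about displaced centers
        coords[rare, 0, :] = [[10.0, 0, 1.0], [10.0, 0, -1.0]]
        coords[rare, 1, :] = [[15.0, 0, 1.0], [15.0, 0, -1.0]]

        def hard_modes(atom, x_offset):
            modes = AtomModes(
                atom,
                np.array([0.95, 0.05]),
                np.array([[x_offset, 0, 0], [x_offset + 10.0, 0, 0]]),
                np.array([np.eye(3)] * 2),
            )
            probs = np.zeros((T, 2))
            probs[~rare, 0] = 1.0
            probs[rare, 1] = 1.0
            return modes, ModePosterior(atom, probs)

        m0, p0 = hard_modes(0, 0.0)
        m1, p1 = hard_modes(1, 5.0)
        traj = make_trajectory(coords)
        all_pairs = atom_pair_mode_correlations(traj, m0, m1, p0, p1)
        by_mode = {(c.mode_k, c.mode_l): c for c in all_pairs}
        assert np.isclose(by_mode[(1, 1)].mean_weight, 0.05)
        assert by_mode[(1, 1)].mdcc_value > by_mode[(0, 0)].mdcc_value

        mat = residue_matrix(traj, {0: m0, 1: m1}, {0: p0, 1: p1}, weight_floor=0.1)
        assert np.isclose(mat.mdcc[0, 1], by_mode[(0, 0)].mdcc_value)
        prov = mat.provenance[(0, 1)]
        assert (prov.mode_k, prov.mode_l) == (0, 0)

        # with a floor below 0.05 the rare, perfectly correlated pair wins
        mat_low = residue_matrix(traj, {0: m0, 1: m1}, {0: p0, 1: p1}, weight_floor=0.01)
        assert np.isclose(mat_low.mdcc[0, 1], by_mode[(1, 1)].mdcc_value)

    def test_three_residue_exhaustive_enumeration_oracle(self):
        """Residue matrix equals a brute-force max over all atom and mode pairs."""
        rng = np.random.default_rng(7)
        # 3 residues x 2 atoms; give one atom a genuine two-state switch
        n, T = 6, 4000
        coords = rng.normal(0, 0.4, (T, n, 3))
        base = np.array(
            [[0, 0, 0], [1.5, 0, 0], [4, 0, 0], [5.5, 0, 0], [8, 0, 0], [9.5, 0, 0]],
            dtype=float,
        )
        coords += base
        flip = rng.random(T) < 0.4
        coords[flip, 3, 2] += 3.0  # atom 3 bimodal along z
        from mdcckit.trajio import Atom, Residue, Topology, Trajectory

        atoms = [
            Atom(i + 1, f"C{i}", "C", "A", i // 2) for i in range(n)
        ]
        residues = [Residue("A", r + 1, "", "ALA") for r in range(3)]
        traj = Trajectory(coords, Topology(atoms, residues, {}))

        modes, post = _fit_posteriors(traj, 2, 7)
        mat = residue_matrix(traj, modes, post, weight_floor=0.1)

        # oracle: exhaustive enumeration with independent max/filter logic
        for a in range(3):
            for b in range(a + 1, 3):
                best = -np.inf
                best_dcc = -np.inf
                for i in (2 * a, 2 * a + 1):
                    for j in (2 * b, 2 * b + 1):
                        best_dcc = max(best_dcc, dcc(traj, i, j))
                        for k in range(modes[i].n_modes):
                            for l in range(modes[j].n_modes):
                                c = mdcc_mode_pair(
                                    traj, modes[i], modes[j], post[i], post[j], k, l
                                )
                                if c.mean_weight > 0.1 and c.defined:
                                    best = max(best, c.mdcc_value)
                ia, ib = mat.labels.index(f"A:{a+1}:ALA"), mat.labels.index(f"A:{b+1}:ALA")
                assert np.isclose(mat.mdcc[ia, ib], best, atol=1e-12)
                assert np.isclose(mat.dcc[ia, ib], best_dcc, atol=1e-12)

    def test_diagonal_and_symmetry(self):
        traj, _ = generate_unimodal_system(4, 300, seed=8)
        modes, post = _fit_posteriors(traj, 2, 8)
        mat = residue_matrix(traj, modes, post)
        assert np.allclose(np.diag(mat.mdcc), 1.0)
        assert np.allclose(mat.mdcc, mat.mdcc.T, equal_nan=True)
        assert np.allclose(mat.dcc, mat.dcc.T, equal_nan=True)


class TestRangeAndTransient:
    @pytest.mark.parametrize("seed", range(5))
    def test_values_bounded_and_symmetric(self, seed):
        """All DCC/mDCC values lie in [-1, 1]; matrices symmetric to 1e-12."""
        traj, _ = generate_two_state_pair(600, rho=0.5, seed=seed, mean_dwell=20)
        modes, post = _fit_posteriors(traj, 3, seed)
        mat = residue_matrix(traj, modes, post)
        finite = mat.mdcc[np.isfinite(mat.mdcc)]
        assert np.all(finite >= -1.0 - 1e-12) and np.all(finite <= 1.0 + 1e-12)
        finite_dcc = mat.dcc[np.isfinite(mat.dcc)]
        assert np.all(finite_dcc >= -1.0 - 1e-12) and np.all(finite_dcc <= 1.0 + 1e-12)
        assert np.abs(np.nan_to_num(mat.mdcc - mat.mdcc.T)).max() < 1e-12
        for i in (0, 1):
            for c in atom_pair_mode_correlations(traj, modes[i], modes[1 - i], post[i], post[1 - i]):
                if c.defined:
                    assert -1.0 - 1e-12 <= c.mdcc_value <= 1.0 + 1e-12

    @pytest.mark.parametrize("seed", range(3))
    def test_anti_aligned_switch_hides_from_dcc_only(self, seed):
        """The planted two-state benchmark: conventional DCC is weak while the
        matched-mode mDCC recovers the within-mode correlation."""
        traj, _ = generate_two_state_pair(20_000, rho=0.9, seed=seed)
        modes, post = _fit_posteriors(traj, 3, seed)
        mat = residue_matrix(traj, modes, post)
        assert mat.dcc[0, 1] <= 0.3
        assert mat.mdcc[0, 1] >= 0.8
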