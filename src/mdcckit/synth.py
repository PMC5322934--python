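"""Seeded synthetic trajectories with planted modes, switching and couplings.

Real multi-microsecond trajectories behind a correlation analysis cannot be
regenerated at desk scale, so every analysis stage is exercised on synthetic
trajectories of labelled point atoms with known ground truth.  Three
generators are provided:

``generate_unimodal_system``
    Independent isotropic Gaussian jitter about fixed, well-separated
    centers — the null system (K = 1 everywhere, no correlations).

``generate_two_state_pair``
    Two atoms sharing one latent two-state process (a Markov chain with a
    configurable mean dwell time, emulating an interaction that is
    repeatedly formed and disrupted).  Each atom hops between two mode
    centers; within-mode jitter of the two atoms is correlated with
    coefficient rho along matched axes.  The *geometry* controls how the two
    inter-center vectors relate: ``anti-aligned`` makes the mode-switch
    contribution to the naive covariance cancel the jitter correlation, the
    scenario in which conventional DCC is blind while the mode-resolved
    correlation recovers rho.

``generate_allosteric_chain``
    Three molecules (A — bridge — B) whose residues form a linear coupling
    path: consecutive path members are in contact (< 5 A) and jitter-coupled
    with rho; everything else is distant and independent.  Optionally the
    central bridge link is a two-state (transient) pair.  The ground truth
    records the intended edge set, the intended transient edges and the
    intended top-betweenness (bridge) residue for end-to-end recovery tests.

All generators are bit-deterministic given their seed, emit coordinates
already superposed (no global rigid motion; a flag adds a rigid tumble to
exercise the superposition stage), and build a minimal synthetic topology so
the whole pipeline runs off standard files if desired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChainSpecError, ParameterError
from .trajio import Atom, Residue, Topology, Trajectory

__all__ = [
    "PlantedMode",
    "SyntheticGroundTruth",
    "generate_unimodal_system",
    "generate_two_state_pair",
    "generate_allosteric_chain",
]


@dataclass
class PlantedMode:
    weight: float
    center: np.ndarray  # (3,) A
    sigma: float  # isotropic within-mode jitter, A


@dataclass
class SyntheticGroundTruth:
    """Planted structure of a synthetic trajectory.

    ``modes[i]`` lists atom i's planted modes (weights sum to 1);
    ``switch_schedule[group]`` is the per-frame latent state of a switching
    atom group; ``couplings`` holds (atom_i, atom_j, rho) jitter couplings.
    The ``intended_*`` fields are only set by the allosteric-chain generator.
    """

    seed: int
    modes: dict[int, list[PlantedMode]]
    couplings: list[tuple[int, int, float]] = field(default_factory=list)
    switch_schedule: dict[str, np.ndarray] = field(default_factory=dict)
    atom_group: dict[int, str] = field(default_factory=dict)
    intended_edges: frozenset[frozenset[str]] | None = None
    intended_transient_edges: frozenset[frozenset[str]] | None = None
    intended_top_residue: str | None = None


def _make_topology(
    residue_specs: list[tuple[str, int, str]],
    molecules: dict[str, str] | None = None,
) -> Topology:
    """One-CA-atom residues from (chain_id, resseq, resname) specs."""
    atoms, residues = [], []
    for idx, (chain, resseq, resname) in enumerate(residue_specs):
        residues.append(Residue(chain, resseq, "", resname))
        atoms.append(Atom(serial=idx + 1, name="CA", element="C", chain_id=chain, residue_index=idx))
    return Topology(atoms, residues, dict(molecules or {}))


def _markov_states(
    rng: np.random.Generator,
    n_frames: int,
    occupancy: float,
    mean_dwell: float | None,
) -> np.ndarray:
    """Two-state latent schedule with stationary P(state=1) = occupancy.

    ``mean_dwell`` (frames) sets the temporal persistence; ``None`` draws
    frames i.i.d. from the stationary distribution.
    """
    if not 0 < occupancy < 1:
        raise ParameterError(f"occupancy must be in (0, 1); got {occupancy}")
    if mean_dwell is None:
        return (rng.random(n_frames) < occupancy).astype(int)
    if mean_dwell <= 0:
        raise ParameterError("mean_dwell must be positive")
    dwell1 = 2.0 * mean_dwell * occupancy
    dwell0 = 2.0 * mean_dwell * (1.0 - occupancy)
    p01 = min(1.0, 1.0 / dwell0)  # leave state 0
    p10 = min(1.0, 1.0 / dwell1)
    states = np.empty(n_frames, dtype=int)
    states[0] = int(rng.random() < occupancy)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        if states[t - 1] == 0:
            states[t] = int(u[t - 1] < p01)
        else:
            states[t] = int(u[t - 1] >= p10)
    return states


def generate_unimodal_system(
    n_atoms: int,
    n_frames: int,
    sigma: float = 1.0,
    seed: int = 0,
    spacing: float = 10.0,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Independent isotropic Gaussian jitter about fixed centers (K = 1)."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive; got {sigma}")
    if n_frames < 2:
        raise ParameterError("need n_frames >= 2")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_atoms, 3))
    centers[:, 0] = spacing * np.arange(n_atoms)
    coords = centers[None, :, :] + rng.normal(0.0, sigma, size=(n_frames, n_atoms, 3))
    topology = _make_topology([("A", i + 1, "ALA") for i in range(n_atoms)])
    truth = SyntheticGroundTruth(
        seed=seed,
        modes={i: [PlantedMode(1.0, centers[i].copy(), sigma)] for i in range(n_atoms)},
    )
    return Trajectory(coords, topology), truth


_GEOMETRIES = ("aligned", "anti-aligned", "orthogonal")


def generate_two_state_pair(
    n_frames: int,
    occupancy: float = 0.5,
    rho: float = 0.9,
    jitter_sigma: float = 0.3,
    separation: float = 6.0,
    geometry: str = "anti-aligned",
    contact_distance: float = 3.5,
    centers_i: np.ndarray | None = None,
    centers_j: np.ndarray | None = None,
    mean_dwell: float | None = 100.0,
    seed: int = 0,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Two atoms with a shared two-state switch and rho-correlated jitter.

    ``separation`` is the center-to-center mode distance in units of
    ``jitter_sigma``.  When explicit mode centers are given (two 3-vectors
    per atom) they override the constructed geometry.  Atom i occupies its
    state-s center plus jitter; atom j's jitter is ``rho`` times atom i's
    plus independent noise, so matched-mode correlation is rho by
    construction.
    """
    if not -1.0 <= rho <= 1.0:
        raise ParameterError(f"rho must be in [-1, 1]; got {rho}")
    if jitter_sigma <= 0:
        raise ParameterError("jitter_sigma must be positive")
    if geometry not in _GEOMETRIES:
        raise ParameterError(f"geometry must be one of {_GEOMETRIES}")

    half = 0.5 * separation * jitter_sigma
    u = np.array([0.0, 0.0, 1.0])
    v = {"aligned": u, "anti-aligned": -u, "orthogonal": np.array([0.0, 1.0, 0.0])}[geometry]
    if centers_i is None:
        centers_i = np.array([-half * u, half * u])
    if centers_j is None:
        offset = np.array([contact_distance, 0.0, 0.0])
        centers_j = np.array([offset - half * v, offset + half * v])
    centers_i = np.asarray(centers_i, dtype=float)
    centers_j = np.asarray(centers_j, dtype=float)
    for c in (centers_i, centers_j):
        if c.shape != (2, 3):
            raise ParameterError("each atom needs exactly two 3-vector centers")
        if np.allclose(c[0], c[1]):
            raise ParameterError("mode centers must be distinct")

    rng = np.random.default_rng(seed)
    states = _markov_states(rng, n_frames, occupancy, mean_dwell)
    e_i = rng.normal(0.0, jitter_sigma, size=(n_frames, 3))
    e_j = rho * e_i + np.sqrt(1.0 - rho**2) * rng.normal(
        0.0, jitter_sigma, size=(n_frames, 3)
    )
    coords = np.empty((n_frames, 2, 3))
    coords[:, 0, :] = centers_i[states] + e_i
    coords[:, 1, :] = centers_j[states] + e_j

    topology = _make_topology(
        [("A", 1, "ALA"), ("B", 1, "ALA")], molecules={"A": "A", "B": "B"}
    )
    truth = SyntheticGroundTruth(
        seed=seed,
        modes={
            0: [
                PlantedMode(1.0 - occupancy, centers_i[0].copy(), jitter_sigma),
                PlantedMode(occupancy, centers_i[1].copy(), jitter_sigma),
            ],
            1: [
                PlantedMode(1.0 - occupancy, centers_j[0].copy(), jitter_sigma),
                PlantedMode(occupancy, centers_j[1].copy(), jitter_sigma),
            ],
        },
        couplings=[(0, 1, rho)],
        switch_schedule={"pair": states},
        atom_group={0: "pair", 1: "pair"},
    )
    return Trajectory(coords, topology), truth


def _apply_tumble(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rigid rotation + translation per frame (exercises superposition)."""
    from scipy.spatial.transform import Rotation

    n_frames = coords.shape[0]
    rots = Rotation.random(n_frames, random_state=np.random.RandomState(rng.integers(2**31)))
    shifts = rng.normal(0.0, 5.0, size=(n_frames, 1, 3))
    center = coords.mean(axis=(0, 1), keepdims=True)
    out = np.einsum("fij,fnj->fni", rots.as_matrix(), coords - center) + center + shifts
    return out


def generate_allosteric_chain(
    n_frames: int = 6000,
    chain_spec: dict[str, int] | None = None,
    n_offpath: int = 2,
    rho: float = 0.9,
    jitter_sigma: float = 0.3,
    spacing: float = 4.0,
    transient_link: bool = True,
    separation: float = 6.0,
    occupancy: float = 0.5,
    mean_dwell: float | None = 100.0,
    broken_links: list[int] | None = None,
    distance_threshold: float = 5.0,
    global_tumble: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Three molecules coupled A -> bridge -> B along a linear contact path.

    ``chain_spec`` maps molecule names ("A", "bridge", "B") to path residue
    counts; the path runs through all of them in order, laid on a line with
    consecutive spacing ``spacing`` A.  Consecutive path members share
    rho-correlated jitter; non-consecutive members are >= 2 x spacing apart,
    so only consecutive members are both coupled and in contact.  Each
    molecule additionally gets ``n_offpath`` distant, independent residues.

    With ``transient_link`` the middle path link becomes a shared two-state
    pair in anti-aligned geometry: its conventional DCC is suppressed while
    matched-mode correlation stays ~rho, so that link (and its two flanking
    links) are planted *transient* edges.

    ``broken_links`` lists 0-based path link positions whose coupling is
    removed (rho = 0), splitting the intended network into components.

    Raises :class:`ChainSpecError` when an intended edge is geometrically
    impossible (coupled pair whose planted mode centers are not within
    ``distance_threshold``).
    """
    chain_spec = dict(chain_spec or {"A": 3, "bridge": 5, "B": 3})
    for mol in ("A", "bridge", "B"):
        if chain_spec.get(mol, 0) < 1:
            raise ChainSpecError(f"chain_spec needs >= 1 residue for {mol!r}")
    broken = set(broken_links or [])
    rng = np.random.default_rng(seed)

    chain_ids = {"A": "A", "bridge": "X", "B": "B"}
    residue_specs: list[tuple[str, int, str]] = []
    path_atoms: list[int] = []
    offpath_atoms: list[int] = []
    for mol in ("A", "bridge", "B"):
        cid = chain_ids[mol]
        start = len(residue_specs)
        for r in range(chain_spec[mol]):
            residue_specs.append((cid, r + 1, "ALA"))
            path_atoms.append(start + r)
        for r in range(n_offpath):
            residue_specs.append((cid, 100 + r + 1, "GLY"))
            offpath_atoms.append(len(residue_specs) - 1)
    n_atoms = len(residue_specs)
    n_path = len(path_atoms)
    n_links = n_path - 1
    if any(b < 0 or b >= n_links for b in broken):
        raise ChainSpecError(f"broken_links must lie in [0, {n_links})")

    topology = _make_topology(
        residue_specs,
        molecules={"A": "A", "X": "bridge", "B": "B"},
    )

    # geometry: path on the x-axis, off-path residues far away on a y-shifted line
    centers = np.zeros((n_atoms, 3))
    for p, i in enumerate(path_atoms):
        centers[i] = [spacing * p, 0.0, 0.0]
    for q, i in enumerate(offpath_atoms):
        centers[i] = [12.0 * q, 40.0, 0.0]

    # transient link: middle path link becomes a shared two-state pair
    ts_pair: tuple[int, int] | None = None
    states = None
    half = 0.5 * separation * jitter_sigma
    u = np.array([0.0, 0.0, 1.0])
    if transient_link:
        mid = n_links // 2
        if mid in broken:
            ts_pair = None
        else:
            ts_pair = (path_atoms[mid], path_atoms[mid + 1])
            states = _markov_states(rng, n_frames, occupancy, mean_dwell)

    # jitter propagated along the path with per-link correlation rho
    link_rho = [0.0 if p in broken else rho for p in range(n_links)]
    jitter = np.empty((n_frames, n_atoms, 3))
    jitter[:, path_atoms[0], :] = rng.normal(0.0, jitter_sigma, size=(n_frames, 3))
    for p in range(1, n_path):
        prev = jitter[:, path_atoms[p - 1], :]
        r = link_rho[p - 1]
        jitter[:, path_atoms[p], :] = r * prev + np.sqrt(1.0 - r**2) * rng.normal(
            0.0, jitter_sigma, size=(n_frames, 3)
        )
    for i in offpath_atoms:
        jitter[:, i, :] = rng.normal(0.0, jitter_sigma, size=(n_frames, 3))

    coords = centers[None, :, :] + jitter
    truth_modes: dict[int, list[PlantedMode]] = {
        i: [PlantedMode(1.0, centers[i].copy(), jitter_sigma)] for i in range(n_atoms)
    }
    schedule: dict[str, np.ndarray] = {}
    atom_group: dict[int, str] = {}
    if ts_pair is not None:
        i, j = ts_pair
        disp = np.where(states[:, None] == 1, half, -half) * u  # (T, 3)
        coords[:, i, :] += disp
        coords[:, j, :] -= disp  # anti-aligned
        truth_modes[i] = [
            PlantedMode(1.0 - occupancy, centers[i] - half * u, jitter_sigma),
            PlantedMode(occupancy, centers[i] + half * u, jitter_sigma),
        ]
        truth_modes[j] = [
            PlantedMode(1.0 - occupancy, centers[j] + half * u, jitter_sigma),
            PlantedMode(occupancy, centers[j] - half * u, jitter_sigma),
        ]
        schedule["transient"] = states
        atom_group[i] = atom_group[j] = "transient"

    # intended network: consecutive unbroken path links
    labels = [topology.residue_label(r) for r in range(n_atoms)]
    intended: set[frozenset[str]] = set()
    transient_edges: set[frozenset[str]] = set()
    couplings: list[tuple[int, int, float]] = []
    for p in range(n_links):
        i, j = path_atoms[p], path_atoms[p + 1]
        if p in broken:
            continue
        couplings.append((i, j, rho))
        # verify the intended contact is geometrically realizable
        min_dist = min(
            float(np.linalg.norm(mi.center - mj.center))
            for mi in truth_modes[i]
            for mj in truth_modes[j]
        )
        if min_dist >= distance_threshold:
            raise ChainSpecError(
                f"coupled path link {p} has no mode-center contact "
                f"({min_dist:.2f} A >= {distance_threshold} A)"
            )
        edge = frozenset((labels[i], labels[j]))
        intended.add(edge)
        if ts_pair is not None and (i in ts_pair or j in ts_pair):
            transient_edges.add(edge)

    # intended top-betweenness node: middle of the path (intact chains only)
    top_label = labels[path_atoms[n_path // 2]] if not broken else None
    truth = SyntheticGroundTruth(
        seed=seed,
        modes=truth_modes,
        couplings=couplings,
        switch_schedule=schedule,
        atom_group=atom_group,
        intended_edges=frozenset(intended),
        intended_transient_edges=frozenset(transient_edges),
        intended_top_residue=top_label,
    )
    if global_tumble:
        coords = _apply_tumble(coords, rng)
    return Trajectory(coords, topology), truth
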