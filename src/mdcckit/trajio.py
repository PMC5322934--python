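"""Trajectory and topology I/O, atom selection, and rigid-body superposition.

The in-memory model is deliberately small: a :class:`Topology` is an ordered
list of atoms grouped into residues and chains, with chains partitioned into
named molecules; a :class:`Trajectory` binds an ``(n_frames, n_atoms, 3)``
coordinate array in Angstrom to a topology.  PDB files are read through
Bio.PDB (strict mode, so malformed records are rejected with the offending
line), binary DCD/XTC trajectories through mdtraj.  Internal frame and atom
indexing is 0-based; PDB serials and residue numbers are preserved exactly as
they appear in the file so that published residue references (e.g. Ets1
Ser332) survive round trips.

Coordinates are assumed pre-imaged (no periodic-boundary handling); a warning
is emitted when a frame's bounding box exceeds a sanity threshold.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AtomLookupError,
    DegenerateFitError,
    FormatError,
    SelectionError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "superpose",
    "kabsch_rotation",
    "select_atoms",
]

_HYDROGEN = {"H", "D"}
_PROTEIN_BACKBONE = {"N", "CA", "C", "O"}
_NUCLEIC_BACKBONE = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}
_BACKBONE_NAMES = _PROTEIN_BACKBONE | _NUCLEIC_BACKBONE


@dataclass(frozen=True)
class Atom:
    """One atom of a topology.  ``residue_index`` points into ``Topology.residues``."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_index: int


@dataclass(frozen=True)
class Residue:
    """Residue identity as written in the source file (resseq + insertion code)."""

    chain_id: str
    resseq: int
    icode: str
    name: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)


@dataclass
class Topology:
    """Ordered atoms grouped into residues; chains partitioned into molecules.

    ``molecules`` maps a chain id to a molecule name; by default every chain
    is its own molecule.
    """

    atoms: list[Atom]
    residues: list[Residue]
    molecules: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        for atom in self.atoms:
            if not 0 <= atom.residue_index < len(self.residues):
                raise ValidationError(
                    f"atom serial {atom.serial} points to missing residue "
                    f"{atom.residue_index}"
                )
            res = self.residues[atom.residue_index]
            ident = (res.chain_id, res.resseq, res.icode, atom.name)
            if ident in seen:
                raise ValidationError(
                    "duplicate atom identity (chain, resSeq, icode, name) = "
                    f"{ident!r}"
                )
            seen.add(ident)
        for res in self.residues:
            self.molecules.setdefault(res.chain_id, res.chain_id)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def molecule_of(self, residue_index: int) -> str:
        return self.molecules[self.residues[residue_index].chain_id]

    def residue_label(self, residue_index: int) -> str:
        res = self.residues[residue_index]
        return f"{res.chain_id}:{res.resseq}{res.icode.strip()}:{res.name}"

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.element.upper() not in _HYDROGEN for a in self.atoms])

    def atom_index(self, chain_id: str, resseq: int, name: str, icode: str = "") -> int:
        for i, atom in enumerate(self.atoms):
            res = self.residues[atom.residue_index]
            if (
                res.chain_id == chain_id
                and res.resseq == resseq
                and res.icode.strip() == icode.strip()
                and atom.name == name
            ):
                return i
        raise AtomLookupError(f"no atom {chain_id}:{resseq}{icode}:{name}")

    def select(self, expr: str) -> np.ndarray:
        return select_atoms(self, expr)


@dataclass
class Trajectory:
    """Time-ordered per-atom coordinates (Angstrom) bound to a :class:`Topology`."""

    coords: np.ndarray
    topology: Topology
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError(
                f"coords must be (n_frames, n_atoms, 3); got {self.coords.shape}"
            )
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"coords hold {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(coords, self.topology, self.frame_times)


# ---------------------------------------------------------------------------
# selection mini-language


def _parse_int_list(spec: str) -> set[int]:
    out: set[int] = set()
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:  # allow negative resseq as lone value
            cut = part.index("-", 1)
            lo, hi = int(part[:cut]), int(part[cut + 1 :])
            out.update(range(lo, hi + 1))
        else:
            out.add(int(part))
    return out


def select_atoms(topology: Topology, expr: str) -> np.ndarray:
    """Resolve a selection expression to sorted atom indices.

    Clauses joined by ``and`` are intersected.  Supported clauses:
    ``all``, ``heavy``, ``backbone``, ``name CA,P``, ``chain A,B``,
    ``resid 3-10,15``.
    """
    n = topology.n_atoms
    mask = np.ones(n, dtype=bool)
    for clause in expr.split(" and "):
        tokens = clause.split()
        if not tokens:
            raise SelectionError(f"empty clause in {expr!r}")
        kw = tokens[0].lower()
        if kw == "all" and len(tokens) == 1:
            continue
        elif kw == "heavy" and len(tokens) == 1:
            mask &= topology.heavy_mask()
        elif kw == "backbone" and len(tokens) == 1:
            mask &= np.array([a.name in _BACKBONE_NAMES for a in topology.atoms])
        elif kw == "name" and len(tokens) == 2:
            names = {t.strip() for t in tokens[1].split(",")}
            mask &= np.array([a.name in names for a in topology.atoms])
        elif kw == "chain" and len(tokens) == 2:
            chains = {t.strip() for t in tokens[1].split(",")}
            mask &= np.array([a.chain_id in chains for a in topology.atoms])
        elif kw == "resid" and len(tokens) == 2:
            ids = _parse_int_list(tokens[1])
            mask &= np.array(
                [topology.residues[a.residue_index].resseq in ids for a in topology.atoms]
            )
        else:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
    return np.nonzero(mask)[0]


def _resolve_selection(topology: Topology, selection) -> np.ndarray:
    if selection is None:
        return np.arange(topology.n_atoms)
    if isinstance(selection, str):
        return select_atoms(topology, selection)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        return np.nonzero(sel)[0]
    return sel.astype(int)


# ---------------------------------------------------------------------------
# PDB reading (Bio.PDB) and writing


def _element_of(name: str, element: str) -> str:
    element = (element or "").strip()
    if element:
        return element.upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _structure_from_pdb(path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        return parser.get_structure("system", str(path))
    except PDBConstructionException as exc:
        msg = str(exc)
        if "defined twice" in msg:
            raise ValidationError(f"duplicate atom identity: {msg}") from exc
        raise FormatError(f"cannot parse PDB {path}: {msg}") from exc
    except ValueError as exc:
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc


def _model_atoms(model):
    """Atoms of a Bio.PDB model in file order, skipping waters."""
    out = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if residue.resname in ("HOH", "WAT"):
                continue
            for atom in residue:
                out.append((chain.id, resseq, icode, residue.resname, atom))
    return out


def read_topology(path, format: str = "pdb", molecules: Mapping[str, str] | None = None) -> Topology:
    """Read a topology from a PDB file (first model).

    ``molecules`` optionally maps chain ids to molecule names; unlisted chains
    become their own molecule.
    """
    if format.lower() != "pdb":
        raise FormatError(f"unsupported topology format {format!r}")
    structure = _structure_from_pdb(path)
    models = list(structure)
    if not models:
        raise FormatError(f"no models in {path}")
    atoms: list[Atom] = []
    residues: list[Residue] = []
    res_lookup: dict[tuple[str, int, str], int] = {}
    for chain_id, resseq, icode, resname, bio_atom in _model_atoms(models[0]):
        key = (chain_id, resseq, icode)
        if key not in res_lookup:
            res_lookup[key] = len(residues)
            residues.append(Residue(chain_id, resseq, icode, resname))
        atoms.append(
            Atom(
                serial=int(bio_atom.serial_number),
                name=bio_atom.get_name(),
                element=_element_of(bio_atom.get_name(), bio_atom.element),
                chain_id=chain_id,
                residue_index=res_lookup[key],
            )
        )
    return Topology(atoms, residues, dict(molecules or {}))


def _check_box(coords: np.ndarray, threshold: float) -> None:
    span = coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))
    if np.any(span > threshold):
        warnings.warn(
            f"bounding box {span} A exceeds {threshold} A; trajectory may not be "
            "pre-imaged",
            stacklevel=3,
        )


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"pdb": "pdb", "ent": "pdb", "dcd": "dcd", "xtc": "xtc"}.get(suffix, suffix)


def _to_mdtraj_topology(topology: Topology):
    import mdtraj as md
    from mdtraj.core import element as md_element

    top = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[int, object] = {}
    for i, atom in enumerate(topology.atoms):
        res = topology.residues[atom.residue_index]
        if res.chain_id not in chains:
            chains[res.chain_id] = top.add_chain()
        if atom.residue_index not in residues:
            residues[atom.residue_index] = top.add_residue(
                res.name, chains[res.chain_id], resSeq=res.resseq
            )
        try:
            elem = md_element.get_by_symbol(atom.element.capitalize())
        except KeyError:
            elem = md_element.virtual
        top.add_atom(atom.name, elem, residues[atom.residue_index])
    return top


def read_trajectory(
    path,
    topology: Topology,
    format: str | None = None,
    box_warn_threshold: float = 500.0,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) onto ``topology``.

    Coordinates are normalized to Angstrom.  Every frame must carry exactly
    ``topology.n_atoms`` atoms, in topology order.
    """
    fmt = (format or _infer_format(path)).lower()
    if fmt == "pdb":
        structure = _structure_from_pdb(path)
        frames = []
        for i, model in enumerate(structure, start=1):
            atoms = _model_atoms(model)
            if len(atoms) != topology.n_atoms:
                raise ShapeError(
                    f"frame {i} has {len(atoms)} atoms, topology has "
                    f"{topology.n_atoms}",
                    frame=i,
                )
            frames.append(np.array([a[4].get_coord() for a in atoms], dtype=float))
        coords = np.stack(frames)
        times = None
    elif fmt in ("dcd", "xtc"):
        import mdtraj as md

        mdtop = _to_mdtraj_topology(topology)
        try:
            mdt = md.load(str(path), top=mdtop)
        except Exception as exc:  # mdtraj raises format-specific errors
            raise FormatError(f"cannot read {fmt} file {path}: {exc}") from exc
        if mdt.n_atoms != topology.n_atoms:
            raise ShapeError(
                f"{fmt} file holds {mdt.n_atoms} atoms, topology has "
                f"{topology.n_atoms}",
                frame=1,
            )
        coords = np.asarray(mdt.xyz, dtype=float) * 10.0  # nm -> A
        times = np.asarray(mdt.time, dtype=float)
    else:
        raise FormatError(f"unsupported trajectory format {fmt!r}")
    traj = Trajectory(coords, topology, times)
    _check_box(traj.coords, box_warn_threshold)
    return traj


def _pdb_atom_name(name: str, element: str) -> str:
    # Names shorter than 4 chars start in column 14 when the element symbol is
    # one character; 4-char names fill columns 13-16.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB (or DCD/XTC via mdtraj)."""
    fmt = (format or _infer_format(path)).lower()
    top = traj.topology
    if fmt == "pdb":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                for i, atom in enumerate(top.atoms):
                    res = top.residues[atom.residue_index]
                    x, y, z = traj.coords[f, i]
                    fh.write(
                        "ATOM  {serial:5d} {name:4s} {res:<3s} {chain:1s}"
                        "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                        "{occ:6.2f}{b:6.2f}          {elem:>2s}\n".format(
                            serial=atom.serial,
                            name=_pdb_atom_name(atom.name, atom.element),
                            res=res.name[:3],
                            chain=atom.chain_id[:1] or "A",
                            resseq=res.resseq,
                            icode=(res.icode.strip() or " ")[:1],
                            x=x,
                            y=y,
                            z=z,
                            occ=1.0,
                            b=0.0,
                            elem=atom.element[:2],
                        )
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif fmt in ("dcd", "xtc"):
        import mdtraj as md

        mdt = md.Trajectory(
            xyz=traj.coords / 10.0, topology=_to_mdtraj_topology(traj.topology)
        )
        mdt.save(str(path))
    else:
        raise FormatError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# rigid-body superposition


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R (row convention, ``P @ R ~ Q``) for centered P, Q.

    The SVD solution with determinant correction: reflections are never
    returned, so chirality is preserved even for mirrored inputs.
    """
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def superpose(traj: Trajectory, reference: np.ndarray, selection=None) -> Trajectory:
    """Rigidly superpose every frame onto ``reference`` (n_atoms, 3).

    The rotation + translation is fitted by least squares on ``selection``
    (default: all atoms) and applied to all atoms.  Raises
    :class:`DegenerateFitError` for fewer than 3 or collinear selected atoms.
    """
    sel = _resolve_selection(traj.topology, selection)
    if sel.size < 3:
        raise DegenerateFitError(f"superposition needs >=3 atoms, got {sel.size}")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ShapeError(
            f"reference must be (n_atoms, 3) = ({traj.n_atoms}, 3); got "
            f"{reference.shape}"
        )
    ref_sel = reference[sel]
    ref_cm = ref_sel.mean(axis=0)
    ref_centered = ref_sel - ref_cm
    svals = np.linalg.svd(ref_centered, compute_uv=False)
    if svals[1] <= 1e-8 * max(svals[0], 1.0):
        raise DegenerateFitError("selected reference atoms are collinear")

    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        cm = frame[sel].mean(axis=0)
        R = kabsch_rotation(frame[sel] - cm, ref_centered)
        out[f] = (frame - cm) @ R + ref_cm
    return traj.with_coords(out)
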