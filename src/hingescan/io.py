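"""Structures, trajectories, subdomain maps and atom selections.

The trajectory dialect is multi-model PDB (``MODEL``/``ENDMDL`` blocks whose
atom count and order match a topology structure). Reading is strict: records
that cannot be parsed raise with their line number, insertion codes are
rejected, and alternate locations other than blank or "A" are dropped with a
warning. Residue numbering is taken verbatim from the records — a residue the
user calls 228 is whatever the input numbers 228.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Default subdomain decomposition of the DnaK nucleotide-binding domain.
# Residues 227-229 (the II-A/II-B tether coil) are deliberately unassigned.
DNAK_DEFAULT_SUBDOMAINS: dict[str, tuple[tuple[int, int], ...]] = {
    "I-A": ((1, 36), (111, 180)),
    "I-B": ((37, 110),),
    "II-A": ((181, 226), (311, 383)),
    "II-B": ((230, 310),),
}


@dataclass
class Structure:
    """A static molecular structure (one model)."""

    atom_names: list[str]
    elements: list[str]
    res_numbers: np.ndarray  # (A,) int, 1-based, verbatim from input
    res_names: list[str]
    chain_ids: list[str]
    coords: np.ndarray  # (A, 3) float, Angstrom
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.n_atoms < 1:
            raise ValueError("structure must contain at least one atom")
        if self.coords.shape != (self.n_atoms, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("structure coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def copy(self) -> "Structure":
        return Structure(
            list(self.atom_names),
            list(self.elements),
            self.res_numbers.copy(),
            list(self.res_names),
            list(self.chain_ids),
            self.coords.copy(),
            dict(self.metadata),
        )


@dataclass
class Trajectory:
    """Frames over a fixed topology. ``frame_interval_ps`` is metadata only."""

    topology: Structure
    frames: np.ndarray  # (F, A, 3) Angstrom
    frame_interval_ps: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (F, A, 3) array with F >= 1")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


class SubdomainMap:
    """Named groups of inclusive 1-based residue ranges.

    Ranges must be valid and a residue may belong to at most one group; gap
    residues (e.g. 227-229 in the DnaK default) stay unassigned.
    """

    def __init__(self, groups: Mapping[str, Iterable[tuple[int, int]]]) -> None:
        self.groups: dict[str, tuple[tuple[int, int], ...]] = {}
        seen: dict[int, str] = {}
        for name, ranges in groups.items():
            ranges = tuple((int(a), int(b)) for a, b in ranges)
            if not ranges:
                raise ValueError(f"group {name!r} has no ranges")
            for lo, hi in ranges:
                if lo > hi or lo < 1:
                    raise ValueError(f"invalid range {lo}-{hi} in group {name!r}")
                for r in range(lo, hi + 1):
                    if r in seen:
                        raise ValueError(
                            f"residue {r} assigned to both {seen[r]!r} and {name!r}"
                        )
                    seen[r] = name
            self.groups[name] = ranges

    def residues(self, *names: str) -> list[int]:
        """Sorted residue numbers of the union of the named groups."""
        out: set[int] = set()
        for name in names:
            if name not in self.groups:
                raise KeyError(f"unknown subdomain group {name!r}")
            for lo, hi in self.groups[name]:
                out.update(range(lo, hi + 1))
        return sorted(out)

    def group_of(self, residue: int) -> str | None:
        for name, ranges in self.groups.items():
            if any(lo <= residue <= hi for lo, hi in ranges):
                return name
        return None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SubdomainMap) and self.groups == other.groups


@dataclass
class LigandSpec:
    """A cofactor entity identified by residue name and optional atom names."""

    name: str
    res_name: str
    atom_names: tuple[str, ...] | None = None

    def resolve(self, structure: Structure) -> np.ndarray:
        idx = [
            i
            for i in range(structure.n_atoms)
            if structure.res_names[i] == self.res_name
            and (self.atom_names is None or structure.atom_names[i] in self.atom_names)
        ]
        if not idx:
            raise ValueError(
                f"ligand spec {self.name!r} selects no atoms "
                f"(res_name={self.res_name!r})"
            )
        return np.asarray(idx, dtype=int)


def make_subdomain_map(spec: str | Mapping[str, Iterable[tuple[int, int]]]) -> SubdomainMap:
    """Build a SubdomainMap from an explicit group dict or a named default.

    ``"dnak_default"`` gives the DnaK NBD decomposition: I-A (1-36, 111-180),
    I-B (37-110), II-A (181-226, 311-383), II-B (230-310).
    """
    if isinstance(spec, str):
        if spec != "dnak_default":
            raise ValueError(f"unknown subdomain map name {spec!r}")
        return SubdomainMap(DNAK_DEFAULT_SUBDOMAINS)
    return SubdomainMap(spec)


def select_atoms(
    structure: Structure,
    res_ranges: Sequence[tuple[int, int]] | None = None,
    atom_names: Sequence[str] | None = None,
    chain_id: str | None = None,
    residues: Iterable[int] | None = None,
) -> np.ndarray:
    """Indices (sorted ascending) of atoms matching every given predicate.

    An empty result is allowed but flagged with a warning.
    """
    if chain_id is not None and chain_id not in structure.chain_ids:
        raise ValueError(f"unknown chain id {chain_id!r}")
    mask = np.ones(structure.n_atoms, dtype=bool)
    if res_ranges is not None:
        m = np.zeros(structure.n_atoms, dtype=bool)
        for lo, hi in res_ranges:
            m |= (structure.res_numbers >= lo) & (structure.res_numbers <= hi)
        mask &= m
    if residues is not None:
        rs = set(int(r) for r in residues)
        mask &= np.fromiter(
            (int(r) in rs for r in structure.res_numbers), bool, structure.n_atoms
        )
    if atom_names is not None:
        names = set(atom_names)
        mask &= np.fromiter(
            (n in names for n in structure.atom_names), bool, structure.n_atoms
        )
    if chain_id is not None:
        mask &= np.fromiter(
            (c == chain_id for c in structure.chain_ids), bool, structure.n_atoms
        )
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn("atom selection is empty", stacklevel=2)
    return idx


def ca_indices(structure: Structure, res_ranges=None) -> np.ndarray:
    """Convenience: CA atom indices, optionally restricted to residue ranges."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return select_atoms(structure, res_ranges=res_ranges, atom_names=("CA",))


# ---------------------------------------------------------------------------
# PDB fixed-width reading / writing
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_num = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ValueError(f"unparsable ATOM/HETATM record at line {lineno}: {exc}") from exc
    if icode not in (" ", ""):
        raise ValueError(f"insertion code {icode!r} at line {lineno} is not supported")
    if not element:
        element = name[:1]
    return name, altloc, res_name, chain, res_num, (x, y, z), element


def _read_models(path: str | Path):
    """All models of a PDB file as lists of parsed atom tuples."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    models: list[list] = []
    current: list = []
    in_model = False
    dropped_altloc = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                in_model = False
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if parsed[1] not in (" ", "", "A"):
                    dropped_altloc += 1
                    continue
                current.append(parsed)
    if current:
        models.append(current)
    if dropped_altloc:
        warnings.warn(f"dropped {dropped_altloc} atoms with altLoc other than blank/'A'")
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return models


def _atoms_to_structure(atoms, metadata=None) -> Structure:
    return Structure(
        atom_names=[a[0] for a in atoms],
        elements=[a[6] for a in atoms],
        res_numbers=np.array([a[4] for a in atoms], dtype=int),
        res_names=[a[2] for a in atoms],
        chain_ids=[a[3] for a in atoms],
        coords=np.array([a[5] for a in atoms], dtype=float),
        metadata=metadata or {},
    )


def read_pdb(path: str | Path, chain_id: str | None = None) -> Structure:
    """Read the first model of a PDB file.

    If the file holds several models, only model 1 is returned and a warning
    is logged. ``chain_id`` restricts the result to one chain; by default all
    atoms of the first model are kept.
    """
    models = _read_models(path)
    if len(models) > 1:
        logger.warning("%s contains %d models; using model 1 only", path, len(models))
    atoms = models[0]
    if chain_id is not None:
        atoms = [a for a in atoms if a[3] == chain_id]
        if not atoms:
            raise ValueError(f"no atoms on chain {chain_id!r} in {path}")
    return _atoms_to_structure(atoms, metadata={"source": str(path)})


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: Structure | None = None,
    label: str = "",
    frame_interval_ps: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB trajectory (one file or a sequence of files).

    Every model must carry the same atoms in the same order as the topology
    (the first model, when no topology is supplied). A mismatch raises an
    error naming the offending model.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_models: list[list] = []
    for p in paths:
        all_models.extend(_read_models(p))
    if topology is None:
        topology = _atoms_to_structure(all_models[0])
    ref_names = topology.atom_names
    ref_res = topology.res_numbers
    frames = np.empty((len(all_models), topology.n_atoms, 3), dtype=float)
    for k, atoms in enumerate(all_models, start=1):
        if len(atoms) != topology.n_atoms:
            raise ValueError(
                f"model {k} has {len(atoms)} atoms, topology has {topology.n_atoms}"
            )
        for i, a in enumerate(atoms):
            if a[0] != ref_names[i] or a[4] != ref_res[i]:
                raise ValueError(
                    f"model {k} atom {i + 1} ({a[0]} res {a[4]}) does not match "
                    f"topology ({ref_names[i]} res {ref_res[i]})"
                )
        frames[k - 1] = [a[5] for a in atoms]
    return Trajectory(topology, frames, frame_interval_ps=frame_interval_ps, label=label)


def _format_atom_line(serial, name, res_name, chain, res_num, xyz, element) -> str:
    # standard fixed-width layout; names shorter than 4 characters start in col 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:5d} {name_field} {res_name:<3s} {chain:1s}{res_num:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (fixed-width ATOM records)."""
    with open(path, "w") as fh:
        for line in _structure_lines(structure):
            fh.write(line + "\n")
        fh.write("END\n")


def _structure_lines(structure: Structure, coords: np.ndarray | None = None):
    coords = structure.coords if coords is None else coords
    for i in range(structure.n_atoms):
        yield _format_atom_line(
            (i % 99999) + 1,
            structure.atom_names[i],
            structure.res_names[i],
            structure.chain_ids[i],
            int(structure.res_numbers[i]),
            coords[i],
            structure.elements[i],
        )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for line in _structure_lines(traj.topology, traj.frames[f]):
                fh.write(line + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
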