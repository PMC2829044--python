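"""Structures, trajectories and domain partitions.

Protein structures are read from PDB files with chymotrypsin-convention
residue identifiers: serine-protease numbering is homology-based, so a
residue label is a *(number, insertion code)* pair such as ``120A``, and
insertion-code order (blank before ``A`` before ``B`` ...) defines sequence
order.  Trajectories are ordered coordinate sets sharing one topology, with
frames at strictly regular times in picoseconds.  A domain partition names
residue subsets (N-terminal domain, domain bridge, C-terminal domain, plus
optional extras) used by the contact and interface analyses.

Heavy atoms only: hydrogens, waters and other non-protein records are
dropped on load so that contact and surface definitions are identical for
crystal structures and simulation snapshots.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DomainConfigError,
    EmptyStructureError,
    FormatError,
    ParameterError,
    TopologyError,
)

__all__ = [
    "ResidueID",
    "Atom",
    "Structure",
    "Trajectory",
    "DomainPartition",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "parse_domain_config",
    "VDW_RADII",
]

#: Van-der-Waals radii (Angstrom) for the heavy elements of proteins.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Default polarity classes: N/O polar, C/S non-polar.
POLARITY: dict[str, str] = {"C": "nonpolar", "S": "nonpolar", "N": "polar", "O": "polar"}


@total_ordering
@dataclass(frozen=True)
class ResidueID:
    """Chymotrypsin-convention residue identifier.

    Ordering is ``(chain, number, icode)`` with a blank insertion code
    sorting before ``'A'``; equality requires all three fields to match.
    """

    chain: str
    number: int
    icode: str = ""

    def _key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    def __lt__(self, other: "ResidueID") -> bool:
        return self._key() < other._key()

    @property
    def label(self) -> str:
        """Author-style label, e.g. ``'120A'``."""
        return f"{self.number}{self.icode}"

    def __repr__(self) -> str:  # compact: used in error messages
        return f"{self.chain}:{self.label}"


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its residue identity and radius/polarity class."""

    name: str
    element: str
    residue: ResidueID
    res_name: str = "GLY"
    polarity: str = "nonpolar"
    radius: float = 1.70

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("Atom.element must be non-empty")
        if self.radius <= 0:
            raise ValueError("Atom.radius must be positive")


class Structure:
    """An ordered atom list plus one coordinate set (Angstrom).

    Parameters
    ----------
    atoms
        Ordered atoms; no two atoms may share ``(name, residue)``.
    coords
        ``(n_atoms, 3)`` array of coordinates in Angstrom.
    """

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        seen = set()
        for a in atoms:
            key = (a.name, a.residue)
            if key in seen:
                raise ValueError(f"duplicate atom {a.name} in residue {a.residue}")
            seen.add(key)
        self.atoms: list[Atom] = list(atoms)
        self.coords: np.ndarray = coords

        residues: list[ResidueID] = []
        res_index = np.empty(len(self.atoms), dtype=int)
        last = None
        for i, a in enumerate(self.atoms):
            if a.residue != last:
                residues.append(a.residue)
                last = a.residue
            res_index[i] = len(residues) - 1
        #: Unique residues in file order.
        self.residues: list[ResidueID] = residues
        #: Per-atom index into :attr:`residues` (sequence-ordinal position).
        self.residue_index: np.ndarray = res_index

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def nonpolar_mask(self) -> np.ndarray:
        return np.array([a.polarity == "nonpolar" for a in self.atoms])

    @property
    def ca_indices(self) -> np.ndarray:
        """Indices of atoms named ``CA`` (one per residue in protein input)."""
        return np.array([i for i, a in enumerate(self.atoms) if a.name == "CA"], dtype=int)

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.ca_indices]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology with a different coordinate set."""
        return Structure(self.atoms, coords)

    def residue_atom_indices(self, residue: ResidueID) -> np.ndarray:
        try:
            ordinal = self.residues.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue} not in structure") from None
        return np.nonzero(self.residue_index == ordinal)[0]


class Trajectory:
    """Ordered frames with times (ps) sharing one topology.

    Frame times must be strictly increasing with a constant spacing equal to
    :attr:`save_interval`.  The convention throughout the package is that a
    simulation of total length ``T`` saved every ``s`` ps yields frames at
    ``t = s, 2s, ..., T`` — the equilibrated ``t = 0`` snapshot is excluded,
    so an 8.1 ns run saved every 10 ps has exactly 810 frames.
    """

    def __init__(self, topology: Structure, coords: np.ndarray, times: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(topology), 3):
            raise TopologyError(
                f"frame shape {coords.shape[1:]} does not match topology "
                f"({len(topology)} atoms)"
            )
        if coords.shape[0] != times.shape[0]:
            raise TopologyError("times length does not match frame count")
        if len(times) >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise TopologyError("frame times must increase by a constant interval")
            self.save_interval = float(dt[0])
        else:
            self.save_interval = float(times[0]) if len(times) else 0.0
        self.topology = topology
        self.coords = coords
        self.times = times

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def duration(self) -> float:
        """Total simulated time in ps (time of the last frame)."""
        return float(self.times[-1]) if len(self) else 0.0

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def ca_coords(self) -> np.ndarray:
        """``(n_frames, n_ca, 3)`` Cα coordinates."""
        return self.coords[:, self.topology.ca_indices, :]

    def strided(self, stride: float) -> "Trajectory":
        """Subsample to frames at ``t = stride, 2*stride, ...``."""
        if stride <= 0:
            raise ParameterError("stride must be positive")
        ratio = stride / self.save_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                f"stride {stride} ps is not a multiple of the save interval "
                f"{self.save_interval} ps"
            )
        step = int(round(ratio))
        idx = np.arange(step - 1, len(self), step)
        return Trajectory(self.topology, self.coords[idx], self.times[idx])


class DomainPartition:
    """Named residue sets partitioning the analysed chain.

    The three primary sets are ``n_domain``, ``bridge`` and ``c_domain``
    (``bridge`` may be empty — trypsin has no domain bridge).  Extra named
    sets (e.g. a C-terminal hairpin) may be carried alongside but do not
    enter intra/inter-domain classification.
    """

    PRIMARY = ("n_domain", "bridge", "c_domain")

    def __init__(self, sets: Mapping[str, Iterable[ResidueID]]):
        self.sets: dict[str, frozenset[ResidueID]] = {
            name: frozenset(v) for name, v in sets.items()
        }
        for name in ("n_domain", "c_domain"):
            if name not in self.sets:
                raise DomainConfigError(f"partition must define '{name}'")
        self.sets.setdefault("bridge", frozenset())
        self._validate_disjoint()
        self._domain_of: dict[ResidueID, str] = {}
        for name in self.PRIMARY:
            for r in self.sets[name]:
                self._domain_of[r] = name

    def _validate_disjoint(self) -> None:
        overlaps = []
        for i, a in enumerate(self.PRIMARY):
            for b in self.PRIMARY[i + 1 :]:
                common = self.sets[a] & self.sets[b]
                if common:
                    overlaps.append((a, b, sorted(common)))
        if overlaps:
            msg = "; ".join(
                f"{a}/{b}: {', '.join(map(repr, rs))}" for a, b, rs in overlaps
            )
            raise DomainConfigError(f"primary domain sets overlap — {msg}")

    def domain_of(self, residue: ResidueID) -> str:
        try:
            return self._domain_of[residue]
        except KeyError:
            raise DomainConfigError(
                f"residue {residue} is not assigned to any primary domain set"
            ) from None

    def covers(self, residues: Iterable[ResidueID]) -> bool:
        return all(r in self._domain_of for r in residues)

    @property
    def all_residues(self) -> frozenset[ResidueID]:
        return frozenset(self._domain_of)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

_WATER = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"}


def _to_biotite(structures: Sequence[Structure]):
    """Build a biotite AtomArray/AtomArrayStack from Structures (shared topology)."""
    import biotite.structure as struc

    base = structures[0]
    n = len(base)
    if len(structures) == 1:
        arr = struc.AtomArray(n)
    else:
        arr = struc.AtomArrayStack(len(structures), n)
    arr.chain_id = np.array([a.residue.chain for a in base.atoms])
    arr.res_id = np.array([a.residue.number for a in base.atoms])
    arr.ins_code = np.array([a.residue.icode for a in base.atoms])
    arr.res_name = np.array([a.res_name for a in base.atoms])
    arr.atom_name = np.array([a.name for a in base.atoms])
    arr.element = np.array([a.element for a in base.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    if len(structures) == 1:
        arr.coord = base.coords
    else:
        arr.coord = np.stack([s.coords for s in structures])
    return arr


def _atoms_from_biotite(arr) -> list[Atom]:
    atoms = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip().upper()
        if not elem:
            elem = re.sub(r"[^A-Z]", "", str(arr.atom_name[i]).upper())[:1]
        rid = ResidueID(
            chain=str(arr.chain_id[i]),
            number=int(arr.res_id[i]),
            icode=str(arr.ins_code[i]).strip(),
        )
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=elem,
                residue=rid,
                res_name=str(arr.res_name[i]),
                polarity=POLARITY.get(elem, "nonpolar"),
                radius=VDW_RADII.get(elem, 1.70),
            )
        )
    return atoms


def _read_pdb_models(path, model=None):
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        # altloc="all" adds the altloc_id annotation used for filtering
        stack = pdb.get_structure(model=model, altloc="all")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise FormatError(f"could not parse PDB file {path!r}: {exc}") from exc
    return stack


def _protein_heavy_mask(arr) -> np.ndarray:
    import biotite.structure as struc

    mask = struc.filter_amino_acids(arr)
    mask &= ~np.isin(arr.res_name, list(_WATER))
    mask &= ~np.isin(arr.element, ["H", "D", ""])
    altloc = arr.get_annotation("altloc_id") if "altloc_id" in arr.get_annotation_categories() else None
    if altloc is not None:
        mask &= np.isin(np.char.strip(altloc.astype(str)), ["", ".", "A"])
    return mask


def load_structure(path, chain: str | None = None) -> Structure:
    """Read one protein chain from a PDB file.

    Non-protein records and hydrogens are dropped; where alternate locations
    are present only the ``'A'`` (or blank) conformation is retained;
    insertion codes are preserved in the residue identifiers.

    Parameters
    ----------
    path
        PDB file path.
    chain
        Chain identifier to keep.  By default the first protein chain.

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    EmptyStructureError
        If no protein atoms remain after filtering.
    """
    arr = _read_pdb_models(path, model=1)
    mask = _protein_heavy_mask(arr)
    arr = arr[mask]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no protein heavy atoms in {path!r}")
    if chain is None:
        chain = str(arr.chain_id[0])
    arr = arr[arr.chain_id == chain]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no protein atoms in chain {chain!r} of {path!r}")
    return Structure(_atoms_from_biotite(arr), np.asarray(arr.coord, dtype=float))


def load_trajectory(
    paths,
    topology: Structure,
    stride: float = 1.0,
    frame_interval: float = 1.0,
    chain: str | None = None,
) -> Trajectory:
    """Load trajectory frames and subsample them to ``stride`` ps.

    ``paths`` may be one path or a sequence; multi-model PDB files are read
    with biotite and binary formats (DCD/XTC) through mdtraj.  Frames in the
    files are assumed to be saved every ``frame_interval`` ps starting at
    ``t = frame_interval`` (the t=0 snapshot is not stored).  The returned
    trajectory keeps frames at ``t = stride, 2*stride, ...``, so e.g. 8.1 ns
    of 1 ps frames at a 10 ps stride yields 810 frames.

    Raises
    ------
    TopologyError
        If any frame's atom count differs from the topology.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in {".dcd", ".xtc", ".trr"}:
            coords = _read_binary_frames(p, topology)
        else:
            coords = _read_pdb_frames(p, topology, chain=chain)
        frames.append(coords)
    coords = np.concatenate(frames, axis=0)
    if coords.shape[1] != len(topology):
        raise TopologyError(
            f"trajectory has {coords.shape[1]} atoms, topology has {len(topology)}"
        )
    n = coords.shape[0]
    times = frame_interval * np.arange(1, n + 1)
    traj = Trajectory(topology, coords, times)
    if abs(stride - frame_interval) > 1e-9:
        traj = traj.strided(stride)
    return traj


def _read_pdb_frames(path, topology: Structure, chain: str | None) -> np.ndarray:
    stack = _read_pdb_models(path, model=None)
    mask = _protein_heavy_mask(stack)
    arr = stack[..., mask]
    if chain is None:
        chain = str(arr.chain_id[0])
    arr = arr[..., arr.chain_id == chain]
    coord = np.asarray(arr.coord, dtype=float)
    if coord.ndim == 2:
        coord = coord[None]
    if coord.shape[1] != len(topology):
        raise TopologyError(
            f"{path}: frames have {coord.shape[1]} atoms, topology has {len(topology)}"
        )
    return coord


def _read_binary_frames(path, topology: Structure) -> np.ndarray:
    import mdtraj

    from .surface import _mdtraj_topology

    t = mdtraj.load(str(path), top=_mdtraj_topology(topology))
    return np.asarray(t.xyz, dtype=float) * 10.0  # nm -> Angstrom


def write_structure(structure: Structure, path, bfactors: np.ndarray | None = None) -> None:
    """Write a Structure to a PDB file, optionally coding per-atom B-factors."""
    from biotite.structure.io.pdb import PDBFile

    arr = _to_biotite([structure])
    if bfactors is not None:
        arr.set_annotation("b_factor", np.asarray(bfactors, dtype=float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    arr = _to_biotite([traj.frame(i) for i in range(len(traj))])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Domain-partition configuration
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def _parse_label(label: str) -> tuple[int, str]:
    m = _LABEL_RE.match(str(label).strip())
    if not m:
        raise DomainConfigError(f"bad residue label {label!r} (expected e.g. '120A')")
    return int(m.group(1)), m.group(2).upper()


def _expand_range(spec: str, structure: Structure) -> list[ResidueID]:
    """Expand ``'15A-120E'``-style ranges against the structure's residues."""
    spec = str(spec).strip()
    if "-" in spec.lstrip("-"):
        head, tail = spec.rsplit("-", 1)
        lo_num, lo_ic = _parse_label(head)
        hi_num, hi_ic = _parse_label(tail)
    else:
        lo_num, lo_ic = hi_num, hi_ic = _parse_label(spec)
        hi_num, hi_ic = lo_num, lo_ic
    lo, hi = (lo_num, lo_ic), (hi_num, hi_ic)
    out = [r for r in structure.residues if lo <= (r.number, r.icode) <= hi]
    if not out:
        raise DomainConfigError(f"range {spec!r} matches no residues in structure")
    return out


def parse_domain_config(config, structure: Structure) -> DomainPartition:
    """Build a DomainPartition from a config mapping or YAML text.

    The config maps set names to lists of residue ranges in author labels,
    e.g. ``{"n_domain": ["15A-120E", "231-245"], "bridge": ["120A-121"],
    "c_domain": ["120G-230"]}``.  Ranges are expanded against the loaded
    structure's residue list under chymotrypsin insertion-code ordering and
    the three primary sets are validated to be pairwise disjoint.

    Raises
    ------
    DomainConfigError
        On bad labels, empty ranges, or overlapping primary sets (the error
        names the offending residues).
    """
    if isinstance(config, str):
        import yaml

        config = yaml.safe_load(config)
    if not isinstance(config, Mapping):
        raise DomainConfigError("domain config must be a mapping of name -> ranges")
    if "n_domain" not in config or "c_domain" not in config:
        raise DomainConfigError("domain config must name at least n_domain and c_domain")
    sets: dict[str, set[ResidueID]] = {}
    for name, ranges in config.items():
        if isinstance(ranges, str):
            ranges = [ranges]
        residues: set[ResidueID] = set()
        for rng in ranges or []:
            residues.update(_expand_range(rng, structure))
        sets[name] = residues
    return DomainPartition(sets)
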