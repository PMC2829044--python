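"""Solvent-accessible surface area and interface-solvation analysis.

SASA is computed with the Shrake–Rupley quadrature-sphere method (mdtraj's
C implementation) with a 1.4 Å probe and 960 sphere points by default;
areas are split into polar (N, O) and non-polar (C, S) totals.  The
non-polar total (NPSASA) is the order parameter that rises as the
hydrophobic core becomes exposed during unfolding.

Relative residue exposure is the residue's SASA divided by a reference
maximum computed internally from an extended Gly-X-Gly tripeptide with the
same probe and radii (self-consistent, rather than a literature table).
A domain-interface residue is *buried* when it participates in at least
one inter-domain residue contact in the crystal and its crystal relative
exposure is below 5%.  During unfolding, buried interface residues are
classed by when they become solvent exposed relative to the
transition-state ensemble: at the TSE, within 600 ps after it, or still
buried beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError
from .structure_io import DomainPartition, ResidueID, Structure, Trajectory

__all__ = [
    "SasaResult",
    "SolvationClassMap",
    "shrake_rupley_sasa",
    "sasa_series",
    "relative_exposure",
    "buried_interface_residues",
    "solvation_classes",
    "fractional_burial",
    "DEFAULT_PROBE",
    "DEFAULT_POINTS",
    "BURIAL_THRESHOLD",
]

DEFAULT_PROBE = 1.4  # Å
DEFAULT_POINTS = 960
BURIAL_THRESHOLD = 0.05  # relative exposure below which a residue is buried


@dataclass
class SasaResult:
    """Per-atom accessible areas (Å²) with polar/non-polar totals."""

    per_atom_area: np.ndarray
    npsasa: float
    psasa: float

    @property
    def total(self) -> float:
        return float(self.npsasa + self.psasa)


@dataclass
class SolvationClassMap:
    """Solvation class per buried-interface residue.

    Classes are exhaustive and mutually exclusive: ``exposed_at_TSE``,
    ``exposed_by_600ps`` (or the configured post-delay) and ``still_buried``.
    """

    classes: dict[ResidueID, str]

    def residues_in(self, cls: str) -> list[ResidueID]:
        return sorted(r for r, c in self.classes.items() if c == cls)

    def as_bfactor_codes(self, structure: Structure) -> np.ndarray:
        """Per-atom class codes (1/2/3, 0 = not an interface residue)."""
        code = {"exposed_at_TSE": 1.0, "exposed_by_600ps": 2.0, "still_buried": 3.0}
        vals = np.zeros(len(structure))
        for i, a in enumerate(structure.atoms):
            vals[i] = code.get(self.classes.get(a.residue, ""), 0.0)
        return vals


def _mdtraj_topology(structure: Structure):
    import mdtraj
    from mdtraj.core import element as mdelem

    top = mdtraj.Topology()
    chain = top.add_chain()
    res = None
    last = None
    for a in structure.atoms:
        if a.residue != last:
            res = top.add_residue(a.res_name, chain, resSeq=a.residue.number)
            last = a.residue
        top.add_atom(a.name, mdelem.get_by_symbol(a.element), res)
    return top


def _mdtraj_sasa(
    structure: Structure, coords: np.ndarray, probe: float, n_points: int
) -> np.ndarray:
    import mdtraj

    top = _mdtraj_topology(structure)
    traj = mdtraj.Trajectory(np.asarray(coords, float) / 10.0, top)  # Å -> nm
    areas = mdtraj.shrake_rupley(
        traj, probe_radius=probe / 10.0, n_sphere_points=n_points, mode="atom"
    )
    return np.asarray(areas, dtype=np.float64) * 100.0  # nm² -> Å²


def shrake_rupley_sasa(
    structure: Structure,
    coords: np.ndarray | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA of one conformation.

    Deterministic for a fixed sphere-point count; the element radii used
    are C 1.70, N 1.55, O 1.52, S 1.80 Å.

    Raises
    ------
    ParameterError
        If ``n_points`` < 32 (the quadrature would be too coarse to trust).
    """
    if n_points < 32:
        raise ParameterError("n_points must be at least 32")
    X = structure.coords if coords is None else np.asarray(coords, float)
    per_atom = _mdtraj_sasa(structure, X[None], probe, n_points)[0]
    np_mask = structure.nonpolar_mask
    return SasaResult(
        per_atom_area=per_atom,
        npsasa=float(per_atom[np_mask].sum()),
        psasa=float(per_atom[~np_mask].sum()),
    )


def sasa_series(
    traj: Trajectory,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> np.ndarray:
    """Per-atom SASA for every frame, shape ``(n_frames, n_atoms)`` (Å²)."""
    if n_points < 32:
        raise ParameterError("n_points must be at least 32")
    return _mdtraj_sasa(traj.topology, traj.coords, probe, n_points)


# ---------------------------------------------------------------------------
# Relative exposure and burial
# ---------------------------------------------------------------------------

def _gly_x_gly_reference(
    structure: Structure,
    residue_ordinal: int,
    probe: float,
    n_points: int,
) -> float:
    """Maximal SASA of the residue in an extended Gly-X-Gly context.

    The tripeptide is built from the residue's own atoms flanked by
    minimal glycine backbones placed on an idealised extended (straight)
    chain, then evaluated with the same probe and radii as the analysis.
    """
    from .structure_io import Atom, ResidueID

    idx = np.nonzero(structure.residue_index == residue_ordinal)[0]
    res_atoms = [structure.atoms[i] for i in idx]
    res_coords = structure.coords[idx]
    center = res_coords.mean(axis=0)
    res_coords = res_coords - center
    # extended-chain displacement: ~3.8 Å per residue along x
    gly_names = ["N", "CA", "C", "O"]
    gly_offsets = np.array(
        [[-1.2, 0.6, 0.0], [0.0, 0.0, 0.0], [1.3, 0.6, 0.0], [1.4, 1.8, 0.0]]
    )
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for k, shift in ((0, -3.8), (2, +3.8)):
        rid = ResidueID(chain="X", number=k + 1)
        for name, off in zip(gly_names, gly_offsets):
            elem = name[0]
            atoms.append(
                Atom(name=name, element=elem, residue=rid, res_name="GLY",
                     polarity="polar" if elem in "NO" else "nonpolar",
                     radius={"N": 1.55, "O": 1.52}.get(elem, 1.70))
            )
            coords.append(off + np.array([shift, 0.0, 0.0]))
    mid = ResidueID(chain="X", number=2)
    for a, xyz in zip(res_atoms, res_coords):
        atoms.append(
            Atom(name=a.name, element=a.element, residue=mid, res_name=a.res_name,
                 polarity=a.polarity, radius=a.radius)
        )
        coords.append(xyz)
    tri = Structure(atoms, np.array(coords))
    areas = shrake_rupley_sasa(tri, probe=probe, n_points=n_points).per_atom_area
    return float(areas[-len(res_atoms):].sum())


def relative_exposure(
    structure: Structure,
    residue: ResidueID | None = None,
    coords: np.ndarray | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    per_atom: np.ndarray | None = None,
) -> float | dict[ResidueID, float]:
    """Residue SASA over its Gly-X-Gly reference maximum.

    With ``residue`` given returns that residue's fraction (typically in
    [0, ~1.2]); otherwise a mapping for every residue.  ``per_atom``
    short-circuits the structure SASA when it was already computed.
    """
    if per_atom is None:
        per_atom = shrake_rupley_sasa(structure, coords, probe, n_points).per_atom_area
    # the Gly-X-Gly references depend only on topology: cache on the structure
    cache_key = (probe, n_points)
    cache = getattr(structure, "_gxg_cache", None)
    if cache is None:
        cache = {}
        structure._gxg_cache = cache  # type: ignore[attr-defined]
    out: dict[ResidueID, float] = {}
    targets = [residue] if residue is not None else structure.residues
    for r in targets:
        ordinal = structure.residues.index(r)
        idx = np.nonzero(structure.residue_index == ordinal)[0]
        if (cache_key, ordinal) not in cache:
            cache[(cache_key, ordinal)] = _gly_x_gly_reference(structure, ordinal, probe, n_points)
        out[r] = float(per_atom[idx].sum() / cache[(cache_key, ordinal)])
    return out[residue] if residue is not None else out


def buried_interface_residues(
    structure: Structure,
    dp: DomainPartition,
    threshold: float = BURIAL_THRESHOLD,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> set[ResidueID]:
    """Buried residues of the domain interface in the crystal structure.

    A residue qualifies when it (a) participates in at least one
    inter-domain residue contact in the crystal and (b) has relative
    exposure below ``threshold`` (default 5%).
    """
    from .contacts import atom_contacts

    native = atom_contacts(structure)
    interface: set[ResidueID] = set()
    for r1, r2 in native.residue_pairs:
        if dp.domain_of(r1) != dp.domain_of(r2):
            interface.update((r1, r2))
    if not interface:
        return set()
    exposures = relative_exposure(structure, probe=probe, n_points=n_points)
    return {r for r in interface if exposures[r] < threshold}


def solvation_classes(
    traj: Trajectory,
    crystal: Structure,
    crossing_time: float,
    residues: Iterable[ResidueID],
    tse_window: float = 10.0,
    post_delay: float = 600.0,
    exposure_threshold: float = BURIAL_THRESHOLD,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> SolvationClassMap:
    """Class each buried-interface residue by when it becomes exposed.

    ``exposed_at_TSE`` — mean relative exposure over the barrier-crossing
    window reaches the threshold; ``exposed_by_600ps`` — exposed at
    ``crossing_time + post_delay``; otherwise ``still_buried``.

    Raises
    ------
    ParameterError
        If the crossing or the post-delay frame lies outside the trajectory.
    """
    times = traj.times
    if not (times[0] <= crossing_time <= times[-1]):
        raise ParameterError("crossing_time outside trajectory")
    t_post = crossing_time + post_delay
    if t_post > times[-1] + 1e-9:
        raise ParameterError("crossing_time + post_delay beyond trajectory end")
    half = tse_window / 2.0
    win = np.nonzero((times > crossing_time - half) & (times <= crossing_time + half))[0]
    if len(win) == 0:
        win = np.array([int(np.argmin(np.abs(times - crossing_time)))])
    i_post = int(np.argmin(np.abs(times - t_post)))
    residues = list(residues)
    classes: dict[ResidueID, str] = {}
    frame_idx = list(win) + [i_post]
    expos = []  # per selected frame: residue -> exposure
    per_atom = sasa_series(
        Trajectory(traj.topology, traj.coords[frame_idx], np.arange(1, len(frame_idx) + 1)),
        probe=probe,
        n_points=n_points,
    )
    for k in range(len(frame_idx)):
        expos.append(
            relative_exposure(traj.topology, per_atom=per_atom[k], probe=probe, n_points=n_points)
        )
    for r in residues:
        at_tse = float(np.mean([expos[k][r] for k in range(len(win))]))
        if at_tse >= exposure_threshold:
            classes[r] = "exposed_at_TSE"
        elif expos[-1][r] >= exposure_threshold:
            classes[r] = "exposed_by_600ps"
        else:
            classes[r] = "still_buried"
    return SolvationClassMap(classes=classes)


def fractional_burial(
    frame_sasa: float,
    native_sasa: float,
    unfolded_ref: float,
) -> float:
    """Fraction of the native burial still present in a conformation.

    Linear in total SASA: 1 at the native structure, 0 at the fully
    unfolded reference.  ``unfolded_ref`` (the SASA of the notional fully
    unfolded chain) must exceed the native SASA.
    """
    if unfolded_ref <= native_sasa:
        raise ParameterError("unfolded_ref must exceed the native SASA")
    return float((unfolded_ref - frame_sasa) / (unfolded_ref - native_sasa))
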