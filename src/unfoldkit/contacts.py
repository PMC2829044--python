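"""Atomic contacts, native/domain classification and contact time series.

Contact rule: two heavy atoms are in contact when they are less than
4.6 Å apart — or less than 5.4 Å apart if either atom is carbon or
sulfur — and their residues are more than two positions separated in the
primary sequence.  Sequence separation is measured on the residue's
ordinal position within the chain (insertion codes count as steps), not on
author numbering, so numbering gaps do not distort the rule.  A residue
pair is in contact when at least one atom pair joining the two residues
is; a contact is *native* when the residue pair is also in contact in the
crystal structure.

Contact categories against a domain partition:

* intra-domain — both residues in the same primary set;
* inter-domain — otherwise;
* DB–DB / DB–other — atom-level contacts with both or exactly one atom in
  the domain-bridge set (the bridge is small, so atom counting is used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AnalysisError, ParameterError
from .structure_io import DomainPartition, ResidueID, Structure, Trajectory

__all__ = [
    "CUTOFF_DEFAULT",
    "CUTOFF_CS",
    "ContactSet",
    "ContactSeries",
    "HBondSet",
    "atom_contacts",
    "classify_contacts",
    "frame_contact_table",
    "contact_fraction_series",
    "mainchain_hbonds",
    "contact_density",
    "MIN_SEQUENCE_SEPARATION",
]

CUTOFF_DEFAULT = 4.6  # Å, any heavy-atom pair
CUTOFF_CS = 5.4  # Å, when either atom is C or S
MIN_SEQUENCE_SEPARATION = 2  # residues must be more than this far apart


@dataclass
class ContactSet:
    """Atom- and residue-level contacts of one conformation."""

    atom_pairs: frozenset[tuple[int, int]]
    residue_pairs: frozenset[tuple[ResidueID, ResidueID]]

    def __len__(self) -> int:
        return len(self.atom_pairs)

    @property
    def n_residue_pairs(self) -> int:
        return len(self.residue_pairs)


@dataclass
class HBondSet:
    """Main-chain N(donor)–O(acceptor) pairs present in one conformation."""

    pairs: frozenset[tuple[int, int]]  # (N atom index, O atom index)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContactSeries:
    """Per-frame contact counts and crystal-normalised fractions by category."""

    times: np.ndarray
    counts: pd.DataFrame  # one column per category
    crystal_counts: dict[str, int]
    fractions: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        frac = {}
        for cat in self.counts.columns:
            ref = self.crystal_counts[cat]
            frac[cat] = self.counts[cat] / ref
        self.fractions = pd.DataFrame(frac)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (time, category, count, fraction) table."""
        rows = []
        for cat in self.counts.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "time_ps": self.times,
                        "category": cat,
                        "count": self.counts[cat].to_numpy(),
                        "fraction": self.fractions[cat].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def atom_contacts(structure: Structure, coords: np.ndarray | None = None) -> ContactSet:
    """All atom contacts of a conformation under the distance/separation rule.

    ``coords`` overrides the structure's own coordinates (same topology),
    which lets one topology serve every trajectory frame.  A cell list
    (kd-tree) restricts candidate pairs to within the larger cutoff; the
    brute-force O(n²) scan gives identical results and is used as the
    oracle in the test suite.
    """
    X = structure.coords if coords is None else np.asarray(coords, float)
    ridx = structure.residue_index
    cs = np.isin(structure.elements, ["C", "S"])
    tree = cKDTree(X)
    pairs = tree.query_pairs(CUTOFF_CS, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(X[i] - X[j], axis=1)
        cut = np.where(cs[i] | cs[j], CUTOFF_CS, CUTOFF_DEFAULT)
        ok = (d < cut) & (np.abs(ridx[i] - ridx[j]) > MIN_SEQUENCE_SEPARATION)
        pairs = pairs[ok]
    atom_pairs = frozenset((int(a), int(b)) for a, b in pairs)
    residues = structure.residues
    residue_pairs = frozenset(
        tuple(sorted((residues[ridx[a]], residues[ridx[b]]))) for a, b in atom_pairs
    )
    return ContactSet(atom_pairs=atom_pairs, residue_pairs=residue_pairs)


def classify_contacts(
    cs: ContactSet,
    native: ContactSet,
    structure: Structure,
    dp: DomainPartition,
) -> dict[str, int]:
    """Category counts for one conformation's contacts.

    Residue-level categories: ``intra_domain``, ``inter_domain`` and their
    native restrictions; atom-level domain-bridge categories ``db_db`` and
    ``db_other`` (native atom contacts with both/one atom in the bridge).

    Raises
    ------
    DomainConfigError
        If a contacting residue is missing from the partition (the error
        names the residue).
    """
    counts = dict.fromkeys(
        ["intra_domain", "inter_domain", "native_intra", "native_inter", "db_db", "db_other"],
        0,
    )
    for r1, r2 in cs.residue_pairs:
        d1, d2 = dp.domain_of(r1), dp.domain_of(r2)
        is_native = (r1, r2) in native.residue_pairs
        if d1 == d2:
            counts["intra_domain"] += 1
            counts["native_intra"] += is_native
        else:
            counts["inter_domain"] += 1
            counts["native_inter"] += is_native
    bridge = dp.sets.get("bridge", frozenset())
    ridx = structure.residue_index
    residues = structure.residues
    # nativeness is defined at residue level: an atom contact is native when
    # its residue pair has a contact in the crystal structure
    for a, b in cs.atom_pairs:
        r1, r2 = residues[ridx[a]], residues[ridx[b]]
        if tuple(sorted((r1, r2))) not in native.residue_pairs:
            continue
        in_b = (r1 in bridge) + (r2 in bridge)
        if in_b == 2:
            counts["db_db"] += 1
        elif in_b == 1:
            counts["db_other"] += 1
    return {k: int(v) for k, v in counts.items()}


def frame_contact_table(
    structure: Structure,
    coords: np.ndarray,
    native: ContactSet,
    dp: DomainPartition,
) -> pd.DataFrame:
    """Vectorised per-frame contact counts over a whole coordinate stack.

    Columns: residue-level ``intra_domain``, ``inter_domain``,
    ``native_intra``, ``native_inter`` and ``native_residue_contacts``;
    atom-level ``native_intra_atom``, ``native_inter_atom``,
    ``nonnative_intra_atom``, ``nonnative_inter_atom`` plus the native
    domain-bridge categories ``db_db`` and ``db_other``.  Equivalent to
    running :func:`atom_contacts` + :func:`classify_contacts` frame by
    frame (the test suite asserts this), just much faster.
    """
    n = len(structure)
    ridx = structure.residue_index
    nres = structure.n_residues
    residues = structure.residues
    dom = np.array([dp.domain_of(r) for r in residues])  # raises if unassigned
    same_dom_res = dom[:, None] == dom[None, :]
    native_res = np.zeros((nres, nres), dtype=bool)
    res_of = {r: k for k, r in enumerate(residues)}
    for r1, r2 in native.residue_pairs:
        k1, k2 = res_of[r1], res_of[r2]
        native_res[k1, k2] = native_res[k2, k1] = True
    cs = np.isin(structure.elements, ["C", "S"])
    cut2 = np.where(cs[:, None] | cs[None, :], CUTOFF_CS, CUTOFF_DEFAULT) ** 2
    sep_ok = np.abs(ridx[:, None] - ridx[None, :]) > MIN_SEQUENCE_SEPARATION
    same_dom_atom = same_dom_res[np.ix_(ridx, ridx)]
    native_atom = native_res[np.ix_(ridx, ridx)]  # residue-level nativeness
    bridge = dp.sets.get("bridge", frozenset())
    in_bridge = np.array([residues[ridx[i]] in bridge for i in range(n)])
    nb = in_bridge[:, None].astype(int) + in_bridge[None, :].astype(int)
    iu_atom = np.triu_indices(n, 1)
    masks = {
        "native_intra_atom": (native_atom & same_dom_atom)[iu_atom],
        "native_inter_atom": (native_atom & ~same_dom_atom)[iu_atom],
        "nonnative_intra_atom": (~native_atom & same_dom_atom)[iu_atom],
        "nonnative_inter_atom": (~native_atom & ~same_dom_atom)[iu_atom],
        "db_db": (native_atom & (nb == 2))[iu_atom],
        "db_other": (native_atom & (nb == 1))[iu_atom],
    }
    iu_res = np.triu_indices(nres, 1)
    res_masks = {
        "intra_domain": same_dom_res[iu_res],
        "inter_domain": ~same_dom_res[iu_res],
        "native_intra": (same_dom_res & native_res)[iu_res],
        "native_inter": (~same_dom_res & native_res)[iu_res],
        "native_residue_contacts": native_res[iu_res],
    }
    starts = np.searchsorted(ridx, np.arange(nres))
    cut2_u = cut2[iu_atom]
    sep_u = sep_ok[iu_atom]
    out = {k: np.empty(len(coords), dtype=int) for k in list(res_masks) + list(masks)}
    for f, X in enumerate(coords):
        diff = X[:, None, :] - X[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        contact = (d2 < cut2) & sep_ok
        cu = contact[iu_atom]
        for k, mask in masks.items():
            out[k][f] = np.sum(cu & mask)
        # residue-level: any atom contact between the residues
        red = np.add.reduceat(contact, starts, axis=0)
        red = np.add.reduceat(red, starts, axis=1)
        rescon = (red > 0)[iu_res]
        for k, mask in res_masks.items():
            out[k][f] = np.sum(rescon & mask)
    return pd.DataFrame(out)


def contact_fraction_series(
    traj: Trajectory,
    native: ContactSet,
    dp: DomainPartition,
    smooth_window: float | None = None,
    categories: Sequence[str] | None = None,
) -> ContactSeries:
    """Per-frame contact counts normalised by the crystal-structure counts.

    ``smooth_window`` (ps) applies the centered running average used for
    time-series figures (default none).  Categories whose crystal count is
    zero cannot be normalised and raise unless excluded via ``categories``.
    """
    crystal = classify_contacts(native, native, traj.topology, dp)
    counts = frame_contact_table(traj.topology, traj.coords, native, dp)
    default_cats = ["intra_domain", "inter_domain", "native_intra", "native_inter",
                    "db_db", "db_other"]
    counts = counts[list(categories) if categories is not None else default_cats]
    for cat in counts.columns:
        if crystal[cat] == 0:
            raise AnalysisError(
                f"category {cat!r} has zero contacts in the crystal structure; "
                "its fraction is undefined"
            )
    series = ContactSeries(times=traj.times, counts=counts, crystal_counts=crystal)
    if smooth_window is not None:
        from .superpose import running_average

        for df in (series.counts, series.fractions):
            for cat in df.columns:
                df[cat] = running_average(df[cat].to_numpy(), smooth_window, traj.save_interval)
    return series


# ---------------------------------------------------------------------------
# Main-chain hydrogen bonds
# ---------------------------------------------------------------------------

HBOND_NO_CUTOFF = 3.5  # Å, backbone N…O distance
HBOND_MIN_ANGLE = 90.0  # degrees, N–O=C angle


def _backbone_indices(structure: Structure):
    names = np.array([a.name for a in structure.atoms])
    idx_n = np.nonzero(names == "N")[0]
    idx_o = np.nonzero(names == "O")[0]
    idx_c = np.nonzero(names == "C")[0]
    # map carbonyl O to its C (same residue)
    ridx = structure.residue_index
    c_of_res = {ridx[i]: i for i in idx_c}
    o_partner = np.array([c_of_res.get(ridx[i], -1) for i in idx_o])
    return idx_n, idx_o, o_partner


def mainchain_hbonds(
    structure: Structure,
    coords: np.ndarray | None = None,
    native_ref: HBondSet | None = None,
) -> tuple[int, int] | HBondSet:
    """Backbone hydrogen bonds under a hydrogen-free geometric criterion.

    A bond is counted for backbone N(donor)–O(acceptor) pairs with N–O
    distance <= 3.5 Å and N–O=C angle >= 90°, excluding pairs closer than
    three residues in sequence.  With ``native_ref`` given, returns
    ``(native_count, non_native_count)`` split by presence of the (N, O)
    pair in the reference; without it, returns the HBondSet itself (use on
    the crystal structure to build the reference).
    """
    X = structure.coords if coords is None else np.asarray(coords, float)
    idx_n, idx_o, o_partner = _backbone_indices(structure)
    ridx = structure.residue_index
    pairs = set()
    if len(idx_n) and len(idx_o):
        dn = X[idx_n][:, None, :] - X[idx_o][None, :, :]
        dist = np.linalg.norm(dn, axis=2)
        sep = np.abs(ridx[idx_n][:, None] - ridx[idx_o][None, :])
        cand = np.nonzero((dist <= HBOND_NO_CUTOFF) & (sep > 2))
        for a, b in zip(*cand):
            n_i, o_i, c_i = idx_n[a], idx_o[b], o_partner[b]
            if c_i < 0:
                continue
            v1 = X[n_i] - X[o_i]
            v2 = X[c_i] - X[o_i]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= HBOND_MIN_ANGLE:
                pairs.add((int(n_i), int(o_i)))
    hb = HBondSet(pairs=frozenset(pairs))
    if native_ref is None:
        return hb
    native = sum(p in native_ref.pairs for p in hb.pairs)
    return native, len(hb.pairs) - native


def contact_density(
    structure: Structure,
    subset: Iterable[ResidueID] | None = None,
    native: ContactSet | None = None,
) -> float:
    """Native residue–residue contacts per residue within a subset.

    For the full protein (``subset=None``) a contact is counted once per
    residue pair with both endpoints in the protein; for a proper subset,
    pairs with at least one endpoint in the subset are counted, reflecting
    how densely the subset is packed against the whole molecule.

    Raises
    ------
    ParameterError
        For an empty subset.
    """
    if native is None:
        native = atom_contacts(structure)
    if subset is None:
        return len(native.residue_pairs) / structure.n_residues
    subset = set(subset)
    if not subset:
        raise ParameterError("contact_density subset must be non-empty")
    n_pairs = sum(1 for r1, r2 in native.residue_pairs if r1 in subset or r2 in subset)
    return n_pairs / len(subset)
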