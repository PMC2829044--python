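"""Contact rule, classification, series and contact density."""

import numpy as np
import pytest

from unfoldkit import contacts as con
from unfoldkit.errors import DomainConfigError, ParameterError
from unfoldkit.structure_io import Atom, DomainPartition, ResidueID, Structure, Trajectory


def _chain(elements, positions, spacing=1):
    """One atom per residue at consecutive chain positions."""
    atoms = []
    for k, e in enumerate(elements):
        atoms.append(Atom(name=f"X{k}", element=e, residue=ResidueID("A", 1 + k)))
    return Structure(atoms, np.asarray(positions, float))


def _pair(e1, e2, distance):
    """Two atoms `distance` apart whose residues sit 4 chain positions apart.

    Sequence separation is counted on ordinal chain position, so three
    far-away filler residues are placed between the probed pair.
    """
    elements = [e1, "C", "C", "C", e2]
    positions = [[0.0, 0.0, 0.0]]
    for k in range(3):
        positions.append([1000.0 + 100.0 * k, 1000.0, 0.0])
    positions.append([distance, 0.0, 0.0])
    s = _chain(elements, positions)
    probed = {(0, 4)}
    return s, probed


def brute_force_contacts(structure, coords=None):
    """O(n^2) oracle for the distance/separation rule."""
    X = structure.coords if coords is None else coords
    ridx = structure.residue_index
    elems = structure.elements
    pairs = set()
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            if abs(ridx[i] - ridx[j]) <= 2:
                continue
            cut = 5.4 if (elems[i] in "CS" or elems[j] in "CS") else 4.6
            if np.linalg.norm(X[i] - X[j]) < cut:
                pairs.add((i, j))
    return pairs


class TestAtomContactRule:
    def test_cs_pair_within_extended_cutoff(self):
        s, probed = _pair("C", "C", 5.0)
        assert con.atom_contacts(s).atom_pairs == probed

    def test_nn_pair_outside_default_cutoff(self):
        s, _ = _pair("N", "N", 5.0)
        assert len(con.atom_contacts(s).atom_pairs) == 0

    def test_nn_pair_within_default_cutoff(self):
        s, probed = _pair("N", "N", 4.5)
        assert con.atom_contacts(s).atom_pairs == probed

    def test_sequence_neighbors_never_contact(self):
        # residues i and i+2 are excluded regardless of distance
        s = _chain(["C", "C", "C"], [[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert len(con.atom_contacts(s).atom_pairs) == 0

    def test_cell_list_matches_brute_force(self, rng):
        n = 60
        atoms = []
        for k in range(n):
            e = ["C", "N", "O", "S"][k % 4]
            atoms.append(Atom(name=f"A{k}", element=e, residue=ResidueID("A", k)))
        X = rng.uniform(0, 25, size=(n, 3))
        s = Structure(atoms, X)
        assert con.atom_contacts(s).atom_pairs == frozenset(brute_force_contacts(s))

    def test_monotone_nesting_in_cutoff(self, toy_structure):
        # every default-cutoff contact is also a contact under the C/S cutoff
        cs = con.atom_contacts(toy_structure)
        X = toy_structure.coords
        for i, j in cs.atom_pairs:
            assert np.linalg.norm(X[i] - X[j]) < con.CUTOFF_CS


class TestClassification:
    @pytest.fixture()
    def toy8(self):
        """8 one-atom residues, two domains, hand-enumerable contacts.

        Residues 2, 3, 6, 7 are far-away spacers so that the probed pairs
        have ordinal sequence separation > 2: contacts are 1-4 and 5-8
        (intra, 4 A), 1-5 and 4-8 (inter, 4 A); 1-8 is 5.66 A (none).
        """
        positions = {
            1: [0, 0, 0], 4: [4, 0, 0], 5: [0, 4, 0], 8: [4, 4, 0],
            2: [300, 300, 0], 3: [400, 300, 0], 6: [300, 500, 0], 7: [400, 500, 0],
        }
        atoms = [Atom(name=f"A{n}", element="C", residue=ResidueID("A", n))
                 for n in range(1, 9)]
        s = Structure(atoms, np.array([positions[n] for n in range(1, 9)], float))
        dp = DomainPartition(
            {
                "n_domain": {ResidueID("A", n) for n in (1, 2, 3, 4)},
                "c_domain": {ResidueID("A", n) for n in (5, 6, 7, 8)},
            }
        )
        return s, dp

    def test_hand_enumerated_counts(self, toy8):
        s, dp = toy8
        cs = con.atom_contacts(s)
        assert cs.n_residue_pairs == 4
        counts = con.classify_contacts(cs, cs, s, dp)
        assert counts["intra_domain"] == 2
        assert counts["inter_domain"] == 2
        assert counts["native_intra"] == 2
        assert counts["native_inter"] == 2

    def test_native_vs_self_all_native(self, toy_structure, toy_partition):
        native = con.atom_contacts(toy_structure)
        counts = con.classify_contacts(native, native, toy_structure, toy_partition)
        assert counts["intra_domain"] == counts["native_intra"]
        assert counts["inter_domain"] == counts["native_inter"]

    def test_empty_contact_set(self, toy_structure, toy_partition):
        empty = con.ContactSet(frozenset(), frozenset())
        native = con.atom_contacts(toy_structure)
        counts = con.classify_contacts(empty, native, toy_structure, toy_partition)
        assert all(v == 0 for v in counts.values())

    def test_unassigned_residue_raises_with_name(self, toy8):
        s, _ = toy8
        dp = DomainPartition(
            {"n_domain": {ResidueID("A", n) for n in (1, 2, 3, 4)},
             "c_domain": {ResidueID("A", n) for n in (5, 6, 7)}}
        )
        cs = con.atom_contacts(s)
        with pytest.raises(DomainConfigError, match="8"):
            con.classify_contacts(cs, cs, s, dp)

    def test_intra_plus_inter_equals_total(self, two_state_run, toy_partition):
        traj, _, _ = two_state_run
        native = con.atom_contacts(traj.topology)
        for f in [0, 40, 60, 99]:
            cs = con.atom_contacts(traj.topology, traj.coords[f])
            counts = con.classify_contacts(cs, native, traj.topology, toy_partition)
            assert counts["intra_domain"] + counts["inter_domain"] == cs.n_residue_pairs


class TestFastFrameTable:
    def test_matches_per_frame_classification(self, two_state_run, toy_partition):
        traj, _, _ = two_state_run
        native = con.atom_contacts(traj.topology)
        sub = traj.coords[::20]
        table = con.frame_contact_table(traj.topology, sub, native, toy_partition)
        for f in range(len(sub)):
            cs = con.atom_contacts(traj.topology, sub[f])
            counts = con.classify_contacts(cs, native, traj.topology, toy_partition)
            for key in ("intra_domain", "inter_domain", "native_intra",
                        "native_inter", "db_db", "db_other"):
                assert table[key][f] == counts[key], (f, key)


class TestContactSeries:
    def test_crystal_frame_fractions_one(self, toy_structure, toy_partition):
        native = con.atom_contacts(toy_structure)
        coords = np.repeat(toy_structure.coords[None], 3, axis=0)
        traj = Trajectory(toy_structure, coords, 10.0 * np.arange(1, 4))
        series = con.contact_fraction_series(traj, native, toy_partition)
        assert np.allclose(series.fractions.to_numpy(), 1.0)

    def test_exploded_frames_fraction_zero(self, toy_structure, toy_partition):
        native = con.atom_contacts(toy_structure)
        # move every residue to its own far-apart location
        X = toy_structure.coords + 50.0 * toy_structure.residue_index[:, None] * np.eye(3)[0]
        traj = Trajectory(toy_structure, X[None], np.array([10.0]))
        series = con.contact_fraction_series(traj, native, toy_partition)
        for cat in ("inter_domain", "native_inter", "db_other"):
            assert series.fractions[cat].iloc[0] == 0.0

    def test_interface_bias_slope_ratio(self):
        # generator truth: inter-domain contacts programmed to be lost twice
        # as fast as intra-domain ones.  Gradual mode keeps both losses in
        # their linear regime, where the rate ratio is identifiable; with
        # only ~10 inter-domain contacts in the toy the per-seed estimate is
        # granular, so the ratio is averaged over seeds.
        from unfoldkit import synthetic_data as syn

        ratios = []
        for seed in range(10):
            spec = syn.SyntheticSpec(seed=seed, duration=1000.0, mode="gradual",
                                     transition_time=400.0, interface_bias=2.0)
            traj, _ = syn.generate_unfolding_trajectory(spec)
            _, dp = syn.make_toy_two_domain_structure(spec)
            native = con.atom_contacts(traj.topology)
            series = con.contact_fraction_series(traj, native, dp)
            t = series.times
            m = (t >= 10) & (t <= 500)
            fi = series.fractions["native_intra"].to_numpy()
            fe = series.fractions["native_inter"].to_numpy()
            ratios.append(np.polyfit(t[m], fe[m], 1)[0] / np.polyfit(t[m], fi[m], 1)[0])
        assert 1.5 <= np.mean(ratios) <= 2.5


class TestHBonds:
    def test_crystal_against_itself_no_nonnative(self, toy_structure):
        ref = con.mainchain_hbonds(toy_structure)
        native, nonnative = con.mainchain_hbonds(
            toy_structure, native_ref=ref
        )
        assert nonnative == 0
        assert native == len(ref)

    def test_extended_chain_no_bonds(self):
        # fully extended chain: no N-O pair within the 3.5 A cutoff
        atoms, coords = [], []
        for k in range(6):
            rid = ResidueID("A", k + 1)
            for name, off in (("N", [-1.2, 0, 0]), ("CA", [0, 0, 0]),
                              ("C", [1.2, 0, 0]), ("O", [1.2, 1.2, 0])):
                atoms.append(Atom(name=name, element=name[0], residue=rid))
                coords.append(np.array([8.0 * k, 0, 0]) + off)
        s = Structure(atoms, np.array(coords))
        hb = con.mainchain_hbonds(s)
        assert len(hb) == 0

    def test_idealised_beta_pair_counts(self):
        # two-strand model with k cross-strand N...O pairs at 2.9 A
        k = 4
        atoms, coords = [], []
        for i in range(k):
            rid = ResidueID("A", i + 1)
            base = np.array([0.0, 3.4 * i, 0.0])
            for name, off in (("N", [-1.0, 0, 0]), ("CA", [0, 0, 0]),
                              ("C", [0.8, 0.6, 0]), ("O", [2.0, 0.8, 0.0])):
                atoms.append(Atom(name=name, element=name[0], residue=rid))
                coords.append(base + off)
        for i in range(k):
            rid = ResidueID("A", 20 + i)
            base = np.array([4.9, 3.4 * i, 0.0])
            for name, off in (("N", [0.0, 0, 0]), ("CA", [1.0, 0, 0]),
                              ("C", [1.8, 0.6, 0]), ("O", [2.6, 0.8, 0.0])):
                atoms.append(Atom(name=name, element=name[0], residue=rid))
                coords.append(base + off)
        s = Structure(atoms, np.array(coords))
        hb = con.mainchain_hbonds(s)
        # each strand-2 N sits 2.9 A from the strand-1 O of the same row
        assert len(hb) >= k


class TestContactDensity:
    def test_single_isolated_residue_zero(self, toy_structure):
        # a subset with no contacts at all has density 0
        far = ResidueID("A", 10)
        lone = Structure(
            [a for a in toy_structure.atoms if a.residue == far],
            toy_structure.coords[toy_structure.residue_index == 0],
        )
        assert con.contact_density(lone, subset=[far]) == 0.0

    def test_full_protein_counts_each_pair_once(self, toy_structure):
        native = con.atom_contacts(toy_structure)
        d = con.contact_density(toy_structure)
        assert d == pytest.approx(len(native.residue_pairs) / toy_structure.n_residues)

    def test_empty_subset_raises(self, toy_structure):
        with pytest.raises(ParameterError):
            con.contact_density(toy_structure, subset=[])
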