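"""Synthetic two-domain structures and unfolding trajectories.

The generator exists so that every stage of the analysis pipeline can be
exercised against known ground truth without molecular dynamics: it is
geometric, not physical — no force field, no integrator.  A toy protein
of two pseudo-β-hairpin domains (4-atom residues: N, CA, C, O) packed
across an interface and joined by a two-residue linker (the "domain
bridge") unfolds by a small set of smooth geometric moves:

* *domain separation* along the interface normal breaks inter-domain
  contacts; the bridge is rebuilt each frame as a constant-link-length
  chain spanning the gap, so covalent connectivity is never violated;
* *hairpin opening* (rigid rotation of each domain's outer strand about a
  hinge at its turn) breaks intra-domain cross-strand contacts while
  preserving all bond lengths;
* post-transition random walks on the hinge angles, domain orientations
  and separation diversify the unfolded ensemble;
* isotropic per-atom jitter models thermal noise throughout.

Contact loss is *programmed*: target native intra- and inter-domain
contact-fraction schedules are set from the mode (``two_state`` — flat
native phase, a jump at the transition time, then exponential approach to
the unfolded state; ``gradual`` — linear progress over the whole run) and
the ``interface_bias`` (ratio of inter- to intra-domain loss rates), then
realised geometrically by inverting calibration curves measured on the
toy structure with the package's own contact rule.  The truth record
carries the programmed schedules for test assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, DomainPartition, ResidueID, Structure, Trajectory


def _smooth_jitter(rng: np.ndarray, structure: Structure, sigma: float) -> np.ndarray:
    """Sequence-correlated thermal jitter (per residue, smoothed along chain).

    Smoothing with a [1, 2, 1]/4 kernel keeps the displacement difference
    between bonded neighbours small so jitter cannot break connectivity,
    while the per-residue RMS displacement stays at ``sigma``.
    """
    nres = structure.n_residues
    g = rng.normal(0.0, 1.0, (nres + 2, 3))
    sm = 0.25 * g[:-2] + 0.5 * g[1:-1] + 0.25 * g[2:]
    sm = sm / np.sqrt(0.375)  # restore unit variance after smoothing
    return sigma * sm[structure.residue_index]


def _clamp_links(structure: Structure, X: np.ndarray, max_link: float = 4.45) -> None:
    """Pull any over-stretched backbone link back within the bond envelope."""
    ca = structure.ca_indices
    ridx = structure.residue_index
    for _ in range(8):
        d = np.linalg.norm(np.diff(X[ca], axis=0), axis=1)
        bad = np.nonzero(d > max_link)[0]
        if len(bad) == 0:
            break
        for k in bad:
            v = X[ca[k + 1]] - X[ca[k]]
            shift = v * (max_link / np.linalg.norm(v) - 1.0)
            X[ridx == ridx[ca[k + 1]]] += shift

__all__ = [
    "SyntheticSpec",
    "TruthRecord",
    "make_toy_two_domain_structure",
    "generate_unfolding_trajectory",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic unfolding run.

    Defaults describe a clearly two-state unfolding of a 26-residue toy
    protein over 2 ns with the transition programmed at 0.8 ns, thermal
    jitter of 0.15 Å and inter-domain contacts lost twice as fast as
    intra-domain ones (the interface-first phenomenology of a kinetically
    stable protease).
    """

    n_residues_per_domain: int = 12
    mode: str = "two_state"  # or "gradual"
    transition_time: float = 800.0  # ps
    duration: float = 2000.0  # ps
    save_interval: float = 10.0  # ps
    native_noise: float = 0.15  # Å isotropic jitter
    unfolded_scale: float = 1.6  # dimensionless; sets the hinge-opening extent
    interface_bias: float = 2.0  # inter/intra contact-loss rate ratio
    seed: int = 0
    intra_loss_total: float = 0.45  # intra-domain native-contact loss at full progress
    jitter_growth: float = 0.5  # fractional jitter increase at full progress

    def __post_init__(self) -> None:
        if not 0 < self.transition_time < self.duration:
            raise ValueError("transition_time must lie inside (0, duration)")
        if self.native_noise < 0:
            raise ValueError("native_noise must be non-negative")
        if self.interface_bias <= 0:
            raise ValueError("interface_bias must be positive")
        if self.n_residues_per_domain < 8:
            raise ValueError("need at least 8 residues per domain")
        if self.mode not in ("two_state", "gradual"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TruthRecord:
    """Programmed ground truth stored alongside a generated trajectory."""

    transition_time: float
    mode: str
    interface_bias: float
    seed: int
    times: np.ndarray
    f_intra: np.ndarray  # programmed native intra-domain contact fraction
    f_inter: np.ndarray  # programmed native inter-domain contact fraction

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "transition_time": self.transition_time,
                    "mode": self.mode,
                    "interface_bias": self.interface_bias,
                    "seed": self.seed,
                    "times": self.times.tolist(),
                    "f_intra": self.f_intra.tolist(),
                    "f_inter": self.f_inter.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "TruthRecord":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            transition_time=d["transition_time"],
            mode=d["mode"],
            interface_bias=d["interface_bias"],
            seed=d["seed"],
            times=np.array(d["times"]),
            f_intra=np.array(d["f_intra"]),
            f_inter=np.array(d["f_inter"]),
        )


# geometry constants (Å)
_CA_SPACING = 3.4  # along-strand CA spacing
_STRAND_SEP = 4.1  # CA column separation inside a hairpin
_INTERFACE_GAP = 4.8  # CA column separation across the domain interface
_MAX_SEP = 8.0  # maximum programmed domain separation
_LINK = 3.85  # bridge link length


def _strand_atoms(
    x_col: float,
    n_res: int,
    direction: int,
    facing: int,
    y0: float,
    stagger: np.ndarray | None = None,
):
    """Backbone atoms of one β-strand column.

    ``direction`` (+1 up / −1 down) sets chain direction along y;
    ``facing`` (+1/−1) points the carbonyl O and amide N toward the
    partner strand so that cross-strand N…O hydrogen bonds form.
    """
    coords = []
    for i in range(n_res):
        y = y0 + direction * _CA_SPACING * i
        z = 0.35 * (-1) ** i
        dx = 0.0 if stagger is None else stagger[i]
        ca = np.array([x_col + dx, y, z])
        # offsets keep every non-bonded N...O pair well clear of the
        # hydrogen-bond cutoff so thermal jitter cannot flicker spurious
        # bonds in and out (cross-strand in-register pairs sit at ~2.6 A,
        # the nearest non-bonded pairs at >= 4 A)
        n = ca + np.array([facing * 0.60, -direction * 0.55, 0.30])
        c = ca + np.array([facing * 0.70, direction * 0.70, -0.30])
        o = ca + np.array([facing * 1.00, direction * 0.25, -0.45])
        coords.append((n, ca, c, o))
    return coords


def _build_toy(n_per_domain: int):
    """Native geometry plus the index bookkeeping the deformers need."""
    n1 = (n_per_domain + 1) // 2  # strand 1 length
    n2 = n_per_domain - n1
    # wedge: the interface gap widens along the strand so that inter-domain
    # contacts break sequentially (not in unison) as the domains separate,
    # giving the separation->contact-loss calibration a graded response
    wedge = np.linspace(-0.45, 0.35, n2)

    # domain A: strand up at x=0, turn, strand down at x=_STRAND_SEP
    a1 = _strand_atoms(0.0, n1, +1, +1, 0.0, None)
    a2 = _strand_atoms(_STRAND_SEP, n2, -1, -1, _CA_SPACING * (n2 - 1), wedge)
    # domain B mirrors A across the interface: strand up, turn, strand down
    xb = _STRAND_SEP + _INTERFACE_GAP
    b1 = _strand_atoms(xb, n1, +1, +1, 0.0, -wedge[::-1])
    b2 = _strand_atoms(xb + _STRAND_SEP, n2, -1, -1, _CA_SPACING * (n2 - 1), None)

    residues: list[tuple[ResidueID, tuple]] = []
    chain = "A"
    num = 10
    for res in a1 + a2:
        residues.append((ResidueID(chain, num), res))
        num += 1
    # bridge: chymotrypsin-style inserted residues 120A-120D (four residues,
    # so the bridge can form internal contacts under the >2-separation rule)
    bridge_ids = [ResidueID(chain, 120, ic) for ic in "ABCD"]
    for rid in bridge_ids:
        residues.append((rid, None))  # coordinates set by the bridge solver
    num = 121
    for res in b1 + b2:
        residues.append((ResidueID(chain, num), res))
        num += 1

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    polarity = {"N": "polar", "O": "polar"}
    radius = {"N": 1.55, "O": 1.52, "C": 1.70}
    placeholder = np.zeros(3)
    for rid, res in residues:
        for name, pos in zip(
            ("N", "CA", "C", "O"), res if res is not None else [placeholder] * 4
        ):
            elem = name[0]
            atoms.append(
                Atom(name=name, element=elem, residue=rid, res_name="GLY",
                     polarity=polarity.get(elem, "nonpolar"), radius=radius[elem])
            )
            coords.append(np.asarray(pos, float))
    structure = Structure(atoms, np.array(coords))

    n_a = n_per_domain
    nb = 4  # bridge residues
    idx = {
        "a1_res": np.arange(0, n1),
        "a2_res": np.arange(n1, n_a),
        "bridge_res": np.arange(n_a, n_a + nb),
        "b1_res": np.arange(n_a + nb, n_a + nb + n1),
        "b2_res": np.arange(n_a + nb + n1, n_a + nb + n_per_domain),
    }
    idx["a_res"] = np.concatenate([idx["a1_res"], idx["a2_res"]])
    idx["b_res"] = np.concatenate([idx["b1_res"], idx["b2_res"]])
    # resolve the native bridge with the constant-link solver
    X = structure.coords.copy()
    _place_bridge(structure, X, idx)
    structure = Structure(atoms, X)

    dp = DomainPartition(
        {
            "n_domain": {structure.residues[i] for i in idx["a_res"]},
            "bridge": {structure.residues[i] for i in idx["bridge_res"]},
            "c_domain": {structure.residues[i] for i in idx["b_res"]},
        }
    )
    return structure, dp, idx


def _atom_idx(structure: Structure, res_ordinals: np.ndarray) -> np.ndarray:
    return np.nonzero(np.isin(structure.residue_index, res_ordinals))[0]


def _place_bridge(structure: Structure, X: np.ndarray, idx) -> None:
    """Rebuild the bridge as a sagging hairpin spanning the domain gap.

    The four bridge CAs are placed on a sinusoidal dip between the last
    N-domain CA and the first C-domain CA, with the sag depth solved so
    that consecutive links are ~3 Å when the gap is narrow; as the domains
    separate the chain straightens, providing slack, and no backbone link
    can ever exceed ~4.5 Å because the straight-line spacing stays small.
    """
    n_bridge = len(idx["bridge_res"])
    n_links = n_bridge + 1
    a_last_ca = _atom_idx(structure, idx["a_res"][[-1]])[1]
    b_first_ca = _atom_idx(structure, idx["b_res"][[0]])[1]
    p0 = X[a_last_ca]
    p1 = X[b_first_ca]
    span = p1 - p0
    D = max(np.linalg.norm(span), 1e-9)
    u = span / D
    down = np.array([0.0, -1.0, 0.0])
    down = down - np.dot(down, u) * u
    nd = np.linalg.norm(down)
    down = down / nd if nd > 1e-6 else np.array([0.0, 0.0, -1.0])
    t = np.arange(1, n_bridge + 1) / n_links
    target = 3.0  # Å desired link length when slack is available

    def max_link(h: float) -> float:
        pts = [p0] + [p0 + u * (D * ti) + down * (h * np.sin(np.pi * ti)) for ti in t] + [p1]
        return max(np.linalg.norm(pts[k + 1] - pts[k]) for k in range(n_links))

    lo, hi = 0.0, 10.0
    if max_link(0.0) < target:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if max_link(mid) < target:
                lo = mid
            else:
                hi = mid
    h = lo
    cas = [p0 + u * (D * ti) + down * (h * np.sin(np.pi * ti)) for ti in t]
    offsets = np.array([[-0.6, -0.5, 0.3], [0.7, 0.6, -0.3], [0.5, -1.2, -0.45]])
    for k, rid_ord in enumerate(idx["bridge_res"]):
        ai = _atom_idx(structure, np.array([rid_ord]))
        ca = cas[k]
        X[ai[1]] = ca
        for name_i, off in zip((ai[0], ai[2], ai[3]), offsets):
            X[name_i] = ca + off


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _deform(
    structure: Structure,
    idx,
    theta_a: float,
    theta_b: float,
    separation: float,
    rot_a: np.ndarray | None = None,
    rot_b: np.ndarray | None = None,
    trans_a: np.ndarray | None = None,
    trans_b: np.ndarray | None = None,
    curl_a: float = 0.0,
    curl_b: float = 0.0,
) -> np.ndarray:
    """Apply hinge opening, rigid domain wander and separation; rebuild bridge."""
    X = structure.coords.copy()
    z = np.array([0.0, 0.0, 1.0])
    # hinge: swing each domain's outer strand about its turn CA
    for strand, turn_src, theta, sign in (
        ("a1_res", "a2_res", theta_a, -1),
        ("b2_res", "b1_res", theta_b, +1),
    ):
        ai = _atom_idx(structure, idx[strand])
        hinge_res = idx[strand][-1] if strand == "a1_res" else idx[strand][0]
        # hinge point: CA of the strand residue adjacent to the turn
        hinge_ca = _atom_idx(structure, np.array([hinge_res]))[1]
        pivot = X[hinge_ca]
        R = _rotation(z, sign * theta)
        X[ai] = (X[ai] - pivot) @ R.T + pivot
    # curl: the outer strand's free half folds back about a mid-strand
    # pivot, so late in unfolding the chain makes new (non-native)
    # intra-domain contacts with itself, as collapsing unfolded chains do
    # the curl continues outward (same sense as the hinge) so intermediate
    # angles never swing the segment back into its native cross-strand
    # register
    for strand, curl, sign, from_start in (
        ("a1_res", curl_a, -1, True),
        ("b2_res", curl_b, +1, False),
    ):
        if curl == 0.0:
            continue
        res = idx[strand]
        h = max(2, len(res) // 2)
        seg = res[:h] if from_start else res[-h:]
        pivot_res = res[h] if from_start else res[-h - 1]
        pivot = X[_atom_idx(structure, np.array([pivot_res]))[1]].copy()
        R = _rotation(z, sign * curl)
        ai = _atom_idx(structure, seg)
        X[ai] = (X[ai] - pivot) @ R.T + pivot
    # rigid wander of whole domains about their centroids
    for res_key, R, tr in (("a_res", rot_a, trans_a), ("b_res", rot_b, trans_b)):
        ai = _atom_idx(structure, idx[res_key])
        if R is not None:
            c = X[ai].mean(axis=0)
            X[ai] = (X[ai] - c) @ R.T + c
        if tr is not None:
            X[ai] = X[ai] + tr
    # separation along the interface normal
    ux = np.array([1.0, 0.0, 0.0])
    X[_atom_idx(structure, idx["a_res"])] -= 0.5 * separation * ux
    X[_atom_idx(structure, idx["b_res"])] += 0.5 * separation * ux
    _place_bridge(structure, X, idx)
    return X


def make_toy_two_domain_structure(
    spec: SyntheticSpec | None = None,
) -> tuple[Structure, DomainPartition]:
    """Build the native toy structure and its three-set domain partition.

    Two compact pseudo-β-hairpin domains of 4-atom residues packed across
    an interface plus a 2-residue linker labelled as the bridge; the
    geometry guarantees at least 5 inter-domain residue contacts under the
    package's contact rule.
    """
    spec = spec or SyntheticSpec()
    structure, dp, _ = _build_toy(spec.n_residues_per_domain)
    return structure, dp


def _calibration_curves(structure: Structure, dp: DomainPartition, idx):
    """Measured native-contact loss vs hinge angle and vs separation."""
    from .contacts import atom_contacts, classify_contacts

    native = atom_contacts(structure)
    ref = classify_contacts(native, native, structure, dp)

    thetas = np.linspace(0.0, np.pi / 2, 33)
    seps = np.linspace(0.0, _MAX_SEP, 49)
    loss_theta = np.zeros_like(thetas)
    loss_sep = np.zeros_like(seps)
    for k, th in enumerate(thetas):
        X = _deform(structure, idx, th, th, 0.0)
        counts = classify_contacts(atom_contacts(structure, X), native, structure, dp)
        loss_theta[k] = 1.0 - counts["native_intra"] / ref["native_intra"]
    for k, s in enumerate(seps):
        X = _deform(structure, idx, 0.0, 0.0, s)
        counts = classify_contacts(atom_contacts(structure, X), native, structure, dp)
        loss_sep[k] = 1.0 - counts["native_inter"] / ref["native_inter"]
    # enforce monotonicity so the inverse map is well defined
    loss_theta = np.maximum.accumulate(loss_theta)
    loss_sep = np.maximum.accumulate(loss_sep)
    return (thetas, loss_theta), (seps, loss_sep)


def generate_unfolding_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, TruthRecord]:
    """Generate one unfolding trajectory with programmed ground truth.

    ``two_state``: frames before the transition are the native structure
    plus isotropic jitter; at the transition the conformation jumps onto a
    diverging unfolded branch (immediate partial contact loss followed by
    exponential approach to the programmed end state, with growing
    conformational wander).  ``gradual``: the same end state is approached
    by continuous linear progress over the whole run.  Inter-domain native
    contacts are programmed to be lost ``interface_bias`` times faster
    than intra-domain ones.  Identical seeds give identical trajectories.
    """
    structure, dp, idx = _build_toy(spec.n_residues_per_domain)
    (thetas, loss_theta), (seps, loss_sep) = _calibration_curves(structure, dp, idx)
    theta_cap = np.pi / 2 * min(1.0, max(spec.unfolded_scale - 1.0, 0.05) / 0.6)

    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.save_interval, spec.duration + 0.5 * spec.save_interval,
                      spec.save_interval)
    n_frames = len(times)
    t_star = spec.transition_time

    # unfolding progress p(t) in [0, 1]
    if spec.mode == "two_state":
        tau = max((spec.duration - t_star) / 6.0, spec.save_interval)
        p = np.where(
            times < t_star,
            0.0,
            0.70 + 0.30 * (1.0 - np.exp(-(times - t_star) / tau)),
        )
    else:
        p = times / spec.duration

    l_intra = np.minimum(spec.intra_loss_total * p, 0.95)
    l_inter = np.minimum(spec.interface_bias * spec.intra_loss_total * p, 1.0)
    f_intra = 1.0 - l_intra
    f_inter = 1.0 - l_inter

    # invert the calibration curves to geometric control parameters;
    # plateaus are collapsed so the inverse map (and hence the geometry)
    # is continuous in the programmed loss
    u_th, i_th = np.unique(loss_theta, return_index=True)
    u_sp, i_sp = np.unique(loss_sep, return_index=True)
    theta_t = np.interp(l_intra, u_th, thetas[i_th])
    theta_t = np.minimum(theta_t, theta_cap)
    sep_t = np.interp(l_inter, u_sp, seps[i_sp])

    # unfolded-branch reorientation: each domain acquires a rigid rotation
    # that scales with unfolding progress (a jump at a two_state transition,
    # a continuous ramp in gradual mode), so the unfolded basin is a
    # genuinely distinct region of conformation space
    def _unit(v):
        return v / np.linalg.norm(v)

    rot0_a = 1.3 * _unit(rng.normal(size=3))
    rot0_b = 1.3 * _unit(rng.normal(size=3))

    # post-transition random walks diversify the unfolded ensemble
    active = (p > 0).astype(float)
    d_theta = np.zeros((n_frames, 2))
    rotvec_a = np.zeros((n_frames, 3))
    rotvec_b = np.zeros((n_frames, 3))
    d_sep = np.zeros(n_frames)
    trans_a = np.zeros((n_frames, 3))
    trans_b = np.zeros((n_frames, 3))
    walk_rot = 0.3  # rad per sqrt(frame) of orientational wander
    walk_theta = 0.01
    walk_sep = 0.05
    walk_trans = 0.5  # A per sqrt(frame) of rigid domain drift
    for f in range(1, n_frames):
        a = active[f]
        d_theta[f] = d_theta[f - 1] + a * rng.normal(0, walk_theta, 2)
        rotvec_a[f] = rotvec_a[f - 1] + a * rng.normal(0, walk_rot, 3)
        rotvec_b[f] = rotvec_b[f - 1] + a * rng.normal(0, walk_rot, 3)
        d_sep[f] = d_sep[f - 1] + a * rng.normal(0, walk_sep)
        trans_a[f] = trans_a[f - 1] + a * rng.normal(0, walk_trans, 3)
        trans_b[f] = trans_b[f - 1] + a * rng.normal(0, walk_trans, 3)
    # temporal smoothing keeps the wander velocity continuous so a gradual
    # run drifts steadily instead of in jerks
    from scipy.ndimage import uniform_filter1d

    for arr in (d_theta, rotvec_a, rotvec_b, trans_a, trans_b):
        arr[:] = uniform_filter1d(arr, size=3, axis=0, mode="nearest")
    d_sep[:] = uniform_filter1d(d_sep, size=3, mode="nearest")
    # wander and reorientation ramp with the programmed inter-domain loss:
    # while the interface is still formed the rigid-body moves are tiny (so
    # the realised contact loss stays on its programmed schedule), and they
    # grow only as the interface is already coming apart
    ramp = l_inter / max(l_inter.max(), 1e-9)
    wf = ramp[:, None]
    rotvec_a = (rotvec_a + rot0_a) * wf
    rotvec_b = (rotvec_b + rot0_b) * wf
    # translations slide the domains laterally (the separation axis
    # component is removed) so wander never closes the opened interface
    trans_a = np.clip(trans_a, -4.0, 4.0) * wf
    trans_b = np.clip(trans_b, -4.0, 4.0) * wf
    trans_a[:, 0] = 0.0
    trans_b[:, 0] = 0.0
    d_theta = d_theta * wf
    d_sep = d_sep * wf[:, 0]
    from scipy.spatial.transform import Rotation

    coords = np.empty((n_frames, len(structure), 3))
    for f in range(n_frames):
        # wander magnitudes are taken as absolute offsets so the random
        # walks diversify the unfolded ensemble without ever re-folding it
        th_a = float(min(theta_t[f] + abs(d_theta[f, 0]), np.pi / 2))
        th_b = float(min(theta_t[f] + abs(d_theta[f, 1]), np.pi / 2))
        sp = float(min(sep_t[f] + abs(d_sep[f]), _MAX_SEP + 4.0))
        if p[f] > 0:
            ra = Rotation.from_rotvec(rotvec_a[f]).as_matrix()
            rb = Rotation.from_rotvec(rotvec_b[f]).as_matrix()
        else:
            ra = rb = None
        # chain collapse late in unfolding: the outer strands curl back on
        # themselves once most native structure is lost
        curl = 2.8 * min(max((p[f] - 0.7) / 0.3, 0.0), 1.0)
        X = _deform(structure, idx, th_a, th_b, sp, ra, rb,
                    trans_a=trans_a[f], trans_b=trans_b[f],
                    curl_a=curl, curl_b=curl)
        sigma = spec.native_noise * (1.0 + spec.jitter_growth * p[f])
        if sigma > 0:
            X = X + _smooth_jitter(rng, structure, sigma)
            # independent side-group wobble on non-CA atoms: leaves the
            # backbone trace (and connectivity) alone but lets marginal
            # atom pairs flicker across the contact cutoffs as in thermal
            # motion
            wobble = rng.normal(0.0, 0.5 * sigma, X.shape)
            wobble[structure.ca_indices] = 0.0
            X = X + wobble
        _clamp_links(structure, X)
        coords[f] = X

    traj = Trajectory(structure, coords, times)
    truth = TruthRecord(
        transition_time=t_star,
        mode=spec.mode,
        interface_bias=spec.interface_bias,
        seed=spec.seed,
        times=times,
        f_intra=f_intra,
        f_inter=f_inter,
    )
    return traj, truth
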