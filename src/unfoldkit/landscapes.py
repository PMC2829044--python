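"""Unfolding landscapes, barrier-crossing detection and TSE extraction.

Two landscape constructions over the pooled frames of all unfolding runs:

* a 2-D histogram of native residue–residue contacts against non-polar
  SASA (bin sizes 5 contacts and 50 Å²), and
* a PCA landscape: ten per-frame conformational properties (Cα RMSD to
  the crystal structure; native/non-native × intra/inter-domain atom
  contacts; radius of gyration; non-polar and polar SASA; native and
  non-native main-chain hydrogen bonds) are z-scaled and reduced to two
  principal components, histogrammed at 0.1-unit bins.

Bin values are the negative natural log of the counts, so
``sum(exp(-value))`` over occupied bins recovers the frame count.  These
are sampling landscapes of non-equilibrium runs, not free-energy surfaces.

Each trajectory crosses the native/non-native bottleneck of either
landscape once; the ten frames (10 ps at 1 ps saves) spanning each run's
crossing are pooled into the transition-state ensemble — five runs give a
50-member TSE.  The per-residue deviation map superposes every member
onto the crystal structure (ordinary least squares over all Cα) and
averages per-Cα deviations across members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError
from .structure_io import DomainPartition, Structure, Trajectory
from .superpose import kabsch_superpose

__all__ = [
    "PCA_COLUMNS",
    "PropertyTable",
    "Landscape2D",
    "PCAModel",
    "TransitionStateEnsemble",
    "NoCrossing",
    "CrossingResult",
    "per_frame_properties",
    "histogram_landscape",
    "pca_landscape",
    "detect_barrier_crossing",
    "auto_regions",
    "extract_tse",
    "tse_deviation_map",
    "BoxRegion",
    "BinRegion",
    "RadialRegion",
]

#: The ten z-scaled inputs of the PCA landscape, in fixed column order.
PCA_COLUMNS = [
    "ca_rmsd",
    "native_intra_atom",
    "native_inter_atom",
    "nonnative_intra_atom",
    "nonnative_inter_atom",
    "radius_of_gyration",
    "npsasa",
    "psasa",
    "nonnative_hbonds",
    "native_hbonds",
]


@dataclass
class PropertyTable:
    """Per-frame values of the landscape properties.

    ``df`` holds the ten PCA columns plus ``native_residue_contacts`` (the
    x-axis of the 2-D landscape) indexed by frame, with ``times`` in ps.
    ``run`` optionally labels which trajectory each frame came from when
    tables are concatenated.
    """

    times: np.ndarray
    df: pd.DataFrame
    run: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def concat(tables: Sequence["PropertyTable"]) -> "PropertyTable":
        times = np.concatenate([t.times for t in tables])
        runs = np.concatenate(
            [np.full(len(t), i) if t.run is None else t.run for i, t in enumerate(tables)]
        )
        return PropertyTable(
            times=times, df=pd.concat([t.df for t in tables], ignore_index=True), run=runs
        )

    def save(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "time_ps", self.times)
        if self.run is not None:
            out.insert(0, "run", self.run)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t")
        run = df.pop("run").to_numpy() if "run" in df else None
        times = df.pop("time_ps").to_numpy()
        return cls(times=times, df=df, run=run)


@dataclass
class Landscape2D:
    """−ln(count) histogram over a fixed origin-anchored grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) integer counts
    x_label: str = "x"
    y_label: str = "y"

    @property
    def values(self) -> np.ndarray:
        """−ln(count) for occupied bins, NaN for unobserved bins."""
        with np.errstate(divide="ignore"):
            v = -np.log(self.counts.astype(float))
        v[self.counts == 0] = np.nan
        return v

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        ix = int(np.searchsorted(self.x_edges, x, side="right")) - 1
        iy = int(np.searchsorted(self.y_edges, y, side="right")) - 1
        return ix, iy

    def to_table(self) -> pd.DataFrame:
        ix, iy = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "x_bin": self.x_edges[ix],
                "y_bin": self.y_edges[iy],
                "count": self.counts[ix, iy],
                "value": self.values[ix, iy],
            }
        )


@dataclass
class PCAModel:
    """Z-scaling plus loadings of the property PCA."""

    means: np.ndarray
    stds: np.ndarray
    loadings: np.ndarray  # (10, k), orthonormal columns
    explained_variance_fractions: np.ndarray
    scores: np.ndarray  # (n, k)
    columns: list[str] = field(default_factory=lambda: list(PCA_COLUMNS))


@dataclass
class TransitionStateEnsemble:
    """Pooled barrier-crossing frames from one or more runs."""

    topology: Structure
    coords: np.ndarray  # (n_members, n_atoms, 3)
    times: np.ndarray  # ps within the source run
    run: np.ndarray  # source run index per member
    crossing_times: list[float]

    @property
    def n_members(self) -> int:
        return self.coords.shape[0]

    def summary(self, crystal: Structure | None = None) -> dict[str, float]:
        out: dict[str, float] = {"n_members": float(self.n_members)}
        if crystal is not None:
            ca = self.topology.ca_indices
            rmsds = [
                kabsch_superpose(self.coords[i][ca], crystal.coords[ca]).rmsd
                for i in range(self.n_members)
            ]
            out["mean_ca_rmsd"] = float(np.mean(rmsds))
            out["sd_ca_rmsd"] = float(np.std(rmsds))
        return out


# ---------------------------------------------------------------------------
# Per-frame properties
# ---------------------------------------------------------------------------

def per_frame_properties(
    traj: Trajectory,
    crystal: Structure,
    dp: DomainPartition,
    sasa_points: int = 240,
) -> PropertyTable:
    """Compute the ten landscape properties (plus native residue contacts).

    The crystal structure supplies the native contact and hydrogen-bond
    references and the Cα RMSD target (single-fit superposition — the
    two-fit rule is reserved for clustering, ALF and cooperativity).
    ``sasa_points`` trades SASA quadrature resolution against runtime for
    long trajectories.
    """
    from .contacts import atom_contacts, frame_contact_table, mainchain_hbonds
    from .surface import sasa_series

    if len(crystal) != len(traj.topology):
        raise AnalysisError("crystal structure does not share the trajectory topology")
    native = atom_contacts(crystal)
    native_hb = mainchain_hbonds(crystal)
    table = frame_contact_table(traj.topology, traj.coords, native, dp)

    ca = traj.topology.ca_indices
    crystal_ca = crystal.coords[ca]
    n_frames = len(traj)
    ca_rmsd = np.empty(n_frames)
    rg = np.empty(n_frames)
    nat_hb = np.empty(n_frames, dtype=int)
    nonnat_hb = np.empty(n_frames, dtype=int)
    for f in range(n_frames):
        X = traj.coords[f]
        try:
            ca_rmsd[f] = kabsch_superpose(X[ca], crystal_ca).rmsd
        except Exception as exc:  # pragma: no cover - degenerate frames
            raise AnalysisError(f"superposition failed at frame {f}: {exc}") from exc
        centred = X - X.mean(axis=0)
        rg[f] = np.sqrt((centred**2).sum(axis=1).mean())
        nat_hb[f], nonnat_hb[f] = mainchain_hbonds(traj.topology, X, native_ref=native_hb)
    areas = sasa_series(traj, n_points=sasa_points)
    np_mask = traj.topology.nonpolar_mask
    df = pd.DataFrame(
        {
            "ca_rmsd": ca_rmsd,
            "native_intra_atom": table["native_intra_atom"],
            "native_inter_atom": table["native_inter_atom"],
            "nonnative_intra_atom": table["nonnative_intra_atom"],
            "nonnative_inter_atom": table["nonnative_inter_atom"],
            "radius_of_gyration": rg,
            "npsasa": areas[:, np_mask].sum(axis=1),
            "psasa": areas[:, ~np_mask].sum(axis=1),
            "nonnative_hbonds": nonnat_hb,
            "native_hbonds": nat_hb,
            "native_residue_contacts": table["native_residue_contacts"],
        }
    )
    return PropertyTable(times=traj.times.copy(), df=df)


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------

def histogram_landscape(
    x: np.ndarray,
    y: np.ndarray,
    bin_x: float,
    bin_y: float,
    origin: tuple[float, float] = (0.0, 0.0),
    labels: tuple[str, str] = ("x", "y"),
) -> Landscape2D:
    """−ln(count) 2-D histogram on a grid anchored at ``origin``.

    The default bins for the contacts × NPSASA landscape are 5 native
    contacts by 50 Å².  Unoccupied bins are flagged (NaN in ``values``)
    rather than given an arbitrary large value.
    """
    if bin_x <= 0 or bin_y <= 0:
        raise ParameterError("bin sizes must be positive")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ParameterError("x and y series must have equal length")

    def edges(v, b, o):
        lo = np.floor((v.min() - o) / b) * b + o
        hi = np.ceil((v.max() - o) / b) * b + o
        if hi <= lo:
            hi = lo + b
        return np.arange(lo, hi + 0.5 * b, b)

    ex = edges(x, bin_x, origin[0])
    ey = edges(y, bin_y, origin[1])
    counts, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    return Landscape2D(
        x_edges=ex, y_edges=ey, counts=counts.astype(int),
        x_label=labels[0], y_label=labels[1],
    )


def pca_landscape(
    pt: PropertyTable,
    bin_size: float = 0.1,
    n_components: int = 2,
) -> tuple[PCAModel, Landscape2D]:
    """Z-scale the ten properties, run PCA, and histogram (PC1, PC2).

    Each component is oriented so that the mean score of the earliest 10%
    of frames is negative (native conformations sit at low PC1).  The
    histogram grid is anchored at −5.0 on both axes so bin identity is
    deterministic across runs.

    Raises
    ------
    AnalysisError
        Naming the column, if any property has zero variance.
    """
    from sklearn.decomposition import PCA

    X = pt.df[PCA_COLUMNS].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise AnalysisError("property table contains missing values")
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    for name, s in zip(PCA_COLUMNS, stds):
        if s == 0:
            raise AnalysisError(f"property column {name!r} has zero variance; cannot z-scale")
    Z = (X - means) / stds
    pca = PCA(n_components=min(len(PCA_COLUMNS), max(n_components, 2)))
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # (10, k)
    # orient: earliest 10% of frames (per pooled table order) score negative
    n_early = max(1, len(Z) // 10)
    order = np.argsort(pt.times, kind="stable")
    early = order[:n_early]
    flip = np.where(scores[early].mean(axis=0) > 0, -1.0, 1.0)
    scores = scores * flip
    loadings = loadings * flip
    model = PCAModel(
        means=means,
        stds=stds,
        loadings=loadings,
        explained_variance_fractions=pca.explained_variance_ratio_,
        scores=scores,
    )
    ls = histogram_landscape(
        scores[:, 0], scores[:, 1], bin_size, bin_size,
        origin=(-5.0, -5.0), labels=("PC1", "PC2"),
    )
    return model, ls


# ---------------------------------------------------------------------------
# Barrier crossing
# ---------------------------------------------------------------------------

class NoCrossing:
    """Sentinel: the trajectory never reached the non-native region."""

    def __repr__(self) -> str:
        return "NoCrossing"


NO_CROSSING = NoCrossing()


@dataclass
class CrossingResult:
    crossing_time: float  # last time inside native before the final departure
    n_crossings: int


class BoxRegion:
    """Axis-aligned region on landscape coordinates; None bounds are open."""

    def __init__(self, xmin=None, xmax=None, ymin=None, ymax=None):
        self.bounds = (xmin, xmax, ymin, ymax)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.bounds
        m = np.ones_like(np.asarray(x, float), dtype=bool)
        if xmin is not None:
            m &= x >= xmin
        if xmax is not None:
            m &= x <= xmax
        if ymin is not None:
            m &= y >= ymin
        if ymax is not None:
            m &= y <= ymax
        return m


class BinRegion:
    """Region defined by a set of occupied landscape bins."""

    def __init__(self, landscape: Landscape2D, bin_mask: np.ndarray):
        self.landscape = landscape
        self.bin_mask = bin_mask

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ls = self.landscape
        ix = np.clip(np.searchsorted(ls.x_edges, x, side="right") - 1, 0, ls.counts.shape[0] - 1)
        iy = np.clip(np.searchsorted(ls.y_edges, y, side="right") - 1, 0, ls.counts.shape[1] - 1)
        return self.bin_mask[ix, iy]


class RadialRegion:
    """Region by distance to a centroid, in per-axis scaled units.

    ``side='inside'`` keeps points within the radius, ``'outside'`` the
    points at or beyond it.
    """

    def __init__(self, center, radius: float, scales, side: str = "inside"):
        self.center = np.asarray(center, float)
        self.radius = float(radius)
        self.scales = scales
        self.side = side

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = np.column_stack([np.asarray(x, float) / self.scales[0],
                             np.asarray(y, float) / self.scales[1]])
        return np.linalg.norm(u - self.center, axis=1)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        d = self.distance(x, y)
        return d <= self.radius if self.side == "inside" else d >= self.radius


def auto_regions(
    landscape: Landscape2D,
    x: np.ndarray,
    y: np.ndarray,
    times: np.ndarray,
) -> tuple[RadialRegion, RadialRegion]:
    """Self-calibrating native and non-native basins on landscape coordinates.

    Both axes are scaled by their standard deviation over all frames.  The
    native basin is a disc around the centroid of the earliest 5% of
    frames; the non-native basin is everything beyond an outer radius near
    the centroid distance of the latest 20% of frames (the endpoint
    ensemble).  The two radii bracket the gap between the native
    ensemble's own scatter (90th-percentile centroid distance of the early
    frames) and the endpoint ensemble's 5th-percentile distance, with 15%
    margins, so frames between them count as in-transit under the crossing
    rule.  Distance to the native centroid is direction-free, which keeps
    broad excursions of the unfolded ensemble from ever reading as a
    return to the native basin.  Explicit :class:`BoxRegion` /
    :class:`BinRegion` thresholds always override this automation.

    Raises
    ------
    AnalysisError
        If the endpoint ensemble does not separate from the native
        ensemble's scatter.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = float(x.std()) or 1.0
    sy = float(y.std()) or 1.0
    u = np.column_stack([x / sx, y / sy])
    order = np.argsort(np.asarray(times, float), kind="stable")
    early = order[: max(5, len(order) // 20)]
    late = order[-max(5, len(order) // 5):]

    center = u[early].mean(axis=0)
    d = np.linalg.norm(u - center, axis=1)
    r_early = float(np.percentile(d[early], 90))
    r_late = float(np.percentile(d[late], 5))
    gap = r_late - r_early
    if gap <= 0:
        raise AnalysisError("the endpoint ensemble does not separate from the "
                            "native one; supply explicit regions")
    scales = (sx, sy)
    # the outer radius sits mid-gap: a frame clearly beyond the native
    # scatter but not yet at the endpoint cloud has still left the basin
    return (
        RadialRegion(center, r_early + 0.15 * gap, scales, "inside"),
        RadialRegion(center, r_early + 0.5 * gap, scales, "outside"),
    )


def detect_barrier_crossing(
    x: np.ndarray,
    y: np.ndarray,
    times: np.ndarray,
    native_region: Callable[[np.ndarray, np.ndarray], np.ndarray],
    nonnative_region: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> CrossingResult | NoCrossing:
    """Locate the native→non-native barrier crossing of one run.

    A crossing is a passage from the native region to the non-native
    region without re-entering the native region in between.  The
    crossing itself happens between two saved frames, so the reported
    ``crossing_time`` is the midpoint between the last time in the native
    region (with no subsequent return) and the first time in the
    non-native region after it; ``n_crossings`` counts every passage (a
    cooperative run crosses once).  Returns :data:`NO_CROSSING` if the
    non-native region is never reached after the last native visit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    in_nat = np.asarray(native_region(x, y), bool)
    in_non = np.asarray(nonnative_region(x, y), bool)
    if not in_nat.any():
        raise AnalysisError("trajectory never visits the native region")
    n_crossings = 0
    state = None
    for f in range(len(x)):
        if in_nat[f]:
            state = "native"
        elif in_non[f] and state == "native":
            n_crossings += 1
            state = "nonnative"
    last_native = int(np.nonzero(in_nat)[0][-1])
    after = np.nonzero(in_non[last_native + 1 :])[0]
    if len(after) == 0:
        return NO_CROSSING
    first_non = last_native + 1 + int(after[0])
    crossing = 0.5 * (float(times[last_native]) + float(times[first_non]))
    return CrossingResult(crossing_time=crossing, n_crossings=n_crossings)


# ---------------------------------------------------------------------------
# TSE
# ---------------------------------------------------------------------------

def extract_tse(
    trajs: Sequence[Trajectory],
    crossing_times: Sequence[float],
    window: float = 10.0,
) -> TransitionStateEnsemble:
    """Pool the frames spanning each run's barrier crossing.

    For each trajectory the ``window/save_interval`` frames centred on its
    crossing time are taken (10 frames for a 10 ps window at 1 ps saves);
    all runs' frames are pooled, so five runs yield a 50-member ensemble.

    Raises
    ------
    ParameterError
        If a window extends beyond its trajectory.
    """
    if len(trajs) != len(crossing_times):
        raise ParameterError("need one crossing time per trajectory")
    coords, times, runs = [], [], []
    for k, (traj, tc) in enumerate(zip(trajs, crossing_times)):
        dt = traj.save_interval
        m = int(round(window / dt))
        if m < 1:
            raise ParameterError("window smaller than one save interval")
        half = window / 2.0
        sel = np.nonzero((traj.times > tc - half) & (traj.times <= tc + half))[0]
        if len(sel) != m:
            raise ParameterError(
                f"crossing window [{tc - half}, {tc + half}] ps does not lie fully "
                f"inside trajectory {k} (found {len(sel)} of {m} frames)"
            )
        coords.append(traj.coords[sel])
        times.append(traj.times[sel])
        runs.append(np.full(len(sel), k))
    return TransitionStateEnsemble(
        topology=trajs[0].topology,
        coords=np.concatenate(coords),
        times=np.concatenate(times),
        run=np.concatenate(runs),
        crossing_times=[float(t) for t in crossing_times],
    )


def tse_deviation_map(tse: TransitionStateEnsemble, crystal: Structure) -> np.ndarray:
    """Mean per-Cα deviation from the crystal structure over TSE members.

    Every member is superposed onto the crystal by ordinary least squares
    over all Cα atoms and the per-Cα deviations are averaged across
    members.  Returns one value per residue (Å), in residue order; write
    it into a B-factor-coded PDB with
    :func:`unfoldkit.structure_io.write_structure`.
    """
    if tse.n_members < 1:
        raise ParameterError("TSE has no members")
    ca = tse.topology.ca_indices
    target = crystal.coords[ca]
    devs = np.zeros((tse.n_members, len(ca)))
    for i in range(tse.n_members):
        devs[i] = kabsch_superpose(tse.coords[i][ca], target).per_atom_deviation
    return devs.mean(axis=0)
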