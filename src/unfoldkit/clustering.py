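"""Conformational clustering by classical multidimensional scaling.

The all-versus-all two-fit Cα RMSD matrix is embedded into three
dimensions with classical (Torgerson) MDS: squared distances are
double-centered, the top eigenpairs extracted, and coordinates scaled by
the square roots of the eigenvalues.  In the embedding a cooperative
unfolding run shows a tight native cluster followed by a sparse excursion
into unfolded space; the exit from the native cluster locates the
transition state.

The original procedure identified the native-cluster exit visually.  The
automated surrogate here estimates the native cluster from an early
presumed-native window (centroid plus a 95th-percentile radius) and
reports the time of permanent departure: the last frame inside the radius
such that no later frame re-enters.  Outputs derived from it are labelled
as coming from this surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .superpose import DistanceMatrix

__all__ = ["Embedding", "classical_mds", "native_cluster_exit", "NoExit"]


class NoExit:
    """Sentinel: the trajectory never (permanently) left the native cluster."""

    def __repr__(self) -> str:
        return "NoExit"


NO_EXIT = NoExit()


@dataclass
class Embedding:
    """Low-dimensional MDS coordinates of the conformations."""

    coords: np.ndarray  # (n, d), columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # first d eigenvalues, descending
    times: np.ndarray

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.times, self.coords])


def classical_mds(dm: DistanceMatrix, d: int = 3) -> Embedding:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, takes the top-``d`` spectral
    decomposition and scales eigenvectors by the square roots of the
    eigenvalues.  Negative eigenvalues (the RMSD matrix need not be
    Euclidean) are truncated to zero with a warning.  The sign of each
    coordinate axis is fixed by making the first frame's coordinate
    non-negative.

    Raises
    ------
    ParameterError
        If ``d`` exceeds the number of conformations.
    """
    n = dm.n
    if d > n:
        raise ParameterError(f"d={d} exceeds the number of conformations ({n})")
    D2 = np.asarray(dm.values, float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:d]
    vals = vals[order]
    vecs = vecs[:, order]
    if np.any(vals < -1e-8 * max(1.0, abs(vals[0]))):
        import warnings

        warnings.warn(
            "distance matrix is not Euclidean: negative eigenvalues truncated to zero",
            stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    coords = vecs * np.sqrt(vals)
    coords = coords - coords.mean(axis=0)  # centred columns
    sign = np.where(coords[0] < 0, -1.0, 1.0)
    coords = coords * sign
    return Embedding(coords=coords, eigenvalues=vals, times=np.asarray(dm.times, float))


def native_cluster_exit(
    emb: Embedding,
    native_window: float,
    radius_percentile: float = 95.0,
    radius_scale: float = 1.5,
) -> float | NoExit:
    """Time of permanent departure from the native cluster.

    The native centroid and radius (``radius_percentile`` of the early
    frames' centroid distances) are estimated from all frames with
    ``time <= native_window`` (which must cover at least 10 frames).
    Because a short native window samples the thermal spread of the native
    cluster sparsely, the radius is widened by ``radius_scale``; the
    native/unfolded separation in the embedding is typically an order of
    magnitude larger than the native radius, so the scale does not blur
    the exit.  The exit is the last frame inside the radius after which no
    later frame re-enters — a brief excursion-and-return does not count,
    only the final departure.  Returns :data:`NO_EXIT` when the last frame
    is still inside the cluster.
    """
    early = emb.times <= native_window
    if early.sum() < 10:
        raise ParameterError("native_window must cover at least 10 early frames")
    centroid = emb.coords[early].mean(axis=0)
    dists = np.linalg.norm(emb.coords - centroid, axis=1)
    radius = radius_scale * np.percentile(dists[early], radius_percentile)
    inside = dists <= radius
    if inside[-1]:
        return NO_EXIT
    last_inside = int(np.nonzero(inside)[0][-1])
    return float(emb.times[last_inside])
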