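"""Rigid-body superposition and two-fit Cα RMSD.

The central quantity is the *two-fit* Cα RMSD between two conformations:
all Cα atoms are superposed by least squares (Kabsch), per-atom deviations
are collected, atoms deviating by more than the mean plus two standard
deviations are discarded, and a second superposition and RMSD are computed
over the remainder only.  Exactly two passes are made — the rule is not
iterated — and the exclusion threshold is a strict inequality, so ties are
kept.  The second-pass RMSD is evaluated over the retained atoms only,
which guarantees two-fit RMSD <= one-fit RMSD for every pair.

All pairwise comparisons are computed with a vectorised (batched 3x3 SVD)
implementation so that the N x N matrices used for conformational
clustering, ALF and the cooperativity profile stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import GeometryError, ParameterError
from .structure_io import Trajectory

__all__ = [
    "SuperpositionResult",
    "DistanceMatrix",
    "TwoFitResult",
    "kabsch_superpose",
    "one_fit_rmsd",
    "two_fit_rmsd",
    "pairwise_matrix",
    "running_average",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform of ``mobile`` onto ``target``.

    ``rotation @ x + translation`` maps mobile coordinates into the target
    frame.  ``per_atom_deviation`` holds the post-fit distance of each
    aligned atom pair and ``rmsd`` their root mean square.
    """

    rotation: np.ndarray
    translation: np.ndarray
    per_atom_deviation: np.ndarray
    rmsd: float


class TwoFitResult(NamedTuple):
    rmsd: float
    n_excluded: int
    fallback: bool  # True when <3 atoms survived and the one-fit RMSD was used


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Cα RMSDs with the frame times."""

    values: np.ndarray
    times: np.ndarray
    mean_excluded_fraction: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def save(self, path) -> None:
        """Plain-text square matrix with a header row of frame times (ps)."""
        header = " ".join(f"{t:.6g}" for t in self.times)
        np.savetxt(path, self.values, fmt="%.6f", header=header)

    @classmethod
    def load(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        values = np.loadtxt(path)
        return cls(values=np.atleast_2d(values), times=np.array(header, dtype=float))


def _check_coords(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise GeometryError(f"{name} must be an (n, 3) coordinate array")
    if x.shape[0] < 3:
        raise GeometryError(f"{name} needs at least 3 atoms, got {x.shape[0]}")
    centered = x - x.mean(axis=0)
    # collinear (or coincident) point sets leave the rotation under-determined
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError(f"{name} is degenerate (collinear or coincident points)")
    return x


def _rotations_from_cov(H: np.ndarray) -> np.ndarray:
    """Proper rotations R (…,3,3) maximising tr(R @ H^T) from covariances H.

    ``H = sum_i a_i b_i^T`` for centered mobile ``a`` and target ``b``; the
    returned R satisfies ``R @ a_i ~ b_i`` in the least-squares sense with
    reflections excluded (det R = +1).
    """
    U, _, Vt = np.linalg.svd(H)
    V = np.swapaxes(Vt, -1, -2)
    d = np.sign(np.linalg.det(V @ np.swapaxes(U, -1, -2)))
    d = np.where(d == 0, 1.0, d)
    V = V.copy()
    V[..., :, -1] *= d[..., None]
    return V @ np.swapaxes(U, -1, -2)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (no reflection) and translation minimising
    the RMSD between the two equal-length Cα coordinate sets, together with
    the per-atom deviations under the optimal transform.

    Raises
    ------
    GeometryError
        For fewer than 3 atoms, mismatched lengths, or degenerate
        (collinear) geometry.
    """
    mobile = _check_coords(mobile, "mobile")
    target = _check_coords(target, "target")
    if mobile.shape != target.shape:
        raise GeometryError("mobile and target must have equal atom counts")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)  # sum_i a_i b_i^T
    R = _rotations_from_cov(H[None])[0]
    t = mu_t - R @ mu_m
    dev = np.linalg.norm(mobile @ R.T + t - target, axis=1)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        per_atom_deviation=dev,
        rmsd=float(np.sqrt(np.mean(dev**2))),
    )


def one_fit_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain least-squares Cα RMSD (single superposition, all atoms)."""
    return kabsch_superpose(a, b).rmsd


def _two_fit_block(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-fit RMSD for paired coordinate sets.

    A, B : (p, n, 3) — p independent pairs aligned over the same n atoms.
    Returns (rmsd, n_excluded, fallback) each of shape (p,).
    """
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    H = np.einsum("pni,pnj->pij", A, B)
    R = _rotations_from_cov(H)
    dev = np.linalg.norm(np.einsum("pij,pnj->pni", R, A) - B, axis=2)
    mu = dev.mean(axis=1, keepdims=True)
    sd = dev.std(axis=1, keepdims=True)
    # strict '>' excluded; ties kept.  The small absolute epsilon keeps
    # numerically-zero deviations (identical structures) from being flagged.
    keep = dev <= mu + 2.0 * sd + 1e-8
    n_excluded = (~keep).sum(axis=1)
    fallback = keep.sum(axis=1) < 3
    keep[fallback] = True
    w = keep.astype(float)
    wsum = w.sum(axis=1)
    A2 = A - (w[:, :, None] * A).sum(axis=1, keepdims=True) / wsum[:, None, None]
    B2 = B - (w[:, :, None] * B).sum(axis=1, keepdims=True) / wsum[:, None, None]
    H2 = np.einsum("pni,pnj->pij", w[:, :, None] * A2, B2)
    R2 = _rotations_from_cov(H2)
    dev2 = np.linalg.norm(np.einsum("pij,pnj->pni", R2, A2) - B2, axis=2)
    rmsd = np.sqrt((w * dev2**2).sum(axis=1) / wsum)
    return rmsd, n_excluded, fallback


def two_fit_rmsd(a: np.ndarray, b: np.ndarray) -> TwoFitResult:
    """Two-fit Cα RMSD between two conformations.

    First fit over all Cα atoms; atoms whose deviations exceed the mean
    plus two standard deviations are discarded; a second fit and the RMSD
    are computed over the retained atoms only.  If fewer than 3 atoms
    survive, the one-fit RMSD is returned with ``fallback=True``.
    """
    a = _check_coords(a, "a")
    b = _check_coords(b, "b")
    if a.shape != b.shape:
        raise GeometryError("conformations must have equal atom counts")
    rmsd, nexc, fb = _two_fit_block(a[None], b[None])
    if fb[0]:
        return TwoFitResult(one_fit_rmsd(a, b), 0, True)
    return TwoFitResult(float(rmsd[0]), int(nexc[0]), False)


def pairwise_matrix(
    traj: Trajectory | np.ndarray,
    stride: float | None = None,
    times: np.ndarray | None = None,
    two_fit: bool = True,
) -> DistanceMatrix:
    """All-versus-all (two-fit) Cα RMSD matrix at the requested stride.

    Accepts a Trajectory (Cα atoms are selected and, when ``stride`` is
    given, frames are subsampled to it) or a raw ``(n_frames, n_ca, 3)``
    array with explicit ``times``.  The result is exactly symmetric with a
    zero diagonal; ``mean_excluded_fraction`` reports the average fraction
    of Cα atoms discarded by the two-fit rule over all pairs.
    """
    if isinstance(traj, Trajectory):
        t = traj.strided(stride) if stride is not None else traj
        X = t.ca_coords()
        times = t.times
    else:
        X = np.asarray(traj, dtype=float)
        if times is None:
            raise ParameterError("times must be given with a raw coordinate array")
    F, n_atoms = X.shape[0], X.shape[1]
    if F < 2:
        raise ParameterError("need at least 2 frames for a pairwise matrix")
    M = np.zeros((F, F))
    excluded_total = 0.0
    n_pairs = 0
    for i in range(F - 1):
        A = np.broadcast_to(X[i], (F - i - 1, n_atoms, 3))
        B = X[i + 1 :]
        if two_fit:
            rmsd, nexc, _ = _two_fit_block(A, B)
            excluded_total += float(nexc.sum())
        else:
            Ac = A - A.mean(axis=1, keepdims=True)
            Bc = B - B.mean(axis=1, keepdims=True)
            H = np.einsum("pni,pnj->pij", Ac, Bc)
            R = _rotations_from_cov(H)
            dev = np.linalg.norm(np.einsum("pij,pnj->pni", R, Ac) - Bc, axis=2)
            rmsd = np.sqrt((dev**2).mean(axis=1))
        M[i, i + 1 :] = rmsd
        M[i + 1 :, i] = rmsd
        n_pairs += F - i - 1
    frac = excluded_total / (n_pairs * n_atoms) if two_fit else 0.0
    return DistanceMatrix(values=M, times=np.asarray(times, float), mean_excluded_fraction=frac)


def running_average(series: np.ndarray, window: float, interval: float = 1.0) -> np.ndarray:
    """Centered moving mean over a ``window`` ps span of a regular series.

    The window must be an odd multiple of the series interval (the default
    smoothing used for time-series figures is 19 points, i.e. 0.019 ns at
    1 ps).  Edges use the truncated window.
    """
    series = np.asarray(series, dtype=float)
    if interval <= 0 or window < interval:
        raise ParameterError("window must span at least one series interval")
    n_pts = window / interval
    if abs(n_pts - round(n_pts)) > 1e-9 or int(round(n_pts)) % 2 == 0:
        raise ParameterError("window must be an odd multiple of the series interval")
    k = int(round(n_pts))
    kernel = np.ones(k)
    sums = np.convolve(series, kernel, mode="same")
    counts = np.convolve(np.ones_like(series), kernel, mode="same")
    return sums / counts
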