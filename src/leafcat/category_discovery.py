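"""Shape-category discovery by mean-shift in the whitened morphospace.

A shape category is a basin of attraction of the kernel density estimate
built over the morphospace points.  Two bandwidth policies are supported:

* fixed: one global bandwidth h for every point (classic mean-shift);
* adaptive: each sample carries its own bandwidth h_i, the mean Euclidean
  distance to its k nearest neighbors (k = 8 by default) — the
  sample-point adaptive estimator, which widens kernels in sparse regions.

The module also exposes the sphere-overlap view used for visualization
(spheres of radius ε_i centered on the points; overlapping spheres form
connected components) and prototype selection (the member closest to the
cluster centroid).  Everything here is deterministic given the input
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist


@dataclass
class BandwidthSet:
    """Either one global bandwidth or one bandwidth per sample."""

    global_h: float | None = None
    per_sample_h: np.ndarray | None = None
    k_neighbors: int = 8

    def __post_init__(self) -> None:
        if (self.global_h is None) == (self.per_sample_h is None):
            raise ValueError(
                "exactly one of global_h / per_sample_h must be given")
        if self.global_h is not None and self.global_h <= 0:
            raise ValueError("global_h must be positive")

    def resolve(self, n: int) -> np.ndarray:
        if self.global_h is not None:
            return np.full(n, float(self.global_h))
        h = np.asarray(self.per_sample_h, dtype=float)
        if len(h) != n:
            raise ValueError("per_sample_h length mismatch")
        if np.any(h <= 0):
            raise ValueError("per-sample bandwidths must be positive")
        return h


@dataclass
class ClusterResult:
    """Partition of the samples plus the density machinery that made it."""

    labels: np.ndarray  # contiguous ids 0..n_clusters-1
    modes: np.ndarray  # (n_clusters, d)
    bandwidths: BandwidthSet
    sphere_radii: np.ndarray  # per-sample ε for the sphere view
    prototypes: np.ndarray  # one sample index per cluster
    n_clusters: int
    converged: bool = True
    n_iter: int = 0

    def to_csv(self, sample_ids, path) -> None:
        is_proto = np.zeros(len(self.labels), dtype=bool)
        is_proto[self.prototypes] = True
        pd.DataFrame({
            "sample_id": list(sample_ids),
            "cluster": self.labels,
            "is_prototype": is_proto,
        }).to_csv(path, index=False)


def knn_bandwidths(points: np.ndarray, k: int = 8) -> np.ndarray:
    """h_i = mean Euclidean distance from point i to its k nearest neighbors.

    The point itself is excluded from its neighbor list; distance ties are
    broken by ascending sample index (stable sort over the full distance
    matrix — exact, adequate at morphospace sizes).
    """
    x = np.asarray(points, dtype=float)
    n = len(x)
    if n <= k:
        raise ValueError(f"need more points than neighbors (n={n}, k={k})")
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)  # exclude self
    order = np.argsort(d, axis=1, kind="stable")
    nearest = np.take_along_axis(d, order[:, :k], axis=1)
    return nearest.mean(axis=1)


def kernel_density(
    at: np.ndarray,
    data: np.ndarray,
    bandwidths: BandwidthSet | np.ndarray,
    kernel: str = "gaussian",
) -> np.ndarray:
    """Sample-point KDE f̂(u) = (1/n) Σ_i h_i^{-d} K((u − u_i)/h_i)."""
    x = np.asarray(data, dtype=float)
    y = np.atleast_2d(np.asarray(at, dtype=float))
    n, d = x.shape
    h = (bandwidths.resolve(n) if isinstance(bandwidths, BandwidthSet)
         else np.asarray(bandwidths, dtype=float))
    u2 = cdist(y, x, "sqeuclidean") / h**2
    if kernel == "gaussian":
        k = np.exp(-0.5 * u2) / (2 * np.pi) ** (d / 2)
    elif kernel == "flat":
        k = (u2 <= 1.0).astype(float)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return (k * h ** (-d)).sum(axis=1) / n


def mean_shift(
    points: np.ndarray,
    bandwidths: BandwidthSet,
    kernel: str = "gaussian",
    tol: float = 1e-5,
    max_iter: int = 300,
    merge_radius: float | None = None,
) -> ClusterResult:
    """Cluster points by iterating them to the modes of the KDE.

    Every point ascends the sample-point density estimate: the shifted
    position is the kernel-weighted mean of all data points, each datum
    contributing with its own bandwidth h_i (weights include the
    h_i^{-(d+2)} factor of the sample-point gradient).  Converged
    positions closer than ``merge_radius`` (default: min bandwidth / 2)
    are merged into one mode; labels are basin memberships.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("points must be 2-D (n, d)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    n, d = x.shape
    h = bandwidths.resolve(n)
    if merge_radius is None:
        merge_radius = float(h.min()) / 2.0

    cw = h ** (-(d + 2))  # sample-point gradient weights
    y = x.copy()
    active = np.ones(n, dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ya = y[active]
        u2 = cdist(ya, x, "sqeuclidean") / h**2
        if kernel == "gaussian":
            w = cw * np.exp(-0.5 * u2)
        elif kernel == "flat":
            w = cw * (u2 <= 1.0)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        s = w.sum(axis=1)
        keep = s > 0
        ynew = ya.copy()
        ynew[keep] = (w[keep] @ x) / s[keep, None]
        disp = np.linalg.norm(ynew - ya, axis=1)
        y[active] = ynew
        still = np.zeros(n, dtype=bool)
        still[np.nonzero(active)[0][disp >= tol]] = True
        active = still
        if not active.any():
            break
    converged = not active.any()
    if not converged:
        warnings.warn(
            f"mean-shift hit max_iter={max_iter} before full convergence",
            RuntimeWarning, stacklevel=2,
        )

    # merge converged positions into modes (components at merge_radius)
    comp = sphere_components(y, np.full(n, merge_radius / 2.0))
    n_clusters = int(comp.max()) + 1
    modes = np.empty((n_clusters, d))
    dens = kernel_density(y, x, h, kernel="gaussian")
    for c in range(n_clusters):
        members = np.nonzero(comp == c)[0]
        best = members[np.argmax(dens[members])]
        modes[c] = y[best]

    protos = prototypes(x, comp)
    return ClusterResult(
        labels=comp, modes=modes, bandwidths=bandwidths,
        sphere_radii=h / 2.0, prototypes=protos, n_clusters=n_clusters,
        converged=converged, n_iter=n_iter,
    )


def adaptive_mean_shift(
    points: np.ndarray,
    k: int = 8,
    kernel: str = "gaussian",
    tol: float = 1e-5,
    max_iter: int = 300,
) -> ClusterResult:
    """Mean-shift with per-sample k-NN bandwidths (the default method)."""
    h = knn_bandwidths(points, k=k)
    bw = BandwidthSet(per_sample_h=h, k_neighbors=k)
    return mean_shift(points, bw, kernel=kernel, tol=tol, max_iter=max_iter)


def fixed_mean_shift(
    points: np.ndarray,
    h: float | None = None,
    k: int = 8,
    kernel: str = "gaussian",
    tol: float = 1e-5,
    max_iter: int = 300,
) -> ClusterResult:
    """Classic mean-shift; h defaults to the median of the k-NN bandwidths."""
    if h is None:
        h = float(np.median(knn_bandwidths(points, k=k)))
    bw = BandwidthSet(global_h=h, k_neighbors=k)
    return mean_shift(points, bw, kernel=kernel, tol=tol, max_iter=max_iter)


def sphere_components(points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Connected components of the sphere-overlap graph.

    Points i and j are joined when ‖u_i − u_j‖ ≤ ε_i + ε_j.  Component
    labels are contiguous and ordered by first appearance in the input.
    """
    x = np.asarray(points, dtype=float)
    r = np.asarray(radii, dtype=float)
    if np.any(r < 0):
        raise ValueError("radii must be >= 0")
    d = cdist(x, x)
    adj = d <= (r[:, None] + r[None, :])
    n_comp, raw = connected_components(csr_matrix(adj), directed=False)
    # relabel by first appearance so labels are input-order deterministic
    remap: dict[int, int] = {}
    labels = np.empty(len(x), dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap)
        labels[i] = remap[c]
    return labels


def prototypes(points: np.ndarray, labels: np.ndarray,
               sample_ids=None) -> np.ndarray:
    """Per cluster, the sample nearest (Euclidean) to the cluster centroid.

    Ties go to the lowest sample index.  Returns indices, or entries of
    ``sample_ids`` when given.
    """
    x = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    out = []
    for c in range(int(lab.max()) + 1):
        members = np.nonzero(lab == c)[0]
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        centroid = x[members].mean(axis=0)
        dist = np.linalg.norm(x[members] - centroid, axis=1)
        out.append(int(members[np.argmin(dist)]))
    idx = np.array(out, dtype=int)
    if sample_ids is not None:
        return np.asarray(list(sample_ids), dtype=object)[idx]
    return idx
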