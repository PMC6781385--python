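"""Quantitative and qualitative evaluation of discovered shape categories.

Quantitative: a class × cluster confusion matrix, a clustering F-measure
(pairwise co-clustering F by default, weighted best-match as an
alternative), and a leave-one-out scheme that re-runs the whole
embed → whiten → cluster chain n times to estimate the variability of the
F-measure.

Qualitative: interpretability artifacts for the principal axes — the
samples nearest to equally spaced points along an axis (axis exemplars)
and synthetic contours reconstructed from points on an axis (axis shapes),
which show what morphological factor each principal component encodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import category_discovery as cd
from . import fourier_descriptor as fd
from . import morphospace as ms
from .contour import Contour


@dataclass
class ConfusionMatrix:
    """Ground-truth classes (rows) × discovered clusters (columns)."""

    counts: np.ndarray
    row_labels: list
    col_labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class EvalReport:
    fscore: float
    fscore_variant: str
    n_clusters: int
    confusion: ConfusionMatrix
    loo_mean: float | None = None
    loo_sd: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "fscore": float(self.fscore),
            "fscore_variant": self.fscore_variant,
            "n_clusters": int(self.n_clusters),
            "loo_mean": self.loo_mean,
            "loo_sd": self.loo_sd,
            "confusion": {
                "counts": self.confusion.counts.tolist(),
                "row_labels": [str(r) for r in self.confusion.row_labels],
                "col_labels": [str(c) for c in self.confusion.col_labels],
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def confusion(true_labels, cluster_labels) -> ConfusionMatrix:
    """Count samples per (class, cluster) cell.

    Rows and columns are both ordered by first appearance in the input,
    which keeps repeated runs byte-identical.
    """
    t = list(true_labels)
    g = list(cluster_labels)
    if len(t) != len(g):
        raise ValueError("label sequences differ in length")
    if not t:
        raise ValueError("empty label sequences")
    rows = list(dict.fromkeys(t))
    cols = list(dict.fromkeys(g))
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for a, b in zip(t, g):
        counts[ri[a], ci[b]] += 1
    return ConfusionMatrix(counts, rows, cols)


def _pairs(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) // 2


def f_measure(conf: ConfusionMatrix, variant: str = "pairwise") -> float:
    """Clustering F-measure against ground-truth classes.

    pairwise: precision/recall of co-clustering decisions over all
    unordered sample pairs.  weighted_best_match: class-size-weighted best
    per-class F1 over clusters.
    """
    m = conf.counts
    if m.sum() == 0:
        raise ValueError("empty confusion matrix")
    if variant == "pairwise":
        tp = _pairs(m).sum()
        same_cluster = _pairs(m.sum(axis=0)).sum()
        same_class = _pairs(m.sum(axis=1)).sum()
        if same_cluster == 0 and same_class == 0:
            return 1.0  # all singletons on both sides: identical partitions
        precision = tp / same_cluster if same_cluster else 0.0
        recall = tp / same_class if same_class else 0.0
        if precision + recall == 0:
            return 0.0
        return float(2 * precision * recall / (precision + recall))
    if variant == "weighted_best_match":
        n = m.sum()
        class_sizes = m.sum(axis=1)
        cluster_sizes = m.sum(axis=0)
        f1 = 2 * m / (class_sizes[:, None] + cluster_sizes[None, :])
        return float((class_sizes / n * f1.max(axis=1)).sum())
    raise ValueError(f"unknown F-measure variant {variant!r}")


def cluster_scores(
    phi: ms.HarmonicMatrix,
    d: int = 3,
    mode: str = "real_stack",
    whitening: bool = True,
    method: str = "ams",
    k: int = 8,
    kernel: str = "gaussian",
    tol: float = 1e-5,
    max_iter: int = 300,
) -> tuple[ms.Morphospace, cd.ClusterResult]:
    """embed → (whiten) → cluster, the chain shared by reports and LOO."""
    space = ms.pca_embed(phi, d=d, mode=mode)
    pts = space.apply_whitening() if whitening else space.scores
    if method == "ams":
        result = cd.adaptive_mean_shift(pts, k=k, kernel=kernel,
                                        tol=tol, max_iter=max_iter)
    elif method == "ms":
        result = cd.fixed_mean_shift(pts, k=k, kernel=kernel,
                                     tol=tol, max_iter=max_iter)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return space, result


def loo_variability(
    phi: ms.HarmonicMatrix,
    true_labels,
    variant: str = "pairwise",
    **chain_kwargs,
) -> tuple[float, float, list[float]]:
    """Leave-one-out variability of the F-measure.

    For each sample i the full embed → whiten → cluster chain is re-run on
    the n−1 remaining samples and scored against their true labels.
    Returns (mean, sample SD, per-run scores).
    """
    labels = list(true_labels)
    n = phi.n_samples
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if len(labels) != n:
        raise ValueError("true_labels length mismatch")
    scores: list[float] = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = ms.HarmonicMatrix(
            phi.phi[:, keep], [phi.sample_ids[j] for j in keep],
            phi.band, phi.n_points, phi.step_length,
        )
        try:
            _, result = cluster_scores(sub, **chain_kwargs)
        except Exception as exc:
            raise RuntimeError(
                f"leave-one-out sub-run failed with sample "
                f"{phi.sample_ids[i]!r} held out"
            ) from exc
        conf = confusion([labels[j] for j in keep], result.labels)
        scores.append(f_measure(conf, variant=variant))
    arr = np.array(scores)
    return float(arr.mean()), float(arr.std(ddof=1)), scores


def axis_exemplars(
    scores: np.ndarray,
    sample_ids,
    axis: int,
    m_points: int,
) -> list:
    """Samples nearest to m equally spaced points along one score axis.

    The target points span [min, max] of the chosen dimension with the
    other coordinates at zero (the axis itself, in the whitened frame).
    Nearness is measured in the full d-space; ties go to the lowest index;
    the same sample may serve several points.
    """
    x = np.asarray(scores, dtype=float)
    if m_points < 2:
        raise ValueError("m_points must be >= 2")
    if not 0 <= axis < x.shape[1]:
        raise ValueError("axis out of range")
    ids = list(sample_ids)
    grid = np.linspace(x[:, axis].min(), x[:, axis].max(), m_points)
    out = []
    for g in grid:
        target = np.zeros(x.shape[1])
        target[axis] = g
        dist = np.linalg.norm(x - target, axis=1)
        out.append(ids[int(np.argmin(dist))])
    return out


def axis_shape(
    space: ms.Morphospace,
    axis: int,
    coordinate: float,
) -> Contour:
    """Contour reconstructed from a single point on a principal axis.

    The point (0, …, coordinate, …, 0) is mapped back through the stored
    whitening and PCA basis to a harmonic vector (plus the removed mean),
    then reconstructed through the inverse slope transform.  At
    coordinate 0 this is the shape of the mean harmonic vector.
    """
    if not 0 <= axis < space.d:
        raise ValueError("axis out of range")
    coords = np.zeros(space.d)
    coords[axis] = coordinate
    harmonics = space.inverse_transform(coords)
    desc = fd.HarmonicDescriptor(
        coefficients=harmonics,
        band=space.band,
        n=space.n_points,
        step_length=space.step_length,
        start=0j,
    )
    return fd.reconstruct(desc)


def evaluate(
    true_labels,
    result: cd.ClusterResult,
    variant: str = "pairwise",
    loo: tuple[float, float] | None = None,
) -> EvalReport:
    conf = confusion(true_labels, result.labels)
    return EvalReport(
        fscore=f_measure(conf, variant=variant),
        fscore_variant=variant,
        n_clusters=result.n_clusters,
        confusion=conf,
        loo_mean=None if loo is None else loo[0],
        loo_sd=None if loo is None else loo[1],
    )
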