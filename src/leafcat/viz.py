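"""Morphospace figures: sphere scatter and principal-axis shape strips."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import evaluation as ev
from .category_discovery import ClusterResult
from .morphospace import Morphospace


def plot_morphospace(
    points: np.ndarray,
    result: ClusterResult,
    path,
    title: str = "Morphospace",
) -> None:
    """3-D scatter of the (whitened) morphospace, colored by category.

    Marker sizes follow the per-sample sphere radii of the clustering;
    cluster prototypes are outlined.
    """
    pts = np.asarray(points, dtype=float)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    size = 40 * (result.sphere_radii / result.sphere_radii.mean()) ** 2
    ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2] if pts.shape[1] > 2 else 0,
               c=result.labels, cmap="tab10", s=size, alpha=0.8)
    proto = pts[result.prototypes]
    ax.scatter(proto[:, 0], proto[:, 1],
               proto[:, 2] if pts.shape[1] > 2 else 0,
               facecolors="none", edgecolors="k", s=160, linewidths=1.5)
    ax.set_xlabel("PC1"); ax.set_ylabel("PC2"); ax.set_zlabel("PC3")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_axis_shapes(
    space: Morphospace,
    axis: int,
    path,
    m_points: int = 5,
    span: float = 2.0,
) -> None:
    """Strip of contours reconstructed at equally spaced axis positions."""
    coords = np.linspace(-span, span, m_points)
    fig, axes = plt.subplots(1, m_points, figsize=(2.2 * m_points, 2.4))
    for ax, c in zip(np.atleast_1d(axes), coords):
        contour = ev.axis_shape(space, axis, float(c))
        v = contour.vertices
        v = v - v.mean(axis=0)
        ax.plot(np.append(v[:, 0], v[0, 0]), np.append(v[:, 1], v[0, 1]),
                lw=1.2, color="forestgreen")
        ax.set_aspect("equal")
        ax.set_title(f"{c:+.1f}", fontsize=9)
        ax.axis("off")
    fig.suptitle(f"PC{axis + 1} axis shapes")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
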