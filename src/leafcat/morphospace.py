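"""Low-dimensional PCA morphospace over harmonic descriptors.

The q retained harmonics of the n samples form a complex matrix
Φ ∈ C^{q×n}.  Two embedding modes are provided:

* ``real_stack`` (default): each complex coefficient contributes its real
  and imaginary parts as two real features (2q × n), and ordinary real PCA
  via SVD produces d real coordinates per sample.  This mode is lossless
  and invertible, which the axis-shape visualizations require.
* ``complex``: the Hermitian covariance C = Φ̂ Φ̂ᴴ/(n−1) is
  eigendecomposed directly and the real parts of the complex principal
  scores are taken as coordinates.

Scores are optionally whitened (per-dimension z-scores with sample SD)
before clustering — proximity in the whitened morphospace is what defines
a shape category downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fourier_descriptor import HarmonicDescriptor


@dataclass
class HarmonicMatrix:
    """Harmonics × samples matrix with its band and sampling metadata."""

    phi: np.ndarray  # complex, (q, n)
    sample_ids: list
    band: np.ndarray
    n_points: int  # N of the source contours
    step_length: float  # reference step length for reconstructions

    @property
    def n_samples(self) -> int:
        return self.phi.shape[1]


def harmonic_matrix(descriptors: list[HarmonicDescriptor],
                    sample_ids: list | None = None) -> HarmonicMatrix:
    """Stack per-sample descriptors into a q × n complex matrix."""
    if not descriptors:
        raise ValueError("no descriptors given")
    band = descriptors[0].band
    for d in descriptors[1:]:
        if not np.array_equal(d.band, band):
            raise ValueError("descriptors carry inconsistent harmonic bands")
    phi = np.column_stack([d.coefficients for d in descriptors])
    ids = list(sample_ids) if sample_ids is not None else list(range(len(descriptors)))
    if len(ids) != phi.shape[1]:
        raise ValueError("sample_ids length mismatch")
    step = float(np.mean([d.step_length for d in descriptors]))
    return HarmonicMatrix(phi, ids, band.copy(), descriptors[0].n, step)


def covariance(mat: HarmonicMatrix, centered: bool = True) -> np.ndarray:
    """Hermitian covariance C = Φ̂ Φ̂ᴴ / (n−1) of the harmonic matrix."""
    phi = mat.phi
    n = phi.shape[1]
    if n < 2:
        raise ValueError("covariance needs at least 2 samples")
    if centered:
        phi = phi - phi.mean(axis=1, keepdims=True)
    return phi @ phi.conj().T / (n - 1)


@dataclass
class Morphospace:
    """Fitted PCA basis, scores, and (optional) whitening statistics."""

    mode: str
    basis: np.ndarray  # (p, d): real (2q) or complex (q) features
    eigenvalues: np.ndarray  # all, descending
    explained_variance_ratio: np.ndarray  # for the retained d
    scores: np.ndarray  # (n, d) real
    center: np.ndarray  # per-feature mean that was removed
    d: int
    band: np.ndarray
    n_points: int
    step_length: float
    whitening: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    @property
    def whitened_scores(self) -> np.ndarray:
        if self.whitening is None:
            return self.scores
        mean, sd = self.whitening
        return (self.scores - mean) / sd

    def apply_whitening(self) -> np.ndarray:
        """Fit and store per-dimension whitening; returns whitened scores."""
        w, stats = whiten(self.scores)
        self.whitening = stats
        return w

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        """Map d-space coordinates back to a complex harmonic vector.

        If whitening statistics are stored, ``coords`` are interpreted in
        the whitened frame and de-standardized first.  Only the real_stack
        mode is invertible (the complex mode discards imaginary score
        parts).
        """
        if self.mode != "real_stack":
            raise ValueError(
                "inverse mapping requires mode='real_stack'; the complex "
                "mode is not invertible from real coordinates"
            )
        c = np.asarray(coords, dtype=float)
        if self.whitening is not None:
            mean, sd = self.whitening
            c = c * sd + mean
        feats = self.basis @ c + self.center
        q = len(feats) // 2
        return feats[:q] + 1j * feats[q:]


def pca_embed(
    mat: HarmonicMatrix,
    d: int = 3,
    mode: str = "real_stack",
    centered: bool = True,
) -> Morphospace:
    """PCA-embed the harmonic matrix into d real coordinates per sample."""
    phi = mat.phi
    n = phi.shape[1]
    if mode == "real_stack":
        x = np.vstack([phi.real, phi.imag])  # (2q, n)
        center = x.mean(axis=1) if centered else np.zeros(x.shape[0])
        xc = x - center[:, None]
        u, s, _vt = np.linalg.svd(xc, full_matrices=False)
        eigenvalues = s**2 / max(n - 1, 1)
        # dimensional rank: numerically degenerate directions are allowed
        # and produce zero eigenvalues / zero scores
        max_d = min(x.shape[0], n - 1 if centered else n)
        if d > max_d:
            raise ValueError(f"d={d} exceeds achievable rank {max_d}")
        basis = u[:, :d]
        scores = (basis.T @ xc).T
    elif mode == "complex":
        phic = phi - phi.mean(axis=1, keepdims=True) if centered else phi
        c = phic @ phic.conj().T / max(n - 1, 1)
        evals, evecs = np.linalg.eigh(c)
        order = np.argsort(evals)[::-1]
        eigenvalues = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        max_d = min(phi.shape[0], n - 1 if centered else n)
        if d > max_d:
            raise ValueError(f"d={d} exceeds achievable rank {max_d}")
        basis = evecs[:, :d]
        scores = (basis.conj().T @ phic).T.real
        center = (phi.mean(axis=1) if centered
                  else np.zeros(phi.shape[0], dtype=complex))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = eigenvalues.sum()
    ratio = eigenvalues[:d] / total if total > 0 else np.zeros(d)
    return Morphospace(
        mode=mode, basis=basis, eigenvalues=eigenvalues,
        explained_variance_ratio=ratio, scores=scores,
        center=center, d=d, band=mat.band, n_points=mat.n_points,
        step_length=mat.step_length,
    )


def whiten(scores: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-dimension z-scores (sample SD, divisor n−1).

    Returns the whitened scores and the stored (mean, sd) so the transform
    can be inverted.
    """
    x = np.asarray(scores, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance dimension(s): {bad.tolist()}")
    return (x - mean) / sd, (mean, sd)


# ---------------------------------------------------------------------------
# persistence helpers (CSV scores + JSON model)


def scores_to_csv(space: Morphospace, sample_ids, path) -> None:
    cols = {f"pc{i+1}": space.scores[:, i] for i in range(space.d)}
    pd.DataFrame({"sample_id": list(sample_ids), **cols}).to_csv(
        path, index=False)


def model_to_json(space: Morphospace, path) -> None:
    basis = space.basis
    payload = {
        "mode": space.mode,
        "d": space.d,
        "band": space.band.tolist(),
        "n_points": space.n_points,
        "step_length": space.step_length,
        "eigenvalues": space.eigenvalues.tolist(),
        "basis_re": np.real(basis).tolist(),
        "basis_im": np.imag(basis).tolist(),
        "center_re": np.real(space.center).tolist(),
        "center_im": np.imag(space.center).tolist(),
        "whitening": None if space.whitening is None else {
            "mean": space.whitening[0].tolist(),
            "sd": space.whitening[1].tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
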