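"""Synthetic leaf contours and images with known class structure.

Real botanical category systems separate leaves along two interpretable
factors: the outline of the blade (elliptic, ovate, obovate, oblong) and the
type of margin (entire, crenate, serrate, dentate).  This module generates
leaf-like closed contours that vary along exactly those two factors, plus
rasterized images on a controlled background, so the whole discovery pipeline
can be exercised with ground truth in hand.

The blade is a width-profile body: two mirror curves about the main axis,
with the half-width profile w(t) selected by the blade family and an
asymmetry parameter that moves the point of maximal width toward the base
(ovate) or the apex (obovate).  The margin is a periodic modulation applied
along the outward normal of the smooth outline, with amplitude proportional
to the local half-width so teeth shrink naturally toward apex and base.
Margin waveforms are smooth, band-limited tooth shapes: a pure sine for
crenate (rounded teeth), a forward-leaning two-harmonic wave for serrate,
and a flattened symmetric wave for dentate.  Petioles are not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .contour import Contour

BLADE_FAMILIES = ("elliptic", "ovate", "obovate", "oblong")
MARGIN_TYPES = ("entire", "crenate", "serrate", "dentate")

#: class-level blade defaults: (aspect_ratio, asymmetry)
BLADE_DEFAULTS = {
    "elliptic": (2.0, 0.0),
    "ovate": (1.6, -0.5),
    "obovate": (1.6, 0.5),
    "oblong": (2.6, 0.0),
}

#: class-level margin defaults: (margin_amplitude, margin_frequency).
#: Crenations are few broad rounded lobes; serrations are many fine sharp
#: teeth; dentations sit in between.
MARGIN_DEFAULTS = {
    "entire": (0.0, 0),
    "crenate": (0.06, 5),
    "serrate": (0.035, 9),
    "dentate": (0.06, 7),
}


@dataclass(frozen=True)
class LeafSpec:
    """Generative parameters for a single synthetic leaf."""

    blade_family: str = "elliptic"
    aspect_ratio: float = 2.0
    asymmetry: float = 0.0
    margin_type: str = "entire"
    margin_amplitude: float = 0.0
    margin_frequency: int = 0
    jitter_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.blade_family not in BLADE_FAMILIES:
            raise ValueError(f"unknown blade family {self.blade_family!r}")
        if self.margin_type not in MARGIN_TYPES:
            raise ValueError(f"unknown margin type {self.margin_type!r}")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [-1, 1]")
        if self.margin_amplitude < 0:
            raise ValueError("margin_amplitude must be >= 0")
        if self.margin_frequency < 0:
            raise ValueError("margin_frequency must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if (self.margin_type == "entire") != (self.margin_amplitude == 0):
            raise ValueError(
                "margin_type 'entire' if and only if margin_amplitude == 0"
            )


def _half_width(t: np.ndarray, family: str, asymmetry: float) -> np.ndarray:
    """Half-width profile w(t) for t in [0, 1]; max half-width is 0.5.

    Both tips keep the rounded sqrt-type profile of an ellipse; a smooth
    linear skew factor moves the point of maximal width toward the base
    (asymmetry < 0, ovate) or the apex (asymmetry > 0, obovate) without
    sharpening either tip.  For small asymmetry the maximum sits near
    t = 0.5 + asymmetry/4.
    """
    tt = np.clip(t, 0.0, 1.0)
    u = 2.0 * tt - 1.0
    if family == "oblong":
        # superellipse exponent 4: flat-sided blade with rounded shoulders
        base = np.sqrt(np.clip(1.0 - u**4, 0.0, None))
    else:
        base = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    alpha = float(np.clip(asymmetry, -0.95, 0.95))
    skew = 1.0 + alpha * (tt - 0.5)
    w = base * skew
    # renormalize so the maximal half-width is exactly 0.5
    grid = np.linspace(0.0, 1.0, 1025)
    ug = 2.0 * grid - 1.0
    if family == "oblong":
        bg = np.sqrt(np.clip(1.0 - ug**4, 0.0, None))
    else:
        bg = np.sqrt(np.clip(1.0 - ug**2, 0.0, None))
    peak = np.max(bg * (1.0 + alpha * (grid - 0.5)))
    return 0.5 * w / peak


def _margin_wave(phase: np.ndarray, margin_type: str) -> np.ndarray:
    """Periodic tooth waveform with unit fundamental, at phase (circuits).

    Real teeth are smooth, so each waveform is a short Fourier series:
    crenate is a pure sine (rounded teeth), serrate leans forward with a
    weak second harmonic, dentate flattens symmetrically with a weak
    third.  ``margin_amplitude`` scales the fundamental; the peak
    displacement can exceed it by at most ~15%.
    """
    th = 2.0 * np.pi * phase
    if margin_type == "entire":
        return np.zeros_like(phase)
    if margin_type == "crenate":
        return np.sin(th)
    if margin_type == "serrate":
        return np.sin(th) + 0.2 * np.sin(2.0 * th)
    if margin_type == "dentate":
        return np.sin(th) - np.sin(3.0 * th) / 9.0
    raise ValueError(f"unknown margin type {margin_type!r}")


def _base_outline(spec: LeafSpec, n_vertices: int):
    """Smooth blade outline (no margin, no jitter) and per-vertex t."""
    u = np.arange(n_vertices) / n_vertices
    top = u <= 0.5
    s = np.where(top, 2.0 * u, 2.0 * (1.0 - u))
    # cosine-spaced axis positions: dense vertices near apex/base keep the
    # rounded tips smooth (for an ellipse this is exact angle spacing)
    t = 0.5 * (1.0 - np.cos(np.pi * s))
    w = _half_width(t, spec.blade_family, spec.asymmetry)
    x = spec.aspect_ratio * t
    y = np.where(top, w, -w)
    # tips carry w = 0 exactly
    return np.column_stack([x, y]), t


def generate_leaf(spec: LeafSpec, n_vertices: int = 512) -> Contour:
    """Generate one closed leaf contour from its generative parameters.

    The result is a simple (non-self-intersecting), counter-clockwise
    polygon, deterministic given ``spec.seed``.  If the margin modulation
    produces a self-intersection the amplitude is halved internally and the
    generation retried; persistent failure raises ``ValueError``.
    """
    spec.validate()
    if n_vertices < 64:
        raise ValueError("n_vertices must be >= 64")

    amplitude = spec.margin_amplitude
    for _attempt in range(4):
        rng = np.random.default_rng(spec.seed)
        pts, t = _base_outline(spec, n_vertices)

        if spec.margin_type != "entire" and spec.margin_frequency > 0:
            # phase from the arc-length fraction of the smooth outline so
            # teeth are evenly spaced along the border and wrap continuously
            seg = np.roll(pts, -1, axis=0) - pts
            seglen = np.hypot(seg[:, 0], seg[:, 1])
            arc = np.concatenate([[0.0], np.cumsum(seglen[:-1])])
            frac = arc / (arc[-1] + seglen[-1])
            phase = spec.margin_frequency * frac

            tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
            tnorm = np.hypot(tang[:, 0], tang[:, 1])
            tnorm[tnorm == 0] = 1.0
            tang = tang / tnorm[:, None]
            area = 0.5 * np.sum(
                pts[:, 0] * np.roll(pts[:, 1], -1)
                - np.roll(pts[:, 0], -1) * pts[:, 1]
            )
            if area >= 0:  # ccw: outward normal is right of travel
                normal = np.column_stack([tang[:, 1], -tang[:, 0]])
            else:
                normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            local_amp = amplitude * _half_width(
                t, spec.blade_family, spec.asymmetry
            )
            wave = _margin_wave(phase, spec.margin_type)
            pts = pts + (local_amp * wave)[:, None] * normal

        if spec.jitter_sd > 0:
            centroid = pts.mean(axis=0)
            radial = pts - centroid
            rlen = np.hypot(radial[:, 0], radial[:, 1])
            rlen[rlen == 0] = 1.0
            radial = radial / rlen[:, None]
            noise = rng.normal(0.0, spec.jitter_sd * spec.aspect_ratio,
                               size=n_vertices)
            pts = pts + noise[:, None] * radial

        contour = Contour(pts).ensure_ccw()
        if contour.is_simple():
            return contour
        amplitude *= 0.5

    raise ValueError(
        "could not generate a simple polygon even after reducing the "
        "margin amplitude"
    )


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class LeafImage:
    """Rendered leaf with the contour-to-pixel transform kept for tests."""

    image: np.ndarray  # (H, W, 3) uint8
    scale: float
    offset: np.ndarray  # (2,) applied before scaling: pixel = (p - offset)*s

    @property
    def height(self) -> int:
        return self.image.shape[0]

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Map contour coordinates to pixel coordinates (x=col, y=-row)."""
        cols_rows = (np.asarray(points, float) - self.offset) * self.scale
        col = cols_rows[:, 0]
        row = (self.height - 1) - cols_rows[:, 1]
        return np.column_stack([col, -row])

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.image)

    def save(self, path) -> None:
        self.to_pil().save(path)


def rasterize_leaf(
    contour: Contour,
    image_size: tuple[int, int] = (256, 256),
    foreground: tuple[int, int, int] = (34, 160, 34),
    background: tuple[int, int, int] = (255, 255, 255),
    margin_px: int = 8,
) -> LeafImage:
    """Render a filled leaf polygon on a low-saturation background.

    The contour is scaled uniformly to fit the image with at least
    ``margin_px`` pixels of border (>= 5 required downstream).
    """
    if margin_px < 5:
        raise ValueError("margin_px must be >= 5")
    h, w = image_size
    v = contour.vertices
    vmin, vmax = v.min(axis=0), v.max(axis=0)
    extent = vmax - vmin
    if np.any(extent <= 0) or \
            abs(_polygon_area(v)) < 1e-12 * float(extent.max()) ** 2:
        raise ValueError("degenerate contour (zero area)")
    scale = min((w - 1 - 2 * margin_px) / extent[0],
                (h - 1 - 2 * margin_px) / extent[1])
    # center the blade in the frame
    pad = (np.array([w - 1, h - 1]) - extent * scale) / 2.0
    offset = vmin - pad / scale

    from skimage.draw import polygon as fill_polygon

    cols_rows = (v - offset) * scale
    rows = (h - 1) - cols_rows[:, 1]
    cols = cols_rows[:, 0]
    arr = np.empty((h, w, 3), dtype=np.uint8)
    arr[:] = np.asarray(background, dtype=np.uint8)
    rr, cc = fill_polygon(rows, cols, shape=(h, w))
    arr[rr, cc] = np.asarray(foreground, dtype=np.uint8)
    return LeafImage(arr, scale, offset)


def _polygon_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# labeled datasets


@dataclass(frozen=True)
class WithinClassVariation:
    """Relative/absolute spreads used to perturb class-level means.

    Teeth count (``margin_frequency``) is treated as a class-characteristic
    trait and not perturbed by default: a change of one tooth displaces the
    margin's spectral lines to neighboring harmonics, which the linear
    harmonic representation reads as a large shape change (see the package
    methods note on descriptor sensitivity).  Within-class variation is
    expressed in tooth size, blade proportions, asymmetry and vertex noise.
    """

    aspect_rel_sd: float = 0.06
    asymmetry_sd: float = 0.04
    amplitude_rel_sd: float = 0.12
    frequency_jitter: int = 0
    jitter_sd: float = 0.004


DEFAULT_CLASSES: tuple[tuple[str, str], ...] = (
    ("elliptic", "dentate"),
    ("elliptic", "crenate"),
    ("elliptic", "serrate"),
    ("oblong", "entire"),
    ("ovate", "crenate"),
    ("obovate", "dentate"),
)


@dataclass
class LeafSample:
    contour: Contour
    image: LeafImage | None
    class_label: tuple[str, str]
    spec: LeafSpec


@dataclass
class SyntheticDataset:
    """Balanced labeled collection of synthetic leaves."""

    samples: list[LeafSample]
    class_labels: list[tuple[str, str]]
    n_per_class: int
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def contours(self) -> list[Contour]:
        return [s.contour for s in self.samples]

    @property
    def labels(self) -> list[str]:
        return [f"{s.class_label[0]}-{s.class_label[1]}" for s in self.samples]

    @property
    def sample_ids(self) -> list[str]:
        return [f"leaf_{i:04d}" for i in range(len(self.samples))]

    def write(self, out_dir) -> None:
        """Write contours as x,y CSVs, images as PNG, and a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for sid, sample in zip(self.sample_ids, self.samples):
            cpath = out / f"{sid}.csv"
            sample.contour.to_csv(cpath)
            entry = {
                "contour": cpath.name,
                "class_label": list(sample.class_label),
            }
            if sample.image is not None:
                ipath = out / f"{sid}.png"
                sample.image.save(ipath)
                entry["image"] = ipath.name
            manifest[sid] = entry
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_dataset(
    class_labels=DEFAULT_CLASSES,
    n_per_class: int = 20,
    within_class_sd: WithinClassVariation | None = None,
    seed: int = 0,
    n_vertices: int = 512,
    with_images: bool = False,
    image_size: tuple[int, int] = (256, 256),
) -> SyntheticDataset:
    """Generate a balanced labeled dataset of leaf contours (and images).

    Each class is a (blade_family, margin_type) pair whose class-level means
    come from :data:`BLADE_DEFAULTS` / :data:`MARGIN_DEFAULTS`; individual
    samples perturb aspect ratio, asymmetry, margin amplitude and frequency
    around those means.  Bit-identical under the same seed.
    """
    class_labels = [tuple(c) for c in class_labels]
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if len(set(class_labels)) != len(class_labels):
        raise ValueError("duplicate class labels")
    var = within_class_sd or WithinClassVariation()

    root_ss = np.random.SeedSequence(seed)
    samples: list[LeafSample] = []
    for ci, (family, margin) in enumerate(class_labels):
        if family not in BLADE_FAMILIES:
            raise ValueError(f"unknown blade family {family!r}")
        if margin not in MARGIN_TYPES:
            raise ValueError(f"unknown margin type {margin!r}")
        aspect0, asym0 = BLADE_DEFAULTS[family]
        amp0, freq0 = MARGIN_DEFAULTS[margin]
        class_rng = np.random.default_rng(root_ss.spawn(1)[0])
        for si in range(n_per_class):
            aspect = aspect0 * (1.0 + var.aspect_rel_sd * class_rng.standard_normal())
            asym = float(np.clip(
                asym0 + var.asymmetry_sd * class_rng.standard_normal(), -1, 1))
            if margin == "entire":
                amp, freq = 0.0, 0
            else:
                amp = max(0.005, amp0 * (
                    1.0 + var.amplitude_rel_sd * class_rng.standard_normal()))
                freq = int(freq0 + class_rng.integers(
                    -var.frequency_jitter, var.frequency_jitter + 1))
                freq = max(3, freq)
            leaf_seed = int(class_rng.integers(0, 2**31 - 1))
            spec = LeafSpec(
                blade_family=family,
                aspect_ratio=max(1.05, aspect),
                asymmetry=asym,
                margin_type=margin,
                margin_amplitude=amp,
                margin_frequency=freq,
                jitter_sd=var.jitter_sd,
                seed=leaf_seed,
            )
            contour = generate_leaf(spec, n_vertices=n_vertices)
            image = rasterize_leaf(contour, image_size) if with_images else None
            samples.append(LeafSample(contour, image, (family, margin), spec))

    return SyntheticDataset(samples, class_labels, n_per_class, seed)


def reconstruction_fixture(seed: int = 0, n_contours: int = 60) -> list[LeafSpec]:
    """Specs for the descriptor-fidelity fixture.

    Covers every blade-family × margin-type combination, with margin
    frequencies cycling over 4–10, margin amplitudes up to 0.08, and no
    vertex jitter, so descriptor fidelity is measured on clean geometry.
    """
    rng = np.random.default_rng(seed)
    combos = [(f, m) for f in BLADE_FAMILIES for m in MARGIN_TYPES]
    # frequency/amplitude menus per margin type: crenations are few broad
    # lobes, serrations many fine teeth, dentations intermediate
    freqs = {"crenate": [4, 5, 6, 7], "serrate": [7, 8, 9, 10],
             "dentate": [5, 6, 7, 8]}
    amps = {"crenate": [0.04, 0.06, 0.08], "serrate": [0.02, 0.03, 0.04],
            "dentate": [0.03, 0.045, 0.06]}
    specs: list[LeafSpec] = []
    i = 0
    while len(specs) < n_contours:
        family, margin = combos[i % len(combos)]
        aspect0, asym0 = BLADE_DEFAULTS[family]
        if margin == "entire":
            amp, freq = 0.0, 0
        else:
            amp = amps[margin][(i // len(combos)) % 3]
            freq = freqs[margin][i % 4]
        specs.append(LeafSpec(
            blade_family=family,
            aspect_ratio=aspect0 * float(rng.uniform(0.9, 1.1)),
            asymmetry=asym0,
            margin_type=margin,
            margin_amplitude=amp,
            margin_frequency=freq,
            jitter_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
        i += 1
    return specs
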