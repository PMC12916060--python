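"""Multi-view object stimulus sets: synthetic generation and directory loading.

The trainer consumes an ordered collection of (object, view) grayscale images.
The synthetic generator stands in for a multi-view photographic library: each
object is a distinct filled base shape, and its views are smooth parametric
transforms (in-plane rotation in fixed angular steps, mild shear and scale
jitter) of that shape, so that views of one object are more pixel-correlated
with each other than with views of any other object.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import polygon as draw_polygon

__all__ = [
    "StimulusSet",
    "generate_synthetic_objects",
    "load_image_directory",
    "save_stimulus_set",
]

#: number of distinct base-shape families the generator cycles through
N_SHAPE_FAMILIES = 4

MIN_IMAGE_SIZE = 32


@dataclass
class StimulusSet:
    """Ordered collection of grayscale images indexed by (object_id, view_id).

    ``images`` is a float array of shape (n_objects, n_views, size, size) with
    luminance values in [0, 1]; ``labels`` maps each flattened presentation row
    (object-major) to its object_id.
    """

    n_objects: int
    n_views: int
    images: np.ndarray
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.images.shape[:2] != (self.n_objects, self.n_views):
            raise ValueError(
                f"images shape {self.images.shape} inconsistent with "
                f"{self.n_objects} objects x {self.n_views} views"
            )
        if self.images.min() < 0.0 or self.images.max() > 1.0:
            raise ValueError("image luminance must lie in [0, 1]")
        self.labels = np.repeat(np.arange(self.n_objects), self.n_views)

    @property
    def size(self) -> int:
        return self.images.shape[-1]

    def image(self, object_id: int, view_id: int) -> np.ndarray:
        return self.images[object_id, view_id]

    def iter_views(self):
        """Yield (object_id, view_id, image) in object-major order."""
        for o in range(self.n_objects):
            for v in range(self.n_views):
                yield o, v, self.images[o, v]


def _base_shape(rng: np.random.Generator, family: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (angles, radii) describing a closed star-domain outline.

    Radii are relative to a unit bounding circle.  Families differ in how the
    radial profile r(theta) is built, keeping objects discriminable even for
    hundreds of objects drawn from the same seeded stream.
    """
    if family == 0:
        # near-regular polygon: evenly spaced vertices with mild jitter
        k = int(rng.integers(5, 9))
        angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
        angles = angles + rng.uniform(-0.12, 0.12, k)
        radii = rng.uniform(0.88, 1.0, k)
    elif family == 1:
        # star: alternating long/short spokes (mild contrast)
        k = int(rng.integers(5, 8))
        angles = np.linspace(0, 2 * np.pi, 2 * k, endpoint=False)
        angles = angles + rng.uniform(0, 2 * np.pi / (2 * k))
        outer = rng.uniform(0.92, 1.0)
        inner = rng.uniform(0.7, 0.84)
        radii = np.where(np.arange(2 * k) % 2 == 0, outer, inner)
        radii = radii * rng.uniform(0.97, 1.03, 2 * k)
    elif family == 2:
        # smooth blob: low-order Fourier radial profile, densely sampled
        angles = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        radii = np.full(72, 0.85)
        for h in (2, 3, 5):
            radii = radii + rng.uniform(0.02, 0.09) * np.cos(
                h * angles + rng.uniform(0, 2 * np.pi)
            )
        radii = np.clip(radii, 0.5, 1.0)
    else:
        # mildly elongated ellipse with a boundary bump
        angles = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        ecc = rng.uniform(0.75, 0.88)
        radii = ecc / np.sqrt(1 - (1 - ecc**2) * np.cos(angles) ** 2)
        radii = radii / radii.max()
        bump_at = rng.uniform(0, 2 * np.pi)
        radii = radii + rng.uniform(0.05, 0.12) * np.exp(
            -0.5 * ((np.mod(angles - bump_at + np.pi, 2 * np.pi) - np.pi) / 0.5) ** 2
        )
        radii = np.clip(radii, 0.4, 1.0)
    return angles, radii


def _render_view(
    angles: np.ndarray,
    radii: np.ndarray,
    size: int,
    rotation: float,
    shear: float,
    scale: float,
    extent: float,
    shading: dict,
) -> np.ndarray:
    """Rasterise one transformed view of a base outline onto a dark background."""
    theta = angles + rotation
    x = radii * np.cos(theta)
    y = radii * np.sin(theta)
    # mild shear then isotropic scale; renormalise so the shape still fills
    # roughly `extent` of the half-frame regardless of transform
    xs = x + shear * y
    ys = y
    norm = max(np.abs(xs).max(), np.abs(ys).max())
    half = size / 2.0
    r_px = half * extent * scale / norm
    cols = half + xs * r_px
    rows = half + ys * r_px
    img = np.zeros((size, size), dtype=np.float64)
    rr, cc = draw_polygon(rows, cols, shape=img.shape)
    if rr.size:
        # rotation-invariant shading: radial fade plus object-specific concentric
        # rings, so views of one object share a pixel pattern that other objects
        # (different ring count/phase/fade) do not
        dr = (rr - half) / (half * extent)
        dc = (cc - half) / (half * extent)
        rho = np.clip(np.hypot(dr, dc), 0.0, 1.0)
        fade = (1.0 - rho) ** shading["power"]
        rings = 0.5 + 0.5 * np.cos(
            2.0 * np.pi * shading["n_rings"] * rho + shading["ring_phase"]
        )
        img[rr, cc] = 0.25 + 0.75 * np.clip(
            (1.0 - shading["ring_depth"]) * fade + shading["ring_depth"] * rings, 0.0, 1.0
        )
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_objects(
    n_objects: int,
    n_views: int,
    size: int = 256,
    seed: int = 0,
    view_step_deg: float = 40.0,
    shear_magnitude: float = 0.08,
    scale_jitter: float = 0.04,
) -> StimulusSet:
    """Generate a deterministic synthetic multi-view object set.

    Each object gets a distinct base shape (cycled over 4 shape families) and
    object-specific size and shading, and each view applies an in-plane
    rotation of ``view_step_deg`` (default 40 degrees, the conventional
    spacing for view-invariance training) plus mild shear/scale jitter.

    Parameters
    ----------
    n_objects, n_views : int
        Set dimensions (both >= 1).
    size : int
        Square image side in pixels (>= 32).
    seed : int
        Seeds all shape and transform randomness; identical arguments yield
        bit-identical pixels.
    """
    if n_objects < 1 or n_views < 1:
        raise ValueError("n_objects and n_views must both be >= 1")
    if size < MIN_IMAGE_SIZE:
        raise ValueError(f"size must be >= {MIN_IMAGE_SIZE} px to render shapes, got {size}")
    rng = np.random.default_rng(seed)
    images = np.zeros((n_objects, n_views, size, size), dtype=np.float64)
    # stratify the strongest identity cues (ring frequency of the interior
    # shading, overall extent) over seeded permutations so that any two
    # objects are guaranteed a minimum separation in at least these cues
    ring_grid = 0.8 + 4.4 * (rng.permutation(n_objects) + 0.5) / n_objects
    extent_grid = 0.6 + 0.35 * (rng.permutation(n_objects) + 0.5) / n_objects
    for o in range(n_objects):
        family = o % N_SHAPE_FAMILIES
        angles, radii = _base_shape(rng, family)
        extent = float(extent_grid[o])
        shading = {
            "power": rng.uniform(0.4, 2.5),
            "n_rings": float(ring_grid[o]),
            "ring_phase": rng.uniform(0, 2 * np.pi),
            "ring_depth": rng.uniform(0.35, 0.7),
        }
        base_rot = rng.uniform(0, 2 * np.pi)
        for v in range(n_views):
            rotation = base_rot + math.radians(view_step_deg) * v
            shear = rng.uniform(-shear_magnitude, shear_magnitude)
            scale = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
            images[o, v] = _render_view(
                angles, radii, size, rotation, shear, scale, extent, shading
            )
    return StimulusSet(n_objects=n_objects, n_views=n_views, images=images)


def _to_unit_grayscale(img: Image.Image, size: int) -> np.ndarray:
    """Luminance conversion, aspect-preserving resize and centre-pad to size x size."""
    gray = img.convert("L")
    w, h = gray.size
    scale = size / max(w, h)
    new_w, new_h = max(1, round(w * scale)), max(1, round(h * scale))
    resized = gray.resize((new_w, new_h), Image.BILINEAR)
    canvas = Image.new("L", (size, size), 0)
    canvas.paste(resized, ((size - new_w) // 2, (size - new_h) // 2))
    return np.asarray(canvas, dtype=np.float64) / 255.0


def load_image_directory(path: str | Path, size: int = 256, layout: str = "flat") -> StimulusSet:
    """Load a multi-view image directory into a :class:`StimulusSet`.

    Two naming conventions are supported:

    - ``layout="flat"``: files named ``obj{o}_view{v}.{png,jpg,jpeg,pgm}`` in
      one directory, with ``o`` and ``v`` zero-based integers.
    - ``layout="nested"``: one subdirectory per object (sorted lexically),
      whose sorted image files are that object's views — the common layout of
      turntable libraries such as ALOI.

    All images are converted to grayscale, resized preserving aspect ratio,
    centre-padded onto a black background, and rescaled to [0, 1].  Every
    object must contribute the same number of views.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"stimulus directory not found: {path}")
    exts = {".png", ".jpg", ".jpeg", ".pgm"}
    per_object: dict[str, list[Path]] = {}
    if layout == "flat":
        for f in sorted(path.iterdir()):
            if f.suffix.lower() not in exts:
                continue
            stem = f.stem
            if not stem.startswith("obj") or "_view" not in stem:
                raise ValueError(f"unrecognised flat-layout filename: {f.name}")
            obj_part, view_part = stem.split("_view", 1)
            per_object.setdefault(obj_part[3:], []).append(f)
    elif layout == "nested":
        for sub in sorted(p for p in path.iterdir() if p.is_dir()):
            files = sorted(f for f in sub.iterdir() if f.suffix.lower() in exts)
            if files:
                per_object[sub.name] = files
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'flat' or 'nested'")
    if not per_object:
        raise ValueError(f"no images found under {path} with layout={layout!r}")
    keys = sorted(per_object, key=lambda k: (len(k), k))
    counts = {k: len(per_object[k]) for k in keys}
    n_views = counts[keys[0]]
    for k, c in counts.items():
        if c != n_views:
            raise ValueError(
                f"object {k!r} has {c} views but object {keys[0]!r} has {n_views}; "
                "all objects must have equal view counts"
            )
    images = np.zeros((len(keys), n_views, size, size), dtype=np.float64)
    for i, k in enumerate(keys):
        for v, f in enumerate(sorted(per_object[k])):
            with Image.open(f) as im:
                images[i, v] = _to_unit_grayscale(im, size)
    return StimulusSet(n_objects=len(keys), n_views=n_views, images=images)


def save_stimulus_set(stimuli: StimulusSet, directory: str | Path) -> Path:
    """Write a StimulusSet as PNGs plus a CSV manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["object_id", "view_id", "filename"])
        for o, v, img in stimuli.iter_views():
            name = f"obj{o}_view{v}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(directory / name)
            writer.writerow([o, v, name])
    return manifest
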