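"""Network construction: neuron grids, diluted retinotopic connectivity, weights.

Each of the four Layers is a square grid of rate neurons.  A neuron's
afferents are sampled from an isotropic 2-D Gaussian centred on its
retinotopic projection into the presynaptic sheet, with the Gaussian scale
set so that approximately 67% of connections fall within the stated radius
(for a 2-D isotropic Gaussian ~67% of the mass lies within 1.5 sigma, so
sigma = radius / 1.5).  Layer 1 samples from the 32-channel Gabor retina,
with connection counts per frequency band following a halving geometric
series that favours low spatial frequencies.  Sampling is without
replacement: one synapse per (pre, post) pair.  Initial weights are
uniform-positive, normalised to unit Euclidean length per neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "LayerSpec",
    "Network",
    "build_network",
    "wrap_or_clip_boundaries",
    "small_32_specs",
    "large_256_specs",
    "input_coverage_fraction",
]

#: radius = GAUSS_RADIUS_SIGMA * sigma contains ~67% of a 2-D isotropic Gaussian
GAUSS_RADIUS_SIGMA = 1.5


@dataclass(frozen=True)
class LayerSpec:
    """Structural and competition parameters of one Layer.

    Parameters
    ----------
    grid : neurons per side (the Layer is grid x grid).
    n_connections : afferent synapses per neuron.
    radius : connection-sampling radius in presynaptic grid units; the
        Gaussian sampling scale is radius / 1.5 so ~67% of connections fall
        inside it.
    sparseness : target fraction ``a`` of the Layer left firing after
        competition.
    beta : sigmoid slope of the activation function.
    max_weight : weight ceiling applied after every update, or None.
    competition : "hard" (sub-threshold neurons exactly zero) or "graded"
        (sigmoid tail below threshold, suppressed as beta grows); see
        :func:`visnet.activation.rates_from_activations`.
    """

    grid: int
    n_connections: int
    radius: float
    sparseness: float = 0.01
    beta: float = 10.0
    max_weight: float | None = None
    competition: str = "hard"

    def __post_init__(self) -> None:
        if self.grid < 1 or self.n_connections < 1:
            raise ValueError("grid and n_connections must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not (0.0 < self.sparseness <= 1.0):
            raise ValueError("sparseness must be in (0, 1]")
        if self.competition not in ("hard", "graded"):
            raise ValueError(f"unknown competition mode {self.competition!r}")

    @property
    def n_neurons(self) -> int:
        return self.grid * self.grid


@dataclass
class Network:
    """Four-Layer network: specs, connectivity and per-neuron weight vectors.

    ``connectivity[l]`` is an int array (n_neurons, n_connections) of flat
    presynaptic indices: for Layer 1 into the raveled (size, size, channels)
    Gabor retina, for Layers 2-4 into the raveled presynaptic neuron grid.
    ``weights[l]`` has the same shape, values >= 0.
    """

    layers: list[LayerSpec]
    connectivity: list[np.ndarray] = field(repr=False)
    weights: list[np.ndarray] = field(repr=False)
    input_size: int
    input_channels: int
    rng_seed: int
    trained_layers: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def copy(self) -> "Network":
        return Network(
            layers=list(self.layers),
            connectivity=[c.copy() for c in self.connectivity],
            weights=[w.copy() for w in self.weights],
            input_size=self.input_size,
            input_channels=self.input_channels,
            rng_seed=self.rng_seed,
            trained_layers=self.trained_layers,
        )

    def save(self, path: str | Path) -> None:
        """Serialize specs + connectivity + weights + seed to one .npz archive."""
        arrays = {"format_version": np.array([1])}
        meta = np.array(
            [self.input_size, self.input_channels, self.rng_seed, self.trained_layers]
        )
        arrays["meta"] = meta
        spec_rows = np.array(
            [
                [
                    s.grid,
                    s.n_connections,
                    s.radius,
                    s.sparseness,
                    s.beta,
                    -1.0 if s.max_weight is None else s.max_weight,
                    0.0 if s.competition == "hard" else 1.0,
                ]
                for s in self.layers
            ]
        )
        arrays["layer_specs"] = spec_rows
        for l in range(self.n_layers):
            arrays[f"conn_{l}"] = self.connectivity[l]
            arrays[f"w_{l}"] = self.weights[l]
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with np.load(path) as data:
            spec_rows = data["layer_specs"]
            layers = [
                LayerSpec(
                    grid=int(r[0]),
                    n_connections=int(r[1]),
                    radius=float(r[2]),
                    sparseness=float(r[3]),
                    beta=float(r[4]),
                    max_weight=None if r[5] < 0 else float(r[5]),
                    competition="hard" if r[6] == 0.0 else "graded",
                )
                for r in spec_rows
            ]
            meta = data["meta"]
            return cls(
                layers=layers,
                connectivity=[data[f"conn_{l}"] for l in range(len(layers))],
                weights=[data[f"w_{l}"] for l in range(len(layers))],
                input_size=int(meta[0]),
                input_channels=int(meta[1]),
                rng_seed=int(meta[2]),
                trained_layers=int(meta[3]),
            )


def small_32_specs(
    sparseness: float = 0.01,
    beta: float = 10.0,
    max_weight: float | None = None,
    max_weight_layers: tuple[int, ...] = (0, 1, 2),
    n_connections: int | None = None,
) -> list[LayerSpec]:
    """The small 32x32 default: Layers 2-4 with 200 connections at radius 7,
    Layer 1 with 340 connections at radius 15 from the Gabor retina.

    ``max_weight`` (when set) applies only to ``max_weight_layers``
    (zero-based; default Layers 1-3).  ``n_connections`` overrides the
    per-layer synapse count uniformly, for capacity experiments.
    """
    base = [
        LayerSpec(32, 340, 15.0, sparseness, beta),
        LayerSpec(32, 200, 7.0, sparseness, beta),
        LayerSpec(32, 200, 7.0, sparseness, beta),
        LayerSpec(32, 200, 7.0, sparseness, beta),
    ]
    out = []
    for l, s in enumerate(base):
        kw = {}
        if max_weight is not None and l in max_weight_layers:
            kw["max_weight"] = max_weight
        if n_connections is not None:
            kw["n_connections"] = n_connections
        out.append(replace(s, **kw) if kw else s)
    return out


def large_256_specs(
    n_connections: int = 1000,
    sparseness: float = 0.0025,
    beta: float = 100.0,
    max_weight: float = 0.06,
) -> list[LayerSpec]:
    """The scaled-up 256x256 configuration: up to 1000 synapses per neuron,
    sparseness 0.0025, beta 100, weight ceiling 0.06 on Layers 1-3."""
    # radii scaled with the grid (x8 relative to the 32-grid defaults)
    return [
        LayerSpec(256, n_connections, 15.0, sparseness, beta, max_weight),
        LayerSpec(256, n_connections, 56.0, sparseness, beta, max_weight),
        LayerSpec(256, n_connections, 56.0, sparseness, beta, max_weight),
        LayerSpec(256, n_connections, 56.0, sparseness, beta, None),
    ]


def wrap_or_clip_boundaries(
    positions: np.ndarray,
    grid: int,
    mode: str = "resample",
    rng: np.random.Generator | None = None,
    center: tuple[float, float] | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Map sampled (row, col) integer positions onto the presynaptic grid.

    ``mode="wrap"`` folds coordinates toroidally (33 on a 32-grid becomes 1).
    ``mode="resample"`` (the default; retinotopic sheets are bounded) redraws
    out-of-grid samples from the same Gaussian until all are in-grid, which
    requires ``rng``, ``center`` and ``sigma``.
    """
    positions = np.asarray(positions)
    if mode == "wrap":
        return np.mod(positions, grid)
    if mode != "resample":
        raise ValueError(f"unknown boundary mode {mode!r}")
    out = positions.copy()
    bad = (out < 0).any(axis=-1) | (out >= grid).any(axis=-1)
    guard = 0
    while bad.any():
        if rng is None or center is None or sigma is None:
            raise ValueError("resample mode needs rng, center and sigma")
        n_bad = int(bad.sum())
        redraw = np.rint(rng.normal(loc=center, scale=sigma, size=(n_bad, 2))).astype(int)
        out[bad] = redraw
        bad = (out < 0).any(axis=-1) | (out >= grid).any(axis=-1)
        guard += 1
        if guard > 1000:
            raise RuntimeError("boundary resampling failed to converge")
    return out


def frequency_allocation(n_connections: int, n_frequencies: int) -> np.ndarray:
    """Connections per frequency band, halving geometrically from low to high.

    Counts are proportional to 2^(n_frequencies-1-f) (lowest frequency gets
    the most), rounded to sum exactly to ``n_connections``.
    """
    raw = np.array([2.0 ** (n_frequencies - 1 - f) for f in range(n_frequencies)])
    frac = raw / raw.sum() * n_connections
    counts = np.floor(frac).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    short = n_connections - counts.sum()
    order = np.argsort(-(frac - np.floor(frac)))
    counts[order[:short]] += 1
    return counts


def _sample_unique_sources(
    rng: np.random.Generator,
    n_needed: int,
    center: tuple[float, float],
    sigma: float,
    grid: int,
    key_of: callable,
    wrap: bool = False,
    max_rounds: int = 200,
) -> np.ndarray:
    """Draw ``n_needed`` distinct flat source keys from a rounded 2-D Gaussian.

    ``key_of(rows, cols)`` maps in-grid integer coordinates to flat keys (it
    may fold in a channel draw).  Out-of-grid draws are toroidally folded
    when ``wrap`` is set, otherwise rejected and redrawn; duplicates are
    always redrawn.  Draw order is preserved for determinism.
    """
    keys: np.ndarray = np.empty(0, dtype=np.int64)
    for _ in range(max_rounds):
        deficit = n_needed - keys.size
        if deficit <= 0:
            return keys[:n_needed]
        batch = max(16, 2 * deficit)
        pts = np.rint(rng.normal(loc=center, scale=sigma, size=(batch, 2))).astype(int)
        if wrap:
            pts = np.mod(pts, grid)
            ok = np.ones(pts.shape[0], dtype=bool)
        else:
            ok = (pts >= 0).all(axis=1) & (pts < grid).all(axis=1)
        if not ok.any():
            continue
        new = key_of(pts[ok, 0], pts[ok, 1])
        pool = np.concatenate([keys, new])
        _, first = np.unique(pool, return_index=True)
        keys = pool[np.sort(first)]
    raise RuntimeError(
        f"could not find {n_needed} distinct sources within the sampling radius "
        f"(sigma={sigma:.3g}, grid={grid}); the radius is too small for this "
        "connection count"
    )


def build_network(
    specs: list[LayerSpec],
    input_size: int = 256,
    input_channels: int = 32,
    seed: int = 0,
    n_frequencies: int = 4,
    boundary: str = "wrap",
) -> Network:
    """Construct connectivity and initial weights for the full hierarchy.

    Layer 1 neurons sample (channel, pixel) sources from the Gabor retina:
    spatial positions from the retinotopic Gaussian, channels allocated
    across frequency bands by :func:`frequency_allocation` and uniformly over
    the 8 (orientation, sign) channels within a band.  Layers 2-4 sample
    presynaptic neurons from the previous grid.  Deterministic per seed.
    """
    if len(specs) < 1:
        raise ValueError("at least one LayerSpec required")
    if input_channels % (2 * n_frequencies) != 0:
        raise ValueError("input_channels must be divisible by 2 * n_frequencies")
    per_band = input_channels // n_frequencies  # orientation x sign channels per band
    rng = np.random.default_rng(seed)
    connectivity: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for l, spec in enumerate(specs):
        if l == 0:
            pre_grid, n_sources = input_size, input_size * input_size * input_channels
        else:
            pre_grid = specs[l - 1].grid
            n_sources = pre_grid * pre_grid
        if spec.n_connections > n_sources:
            raise ValueError(
                f"Layer {l + 1}: {spec.n_connections} connections exceed "
                f"{n_sources} available distinct sources"
            )
        sigma = spec.radius / GAUSS_RADIUS_SIGMA
        conn = np.empty((spec.n_neurons, spec.n_connections), dtype=np.int64)
        if l == 0:
            counts = frequency_allocation(spec.n_connections, n_frequencies)
        for idx in range(spec.n_neurons):
            i, j = divmod(idx, spec.grid)
            # retinotopic projection of this neuron into the presynaptic sheet
            cy = (i + 0.5) * pre_grid / spec.grid - 0.5
            cx = (j + 0.5) * pre_grid / spec.grid - 0.5
            wrap = boundary == "wrap"

            def key_plain(rr, cc, _g=pre_grid):
                return rr * _g + cc

            if l == 0:
                parts = []
                for f in range(n_frequencies):
                    lo = f * per_band

                    def key_band(rr, cc, _lo=lo):
                        ch = rng.integers(_lo, _lo + per_band, size=rr.shape[0])
                        return (rr * pre_grid + cc) * input_channels + ch

                    parts.append(
                        _sample_unique_sources(
                            rng, int(counts[f]), (cy, cx), sigma, pre_grid, key_band, wrap
                        )
                    )
                conn[idx] = np.concatenate(parts)
            else:
                conn[idx] = _sample_unique_sources(
                    rng, spec.n_connections, (cy, cx), sigma, pre_grid, key_plain, wrap
                )
        w = rng.uniform(0.0, 1.0, size=conn.shape)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        connectivity.append(conn)
        weights.append(w)
    return Network(
        layers=list(specs),
        connectivity=connectivity,
        weights=weights,
        input_size=input_size,
        input_channels=input_channels,
        rng_seed=seed,
    )


def input_coverage_fraction(network: Network) -> float:
    """Fraction of retina pixels reachable (transitively) from the top Layer.

    Propagates the union of afferent fields down the hierarchy; the radii of
    the default configurations are chosen so this is 1.0 (every top-Layer
    population covers the entire input retina).
    """
    top = network.n_layers - 1
    reachable = np.unique(network.connectivity[top])
    for l in range(top - 1, -1, -1):
        reachable = np.unique(network.connectivity[l][reachable].ravel())
    pixels = np.unique(reachable // network.input_channels)
    return pixels.size / float(network.input_size**2)
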