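"""Neuron activations, lateral inhibition, and sparseness-targeted rates.

Competition within a Layer is implemented by thresholding: the sigmoid
threshold is placed by monotone search so that, after zeroing all neurons
below it and passing the rest through the sigmoid

    y = 1 / (1 + exp(-2 beta (r - threshold))),

the measured sparseness

    a = (sum_i y_i / n)^2 / (sum_i y_i^2 / n)

of the resulting rate vector matches the Layer's target.  Sub-threshold
neurons are set to exactly zero — only the most activated neurons fire.  On
binary rate vectors the sparseness measure equals the active fraction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import convolve as nd_convolve
from scipy.special import expit

__all__ = [
    "compute_activations",
    "lateral_inhibition",
    "dog_kernel",
    "sparseness",
    "rates_from_activations",
]


def compute_activations(prev_rates: np.ndarray, network, layer_index: int) -> np.ndarray:
    """Dot product of each neuron's weight vector with its afferent rates.

    ``prev_rates`` is the flattened presynaptic representation: the raveled
    (size, size, channels) Gabor retina for Layer 1 (``layer_index`` 0), or
    the raveled rate grid of the Layer below otherwise.
    """
    prev_rates = np.asarray(prev_rates).ravel()
    spec = network.layers[layer_index]
    if layer_index == 0:
        expected = network.input_size**2 * network.input_channels
    else:
        expected = network.layers[layer_index - 1].n_neurons
    if prev_rates.size != expected:
        raise ValueError(
            f"presynaptic rate vector has {prev_rates.size} elements, "
            f"Layer {layer_index + 1} expects {expected}"
        )
    x = prev_rates[network.connectivity[layer_index]]
    return np.einsum("ij,ij->i", network.weights[layer_index], x)


def dog_kernel(sigma_centre: float = 1.0, sigma_surround: float = 2.0, half: int | None = None) -> np.ndarray:
    """Zero-sum Difference-of-Gaussians kernel (excitatory centre, inhibitory surround)."""
    if half is None:
        half = int(np.ceil(3 * sigma_surround))
    ax = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    centre = np.exp(-r2 / (2 * sigma_centre**2))
    surround = np.exp(-r2 / (2 * sigma_surround**2))
    centre /= centre.sum()
    surround /= surround.sum()
    return centre - surround


def lateral_inhibition(
    activations: np.ndarray,
    grid: int,
    sigma_centre: float = 1.0,
    sigma_surround: float = 2.0,
    enabled: bool = True,
) -> np.ndarray:
    """Convolve the activation map with a zero-sum DoG filter (optional stage).

    A uniform map maps to ~0 everywhere; a single active neuron produces a
    positive centre with a negative surround ring.  Disabled, this is the
    identity.
    """
    activations = np.asarray(activations, dtype=np.float64)
    if not enabled:
        return activations
    amap = activations.reshape(grid, grid)
    kernel = dog_kernel(sigma_centre, sigma_surround)
    return nd_convolve(amap, kernel, mode="nearest").ravel()


def sparseness(rates: np.ndarray) -> float:
    """Population sparseness a = (mean y)^2 / mean(y^2), in (0, 1].

    Equals the active fraction for binary rate vectors; by convention 0 for
    an all-zero vector.
    """
    y = np.asarray(rates, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("rate vector must have at least one element")
    sq = float(np.mean(y**2))
    if sq == 0.0:
        return 0.0
    return float(np.mean(y)) ** 2 / sq


def _rates_for_k(r: np.ndarray, order: np.ndarray, k: int, beta: float) -> np.ndarray:
    """Keep the top-k activations (index tie-break), sigmoid about the k-th."""
    y = np.zeros_like(r)
    kept = order[:k]
    thr = r[kept[-1]]
    y[kept] = 1.0 / (1.0 + np.exp(-2.0 * beta * (r[kept] - thr)))
    return y


def _sparseness_for_k(rs: np.ndarray, k: int, beta: float, n: int) -> float:
    """Sparseness of the thresholded sigmoid vector, from sorted activations.

    Equivalent to ``sparseness(_rates_for_k(...))`` but touches only the k
    kept values: with s1 = sum(y), s2 = sum(y^2) over kept neurons (the rest
    are zero), a = s1^2 / (n * s2).
    """
    kept = 1.0 / (1.0 + np.exp(-2.0 * beta * (rs[:k] - rs[k - 1])))
    s1 = float(kept.sum())
    s2 = float((kept * kept).sum())
    return s1 * s1 / (n * s2)


def rates_from_activations(
    activations: np.ndarray,
    a_target: float,
    beta: float,
    mode: str = "hard",
) -> np.ndarray:
    """Convert activations to firing rates at (approximately) a target sparseness.

    Two readings of the sparseness-setting competition are provided:

    ``mode="hard"`` (default): the sigmoid threshold is the activation of the
    k-th most activated neuron (so that neuron fires at exactly 0.5); k is
    found by bisection so that the measured sparseness of the thresholded,
    sigmoid-transformed vector is as close as possible to ``a_target``.
    Neurons below threshold are exactly 0, and only neurons with strictly
    positive activation can be kept (when any exist): a silent afferent
    field is not "most activated".

    ``mode="graded"``: the sigmoid is applied to every neuron about the
    threshold at the (1 - a_target) activation percentile, so sub-threshold
    neurons keep small graded rates whose magnitude shrinks as ``beta``
    grows — at very large beta the rates become binary and the active
    fraction equals ``a_target`` exactly.  This is the regime in which the
    sigmoid slope controls whether low-rate neurons participate in learning.

    Ties and the degenerate all-equal case are broken by neuron index (with
    a warning for the degenerate case).
    """
    if not (0.0 < a_target <= 1.0):
        raise ValueError("a_target must be in (0, 1]")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if mode not in ("hard", "graded"):
        raise ValueError(f"unknown competition mode {mode!r}")
    r = np.asarray(activations, dtype=np.float64).ravel()
    n = r.size
    if np.ptp(r) == 0.0:
        warnings.warn(
            "all activations identical; degenerate top-k selection by index",
            stacklevel=2,
        )
        k = max(1, round(a_target * n))
        y = np.zeros(n)
        y[:k] = 0.5
        return y
    if mode == "graded":
        k = max(1, round(a_target * n))
        thr = np.partition(r, n - k)[n - k]
        y = expit(2.0 * beta * (r - thr))
        y[y < 1e-9] = 0.0
        return y
    # stable sort on (-r, index): highest activation first, index tie-break
    order = np.argsort(-r, kind="stable")
    rs = r[order]
    k_max = int(max(1, (r > 0).sum())) if r.max() > 0 else n
    lo, hi = 1, k_max
    # sparseness of the thresholded vector is nondecreasing in k: bisect,
    # then take the better of the two bracketing candidates
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _sparseness_for_k(rs, mid, beta, n) < a_target:
            lo = mid
        else:
            hi = mid
    best = min(
        sorted({lo, hi}),
        key=lambda k: abs(_sparseness_for_k(rs, k, beta, n) - a_target),
    )
    return _rates_for_k(r, order, best, beta)
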