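"""Layer-by-layer training orchestration.

Layers are trained strictly sequentially: Layer 1 to convergence-by-epoch-
count with a purely associative (trace-free) rule so feature-combination
neurons form before any invariance learning, then Layers 2-4 with the trace.
Within an epoch all views of one object are presented consecutively in random
order before the next object (object-blocked schedule), so the short-term
trace binds views of the same object and not across objects.  Because lower
layers are frozen while a layer trains, their responses to every stimulus are
precomputed once per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from visnet.activation import compute_activations, lateral_inhibition, rates_from_activations
from visnet.architecture import Network
from visnet.gabor import GaborBank, build_gabor_bank, filter_image
from visnet.learning import LearningConfig, TraceState, update_trace


def _update_weights_inplace(
    rule: str,
    w: np.ndarray,
    x: np.ndarray,
    post: np.ndarray,
    lr: float,
    max_weight: float | None,
    buf: np.ndarray,
) -> None:
    """In-place, low-allocation equivalent of :func:`visnet.learning.apply_rule`.

    ``buf`` is a reusable scratch array of w's shape.  Semantics match the
    pure rule functions exactly (verified by test); this path exists because
    the update runs once per presentation per neuron sheet.
    """
    if lr == 0.0:
        return
    col = (lr * post)[:, None]
    if rule == "competitive_standard":
        np.subtract(x, w, out=buf)
        buf *= col
        w += buf
    elif rule == "oja":
        np.multiply(w, post[:, None], out=buf)
        np.subtract(x, buf, out=buf)
        buf *= col
        w += buf
    elif rule == "hebb_normalized":
        np.multiply(x, col, out=buf)
        w += buf
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        w /= norms
    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown rule {rule!r}")
    if max_weight is not None:
        np.minimum(w, max_weight, out=w)
from visnet.stimuli import StimulusSet

__all__ = [
    "TrainingSchedule",
    "precompute_filtered",
    "forward_rates",
    "train_layer",
    "train_network",
]

logger = logging.getLogger("visnet")


@dataclass
class TrainingSchedule:
    """Presentation schedule: per-Layer epoch counts and the ordering seed.

    ``epochs_per_layer`` may be a single int (same for every Layer) or a
    sequence of four.  Orders are object-blocked: per epoch, objects appear
    in shuffled order and the views within each object are shuffled, but all
    views of one object are consecutive.
    """

    epochs_per_layer: int | tuple[int, ...] = 50
    rng_seed: int = 0
    shuffle_objects: bool = True

    def epochs(self, layer_index: int) -> int:
        if isinstance(self.epochs_per_layer, int):
            return self.epochs_per_layer
        return int(self.epochs_per_layer[layer_index])

    def presentation_order(
        self, n_objects: int, n_views: int, layer_index: int, epoch: int
    ) -> list[tuple[int, int]]:
        """Deterministic object-blocked (object, view) order for one epoch."""
        rng = np.random.default_rng(
            (self.rng_seed, layer_index, epoch)
        )
        objects = np.arange(n_objects)
        if self.shuffle_objects:
            rng.shuffle(objects)
        order: list[tuple[int, int]] = []
        for o in objects:
            views = rng.permutation(n_views)
            order.extend((int(o), int(v)) for v in views)
        return order


def precompute_filtered(stimuli: StimulusSet, bank: GaborBank) -> list[np.ndarray]:
    """Gabor-filter every stimulus once; raveled float32 responses, object-major."""
    out = []
    for _o, _v, img in stimuli.iter_views():
        out.append(filter_image(img, bank).astype(np.float32).ravel())
    return out


def forward_rates(
    network: Network,
    filtered_flat: np.ndarray,
    n_layers: int | None = None,
    inhibition: dict | None = None,
) -> list[np.ndarray]:
    """Forward pass (no learning): per-Layer rate vectors for one stimulus.

    ``inhibition``, when given, holds DoG parameters
    (``sigma_centre``, ``sigma_surround``) applied to each Layer's
    activation map before the sparseness-setting sigmoid.
    """
    if n_layers is None:
        n_layers = network.n_layers
    rates: np.ndarray = filtered_flat
    out: list[np.ndarray] = []
    for l in range(n_layers):
        spec = network.layers[l]
        r = compute_activations(rates, network, l)
        if inhibition:
            r = lateral_inhibition(
                r,
                spec.grid,
                sigma_centre=inhibition.get("sigma_centre", 1.0),
                sigma_surround=inhibition.get("sigma_surround", 2.0),
            )
        y = rates_from_activations(r, spec.sparseness, spec.beta, mode=spec.competition)
        out.append(y)
        rates = y
    return out


def train_layer(
    network: Network,
    layer_index: int,
    stimuli: StimulusSet,
    schedule: TrainingSchedule,
    learning_config: LearningConfig,
    filtered: list[np.ndarray] | None = None,
    bank: GaborBank | None = None,
    inhibition: dict | None = None,
    presentation_log: list | None = None,
) -> Network:
    """Train one Layer in place with all lower Layers frozen.

    For each presentation: forward pass through the frozen lower Layers,
    compute this Layer's rates, update the trace, and update this Layer's
    weights with the configured rule (then clip).  Layer 1
    (``layer_index`` 0) uses the instantaneous rate as the postsynaptic
    term; higher Layers use the short-term trace — by default the trace from
    the previous presentation only.
    """
    if not (0 <= layer_index < network.n_layers):
        raise IndexError(f"layer_index {layer_index} out of range")
    if layer_index > network.trained_layers:
        raise RuntimeError(
            f"Layer {layer_index + 1} requires Layers below it to be trained first"
        )
    if filtered is None:
        if bank is None:
            bank = build_gabor_bank()
        filtered = precompute_filtered(stimuli, bank)
    # lower layers are frozen: cache their output for every stimulus
    if layer_index == 0:
        prev = filtered
    else:
        prev = [
            forward_rates(network, f, n_layers=layer_index, inhibition=inhibition)[-1]
            for f in filtered
        ]
    spec = network.layers[layer_index]
    conn = network.connectivity[layer_index]
    w = network.weights[layer_index]
    cfg = learning_config
    trace = TraceState.zeros(spec.n_neurons, cfg.eta)
    n_views = stimuli.n_views
    # afferent rates per stimulus, gathered once (lower layers are frozen);
    # skipped for very large layers where the cache would dominate memory
    cache_bytes = len(prev) * conn.size * 8
    if cache_bytes <= 512 * 1024**2:
        gathered = [np.asarray(p, dtype=np.float64)[conn] for p in prev]
    else:
        gathered = None
    buf = np.empty_like(w)
    for epoch in range(schedule.epochs(layer_index)):
        w_before = w.copy()
        order = schedule.presentation_order(
            stimuli.n_objects, n_views, layer_index, epoch
        )
        current_object = None
        for o, v in order:
            if o != current_object:
                current_object = o
                if cfg.reset_trace_per_object:
                    trace.reset()
            idx = o * n_views + v
            x = gathered[idx] if gathered is not None else prev[idx][conn]
            r = np.einsum("ij,ij->i", w, x)
            if inhibition:
                r = lateral_inhibition(
                    r,
                    spec.grid,
                    sigma_centre=inhibition.get("sigma_centre", 1.0),
                    sigma_surround=inhibition.get("sigma_surround", 2.0),
                )
            y = rates_from_activations(r, spec.sparseness, spec.beta, mode=spec.competition)
            if layer_index == 0:
                post = y
            elif cfg.use_previous_trace_only:
                post = trace.trace.copy()
                update_trace(y, trace)
            else:
                update_trace(y, trace)
                post = trace.trace
            if np.any(post):
                _update_weights_inplace(
                    cfg.rule, w, x, post, cfg.learning_rate, spec.max_weight, buf
                )
            if presentation_log is not None:
                presentation_log.append((epoch, o, v))
        network.weights[layer_index] = w
        logger.info(
            "layer %d epoch %d/%d mean |dw| = %.3e",
            layer_index + 1,
            epoch + 1,
            schedule.epochs(layer_index),
            float(np.abs(w - w_before).mean()),
        )
    network.trained_layers = max(network.trained_layers, layer_index + 1)
    return network


def train_network(
    network: Network,
    stimuli: StimulusSet,
    schedule: TrainingSchedule,
    learning_config: LearningConfig,
    bank: GaborBank | None = None,
    inhibition: dict | None = None,
) -> Network:
    """Train Layers 1..4 sequentially; returns the (mutated) network.

    Gabor responses of all stimuli are computed once up front and reused for
    every Layer and epoch (the stimuli are static across training).
    """
    if stimuli.n_objects < 1:
        raise ValueError("stimulus set is empty")
    if bank is None:
        bank = build_gabor_bank()
    filtered = precompute_filtered(stimuli, bank)
    for l in range(network.n_layers):
        train_layer(
            network,
            l,
            stimuli,
            schedule,
            learning_config,
            filtered=filtered,
            bank=bank,
            inhibition=inhibition,
        )
    return network
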