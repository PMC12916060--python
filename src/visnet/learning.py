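"""Synaptic learning: trace state, the three update rules, and weight clipping.

Three rules are compared throughout:

- ``hebb_normalized``: classic associative increase ``dw_j = alpha * y * x_j``
  followed by renormalising the weight vector to unit Euclidean length.
- ``competitive_standard``: ``dw_j = alpha * y * (x_j - w_j)`` — Hebbian LTP
  plus heterosynaptic LTD of strong weights on strongly activated neurons;
  self-scaling, no explicit normalisation needed.  The package default.
- ``oja``: ``dw_j = alpha * y * (x_j - y * w_j)`` — implicit weight-vector
  normalisation; identical to the competitive rule when y = 1 (binary rates).

In Layers 2-4 the postsynaptic term is a short-term memory trace
``ybar_tau = (1 - eta) * y_tau + eta * ybar_(tau-1)`` of recent firing
(default: the trace from the previous presentation only), which binds
temporally adjacent views of one object.  Layer 1 learns purely
associatively with the instantaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RULES",
    "TraceState",
    "LearningConfig",
    "update_trace",
    "hebb_update_normalized",
    "competitive_standard_update",
    "oja_update",
    "clip_weights",
    "apply_rule",
]

RULES = ("hebb_normalized", "competitive_standard", "oja")


@dataclass
class TraceState:
    """Per-neuron short-term memory trace ybar with mixing proportion eta."""

    trace: np.ndarray
    eta: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta < 1.0):
            raise ValueError("eta must be in [0, 1)")
        self.trace = np.asarray(self.trace, dtype=np.float64)

    @classmethod
    def zeros(cls, n: int, eta: float = 0.8) -> "TraceState":
        return cls(trace=np.zeros(n), eta=eta)

    def reset(self) -> None:
        self.trace[:] = 0.0


@dataclass(frozen=True)
class LearningConfig:
    """Rule selection and learning parameters.

    ``use_previous_trace_only`` (default on) makes the postsynaptic term of
    Layers 2-4 the trace from the previous presentation, with no contribution
    from the current (possibly never-seen) view.  ``reset_trace_per_object``
    (default on) zeroes the trace at object boundaries so the last views of
    one object are not associated into the next.
    """

    rule: str = "competitive_standard"
    learning_rate: float = 0.5
    eta: float = 0.8
    max_weight: float | None = None
    use_previous_trace_only: bool = True
    reset_trace_per_object: bool = True
    epochs_per_layer: int = 50

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0 (0 = dry run, no learning)")
        if not (0.0 <= self.eta < 1.0):
            raise ValueError("eta must be in [0, 1)")

    def with_rule(self, rule: str) -> "LearningConfig":
        return replace(self, rule=rule)


def update_trace(y: np.ndarray, state: TraceState) -> TraceState:
    """ybar_new = (1 - eta) * y + eta * ybar_old, elementwise (in place)."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape != state.trace.shape:
        raise ValueError(f"rate shape {y.shape} != trace shape {state.trace.shape}")
    state.trace = (1.0 - state.eta) * y + state.eta * state.trace
    return state


def _post_col(y_post, w: np.ndarray):
    """Broadcast the postsynaptic term against a 1-D or 2-D weight array."""
    y = np.asarray(y_post, dtype=np.float64)
    if w.ndim == 2:
        return y.reshape(-1, 1)
    return y


def hebb_update_normalized(w: np.ndarray, x: np.ndarray, y_post, alpha: float = 1.0) -> np.ndarray:
    """w' = w + alpha * y_post * x, then w' <- w' / ||w'||_2.

    Works on a single weight vector or row-wise on an (n_neurons, n_conn)
    array with ``y_post`` a vector.  Returned rows have unit Euclidean length
    (rows that would be zero are left at zero).
    """
    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    out = w + alpha * _post_col(y_post, w) * x
    norms = np.linalg.norm(out, axis=-1, keepdims=True)
    norms = np.where(norms == 0.0, 1.0, norms)
    return out / norms


def competitive_standard_update(w: np.ndarray, x: np.ndarray, y_post, alpha: float = 1.0) -> np.ndarray:
    """dw_j = alpha * y_post * (x_j - w_j): LTP towards x, heterosynaptic LTD
    of weights above the presynaptic rate.  With alpha * y_post <= 1 and
    x, w in [0, 1] the update is a convex combination and weights stay in
    [0, 1]; x_j = w_j is a fixed point."""
    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    return w + alpha * _post_col(y_post, w) * (x - w)


def oja_update(w: np.ndarray, x: np.ndarray, y_post, alpha: float = 1.0) -> np.ndarray:
    """dw_j = alpha * y_post * (x_j - y_post * w_j).

    The postsynaptic term enters quadratically (this is what normalises the
    weight-vector length implicitly); reduces to the competitive rule when
    y_post = 1.
    """
    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    y = _post_col(y_post, w)
    return w + alpha * y * (x - y * w)


def clip_weights(w: np.ndarray, max_weight: float | None) -> np.ndarray:
    """Elementwise ceiling min(w, max_weight); identity when max_weight is None."""
    if max_weight is None:
        return np.asarray(w, dtype=np.float64)
    if max_weight <= 0:
        raise ValueError("max_weight must be > 0")
    return np.minimum(np.asarray(w, dtype=np.float64), max_weight)


def apply_rule(
    rule: str,
    w: np.ndarray,
    x: np.ndarray,
    y_post: np.ndarray,
    learning_rate: float,
    max_weight: float | None = None,
) -> np.ndarray:
    """One weight update with the named rule, followed by clipping if enabled."""
    if rule == "hebb_normalized":
        out = hebb_update_normalized(w, x, y_post, alpha=learning_rate)
    elif rule == "competitive_standard":
        out = competitive_standard_update(w, x, y_post, alpha=learning_rate)
    elif rule == "oja":
        out = oja_update(w, x, y_post, alpha=learning_rate)
    else:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    return clip_weights(out, max_weight)
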