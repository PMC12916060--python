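"""Evaluation: correlation matrices, object selectivity, replicates, capacity.

The object-selectivity statistic S summarises the top-Layer correlation
matrix over all views of all objects:

    S = W / (W_perfect + B)

where W is the sum of within-object off-diagonal correlations, W_perfect is
the value W would take if every within-object off-diagonal correlation were
1 (= n_objects * n_views * (n_views - 1), both triangles), and B is the sum
of all between-object correlations.  Negative correlations are clipped at 0
before summation, so S is 1 for a perfect block-diagonal correlation
structure (views of each object perfectly correlated, no correlation across
objects) and 0 when nothing correlates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from visnet.activation import sparseness
from visnet.architecture import Network, build_network
from visnet.gabor import GaborBank, build_gabor_bank
from visnet.learning import LearningConfig
from visnet.stimuli import StimulusSet
from visnet.training import TrainingSchedule, forward_rates, precompute_filtered, train_layer

__all__ = [
    "EvaluationResult",
    "response_matrix",
    "correlation_matrix",
    "object_selectivity",
    "evaluate_network",
    "replicate_statistics",
    "capacity_at_criterion",
    "capacity_sweep",
    "weight_distribution_diagnostics",
]


@dataclass
class EvaluationResult:
    """Top-Layer rate matrix, its view x object correlation matrix, and S."""

    rate_matrix: np.ndarray
    corr: np.ndarray
    object_selectivity: float
    n_objects: int
    n_views: int


def response_matrix(
    network: Network,
    stimuli: StimulusSet,
    bank: GaborBank | None = None,
    filtered: list[np.ndarray] | None = None,
    inhibition: dict | None = None,
) -> np.ndarray:
    """Top-Layer rates for every (object, view): rows object-major.

    A pure forward pass — no learning, no trace.  Shape
    (n_objects * n_views, n_neurons of the top Layer).
    """
    if network.trained_layers < network.n_layers:
        warnings.warn("network is not fully trained; computing responses anyway", stacklevel=2)
    if filtered is None:
        if bank is None:
            bank = build_gabor_bank()
        filtered = precompute_filtered(stimuli, bank)
    rows = [forward_rates(network, f, inhibition=inhibition)[-1] for f in filtered]
    return np.vstack(rows)


def correlation_matrix(rate_matrix: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between rows.

    Zero-variance rows correlate 0 with everything and 1 with themselves.
    """
    rm = np.asarray(rate_matrix, dtype=np.float64)
    if rm.ndim != 2 or rm.shape[0] < 2:
        raise ValueError("rate matrix must be 2-D with at least 2 rows")
    sd = rm.std(axis=1)
    ok = sd > 0
    corr = np.zeros((rm.shape[0], rm.shape[0]))
    if ok.any():
        sub = np.corrcoef(rm[ok])
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 1.0)
    return corr


def object_selectivity(
    corr: np.ndarray,
    n_objects: int,
    n_views: int,
    clip_negative: bool = True,
) -> float:
    """Object selectivity S = W / (W_perfect + B) in [0, 1].

    ``corr`` must be the (n_objects * n_views)^2 correlation matrix with rows
    object-major.  Within-object sums exclude the diagonal; W_perfect counts
    both triangles.  Negative correlations are clipped at 0 before summation
    (switchable), which pins the minimum at exactly 0.
    """
    corr = np.asarray(corr, dtype=np.float64)
    n = n_objects * n_views
    if corr.shape != (n, n):
        raise ValueError(f"corr has shape {corr.shape}, expected ({n}, {n})")
    if n_views < 2:
        raise ValueError("object selectivity is undefined for n_views < 2")
    c = np.clip(corr, 0.0, None) if clip_negative else corr
    labels = np.repeat(np.arange(n_objects), n_views)
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    within = float(c[same & off_diag].sum())
    between = float(c[~same].sum())
    w_perfect = float(n_objects * n_views * (n_views - 1))
    return within / (w_perfect + between)


def evaluate_network(
    network: Network,
    stimuli: StimulusSet,
    bank: GaborBank | None = None,
    filtered: list[np.ndarray] | None = None,
    inhibition: dict | None = None,
) -> EvaluationResult:
    """Forward-pass evaluation: rate matrix, correlation matrix, selectivity."""
    rm = response_matrix(network, stimuli, bank=bank, filtered=filtered, inhibition=inhibition)
    corr = correlation_matrix(rm)
    s = object_selectivity(corr, stimuli.n_objects, stimuli.n_views)
    return EvaluationResult(
        rate_matrix=rm,
        corr=corr,
        object_selectivity=s,
        n_objects=stimuli.n_objects,
        n_views=stimuli.n_views,
    )


def _run_once(
    specs,
    stimuli: StimulusSet,
    learning_config: LearningConfig,
    schedule: TrainingSchedule,
    network_seed: int,
    bank: GaborBank | None = None,
    filtered: list[np.ndarray] | None = None,
    inhibition: dict | None = None,
) -> tuple[float, Network]:
    """Build, train and evaluate one network; returns (selectivity, network)."""
    if bank is None:
        bank = build_gabor_bank()
    if filtered is None:
        filtered = precompute_filtered(stimuli, bank)
    network = build_network(
        specs, input_size=stimuli.size, input_channels=bank.n_channels, seed=network_seed
    )
    for l in range(network.n_layers):
        train_layer(
            network, l, stimuli, schedule, learning_config,
            filtered=filtered, bank=bank, inhibition=inhibition,
        )
    result = evaluate_network(network, stimuli, bank=bank, filtered=filtered, inhibition=inhibition)
    return result.object_selectivity, network


def replicate_statistics(
    specs,
    stimuli: StimulusSet,
    learning_configs: dict[str, LearningConfig],
    schedule: TrainingSchedule,
    seeds: list[int],
    bank: GaborBank | None = None,
    inhibition: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[float]]]:
    """Full train+evaluate replicates per condition over a shared seed list.

    New network seeds per run, shared stimuli across conditions.  Returns
    (summary, pairwise, raw): per-condition
    mean/SD, two-sample equal-variance t-statistics between conditions
    (df = n1 + n2 - 2), and the raw per-seed selectivities.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds for replicate statistics")
    if bank is None:
        bank = build_gabor_bank()
    filtered = precompute_filtered(stimuli, bank)
    raw: dict[str, list[float]] = {}
    for name, cfg in learning_configs.items():
        raw[name] = [
            _run_once(specs, stimuli, cfg, schedule, seed, bank, filtered, inhibition)[0]
            for seed in seeds
        ]
    summary = pd.DataFrame(
        {
            "condition": list(raw),
            "mean": [float(np.mean(v)) for v in raw.values()],
            "sd": [float(np.std(v, ddof=1)) for v in raw.values()],
            "n": [len(v) for v in raw.values()],
        }
    )
    names = list(raw)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(raw[names[i]], raw[names[j]], equal_var=True)
            rows.append(
                {
                    "condition_a": names[i],
                    "condition_b": names[j],
                    "t": float(t),
                    "df": len(raw[names[i]]) + len(raw[names[j]]) - 2,
                    "p": float(p),
                }
            )
    pairwise = pd.DataFrame(rows)
    return summary, pairwise, raw


def capacity_at_criterion(
    object_counts: list[int], selectivities: list[float], criterion: float = 0.6
) -> int:
    """Largest object count before selectivity first drops to/below criterion.

    Mirrors the load-until-failure protocol: counts are scanned in ascending
    order and the capacity is the last count whose selectivity exceeds the
    criterion before the first failure (0 if the first count already fails).
    """
    if sorted(object_counts) != list(object_counts):
        raise ValueError("object_counts must be ascending")
    capacity = 0
    for count, s in zip(object_counts, selectivities):
        if s <= criterion:
            break
        capacity = count
    return capacity


def capacity_sweep(
    make_specs,
    make_stimuli,
    learning_config: LearningConfig,
    schedule: TrainingSchedule,
    object_counts: list[int],
    criterion: float = 0.6,
    network_seed: int = 0,
    bank: GaborBank | None = None,
) -> tuple[int, pd.DataFrame]:
    """Train/evaluate at each (ascending) object count; capacity at criterion.

    ``make_specs()`` returns the LayerSpecs and ``make_stimuli(n_objects)``
    the stimulus set for one sweep point.  Returns the capacity (per
    :func:`capacity_at_criterion`) and the full S-vs-count table.
    """
    if sorted(object_counts) != list(object_counts):
        raise ValueError("object_counts must be ascending")
    if bank is None:
        bank = build_gabor_bank()
    rows = []
    for count in object_counts:
        stimuli = make_stimuli(count)
        s, _net = _run_once(
            make_specs(), stimuli, learning_config, schedule, network_seed, bank
        )
        rows.append({"n_objects": count, "object_selectivity": s})
    table = pd.DataFrame(rows)
    capacity = capacity_at_criterion(
        list(table["n_objects"]), list(table["object_selectivity"]), criterion
    )
    return capacity, table


def weight_distribution_diagnostics(
    network: Network,
    layer_index: int,
    n_bins: int = 50,
    near_max_fraction: float = 0.1,
) -> dict:
    """Weight-distribution summary for one Layer with a lognormal fit.

    Returns histogram (counts, bin edges), the fraction of weights within
    ``near_max_fraction`` of the Layer's ceiling (the configured max_weight,
    or the observed maximum when unclipped), and a lognormal fit (location
    fixed at 0, strictly positive weights only) with a Kolmogorov-Smirnov
    goodness-of-fit statistic.
    """
    w = network.weights[layer_index].ravel()
    ceiling = network.layers[layer_index].max_weight
    if ceiling is None:
        ceiling = float(w.max()) if w.size else 0.0
    positive = w[w > 0]
    out: dict = {
        "layer": layer_index,
        "n_weights": int(w.size),
        "max_weight_ceiling": float(ceiling),
        "near_max_fraction": (
            float((w >= (1.0 - near_max_fraction) * ceiling).mean()) if ceiling > 0 else 0.0
        ),
        "histogram": np.histogram(w, bins=n_bins),
    }
    if positive.size < 10 or np.ptp(positive) == 0:
        out["lognormal"] = None
        return out
    shape, loc, scale = stats.lognorm.fit(positive, floc=0)
    ks = stats.kstest(positive, "lognorm", args=(shape, loc, scale))
    out["lognormal"] = {
        "sigma": float(shape),
        "mu": float(np.log(scale)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
    return out


def row_sparseness(rate_matrix: np.ndarray) -> np.ndarray:
    """Measured sparseness of each row of a rate matrix (diagnostic)."""
    return np.array([sparseness(row) for row in np.asarray(rate_matrix)])
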