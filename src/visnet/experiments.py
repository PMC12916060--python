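"""Shipped desk-scale experiments: rule comparison, clipping, beta, capacity.

These functions reproduce the model's headline comparisons at problem sizes
a single CPU core handles in minutes: a 64-pixel retina (Gabor wavelengths
16/8/4/2 px), four 32x32 Layers with 100 afferents per neuron (Layer-1
radius 4 px on the retina, higher radii 7 grid units), sparseness 0.01,
sigmoid slope 10, trace proportion 0.8, learning rate 0.5, and 25 epochs
per Layer.  Relative to the full-size configuration this keeps every
mechanism (frequency-scaled Gabor sampling, diluted retinotopic
convergence, trace binding, competition) while shrinking the retina and
synapse counts; reported selectivities are accordingly lower than full-size
runs, and the experiments read out directions and orderings, not absolute
levels.

Every function takes a single ``seed`` that drives all stimulus, network
and schedule randomness, and returns plain dictionaries of computed
numbers.
"""

from __future__ import annotations

import numpy as np

from visnet.architecture import LayerSpec, build_network
from visnet.evaluation import (
    capacity_at_criterion,
    evaluate_network,
    weight_distribution_diagnostics,
)
from visnet.gabor import build_gabor_bank
from visnet.learning import RULES, LearningConfig
from visnet.stimuli import generate_synthetic_objects
from visnet.training import TrainingSchedule, precompute_filtered, train_layer

__all__ = [
    "SCALED_RETINA",
    "scaled_specs",
    "scaled_bank",
    "run_scaled",
    "rule_comparison",
    "clipping_experiment",
    "beta_experiment",
    "capacity_experiment",
]

SCALED_RETINA = 64
SCALED_EPOCHS = 25
SCALED_LEARNING_RATE = 0.5
SCALED_N_CONNECTIONS = 100


def scaled_specs(
    n_connections: int = SCALED_N_CONNECTIONS,
    sparseness: float = 0.01,
    beta: float = 10.0,
    max_weight: float | None = None,
    max_weight_layers: tuple[int, ...] = (0, 1, 2),
    competition: str = "hard",
) -> list[LayerSpec]:
    """Layer specs of the desk-scale network (radii scaled with the retina)."""
    out = []
    for l in range(4):
        radius = 4.0 if l == 0 else 7.0
        mw = max_weight if (max_weight is not None and l in max_weight_layers) else None
        out.append(
            LayerSpec(
                grid=32,
                n_connections=n_connections,
                radius=radius,
                sparseness=sparseness,
                beta=beta,
                max_weight=mw,
                competition=competition,
            )
        )
    return out


def scaled_bank():
    return build_gabor_bank(base_wavelength=16.0)


def run_scaled(
    stimuli,
    specs,
    rule: str = "competitive_standard",
    network_seed: int = 0,
    epochs: int = SCALED_EPOCHS,
    learning_rate: float = SCALED_LEARNING_RATE,
    bank=None,
    filtered=None,
):
    """Train the desk-scale network once and evaluate it.

    Returns (selectivity, network).
    """
    if bank is None:
        bank = scaled_bank()
    if filtered is None:
        filtered = precompute_filtered(stimuli, bank)
    network = build_network(
        specs, input_size=stimuli.size, input_channels=bank.n_channels, seed=network_seed
    )
    schedule = TrainingSchedule(epochs_per_layer=epochs, rng_seed=network_seed)
    config = LearningConfig(rule=rule, learning_rate=learning_rate)
    for l in range(4):
        train_layer(network, l, stimuli, schedule, config, filtered=filtered, bank=bank)
    result = evaluate_network(network, stimuli, bank=bank, filtered=filtered)
    return result.object_selectivity, network


def rule_comparison(seed: int, n_runs: int = 10, n_objects: int = 9, n_views: int = 9) -> dict:
    """Mean object selectivity per learning rule over paired replicate runs.

    Each run draws a fresh stimulus set and network (both derived from
    ``seed``); the three rules are trained on identical stimuli/architecture
    within a run, so the comparison is paired.
    """
    raw: dict[str, list[float]] = {rule: [] for rule in RULES}
    for i in range(n_runs):
        stimuli = generate_synthetic_objects(n_objects, n_views, size=SCALED_RETINA, seed=seed + i)
        bank = scaled_bank()
        filtered = precompute_filtered(stimuli, bank)
        for rule in RULES:
            s, _ = run_scaled(
                stimuli,
                scaled_specs(),
                rule=rule,
                network_seed=seed + i,
                bank=bank,
                filtered=filtered,
            )
            raw[rule].append(s)
    return {
        "mean": {rule: float(np.mean(v)) for rule, v in raw.items()},
        "sd": {rule: float(np.std(v, ddof=1)) for rule, v in raw.items()},
        "n_runs": n_runs,
        "raw": raw,
    }


def clipping_experiment(
    seed: int, n_runs: int = 10, n_objects: int = 20, n_views: int = 9, max_weight: float = 0.1
) -> dict:
    """Clipped (weight ceiling on Layers 1-3) vs unclipped training.

    Returns mean selectivities and the mean fraction of Layer-3 weights
    within 10% of the ceiling (clipped) or of the observed maximum
    (unclipped) — the distributional signature of clipping.
    """
    sel = {"clipped": [], "unclipped": []}
    near_max = {"clipped": [], "unclipped": []}
    for i in range(n_runs):
        stimuli = generate_synthetic_objects(n_objects, n_views, size=SCALED_RETINA, seed=seed + i)
        bank = scaled_bank()
        filtered = precompute_filtered(stimuli, bank)
        for label, mw in (("clipped", max_weight), ("unclipped", None)):
            s, net = run_scaled(
                stimuli,
                scaled_specs(max_weight=mw),
                network_seed=seed + i,
                bank=bank,
                filtered=filtered,
            )
            sel[label].append(s)
            diag = weight_distribution_diagnostics(net, 2)
            near_max[label].append(diag["near_max_fraction"])
    return {
        "mean": {k: float(np.mean(v)) for k, v in sel.items()},
        "near_max_fraction": {k: float(np.mean(v)) for k, v in near_max.items()},
        "n_runs": n_runs,
        "raw": sel,
    }


def beta_experiment(
    seed: int,
    n_runs: int = 6,
    n_objects: int = 20,
    n_views: int = 9,
    betas: tuple[float, float] = (10.0, 100.0),
) -> dict:
    """Effect of the sigmoid slope on a heavily loaded network.

    Runs in the graded competition mode, where beta controls how strongly
    low-rate neurons participate in learning: at beta 10 sub-threshold
    neurons keep small rates and contribute weak synaptic updates, at
    beta >= 100 they are effectively silenced (the NMDA-nonlinearity
    analogy).
    """
    sel: dict[float, list[float]] = {b: [] for b in betas}
    for i in range(n_runs):
        stimuli = generate_synthetic_objects(n_objects, n_views, size=SCALED_RETINA, seed=seed + i)
        bank = scaled_bank()
        filtered = precompute_filtered(stimuli, bank)
        for beta in betas:
            s, _ = run_scaled(
                stimuli,
                scaled_specs(beta=beta, competition="graded"),
                network_seed=seed + i,
                bank=bank,
                filtered=filtered,
            )
            sel[beta].append(s)
    return {
        "mean": {beta: float(np.mean(v)) for beta, v in sel.items()},
        "n_runs": n_runs,
        "raw": {beta: v for beta, v in sel.items()},
    }


#: sampling radius (Layers 2-4) per synapse count in the capacity sweep,
#: scaled so the dilution of the afferent neighbourhood stays roughly
#: constant as synapses are added — added synapses then sample new sources
#: instead of exhausting a fixed neighbourhood
CAPACITY_RADIUS = {50: 5.0, 100: 7.0, 200: 10.0}


def capacity_experiment(
    seed: int,
    synapse_counts: tuple[int, ...] = (50, 100, 200),
    object_counts: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_views: int = 9,
    criterion: float = 0.6,
    n_runs: int = 3,
) -> dict:
    """Objects stored at the selectivity criterion vs synapses per neuron.

    For each synapse count, trains at each (ascending) object count until
    mean selectivity over ``n_runs`` replicates first drops to or below
    ``criterion``; the capacity is the last count before that crossing
    (0 if even the smallest count fails).  This mirrors the load-until-
    failure protocol of capacity testing.  The sampling radius scales with
    the synapse count (:data:`CAPACITY_RADIUS`) to hold dilution constant.
    """
    capacities: dict[int, int] = {}
    tables: dict[int, list] = {}
    bank = scaled_bank()
    for nc in synapse_counts:
        radius = CAPACITY_RADIUS.get(nc, 7.0)
        specs = [
            LayerSpec(32, nc, 4.0 if l == 0 else radius, 0.01, 10.0) for l in range(4)
        ]
        rows = []
        for n_objects in object_counts:
            vals = []
            for i in range(n_runs):
                stimuli = generate_synthetic_objects(
                    n_objects, n_views, size=SCALED_RETINA, seed=seed + i
                )
                s, _ = run_scaled(stimuli, specs, network_seed=seed + i, bank=bank)
                vals.append(s)
            rows.append({"n_objects": n_objects, "object_selectivity": float(np.mean(vals))})
            if rows[-1]["object_selectivity"] <= criterion:
                break
        capacities[nc] = capacity_at_criterion(
            [r["n_objects"] for r in rows],
            [r["object_selectivity"] for r in rows],
            criterion,
        )
        tables[nc] = rows
    return {"capacity": capacities, "tables": tables, "criterion": criterion}
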