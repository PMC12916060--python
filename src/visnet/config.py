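"""Run configuration, presets, and reproducible end-to-end experiments.

A run is fully described by a YAML config (schema version 1): input retina
and filter-bank parameters, the four LayerSpecs, the learning rule and its
constants, the presentation schedule, the stimulus source (synthetic
parameters or an image directory), and seeds.  Every artifact a run writes
is regenerable from its config plus seeds alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from visnet.architecture import LayerSpec, build_network
from visnet.evaluation import evaluate_network, replicate_statistics
from visnet.gabor import build_gabor_bank
from visnet.learning import RULES, LearningConfig
from visnet.stimuli import StimulusSet, generate_synthetic_objects, load_image_directory
from visnet.training import TrainingSchedule, train_network

__all__ = ["RunConfig", "load_preset", "run_experiment", "compare_rules", "PRESETS"]

SCHEMA_VERSION = 1

PRESETS = ("small-32", "large-256")


@dataclass
class RunConfig:
    """Complete, serializable description of one experiment."""

    preset: str = "small-32"
    input_size: int = 256
    input_channels: int = 32
    base_wavelength: float = 16.0
    layers: list[dict] = field(default_factory=list)
    learning: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    stimuli: dict = field(default_factory=dict)
    network_seed: int = 0
    version: int = SCHEMA_VERSION

    # ---- construction -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        version = data.get("version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    # ---- realised objects ---------------------------------------------
    def layer_specs(self) -> list[LayerSpec]:
        return [LayerSpec(**d) for d in self.layers]

    def learning_config(self) -> LearningConfig:
        cfg = LearningConfig(**self.learning)
        if cfg.rule not in RULES:  # re-validated for clear CLI errors
            raise ValueError(f"unknown rule {cfg.rule!r}")
        return cfg

    def training_schedule(self) -> TrainingSchedule:
        return TrainingSchedule(**self.schedule)

    def make_stimuli(self) -> StimulusSet:
        src = dict(self.stimuli)
        kind = src.pop("kind", "synthetic")
        if kind == "synthetic":
            src.setdefault("size", self.input_size)
            return generate_synthetic_objects(**src)
        if kind == "directory":
            return load_image_directory(
                src["path"], size=self.input_size, layout=src.get("layout", "flat")
            )
        raise ValueError(f"unknown stimuli kind {kind!r}")

    def make_bank(self):
        return build_gabor_bank(base_wavelength=self.base_wavelength)


def load_preset(name: str) -> RunConfig:
    """Load a shipped preset config: ``small-32`` (32x32 Layers, 200/340
    connections) or ``large-256`` (256x256 Layers, sparseness 0.0025,
    beta 100, weight ceiling 0.06 on Layers 1-3)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("visnet").joinpath(f"presets/{name}.yaml")
    return RunConfig.from_dict(yaml.safe_load(ref.read_text()))


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute stimuli -> filtering -> build -> train -> evaluate; write artifacts.

    The run directory receives the config copy, the trained network archive,
    the top-Layer correlation-matrix heatmap, and a JSON summary with the
    object selectivity.  Reruns from the saved config reproduce the same
    numbers.
    """
    # validate before any compute so bad configs fail fast
    specs = config.layer_specs()
    learning = config.learning_config()
    schedule = config.training_schedule()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    stimuli = config.make_stimuli()
    bank = config.make_bank()
    network = build_network(
        specs,
        input_size=stimuli.size,
        input_channels=bank.n_channels,
        seed=config.network_seed,
    )
    train_network(network, stimuli, schedule, learning, bank=bank)
    result = evaluate_network(network, stimuli, bank=bank)

    network.save(out_dir / "network.npz")
    np.save(out_dir / "rate_matrix.npy", result.rate_matrix)
    _save_heatmap(result.corr, out_dir / "correlation_matrix.png", stimuli.n_views)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(
            {
                "object_selectivity": result.object_selectivity,
                "n_objects": stimuli.n_objects,
                "n_views": stimuli.n_views,
                "preset": config.preset,
                "rule": learning.rule,
            },
            fh,
            indent=2,
        )
    return out_dir


def _save_heatmap(corr: np.ndarray, path: Path, n_views: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr, vmin=-0.2, vmax=1.0, cmap="viridis")
    ax.set_xlabel("transform (views, object-major)")
    ax.set_ylabel("transform (views, object-major)")
    for b in range(n_views, corr.shape[0], n_views):
        ax.axhline(b - 0.5, color="w", lw=0.3)
        ax.axvline(b - 0.5, color="w", lw=0.3)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_rules(
    config: RunConfig,
    rules: list[str] | None = None,
    n_runs: int = 20,
    seed0: int = 0,
) -> tuple["pd.DataFrame", "pd.DataFrame", dict]:
    """Replicate comparison of learning rules on one shared stimulus set.

    Runs ``replicate_statistics`` with a fresh network seed per run and the
    same stimuli for every rule; returns the mean/SD summary, the pairwise
    t table, and the raw per-seed selectivities.
    """
    if rules is None:
        rules = list(RULES)
    if len(rules) < 2:
        raise ValueError("need at least 2 rules to compare")
    base = config.learning_config()
    configs = {rule: base.with_rule(rule) for rule in rules}
    stimuli = config.make_stimuli()
    return replicate_statistics(
        config.layer_specs(),
        stimuli,
        configs,
        config.training_schedule(),
        seeds=[seed0 + i for i in range(n_runs)],
        bank=config.make_bank(),
    )
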