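"""Pipeline configuration: defaults, YAML loading, strict key checking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything needed to run the full pipeline reproducibly.

    A fully-defaulted config is valid; unknown keys in a YAML file are
    rejected. The config (with the seed) is echoed into the output
    manifest so every output is reproducible from config + seed alone.
    """

    input_dir: str | None = None
    output_dir: str = "msdyn_out"
    # preprocessing
    do_preprocess: bool = True
    bandpass_low: float = 0.1
    bandpass_high: float = 80.0
    notch_band: tuple[float, float] = (48.0, 52.0)
    target_sfreq: float = 500.0
    # microstates
    k: int = 4
    n_init: int = 100
    kmeans_max_iter: int = 1000
    center_update: str = "mean"  # or "eigen"
    peak_exclusion: str = "mean+2sd"  # or "2sd"
    smoothing_min_ms: float = 0.0  # 0 disables backfit smoothing
    include_boundary_runs: bool = True
    clustering_seed: int = 0
    # stats
    t_variant: str = "student"
    alpha: float = 0.05
    # simulation (used when input_dir is None)
    simulation: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if self.peak_exclusion not in ("mean+2sd", "2sd"):
            raise ValueError(f"unknown peak exclusion rule {self.peak_exclusion!r}")
        if self.center_update not in ("mean", "eigen"):
            raise ValueError(f"unknown center update {self.center_update!r}")
        if self.t_variant not in ("student", "welch"):
            raise ValueError(f"unknown t variant {self.t_variant!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        if sim.get("transition") is not None:
            sim["transition"] = [list(map(float, row)) for row in sim["transition"]]
        return d


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return data


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file (strict keys) and apply keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    sim_data = data.pop("simulation", {})
    _build(PipelineConfig, data, "pipeline")
    if isinstance(sim_data, SimConfig):
        sim = sim_data
    else:
        _build(SimConfig, sim_data, "simulation")
        sim = SimConfig(**sim_data)
    cfg = PipelineConfig(simulation=sim, **data)
    cfg.validate()
    return cfg
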