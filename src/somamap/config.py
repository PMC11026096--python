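"""Pipeline configuration: every numeric threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end analysis.

    Defaults follow the analysis conventions: cleft filter at 50, per-edge
    synapse thresholds 7 (main pass) / 3 (sparse-type pass) with 6 as the
    figure variant, output-graph edge retention above 5%, composition
    reporting at 20%, strict midline at x = 0.
    """

    units_scale: float = 1.0
    prune_keep: str = "largest"  # largest|all
    prune_pad_um: float = 2.0
    prune_enabled: bool = True
    resample_step_um: float | None = None
    dotprops_k: int = 5
    sigma_um: float = 3.0
    cleft_min: float = 50.0
    edge_min_main: int = 7
    edge_min_low: int = 3
    edge_min_figure: int = 6
    threshold_mode: str = "per_edge"  # per_edge|per_partner
    fraction_min: float = 0.05
    composition_min_fraction: float = 0.20
    morphology_cut_k: int | None = None  # default: number of types
    morphology_cut_height: float | None = None
    connectivity_cut_k: int | None = None
    connectivity_cut_height: float | None = None
    low_pass_cut_k: int = 5
    large_type: str = "InOm"  # type analyzed separately at the low threshold
    joint: bool = False
    midline_x: float = 0.0
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # generator overrides

    def __post_init__(self) -> None:
        if self.prune_keep not in ("largest", "all"):
            raise ConfigError(f"prune_keep must be largest|all, got {self.prune_keep!r}")
        if self.threshold_mode not in ("per_edge", "per_partner"):
            raise ConfigError(f"bad threshold_mode {self.threshold_mode!r}")
        if self.cleft_min < 0:
            raise ConfigError("cleft_min must be >= 0")
        for name in ("edge_min_main", "edge_min_low", "edge_min_figure"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 <= self.fraction_min < 1:
            raise ConfigError("fraction_min must be in [0, 1)")
        if not 0 <= self.composition_min_fraction <= 1:
            raise ConfigError("composition_min_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
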