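"""Pipeline configuration with the study's default thresholds.

Defaults encode the analysis conventions: a feature is disease-specific when
its score exceeds 2 pooled-IQR units with (BH-adjusted) p < 0.01; the
expression-level GSEA battery is thresholded at adjusted p < 0.01 and the
much larger per-TF regulation battery at 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import yaml

log = logging.getLogger(__name__)


@dataclass
class PandaConfig:
    """Message-passing constants: update rate, stopping rule."""

    alpha: float = 0.1
    tolerance: float = 1e-3
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PipelineConfig:
    score_threshold: float = 2.0
    p_gene: float = 0.01
    p_pathway_expr: float = 0.01
    p_pathway_reg: float = 0.05
    use_adjusted_p: bool = True  # raw-p mode available as a documented switch
    alpha: float = 0.1
    tolerance: float = 1e-3
    max_iterations: int = 200
    permutations_expr: int = 2000
    permutations_reg: int = 500
    gsea_weight_exponent: float = 1.0
    prune_gap_fraction: float = 0.25
    min_cluster_size: int = 2
    seed: int = 0
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        # reuse PandaConfig validation for the shared constants
        PandaConfig(self.alpha, self.tolerance, self.max_iterations)
        if self.score_threshold < 0:
            raise ValueError("score_threshold must be nonnegative")
        for name in ("p_gene", "p_pathway_expr", "p_pathway_reg"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def panda(self) -> PandaConfig:
        return PandaConfig(self.alpha, self.tolerance, self.max_iterations)


def load_config(path: str | None = None) -> PipelineConfig:
    """Read a YAML config; absent keys fall back to the defaults above.

    Unknown keys are an error so that typos do not silently run with
    defaults.  Every effective value is logged at startup.
    """
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        overrides = loaded or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extra"}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**overrides)
    for key, value in asdict(cfg).items():
        if key != "extra":
            log.info("config: %s = %r", key, value)
    return cfg
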