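"""Pipeline configuration: every tunable of the model-selection pipeline in
one dataclass, loadable from YAML and hashable for provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the signature-derivation pipeline.

    Defaults follow the method's stated operating point: correlation filter
    at local-FDR q < 0.2, prognostic filter at meta-analysis alpha 0.05,
    NetRank damping 0.3 over a |r| >= 0.5 unlabeled-sample network, nested
    candidate models up to 15 genes retained within Delta-AIC 10.
    """

    histology: str = "ADC"
    q_threshold: float = 0.2
    alpha: float = 0.05
    corr_method: str = "pearson"        # or "spearman"
    fdr_method: str = "lfdr"            # or "bh"
    damping: float = 0.3
    edge_threshold: float = 0.5
    relevance_transform: str = "neglog10"  # or "one_minus_p"
    dangling: str = "drop"              # or "uniform"
    k_max: int = 15
    delta_aic_max: float = 10.0
    weight_by: str = "bases"            # or "markers"
    threshold_mode: str = "training-median"  # or "cohort-median"

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1 or not 0 < self.alpha < 1:
            raise ValidationError("q_threshold and alpha must lie in (0, 1)")
        if not 0 <= self.damping < 1:
            raise ValidationError("damping must lie in [0, 1)")
        if self.k_max < 0 or self.delta_aic_max < 0:
            raise ValidationError("k_max and delta_aic_max must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
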