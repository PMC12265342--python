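"""Run configuration: defaults, YAML round trip, provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .confidence import ConfidenceConfig
from .graph import GraphConfig
from .score_model import ScoreModelConfig
from .sde import NoiseSchedule


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; all defaults resolve without a file."""

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    graph: GraphConfig = field(default_factory=GraphConfig)
    score: ScoreModelConfig = field(default_factory=ScoreModelConfig)
    confidence: ConfidenceConfig = field(default_factory=ConfidenceConfig)
    n_candidates: int = 100
    n_steps: int = 20
    denoise_last: bool = True
    confidence_cutoff: float = 0.5
    cluster_eps: float = 5.0
    cluster_min_samples: int = 2
    seed: int = 0

    def resolved_score(self) -> ScoreModelConfig:
        """Score config with the shared schedule/graph blocks substituted."""
        return ScoreModelConfig(
            graph=self.graph,
            schedule=self.schedule,
            hidden=self.score.hidden,
            lr=self.score.lr,
            batch_size=self.score.batch_size,
            epochs=self.score.epochs,
            loss_weighting=self.score.loss_weighting,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        blob = yaml.safe_load(text) or {}
        kwargs = {}
        if "schedule" in blob:
            kwargs["schedule"] = NoiseSchedule(**blob.pop("schedule"))
        if "graph" in blob:
            kwargs["graph"] = GraphConfig(**blob.pop("graph"))
        if "score" in blob:
            sc = blob.pop("score")
            sc.pop("graph", None), sc.pop("schedule", None)
            kwargs["score"] = ScoreModelConfig(**sc)
        if "confidence" in blob:
            kwargs["confidence"] = ConfidenceConfig(**blob.pop("confidence"))
        kwargs.update(blob)
        return cls(**kwargs)

    def dump(self, directory: str | Path) -> Path:
        """Write the resolved config into a run directory for provenance."""
        path = Path(directory) / "config.yaml"
        path.write_text(self.to_yaml())
        return path
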