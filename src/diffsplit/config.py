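"""YAML-driven run configuration.

One file drives the whole pipeline; each CLI stage accepts the same file so
stages can be run independently.  Every randomized stage derives its seed
from the single master ``seed``, so a config reproduces a run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .diffusion import DiffusionTrainConfig, make_schedule
from .nn import BackboneSpec, ConfigError
from .segmenter import SegmenterConfig
from .semantic import TrainConfig
from .synthetic import SceneParams


@dataclass(frozen=True)
class RunConfig:
    scene: SceneParams = SceneParams()
    n_train_scenes: int = 40
    n_test_scenes: int = 20
    semantic_spec: BackboneSpec = BackboneSpec(
        channels_per_level=(8, 16, 32), in_channels=1, out_channels=1
    )
    split_spec: BackboneSpec = BackboneSpec(
        channels_per_level=(8, 16, 32), in_channels=4, out_channels=2
    )
    semantic_train: TrainConfig = TrainConfig(steps=200, batch_size=8)
    split_train: DiffusionTrainConfig = field(
        default_factory=lambda: DiffusionTrainConfig(
            schedule=make_schedule(10), steps=400, batch_size=8
        )
    )
    segmenter: SegmenterConfig = SegmenterConfig()
    eval_thresholds: tuple[float, ...] = tuple(
        np.round(np.arange(0.50, 0.951, 0.05), 2)
    )
    seed: int = 0

    def derived_seeds(self) -> dict[str, int]:
        names = ["synthesize_train", "synthesize_test", "semantic", "split", "segment"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s) % (2**31) for n, s in zip(names, state)}

    def with_seeds(self) -> "RunConfig":
        """Propagate the derived per-stage seeds into the sub-configs."""
        seeds = self.derived_seeds()
        return replace(
            self,
            scene=replace(self.scene, seed=seeds["synthesize_train"]),
            semantic_train=replace(self.semantic_train, seed=seeds["semantic"]),
            split_train=replace(self.split_train, seed=seeds["split"]),
        )


def _build(cls, section: dict, **extra):
    try:
        return cls(**{**section, **extra})
    except TypeError as exc:
        raise ConfigError(f"bad {cls.__name__} section: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; missing sections fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    if "scene" in doc:
        sc = dict(doc["scene"])
        for key in ("radius_range", "eccentricity_range"):
            if key in sc:
                sc[key] = tuple(sc[key])
        kwargs["scene"] = _build(SceneParams, sc)
    for key in ("n_train_scenes", "n_test_scenes", "seed"):
        if key in doc:
            kwargs[key] = int(doc[key])
    for key, cls in (("semantic_spec", BackboneSpec), ("split_spec", BackboneSpec)):
        if key in doc:
            sec = dict(doc[key])
            if "channels_per_level" in sec:
                sec["channels_per_level"] = tuple(sec["channels_per_level"])
            kwargs[key] = _build(cls, sec)
    if "semantic_train" in doc:
        kwargs["semantic_train"] = _build(TrainConfig, dict(doc["semantic_train"]))
    if "split_train" in doc:
        sec = dict(doc["split_train"])
        n = int(sec.pop("schedule_steps", 10))
        kwargs["split_train"] = _build(
            DiffusionTrainConfig, sec, schedule=make_schedule(n)
        )
    if "segmenter" in doc:
        kwargs["segmenter"] = _build(SegmenterConfig, dict(doc["segmenter"]))
    if "eval_thresholds" in doc:
        kwargs["eval_thresholds"] = tuple(float(t) for t in doc["eval_thresholds"])
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    """JSON/YAML-serializable view of a RunConfig (for provenance records)."""
    d = asdict(cfg)
    d["split_train"]["schedule"] = {"n": cfg.split_train.schedule.n}
    d["eval_thresholds"] = list(cfg.eval_thresholds)
    return _plainify(d)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
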