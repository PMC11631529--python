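"""End-to-end pipeline: synthesize → train-semantic → train-split → segment
→ evaluate, with per-stage seeding, logging and a provenance record."""

from __future__ import annotations

import csv
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, config_to_dict
from .diffusion import train_split_model
from .evaluation import recall_curve
from .segmenter import segment
from .semantic import predict_semantic, train_semantic
from .synthetic import generate_dataset

log = logging.getLogger("diffsplit")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_loss_csv(path: Path, trace: list[float]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "loss"])
        for i, v in enumerate(trace):
            writer.writerow([i, f"{v:.6f}"])


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute all five stages on synthetic data; returns a report dict.

    Rerunning with the same config reproduces metrics bit-for-bit.  Partial
    outputs are preserved on stage failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg.with_seeds()
    seeds = cfg.derived_seeds()
    report: dict = {"out_dir": str(out)}
    t0 = time.time()

    def stage(name):
        log.info("stage=%s step=start t=%.1fs", name, time.time() - t0)

    try:
        stage("synthesize")
        train_scenes = generate_dataset(
            cfg.scene, cfg.n_train_scenes, seeds["synthesize_train"]
        )
        test_scenes = generate_dataset(
            cfg.scene, cfg.n_test_scenes, seeds["synthesize_test"]
        )
    except Exception as exc:
        raise PipelineError("synthesize", exc) from exc

    try:
        stage("train-semantic")
        sem = train_semantic(train_scenes, cfg.semantic_spec, cfg.semantic_train)
        sem.save(out / "semantic_model.npz")
        _write_loss_csv(out / "semantic_loss.csv", sem.loss_trace)
        report["semantic_final_loss"] = sem.loss_trace[-1] if sem.loss_trace else None
    except Exception as exc:
        raise PipelineError("train-semantic", exc) from exc

    try:
        stage("train-split")
        split = train_split_model(
            train_scenes, cfg.split_spec, cfg.split_train, semantic_model=sem
        )
        split.save(out / "split_model.npz")
        _write_loss_csv(out / "split_loss.csv", split.loss_trace)
        report["split_final_loss"] = split.loss_trace[-1] if split.loss_trace else None
    except Exception as exc:
        raise PipelineError("train-split", exc) from exc

    try:
        stage("segment")
        seg_seeds = np.random.SeedSequence(seeds["segment"]).generate_state(
            len(test_scenes)
        )
        predictions = []
        for i, sc in enumerate(test_scenes):
            s_pred = predict_semantic(sem, sc.image)
            predictions.append(
                segment(
                    split,
                    sc.image,
                    s_pred,
                    cfg.split_train.schedule,
                    cfg.segmenter,
                    seed=int(seg_seeds[i]) % (2**31),
                )
            )
    except Exception as exc:
        raise PipelineError("segment", exc) from exc

    try:
        stage("evaluate")
        truths = [sc.labels for sc in test_scenes]
        curve = recall_curve(predictions, truths, cfg.eval_thresholds)
        with open(out / "metrics.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "n_truth", "n_matched", "recall"])
            n_truth_total = sum(len(t) for t in truths)
            for thr, rec in curve:
                n_matched = 0 if rec is None else round(rec * n_truth_total)
                writer.writerow(
                    [f"{thr:.2f}", n_truth_total, n_matched,
                     "" if rec is None else f"{rec:.6f}"]
                )
        report["recall_curve"] = curve
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc

    provenance = {
        "version": __version__,
        "numpy": np.__version__,
        "config": config_to_dict(cfg),
        "seeds": seeds,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    report["seeds"] = seeds
    return report
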