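"""End-to-end pipeline: segments -> graphs -> cross-validated metrics.

This is the glue the CLI and the examples call: build one graph sample per
labeled window, carve out a stratified hold-out test split, run stratified
k-fold cross-validation on the remainder, train a final model on the
remainder and score it on the hold-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_io import SegmentSet
from .graph import GraphConfig, GraphSample, build_graph_sample
from .model import ArchConfig, ModelParams, init_params
from .train_eval import (
    CVResult, EvalMetrics, StackedDataset, TrainConfig, TrainHistory,
    evaluate, holdout_split, kfold_cv, stack_samples, train,
)


def build_graph_samples(segments: SegmentSet | Sequence,
                        cfg: GraphConfig | None = None,
                        labels: Sequence[str] | None = None,
                        ) -> list[GraphSample]:
    """One graph sample per segment; optional labels override segment labels."""
    cfg = cfg or GraphConfig()
    samples = []
    for i, seg in enumerate(segments):
        if labels is not None:
            seg = replace(seg, label=labels[i]) if hasattr(seg, "label") else seg
        samples.append(build_graph_sample(seg, cfg))
    return samples


@dataclass
class PipelineResult:
    cv: CVResult
    holdout: EvalMetrics | None
    final_history: TrainHistory | None
    final_params: ModelParams | None

    def report(self) -> dict:
        """JSON-ready metrics report."""
        out = {
            "cv": {
                "per_fold": [m.as_dict() for m in self.cv.fold_metrics],
                "mean": self.cv.mean,
                "std": self.cv.std,
            }
        }
        if self.holdout is not None:
            out["holdout"] = self.holdout.as_dict()
        return out


def run_pipeline(samples: Sequence[GraphSample] | StackedDataset,
                 train_cfg: TrainConfig | None = None,
                 arch: ArchConfig | None = None,
                 fit_final: bool = True) -> PipelineResult:
    """Hold-out split, k-fold CV, and (optionally) a final hold-out fit."""
    train_cfg = train_cfg or TrainConfig()
    if not isinstance(samples, StackedDataset):
        samples = stack_samples(samples)
    if arch is None:
        arch = ArchConfig(n_nodes=samples.X.shape[1],
                          feature_dim=samples.X.shape[2])
    rest, hold = holdout_split(samples, train_cfg)
    cv = kfold_cv(rest, train_cfg, arch)
    holdout_metrics = None
    final_history = None
    final_params = None
    if fit_final and len(hold):
        # inner validation split of the CV pool drives early stopping
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(rest))
        tr, va = train_test_split(idx, test_size=0.2, stratify=rest.y,
                                  random_state=train_cfg.seed)
        params = init_params(arch, train_cfg.seed)
        final_params, final_history = train(
            rest.subset(tr), rest.subset(va), params, train_cfg)
        holdout_metrics = evaluate(final_params, hold)
    return PipelineResult(cv=cv, holdout=holdout_metrics,
                          final_history=final_history,
                          final_params=final_params)
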