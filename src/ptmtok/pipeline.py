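"""End-to-end training pipeline: enumerate candidates, balance, split,
train, evaluate — optionally as Monte Carlo cross-validation and optionally
as a paired comparison of with-labels vs without-labels models."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .alphabet import LabelChannel, ModAlphabet, build_alphabet
from .datasets import (
    DatasetSplit,
    balance_negatives,
    enumerate_candidates,
    identity_filter,
    split_dataset,
)
from .evaluation import CVSummary, MetricReport, compute_metrics, summarize_cv
from .model import ModelConfig, TrainedModel, build_model, train

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    alphabet: ModAlphabet
    folds: list[DatasetSplit]
    models: list[TrainedModel]
    reports: list[MetricReport]


def make_config(k: int, alphabet: ModAlphabet, overrides: dict | None = None) -> ModelConfig:
    """Default config for window length ``k``, shrinking the convolution
    kernel and pool for small windows so every k yields a valid network."""
    height = min(7, k)
    pool = max(1, min(4, k - height + 1))
    cfg = ModelConfig(
        k=k,
        vocab_size=alphabet.vocab_size,
        embedding_dim=alphabet.embedding_dim,
        conv_kernel=(height, alphabet.embedding_dim),
        pool=pool,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def run_pipeline(
    proteins: dict[str, str],
    positives: set[tuple[str, int]],
    residue_targets: set[str],
    channels: list[LabelChannel],
    *,
    k: int = 53,
    n_folds: int = 10,
    seed: int = 0,
    identity_cutoff: float = 1.0,
    balance: bool = True,
    config_overrides: dict | None = None,
    per_residue_tokens: bool = True,
) -> PipelineResult:
    """Full train/evaluate run over ``n_folds`` Monte Carlo folds.

    Each fold draws a fresh negative subsample and a fresh split from seed
    ``seed + fold``; the same seeds produce paired folds across calls with
    different ``channels`` (the candidate universe is identical, only the
    window tokens differ).
    """
    alphabet = build_alphabet(channels, per_residue_tokens=per_residue_tokens)
    records = enumerate_candidates(
        proteins, residue_targets, positives, channels, k, alphabet
    )
    logger.info("enumerated %d candidate sites (%d positive)",
                len(records), sum(r.label for r in records))
    cfg = make_config(k, alphabet, config_overrides)

    folds: list[DatasetSplit] = []
    models: list[TrainedModel] = []
    reports: list[MetricReport] = []
    for fold in range(n_folds):
        fold_seed = seed + fold
        pool = balance_negatives(records, fold_seed) if balance else list(records)
        split = split_dataset(pool, seed=fold_seed)
        if identity_cutoff < 1.0:
            split = identity_filter(split, identity_cutoff)
        model = build_model(cfg, alphabet, seed=fold_seed)
        model = train(model, split, seed=fold_seed)
        scores = model.predict([r.window for r in split.test])
        labels = [r.label for r in split.test]
        report = compute_metrics(scores, labels)
        logger.info("fold %d: AUC %.3f AUPRC %.3f (test n=%d)",
                    fold, report.auc, report.auprc, len(labels))
        folds.append(split)
        models.append(model)
        reports.append(report)
    return PipelineResult(alphabet=alphabet, folds=folds, models=models,
                         reports=reports)


def compare_label_channels(
    proteins: dict[str, str],
    positives: set[tuple[str, int]],
    residue_targets: set[str],
    channels: list[LabelChannel],
    **kwargs,
) -> tuple[CVSummary, PipelineResult, PipelineResult]:
    """Paired with-labels vs without-labels comparison over shared fold seeds.

    Returns the paired :class:`CVSummary` (labels arm first) plus both runs.
    """
    with_labels = run_pipeline(
        proteins, positives, residue_targets, channels, **kwargs
    )
    without_labels = run_pipeline(
        proteins, positives, residue_targets, [], **kwargs
    )
    summary = summarize_cv(with_labels.reports, without_labels.reports)
    return summary, with_labels, without_labels
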