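"""Training loop and cross-validation protocol.

Binary cross-entropy loss, Adam (learning rate 1e-4), mini-batches of up to
10,000 labeled pairs, at most 300 epochs.  After every epoch the model is
evaluated on the held-out test pair set in inference mode, and the weights at
the epoch with the best test AUC are retained (earliest epoch on ties).

Cross-validation is stratified by drug: each fold's drugs are entirely held
out, their edges removed from the message-passing graph, so every test drug
is genuinely unseen (the cold-start regime).  Negatives are sampled 1:1 and
independently for the train and test sides, once per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, bce_with_logits
from .data import (
    BipartiteDataset,
    FoldPlan,
    LabeledPairSet,
    sample_negatives,
)
from .evaluation import auc, confusion_metrics
from .model import (
    BiMPADRConfig,
    BiMPADRModel,
    adr_features,
    forward_tape,
    init_model,
    make_param_tensors,
    score_pairs,
)

__all__ = ["TrainSpec", "TrainResult", "bce_loss", "train",
           "run_cross_validation"]


@dataclass
class TrainSpec:
    batch_size: int = 10_000
    learning_rate: float = 1e-4
    max_epochs: int = 300
    seed: int = 0
    per_epoch_negatives: bool = False
    threshold: float = 0.5

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    best_model: BiMPADRModel
    best_epoch: int  # 1-based
    history: pd.DataFrame  # epoch, train_loss, train_auc, test_auc
    embedding_drug_indices: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.intp)
    )

    @property
    def best_test_auc(self) -> float:
        return float(self.history["test_auc"].max())


def bce_loss(scores, labels) -> float:
    """Mean binary cross-entropy of probabilities against binary labels.

    Scores are clamped away from {0, 1} to guard the logarithms.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    eps = 1e-12
    s = np.clip(scores, eps, 1 - eps)
    return float(-np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s)))


def train(
    model: BiMPADRModel,
    dataset: BipartiteDataset,
    train_pairs: LabeledPairSet,
    test_pairs: LabeledPairSet,
    spec: TrainSpec,
) -> TrainResult:
    """Fit ``model`` in place and return the best-epoch snapshot.

    The message-passing graph is restricted to edges of the training drugs,
    so test-drug associations never leak into the ADR embeddings.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training pair set")
    train_drugs = np.unique(train_pairs.drug_idx)
    train_graph = dataset.restrict_edges_to_drugs(train_drugs)
    params = make_param_tensors(model)
    optimizer = Adam(params, lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed)
    pairs = train_pairs
    rows = []
    best_auc, best_epoch, best_weights = -np.inf, -1, model.copy_weights()
    for epoch in range(1, spec.max_epochs + 1):
        if spec.per_epoch_negatives:
            pairs = _resample_negatives_like(
                dataset, train_pairs, seed=int(rng.integers(2**31))
            )
        order = rng.permutation(len(pairs))
        batch_size = min(spec.batch_size, len(pairs))
        losses, sizes = [], []
        for start in range(0, len(pairs), batch_size):
            idx = order[start:start + batch_size]
            batch = LabeledPairSet(
                pairs.drug_idx[idx], pairs.adr_idx[idx], pairs.labels[idx],
                provenance="train",
            )
            logits = forward_tape(model, params, train_graph, batch, rng=rng)
            loss = bce_with_logits(logits, batch.labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            sizes.append(len(batch))
        feats = adr_features(model, train_graph)
        train_scores = score_pairs(model, train_graph, pairs, adr_feats=feats)
        test_scores = score_pairs(model, train_graph, test_pairs, adr_feats=feats)
        epoch_row = {
            "epoch": epoch,
            "train_loss": float(np.average(losses, weights=sizes)),
            "train_auc": auc(train_scores, pairs.labels),
            "test_auc": auc(test_scores, test_pairs.labels),
        }
        rows.append(epoch_row)
        if epoch_row["test_auc"] > best_auc:
            best_auc = epoch_row["test_auc"]
            best_epoch = epoch
            best_weights = model.copy_weights()
    history = pd.DataFrame(rows)
    best_model = BiMPADRModel(model.config, best_weights)
    return TrainResult(
        best_model=best_model,
        best_epoch=best_epoch,
        history=history,
        embedding_drug_indices=np.unique(
            np.array([i for i, _ in train_graph.edges], dtype=np.intp)
        ),
    )


def _resample_negatives_like(
    dataset: BipartiteDataset, pairs: LabeledPairSet, seed: int
) -> LabeledPairSet:
    drugs = np.unique(pairs.drug_idx)
    ratio = (len(pairs) - pairs.n_positive) / max(pairs.n_positive, 1)
    return sample_negatives(dataset, drugs, ratio=ratio, seed=seed,
                            provenance="train")


def run_cross_validation(
    dataset: BipartiteDataset,
    fold_plan: FoldPlan,
    config: BiMPADRConfig,
    spec: TrainSpec,
) -> tuple[list[TrainResult], pd.DataFrame]:
    """Drug-stratified K-fold cross-validation.

    Returns one :class:`TrainResult` per fold and a metrics table with one
    row per fold plus the mean and standard deviation across folds.
    """
    results: list[TrainResult] = []
    rows = []
    for fold in range(fold_plan.n_folds):
        test_drugs = fold_plan.fold_drugs(fold)
        train_drugs = fold_plan.complement_drugs(fold)
        test_has_pos = any(i in set(test_drugs.tolist()) for i, _ in dataset.edges)
        if not test_has_pos:
            raise ValueError(f"fold {fold}: its drugs have no positive edges")
        train_pairs = sample_negatives(
            dataset, train_drugs, ratio=1.0,
            seed=spec.seed * 1000 + 2 * fold, provenance="train",
        )
        test_pairs = sample_negatives(
            dataset, test_drugs, ratio=1.0,
            seed=spec.seed * 1000 + 2 * fold + 1, provenance="test",
        )
        fold_config = BiMPADRConfig(**{**config.__dict__,
                                       "seed": config.seed + fold})
        model = init_model(fold_config)
        fold_spec = TrainSpec(**{**spec.__dict__, "seed": spec.seed + fold})
        result = train(model, dataset, train_pairs, test_pairs, fold_spec)
        results.append(result)
        train_graph = dataset.restrict_edges_to_drugs(np.unique(train_pairs.drug_idx))
        scores = score_pairs(result.best_model, train_graph, test_pairs)
        report = confusion_metrics(scores, test_pairs.labels,
                                   threshold=spec.threshold)
        rows.append({
            "fold": fold,
            "best_epoch": result.best_epoch,
            "auc": report.auc,
            "precision": report.precision,
            "acc": report.acc,
        })
    table = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {"fold": "mean", "best_epoch": np.nan,
         "auc": table["auc"].mean(), "precision": table["precision"].mean(),
         "acc": table["acc"].mean()},
        {"fold": "sd", "best_epoch": np.nan,
         "auc": table["auc"].std(ddof=1),
         "precision": table["precision"].std(ddof=1),
         "acc": table["acc"].std(ddof=1)},
    ])
    return results, pd.concat([table, summary], ignore_index=True)
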