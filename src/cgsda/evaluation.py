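"""Cross-validation, metrics, ablation driver, and case-study rankings.

Evaluation follows the balanced protocol: known associations are
positives, and each fold's held-out positives are scored against an
equal-size sample of negatives drawn from pairs that are positives
nowhere (train or test) — the strict reading of "unverified pairs are
negatives".  Evaluation negatives are excluded from the training-time
negative pool of their fold to avoid leakage.

Seven metrics are reported per fold: AUC, AUPR, F1, accuracy, recall,
specificity, and precision, the confusion-based five at a fixed 0.5
threshold (appropriate for balanced evaluation sets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import AssociationDataset, TrainSplit
from .model import ModelConfig, TrainedModel, train

__all__ = ["make_folds", "sample_negatives", "compute_metrics",
           "cross_validate", "ablation_study", "rank_candidates",
           "holdout_recovery"]

METRIC_COLUMNS = ["AUC", "AUPR", "F1", "Acc", "Rec", "Spe", "Pre"]


def make_folds(dataset: AssociationDataset, k: int = 10,
               seed: int = 0) -> list[np.ndarray]:
    """Uniform random partition of the positive pairs into k folds.

    Returns k arrays of (snoRNA index, disease index) rows; fold sizes
    differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pos = dataset.positive_pairs()
    if k > len(pos):
        raise ValueError("more folds than positive pairs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    return [pos[idx] for idx in np.array_split(perm, k)]


def sample_negatives(dataset: AssociationDataset, n: int,
                     exclude: set[tuple[int, int]],
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """n distinct pairs drawn uniformly from A's zero entries minus exclude."""
    candidate = dataset.A == 0
    for i, j in exclude:
        candidate[i, j] = False
    pool = np.flatnonzero(candidate.ravel())
    if len(pool) < n:
        raise ValueError(f"negative pool has {len(pool)} pairs, need {n}")
    chosen = rng.choice(pool, size=n, replace=False)
    n_d = dataset.n_disease
    return [(int(f) // n_d, int(f) % n_d) for f in chosen]


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """The seven-metric row for one evaluation set.

    AUC is the rank statistic (ties count one half); AUPR the step-summed
    area under the precision-recall curve; the remaining five derive from
    the confusion table at ``threshold``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC/AUPR")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return {
        "AUC": float(roc_auc_score(labels, scores)),
        "AUPR": float(average_precision_score(labels, scores)),
        "F1": 2 * pre * rec / (pre + rec) if pre + rec else 0.0,
        "Acc": (tp + tn) / len(labels),
        "Rec": rec,
        "Spe": tn / (tn + fp) if tn + fp else 0.0,
        "Pre": pre,
    }


def cross_validate(dataset: AssociationDataset, F_s0: np.ndarray,
                   F_d0: np.ndarray, config: ModelConfig, k: int = 10,
                   seed: int | None = None) -> pd.DataFrame:
    """k-fold cross-validation over the positive pairs.

    Each fold trains on the remaining positives (balanced resampled
    negatives) and is evaluated on its held-out positives plus an equal
    number of negatives disjoint from all positives and from that fold's
    training negative pool.  Returns k fold rows plus mean and SD.
    """
    seed = config.seed if seed is None else seed
    folds = make_folds(dataset, k=k, seed=seed)
    all_pos = {tuple(p) for p in dataset.positive_pairs()}
    rows = []
    for f, fold in enumerate(folds):
        held_out = [tuple(p) for p in fold]
        split = TrainSplit.holding_out(dataset, held_out)
        rng = np.random.default_rng([seed, f])
        eval_neg = sample_negatives(dataset, len(held_out), all_pos, rng)
        fold_config = ModelConfig.from_dict(
            {**config.to_dict(), "seed": int(np.random.SeedSequence([seed, f])
                                             .generate_state(1)[0] % (2**31))})
        fitted = train(dataset, split, F_s0, F_d0, fold_config,
                       exclude_negatives=set(eval_neg))
        block = fitted.score_matrix()
        pairs = held_out + eval_neg
        scores = np.array([block[i, j] for i, j in pairs])
        labels = np.array([1] * len(held_out) + [0] * len(eval_neg))
        rows.append(compute_metrics(scores, labels))
    frame = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    frame.index = [f"fold_{i + 1}" for i in range(len(rows))]
    frame.loc["mean"] = frame.iloc[:k].mean()
    frame.loc["sd"] = frame.iloc[:k].std(ddof=1)
    return frame


def holdout_recovery(dataset: AssociationDataset, F_s0: np.ndarray,
                     F_d0: np.ndarray, config: ModelConfig,
                     holdout_frac: float = 0.1,
                     seed: int | None = None) -> dict[str, float]:
    """Single balanced hold-out evaluation (one split, all seven metrics).

    Holds out ``holdout_frac`` of the positives, trains on the rest, and
    scores the held-out positives against an equal number of negatives
    disjoint from every positive and from the training negative pool.
    """
    seed = config.seed if seed is None else seed
    pos = dataset.positive_pairs()
    rng = np.random.default_rng(seed)
    n_held = max(1, int(len(pos) * holdout_frac))
    held = [tuple(p) for p in pos[rng.permutation(len(pos))[:n_held]]]
    split = TrainSplit.holding_out(dataset, held)
    all_pos = {tuple(p) for p in pos}
    eval_neg = sample_negatives(dataset, len(held), all_pos, rng)
    cfg = ModelConfig.from_dict({**config.to_dict(), "seed": seed})
    fitted = train(dataset, split, F_s0, F_d0, cfg,
                   exclude_negatives=set(eval_neg))
    block = fitted.score_matrix()
    scores = np.array([block[i, j] for i, j in held + eval_neg])
    labels = np.array([1] * len(held) + [0] * len(eval_neg))
    return compute_metrics(scores, labels)


def ablation_study(dataset: AssociationDataset, F_s0: np.ndarray,
                   F_d0: np.ndarray, config: ModelConfig,
                   variants: tuple[str, ...] = ("full", "no-cheb",
                                                "no-gated", "no-residual"),
                   k: int = 10, seed: int | None = None) -> pd.DataFrame:
    """Mean cross-validation metrics per model variant, one row each."""
    rows = {}
    for variant in variants:
        cfg = ModelConfig.from_dict({**config.to_dict(), "variant": variant})
        report = cross_validate(dataset, F_s0, F_d0, cfg, k=k, seed=seed)
        rows[variant] = report.loc["mean"]
    return pd.DataFrame(rows).T[METRIC_COLUMNS]


def rank_candidates(dataset: AssociationDataset, F_s0: np.ndarray,
                    F_d0: np.ndarray, config: ModelConfig, target: str,
                    mode: str = "novel-association",
                    top_n: int = 15) -> pd.DataFrame:
    """Case-study ranking of snoRNAs for one target disease.

    ``novel-disease``: every edge incident to the target is removed before
    training, so the disease is scored as unseen; all snoRNAs are ranked.
    ``novel-association``: train on all known positives and rank only the
    pairs not already known.  Ties break by snoRNA id for determinism.
    """
    j = dataset.disease_index(target)
    if mode == "novel-disease":
        held_out = [(int(i), j) for i in np.flatnonzero(dataset.A[:, j])]
        split = TrainSplit.holding_out(dataset, held_out)
        candidates = np.arange(dataset.n_snorna)
    elif mode == "novel-association":
        split = TrainSplit.full(dataset)
        candidates = np.flatnonzero(dataset.A[:, j] == 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fitted = train(dataset, split, F_s0, F_d0, config)
    column = fitted.score_matrix()[:, j]
    rows = sorted(((float(column[i]), dataset.snorna_ids[i]) for i in candidates),
                  key=lambda t: (-t[0], t[1]))
    frame = pd.DataFrame(rows[:top_n], columns=["score", "snorna"])
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame["disease"] = target
    return frame
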