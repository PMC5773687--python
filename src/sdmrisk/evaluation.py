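"""Split design, AUC/TSS scoring, and max-TSS threshold selection.

The evaluation design mirrors the standard ensemble-modelling protocol:
each pseudo-absence replicate is split into 70% calibration / 30%
evaluation several times, every algorithm is fitted on each calibration
part, and AUC (rank / Mann-Whitney formulation, ties counted half) and
TSS (sensitivity + specificity - 1, at the threshold maximising TSS) are
computed on the held-out part only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import learners
from .errors import SplitError, UndefinedMetricError
from .preprocess import TrainingSet


@dataclass
class SplitPlan:
    replicate_id: int
    train_fraction: float
    split_seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class EvaluationRecord:
    species: str
    algorithm_id: str
    pa_replicate: int
    split_replicate: int
    auc: float
    tss: float
    threshold: float


def make_splits(
    ts: TrainingSet,
    n_splits: int = 5,
    fraction: float = 0.70,
    seed: int = 0,
    method: str = "shuffle",
) -> list[SplitPlan]:
    """Stratified splits of one training set.

    ``method='shuffle'`` (default) draws ``n_splits`` independent
    stratified train/test splits with the given train fraction;
    ``method='kfold'`` instead yields a stratified K-fold partition with
    K = n_splits (the train fraction is then (K-1)/K).  Both classes must
    land on both sides of every split.
    """
    y = ts.labels
    if n_splits < 1:
        raise SplitError("n_splits must be >= 1")
    try:
        if method == "shuffle":
            splitter = StratifiedShuffleSplit(
                n_splits=n_splits, train_size=fraction, random_state=seed
            )
        elif method == "kfold":
            splitter = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=seed
            )
        else:
            raise SplitError(f"unknown split method {method!r}")
        plans = [
            SplitPlan(
                replicate_id=i,
                train_fraction=fraction if method == "shuffle" else 1 - 1 / n_splits,
                split_seed=seed,
                train_idx=np.asarray(tr),
                test_idx=np.asarray(te),
            )
            for i, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y))
        ]
    except ValueError as exc:
        raise SplitError(str(exc)) from exc
    for p in plans:
        for side, idx in (("train", p.train_idx), ("test", p.test_idx)):
            if len(np.unique(y[idx])) < 2:
                raise SplitError(
                    f"split {p.replicate_id}: {side} part lacks one class"
                )
    return plans


def auc(scores, labels) -> float:
    """Probability a random presence outscores a random (pseudo-)absence,
    ties counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def tss(c: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        raise UndefinedMetricError("TSS undefined without both classes")
    return c.tp / pos + c.tn / neg - 1.0


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
    )


def max_tss_threshold(scores, labels) -> tuple[float, float]:
    """Smallest distinct score value maximising TSS under the rule
    ``score >= threshold -> presence``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("threshold selection needs both classes")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    candidates = np.unique(scores)
    # score >= t: vectorised cumulative counts over sorted candidates
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = pos[order]
    # number of positives/negatives with score >= t  (t a candidate value)
    idx = np.searchsorted(s_sorted, candidates, side="left")
    cum_pos = np.concatenate([np.cumsum(y_sorted[::-1])[::-1], [0]])
    cum_neg = np.concatenate([np.cumsum(~y_sorted[::-1])[::-1], [0]])
    tp = cum_pos[idx]
    fp = cum_neg[idx]
    tss_values = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    best = np.max(tss_values)
    # smallest candidate attaining the max
    t = candidates[np.argmax(tss_values >= best - 1e-12)]
    return float(t), float(best)


def evaluate_run(
    algorithm_id: str,
    split: SplitPlan,
    ts: TrainingSet,
    seed: int = 0,
) -> EvaluationRecord:
    """Fit on the split's train rows only and score on its test rows."""
    X = ts.features
    y = ts.labels
    model = learners.fit(
        algorithm_id, X.iloc[split.train_idx], y[split.train_idx], ts.schema, seed=seed
    )
    test_scores = learners.predict(model, X.iloc[split.test_idx])
    test_labels = y[split.test_idx]
    ok = np.isfinite(test_scores)
    test_scores, test_labels = test_scores[ok], test_labels[ok]
    try:
        a = auc(test_scores, test_labels)
        t, s = max_tss_threshold(test_scores, test_labels)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(
            f"{ts.species} / {algorithm_id} / pa{ts.replicate_id} / "
            f"split{split.replicate_id}: {exc}"
        ) from exc
    return EvaluationRecord(
        species=ts.species,
        algorithm_id=algorithm_id,
        pa_replicate=ts.replicate_id,
        split_replicate=split.replicate_id,
        auc=a,
        tss=s,
        threshold=t,
    )


def evaluate_all(
    training_sets: list[TrainingSet],
    algorithms: list[str],
    n_splits: int = 5,
    fraction: float = 0.70,
    seed: int = 0,
    method: str = "shuffle",
) -> list[EvaluationRecord]:
    """The full run design: every pseudo-absence replicate × algorithm ×
    split replicate (e.g. 3 × 9 × 5 = 135 records)."""
    records: list[EvaluationRecord] = []
    for ts in training_sets:
        split_seed = int(
            np.random.SeedSequence([seed, ts.replicate_id]).generate_state(1)[0]
            % (2**31)
        )
        plans = make_splits(ts, n_splits=n_splits, fraction=fraction,
                            seed=split_seed, method=method)
        for algorithm_id in algorithms:
            for plan in plans:
                records.append(evaluate_run(algorithm_id, plan, ts, seed=split_seed))
    return records


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "algorithm": r.algorithm_id,
                "pa_rep": r.pa_replicate,
                "split_rep": r.split_replicate,
                "auc": r.auc,
                "tss": r.tss,
                "threshold": r.threshold,
            }
            for r in records
        ]
    )


def summarize_by_algorithm(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Per-algorithm mean AUC and mean TSS (the model-accuracy summary)."""
    df = records_to_frame(records)
    return (
        df.groupby(["species", "algorithm"])[["auc", "tss"]]
        .mean()
        .reset_index()
        .rename(columns={"auc": "mean_auc", "tss": "mean_tss"})
    )
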