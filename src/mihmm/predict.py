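"""Subgroup-level quality prediction.

Individual sessions are too short for stable HMM estimation, so sessions
are bundled into subgroups of (by default) 7 same-quality sessions sampled
from their quality pool; sessions may recur across subgroups. Each
subgroup's pooled HMM yields a canonical 3x3 transition matrix whose nine
row-major entries are the classifier features. A ridge-regularized logistic
regression predicts subgroup quality under subgroup-level leave-one-out
cross-validation; the whole procedure (subgroup resampling + LOOCV) is
repeated over independent iterations and metrics are reported mean +/- SD.

The positive class for threshold-free metrics is "low" quality — the
clinically critical minority under the imbalanced 3:1 design — but every
metric is reported class-wise for both classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support

from .data import Quality, SessionSet
from .errors import ValidationError
from .hmm import HMMConfig, fit_bank, fit_hmm, label_states, pad_sequences

POSITIVE_CLASS = "low"
CLASSES = ("high", "low")


@dataclass(frozen=True)
class Subgroup:
    subgroup_id: str
    quality: Quality
    member_sessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.member_sessions)) != len(self.member_sessions):
            raise ValidationError(
                f"subgroup {self.subgroup_id!r}: member sessions must be distinct"
            )


@dataclass(frozen=True)
class FeatureRow:
    subgroup_id: str
    features: tuple[float, ...]  # row-major flattened canonical labeled_A
    label: Quality
    gradient_valid: bool


@dataclass
class MetricBundle:
    """Metrics for one pooled set of held-out predictions."""

    accuracy: float
    roc_auc: float
    per_class: dict  # class -> {precision, recall_sensitivity, specificity, f1}
    confusion: np.ndarray  # 2x2 row-normalized, rows = true (high, low)
    flags: dict = field(default_factory=dict)


@dataclass
class ClassificationReport:
    per_iteration: list[MetricBundle]
    mean: dict
    sd: dict
    confusion_mean: np.ndarray
    held_out_probabilities: list  # per iteration: list of (subgroup_id, truth, p_low)
    feature_rows: list  # per iteration: the FeatureRow list used
    seeds: list[int]
    skipped_folds: int
    design: str


# ---------------------------------------------------------------------------


def make_subgroups(
    pool: SessionSet,
    n_subgroups: int,
    size: int = 7,
    seed: int = 0,
    disjoint: bool = False,
) -> list[Subgroup]:
    """Sample subgroups of distinct sessions from a single-quality pool.

    Sessions recur across subgroups (the default design); ``disjoint=True``
    partitions the pool instead, for a stricter leakage-free evaluation.
    """
    qualities = {s.quality for s in pool}
    if len(qualities) != 1:
        raise ValidationError("subgroup pool must contain a single quality label")
    quality = qualities.pop()
    ids = [s.session_id for s in pool]
    if size > len(ids):
        raise ValidationError(
            f"subgroup size {size} exceeds pool size {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    if disjoint:
        if n_subgroups * size > len(ids):
            raise ValidationError(
                "disjoint subgroups require n_subgroups * size <= pool size"
            )
        perm = rng.permutation(len(ids))
        for i in range(n_subgroups):
            members = tuple(ids[j] for j in perm[i * size : (i + 1) * size])
            out.append(Subgroup(f"{quality.value}-{i:03d}", quality, members))
        return out
    for i in range(n_subgroups):
        members = tuple(ids[j] for j in rng.choice(len(ids), size=size, replace=False))
        out.append(Subgroup(f"{quality.value}-{i:03d}", quality, members))
    return out


def subgroup_features(
    subgroup: Subgroup, sessions: SessionSet, config: HMMConfig = HMMConfig()
) -> FeatureRow:
    """Fit the subgroup's pooled HMM and flatten its canonical transition matrix."""
    by_id = {s.session_id: s for s in sessions}
    seqs = []
    for sid in subgroup.member_sessions:
        if sid not in by_id:
            raise ValidationError(f"subgroup member {sid!r} missing from session set")
        sc = by_id[sid].client_scores()
        if not sc:
            raise ValidationError(f"session {sid!r} carries no client scores")
        seqs.append(sc)
    labeled = label_states(fit_hmm(seqs, config))
    return FeatureRow(
        subgroup_id=subgroup.subgroup_id,
        features=tuple(float(x) for x in labeled.labeled_A.ravel()),
        label=subgroup.quality,
        gradient_valid=labeled.gradient_valid,
    )


def _features_banked(
    subgroups: Sequence[Subgroup], pool: SessionSet, config: HMMConfig
) -> list[FeatureRow]:
    """Fit all subgroups of one pool in a single bank (equals per-subgroup fits)."""
    ids = [s.session_id for s in pool]
    idx = {sid: i for i, sid in enumerate(ids)}
    seqs = [s.client_scores() for s in pool]
    if any(not sc for sc in seqs):
        raise ValidationError("all pool sessions must carry client scores")
    obs, lengths, _ = pad_sequences(seqs)
    weights = np.zeros((len(subgroups), len(ids)))
    for m, sg in enumerate(subgroups):
        for sid in sg.member_sessions:
            if sid not in idx:
                raise ValidationError(f"subgroup member {sid!r} missing from session set")
            weights[m, idx[sid]] = 1.0
    bank = fit_bank(obs, lengths, weights, config)
    from .compare import _canonical_A_bank, _gradient_valid_bank

    canon = _canonical_A_bank(bank)
    valid = _gradient_valid_bank(bank)
    return [
        FeatureRow(
            subgroup_id=sg.subgroup_id,
            features=tuple(float(x) for x in canon[m].ravel()),
            label=sg.quality,
            gradient_valid=bool(valid[m]),
        )
        for m, sg in enumerate(subgroups)
    ]


# ---------------------------------------------------------------------------
# Metrics


def rank_roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney rank statistic (ties count 1/2)."""
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    r_pos = ranks[y_true].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(
    truths: Sequence, predictions: Sequence, prob_positive: Sequence[float]
) -> MetricBundle:
    """Accuracy, rank ROC AUC, class-wise precision/recall/specificity/F1,
    and a row-normalized confusion matrix (rows = true high, low)."""
    t = np.array([getattr(x, "value", x) for x in truths])
    p = np.array([getattr(x, "value", x) for x in predictions])
    prob = np.asarray(prob_positive, dtype=float)
    if not (len(t) == len(p) == len(prob)) or len(t) == 0:
        raise ValidationError("truths, predictions and probabilities must align and be non-empty")
    accuracy = float((t == p).mean())
    auc = rank_roc_auc(t == POSITIVE_CLASS, prob)
    prec, rec, f1, _ = precision_recall_fscore_support(
        t, p, labels=list(CLASSES), zero_division=0.0
    )
    flags = {}
    per_class = {}
    for i, cls in enumerate(CLASSES):
        other = CLASSES[1 - i]
        if (p == cls).sum() == 0:
            flags[f"no_predicted_{cls}"] = True
        per_class[cls] = {
            "precision": float(prec[i]),
            "recall_sensitivity": float(rec[i]),
            "specificity": float(rec[1 - i]) if (t == other).sum() else 0.0,
            "f1": float(f1[i]),
        }
    confusion = np.zeros((2, 2))
    for i, true_cls in enumerate(CLASSES):
        row_n = (t == true_cls).sum()
        for j, pred_cls in enumerate(CLASSES):
            if row_n:
                confusion[i, j] = ((t == true_cls) & (p == pred_cls)).sum() / row_n
    return MetricBundle(accuracy, auc, per_class, confusion, flags)


# ---------------------------------------------------------------------------
# LOOCV


def loocv_once(rows: Sequence[FeatureRow], C: float = 1.0):
    """One subgroup-level LOOCV pass over fixed feature rows.

    Returns (metrics, held_out, n_skipped): held_out is a list of
    (subgroup_id, truth, p_low) triples, one per completed fold.
    """
    for q in (Quality.HIGH, Quality.LOW):
        if sum(r.label is q for r in rows) < 2:
            raise ValidationError("LOOCV needs >= 2 feature rows per class")
    x = np.array([r.features for r in rows])
    y = np.array([r.label.value for r in rows])
    held, truths, preds, probs = [], [], [], []
    n_skipped = 0
    for i in range(len(rows)):
        train = np.ones(len(rows), dtype=bool)
        train[i] = False
        if len(set(y[train])) < 2:
            n_skipped += 1
            continue
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(x[train], y[train])
        p_low = float(clf.predict_proba(x[i : i + 1])[0, list(clf.classes_).index("low")])
        pred = "low" if p_low >= 0.5 else "high"
        held.append((rows[i].subgroup_id, y[i], p_low))
        truths.append(y[i])
        preds.append(pred)
        probs.append(p_low)
    metrics = compute_metrics(truths, preds, probs)
    return metrics, held, n_skipped


def loocv_classify(
    sessions: SessionSet,
    design: str = "balanced",
    n_iterations: int = 10,
    n_subgroups_high: int = 30,
    size: int = 7,
    config: HMMConfig = HMMConfig(),
    seed: int = 0,
    C: float = 1.0,
    exclude_gradient_invalid: bool = False,
    disjoint_subgroups: bool = False,
    permute_labels: bool = False,
) -> ClassificationReport:
    """Repeated subgroup resampling + subgroup-level LOOCV classification.

    ``design`` is "balanced" (30 + 30 subgroups by default) or
    "imbalanced_3to1" (30 + 10). Each iteration redraws all subgroups with a
    fresh child seed, refits their HMM features, and runs a full LOOCV;
    metrics are aggregated mean +/- SD over iterations.
    ``permute_labels=True`` shuffles the subgroup labels relative to the
    features in every iteration (chance-level control).
    """
    if design == "balanced":
        n_low = n_subgroups_high
    elif design == "imbalanced_3to1":
        n_low = max(1, n_subgroups_high // 3)
    else:
        raise ValidationError(f"unknown design {design!r}")
    high_pool = sessions.by_quality(Quality.HIGH)
    low_pool = sessions.by_quality(Quality.LOW)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iterations)]

    per_iter, held_all, rows_all = [], [], []
    skipped = 0
    for it, it_seed in enumerate(child_seeds):
        sg_high = make_subgroups(high_pool, n_subgroups_high, size, it_seed, disjoint_subgroups)
        sg_low = make_subgroups(low_pool, n_low, size, it_seed + 1, disjoint_subgroups)
        rows = _features_banked(sg_high, high_pool, config) + _features_banked(
            sg_low, low_pool, config
        )
        if exclude_gradient_invalid:
            rows = [r for r in rows if r.gradient_valid]
        if permute_labels:
            rng = np.random.default_rng(it_seed + 2)
            perm = rng.permutation(len(rows))
            rows = [
                FeatureRow(r.subgroup_id, r.features, rows[j].label, r.gradient_valid)
                for r, j in zip(rows, perm)
            ]
        metrics, held, n_skip = loocv_once(rows, C=C)
        per_iter.append(metrics)
        held_all.append(held)
        rows_all.append(rows)
        skipped += n_skip

    mean, sd = _aggregate(per_iter)
    confusion_mean = np.mean([m.confusion for m in per_iter], axis=0)
    return ClassificationReport(
        per_iteration=per_iter,
        mean=mean,
        sd=sd,
        confusion_mean=confusion_mean,
        held_out_probabilities=held_all,
        feature_rows=rows_all,
        seeds=child_seeds,
        skipped_folds=skipped,
        design=design,
    )


def _aggregate(per_iter: list[MetricBundle]):
    def stats(values):
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    mean, sd = {}, {}
    mean["accuracy"], sd["accuracy"] = stats([m.accuracy for m in per_iter])
    mean["roc_auc"], sd["roc_auc"] = stats([m.roc_auc for m in per_iter])
    for cls in CLASSES:
        for metric in ("precision", "recall_sensitivity", "specificity", "f1"):
            key = f"{cls}_{metric}"
            mean[key], sd[key] = stats([m.per_class[cls][metric] for m in per_iter])
    return mean, sd
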