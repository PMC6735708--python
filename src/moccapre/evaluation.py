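"""Cross-validation, precision/recall curves and threshold calibration.

Generalization is measured by the area under the precision/recall curve
(PRC AUC), which stays informative at the 1:100 class imbalance used for
testing, unlike ROC.  Curves are computed at every distinct score
threshold (ties processed together) and integrated by the trapezoidal
rule over recall, anchoring recall 0 at the first observed precision.
Confidence intervals on the mean AUC over cross-validation repetitions
use the normal approximation (z = 1.96).

Threshold calibration searches the precision/recall space of a scorer on
held-out positives versus freshly generated background sequences for the
threshold with the highest recall at a target precision, interpolating
linearly between adjacent thresholds when the target falls strictly
between achieved precisions, and averages the threshold over repeated
background draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence as TypingSequence

import numpy as np

from .markov import MarkovModel, generate
from .seqio import Sequence


@dataclass
class PRCurve:
    """Precision/recall points (recall nondecreasing) and the AUC."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auc: float


def pr_curve(scores_pos, scores_neg) -> PRCurve:
    """Precision/recall curve over all distinct score thresholds.

    At threshold t an item is predicted positive iff its score >= t.
    Tied scores are processed together (one curve point per distinct
    score).  AUC is trapezoidal over recall, with the recall-0 anchor
    extending the first precision value.
    """
    sp = np.asarray(scores_pos, dtype=float)
    sn = np.asarray(scores_neg, dtype=float)
    if len(sp) == 0 or len(sn) == 0:
        raise ValueError("both score lists must be non-empty")
    scores = np.concatenate([sp, sn])
    labels = np.concatenate([np.ones(len(sp)), np.zeros(len(sn))])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # indices where a run of tied scores ends
    distinct = np.flatnonzero(np.diff(scores)) if len(scores) > 1 else np.array([], int)
    ends = np.concatenate([distinct, [len(scores) - 1]])
    tp = np.cumsum(labels)[ends]
    n_pred = ends + 1.0
    fp = n_pred - tp
    precision = tp / n_pred
    recall = tp / len(sp)
    thresholds = scores[ends]
    auc = _trapezoid_auc(recall, precision)
    return PRCurve(recall, precision, thresholds, auc)


def _trapezoid_auc(recall: np.ndarray, precision: np.ndarray) -> float:
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(p, r))


def summarize_auc(curves: list[PRCurve]) -> tuple[float, float, float]:
    """Mean AUC with a 95% normal CI: mean +- 1.96 * sd / sqrt(n)."""
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    aucs = np.array([c.auc for c in curves])
    mean = float(aucs.mean())
    half = 1.96 * float(aucs.std(ddof=1)) / math.sqrt(len(aucs))
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVPlan:
    """Repetitions and split sizes for shuffled cross-validation."""

    repetitions: int = 50
    n_train: int = 110
    n_test_pos: int = 50
    n_test_neg: int = 5000
    seed: int = 0


def cross_validate(
    pos: list[Sequence],
    neg_classes: dict[str, list[Sequence]],
    trainer: Callable[[list[Sequence], dict[str, list[Sequence]]], Callable[[Sequence], float]],
    plan: CVPlan,
    eval_neg: str | None = None,
) -> list[PRCurve]:
    """Repeated shuffled-split cross-validation.

    Per repetition every set is shuffled independently; the first
    ``n_train`` sequences of each set train the model (via ``trainer``,
    which returns a per-sequence scorer), and the next ``n_test_pos``
    positives and ``n_test_neg`` sequences of the evaluation negative
    class form the test set.  Train and test indices are disjoint within
    every repetition.  Returns one PR curve per repetition.
    """
    if eval_neg is None:
        eval_neg = next(iter(neg_classes))
    if eval_neg not in neg_classes:
        raise ValueError(f"evaluation class {eval_neg!r} not in neg_classes")
    if len(pos) < plan.n_train + plan.n_test_pos:
        raise ValueError(
            f"positive set too small: need {plan.n_train + plan.n_test_pos}, "
            f"have {len(pos)}"
        )
    for label, seqs in neg_classes.items():
        need = plan.n_train + (plan.n_test_neg if label == eval_neg else 0)
        if len(seqs) < need:
            raise ValueError(f"set {label!r} too small: need {need}, have {len(seqs)}")
    rng = np.random.default_rng(plan.seed)
    curves = []
    for _rep in range(plan.repetitions):
        pidx = rng.permutation(len(pos))
        train_pos = [pos[i] for i in pidx[: plan.n_train]]
        test_pos = [pos[i] for i in pidx[plan.n_train : plan.n_train + plan.n_test_pos]]
        train_negs: dict[str, list[Sequence]] = {}
        test_neg: list[Sequence] = []
        for label, seqs in neg_classes.items():
            nidx = rng.permutation(len(seqs))
            train_negs[label] = [seqs[i] for i in nidx[: plan.n_train]]
            if label == eval_neg:
                test_neg = [
                    seqs[i]
                    for i in nidx[plan.n_train : plan.n_train + plan.n_test_neg]
                ]
        scorer = trainer(train_pos, train_negs)
        sp = [scorer(s) for s in test_pos]
        sn = [scorer(s) for s in test_neg]
        curves.append(pr_curve(sp, sn))
    return curves


# ---------------------------------------------------------------------------
# threshold calibration


@dataclass
class CalibratedThreshold:
    """A score cutoff targeting a precision, averaged over repetitions."""

    threshold: float
    target_precision: float
    achieved_precision: float
    achieved_recall: float
    repetitions: int
    unreachable: bool = False


def _threshold_for_precision(
    sp: np.ndarray, sn: np.ndarray, target: float
) -> tuple[float, float, float, bool]:
    """(threshold, precision, recall, unreachable) for one score draw.

    Picks the threshold with the highest recall whose precision is at
    least the target; when the target falls strictly between the
    precisions of adjacent thresholds, the threshold is linearly
    interpolated between them.
    """
    curve = pr_curve(sp, sn)
    ok = np.flatnonzero(curve.precision >= target)
    if len(ok) == 0:
        return float(curve.thresholds[0]), float(curve.precision[0]), float(
            curve.recall[0]
        ), True
    k = int(ok[np.argmax(curve.recall[ok])])
    # prefer the latest (highest-recall, lowest-threshold) qualifying point
    while (
        k + 1 < len(curve.precision)
        and curve.precision[k + 1] >= target
    ):  # pragma: no cover - argmax already maximal, ties only
        k += 1
    thr = float(curve.thresholds[k])
    prec, rec = float(curve.precision[k]), float(curve.recall[k])
    if k + 1 < len(curve.precision) and curve.precision[k + 1] < target < prec:
        t_hi, t_lo = thr, float(curve.thresholds[k + 1])
        p_hi, p_lo = prec, float(curve.precision[k + 1])
        thr = t_lo + (t_hi - t_lo) * (target - p_lo) / (p_hi - p_lo)
    return thr, prec, rec, False


def calibrate_threshold(
    scorer: Callable[[Sequence], float],
    positives: list[Sequence],
    genome_model: MarkovModel,
    target_precision: float = 0.80,
    n_neg: int = 44626,
    neg_len: int = 3000,
    repetitions: int = 10,
    seed: int = 0,
) -> CalibratedThreshold:
    """Calibrate a score threshold for a target genome-wide precision.

    Per repetition, ``n_neg`` background sequences of ``neg_len`` bp are
    generated from the genome chain (defaults approximate one fly genome:
    44626 x 3 kb = 133.9 Mb), positives and negatives are scored, and the
    per-repetition threshold found; the final threshold is the mean.  If
    the target precision is unreachable even at the top score, the top
    score is returned with ``unreachable`` set.
    """
    if not 0 < target_precision <= 1:
        raise ValueError("target_precision must be in (0, 1]")
    sp = np.array([scorer(s) for s in positives])
    thrs, precs, recs, flags = [], [], [], []
    for rep in range(repetitions):
        rng = np.random.default_rng(seed + rep)
        sn = np.array(
            [scorer(generate(genome_model, neg_len, rng)) for _ in range(n_neg)]
        )
        t, p, r, bad = _threshold_for_precision(sp, sn, target_precision)
        thrs.append(t)
        precs.append(p)
        recs.append(r)
        flags.append(bad)
    return CalibratedThreshold(
        threshold=float(np.mean(thrs)),
        target_precision=target_precision,
        achieved_precision=float(np.mean(precs)),
        achieved_recall=float(np.mean(recs)),
        repetitions=repetitions,
        unreachable=any(flags),
    )
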