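"""ROC analysis and leave-one-out cross-validation for the balance classifier.

Two assessment modes:

* **Discriminatory value** — with fixed (default unit) coefficients, sweep
  every distinct Z value as a cut-off and build the ROC curve per binary
  question.  Ternary datasets pose two one-vs-rest questions: prolongation
  scored by Z and shortening scored by −Z, so "higher discriminant = more
  positive" holds for every question.  The AUC is computed twice — as the
  trapezoidal area under the swept curve and as the tie-corrected
  Mann–Whitney rank statistic (ties count ½) — and the two are required to
  agree to 1e-12.

* **Predictive power** — leave-one-out cross-validation in which the
  coefficients (a0, a1, a2) and decision threshold(s) are re-fitted on every
  training fold by a deterministic search: a coarse grid over the
  coefficients with an exhaustive threshold sweep at candidate Z midpoints,
  then a local multiplicative refinement around the best grid point.  Equal
  objectives break ties toward the lexicographically smallest parameter
  vector, so results are bitwise reproducible.  Performance is summarised by
  sensitivity, specificity and balanced accuracy = (sensitivity +
  specificity) / 2; ternary endpoints report per-direction one-vs-rest
  metrics and their mean.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from . import classifier as _cls
from .classifier import ClassifierParams, DecisionRule, RuleKind
from .io import LABELS, Dataset, Endpoint, positive_label
from .pharmacology import block_profile

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "Question",
    "FitResult",
    "FoldResult",
    "DirectionMetrics",
    "CVResult",
    "SearchConfig",
    "UndefinedROCError",
    "CannotFitError",
    "roc_curve",
    "binary_questions",
    "compute_scores",
    "fit_params",
    "loocv",
    "metrics_from_confusion",
    "metrics_from_counts",
    "permutation_null",
]

UNDEFINED = math.nan  # marker for 0/0 metrics (empty class), never a crash


class UndefinedROCError(ValueError):
    """ROC/AUC is undefined when the labels contain a single class."""


class CannotFitError(ValueError):
    """Parameter fitting requires at least two classes in the training set."""


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    question_id: str
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), (0,0) .. (1,1)
    auc: float
    n_positive: int
    n_negative: int


def roc_curve(scores: Sequence[float], labels: Sequence[bool],
              question_id: str = "question") -> ROCResult:
    """ROC curve over all distinct score cut-offs, with dual-route AUC.

    Tied scores collapse to a single ROC vertex.  The trapezoidal area and
    the rank-statistic (Mann–Whitney with ties counted ½) AUC are both
    computed and must agree to 1e-12; disagreement would indicate an
    implementation defect and raises.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(
            f"need at least one positive and one negative label "
            f"(got {n_pos} positive, {n_neg} negative)"
        )

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # vertices where the threshold passes a block of tied scores
    boundary = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([boundary, [s_sorted.size - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(~y_sorted)[idx]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc_trap = float(np.trapezoid(tpr, fpr))

    # independent route: tie-corrected rank statistic
    ranks = rankdata(s)  # average ranks => ties count 1/2
    u = float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0
    auc_rank = u / (n_pos * n_neg)
    if abs(auc_trap - auc_rank) > 1e-12:
        raise AssertionError(
            f"trapezoidal AUC {auc_trap!r} and rank-statistic AUC "
            f"{auc_rank!r} disagree beyond 1e-12"
        )

    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return ROCResult(question_id=question_id, points=points, auc=auc_trap,
                     n_positive=n_pos, n_negative=n_neg)


@dataclass(frozen=True)
class Question:
    """A binary one-vs-rest question posed to a dataset.

    ``sign`` orients the discriminant: +1 scores by Z (prolongation/risk
    direction), −1 scores by −Z (shortening direction), so higher always
    means "more positive".
    """

    question_id: str
    y: tuple[bool, ...]
    sign: int = 1


def binary_questions(dataset: Dataset) -> list[Question]:
    """The binary classification question(s) a dataset supports.

    Binary endpoints yield one pass-through question.  Ternary endpoints
    yield prolongation-vs-rest (scored by Z) and shortening-vs-rest
    (scored by −Z).  A question with zero positives is skipped with a
    warning.
    """
    labels = dataset.labels()
    questions: list[Question] = []
    if dataset.endpoint is Endpoint.APD_TERNARY:
        candidates = [
            ("prolongation", _cls.PROLONG, 1),
            ("shortening", _cls.SHORTEN, -1),
        ]
        for qid, target, sign in candidates:
            y = tuple(lab == target for lab in labels)
            if not any(y):
                logger.warning(
                    "dataset %r: question %r skipped (zero positives)",
                    dataset.name, qid,
                )
                continue
            questions.append(Question(question_id=qid, y=y, sign=sign))
    else:
        pos = positive_label(dataset.endpoint)
        y = tuple(lab == pos for lab in labels)
        if not any(y):
            logger.warning(
                "dataset %r: question %r skipped (zero positives)",
                dataset.name, pos,
            )
        else:
            questions.append(Question(question_id=pos, y=y, sign=1))
    return questions


def compute_scores(dataset: Dataset,
                   params: ClassifierParams | None = None) -> np.ndarray:
    """Z score for every compound at its own test concentration."""
    if params is None:
        params = ClassifierParams()
    from .classifier import z_score
    return np.array(
        [z_score(block_profile(rec), params) for rec in dataset.records]
    )


# --------------------------------------------------------------------------
# Parameter fitting (grid + threshold sweep + local refinement)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Deterministic search configuration for coefficient fitting.

    ``coef_grid`` is the coarse per-coefficient grid; ``refine_factors``
    are the multiplicative local-refinement steps applied around the best
    coarse point (zero coefficients are refined against a small positive
    alternative instead).
    """

    coef_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    refine: bool = True
    refine_factors: tuple[float, ...] = (2 / 3, 0.8, 1.0, 1.25, 1.5)
    zero_refine_candidates: tuple[float, ...] = (0.0, 0.125)


@dataclass(frozen=True)
class FitResult:
    params: ClassifierParams
    rule: DecisionRule
    objective: float  # balanced accuracy achieved on the training data


def _profile_matrix(records: Sequence) -> np.ndarray:
    """(n, 3) array of (S_CaL, S_Na, S_Kr) per compound."""
    rows = []
    for rec in records:
        p = block_profile(rec)
        rows.append((p.s_cal, p.s_na, p.s_kr))
    return np.asarray(rows, dtype=float)


def _threshold_candidates(z: np.ndarray) -> np.ndarray:
    """Cut-off candidates: below min, midpoints of distinct sorted Z, above max."""
    zs = np.unique(z)
    mids = (zs[:-1] + zs[1:]) / 2.0
    return np.concatenate([[zs[0] - 1.0], mids, [zs[-1] + 1.0]])


def _best_binary_threshold(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(balanced accuracy, threshold) maximising bacc of ``z >= t``.

    Ties go to the smallest threshold (candidates swept in ascending
    order, first maximum kept).
    """
    cand = _threshold_candidates(z)
    pred = z[None, :] >= cand[:, None]
    tp = (pred & y).sum(axis=1)
    fp = (pred & ~y).sum(axis=1)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    bacc = 0.5 * (sens + spec)
    i = int(np.argmax(bacc))
    return float(bacc[i]), float(cand[i])


def _best_ternary_thresholds(
    z: np.ndarray, labels: Sequence[str]
) -> tuple[float, float, float]:
    """(objective, t_low, t_high) maximising the mean of per-direction baccs.

    Prolongation-vs-rest depends only on ``t_high`` (predict prolong iff
    z >= t_high); shortening-vs-rest only on ``t_low`` (predict shorten iff
    z <= t_low).  The joint optimum over t_low <= t_high is taken on the
    candidate grid; if a direction has no positives it is dropped from the
    objective and its threshold pushed to the non-predicting extreme.
    """
    lab = np.asarray(labels)
    y_p = lab == _cls.PROLONG
    y_s = lab == _cls.SHORTEN
    cand = _threshold_candidates(z)
    k = cand.size

    def direction_bacc(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
        n_pos = int(y.sum())
        n_neg = y.size - n_pos
        tp = (pred & y).sum(axis=1)
        fp = (pred & ~y).sum(axis=1)
        return 0.5 * (tp / n_pos + (n_neg - fp) / n_neg)

    have_p = bool(y_p.any())
    have_s = bool(y_s.any())
    pred_high = z[None, :] >= cand[:, None]   # prolong predictions per t_high
    pred_low = z[None, :] <= cand[:, None]    # shorten predictions per t_low

    if have_p and have_s:
        bp = direction_bacc(pred_high, y_p)   # indexed by t_high
        bs = direction_bacc(pred_low, y_s)    # indexed by t_low
        obj = 0.5 * (bs[:, None] + bp[None, :])      # [t_low, t_high]
        invalid = np.triu(np.ones((k, k), dtype=bool), k=1).T  # t_low > t_high
        obj = np.where(invalid, -np.inf, obj)
        flat = int(np.argmax(obj))  # row-major: smallest t_low, then t_high
        i, j = divmod(flat, k)
        return float(obj[i, j]), float(cand[i]), float(cand[j])
    if have_p:
        bp = direction_bacc(pred_high, y_p)
        j = int(np.argmax(bp))
        return float(bp[j]), float(cand[0]), float(cand[j])
    if have_s:
        bs = direction_bacc(pred_low, y_s)
        i = int(np.argmax(bs))
        return float(bs[i]), float(cand[i]), float(cand[-1])
    raise CannotFitError("training set has neither prolong nor shorten labels")


def _evaluate_coeffs(
    S: np.ndarray,
    labels: Sequence[str],
    endpoint: Endpoint,
    coeffs: tuple[float, float, float],
) -> tuple[float, DecisionRule]:
    a0, a1, a2 = coeffs
    z = (1.0 + a0 * S[:, 0] + a1 * S[:, 1]) / (1.0 + a2 * S[:, 2])
    if endpoint is Endpoint.APD_TERNARY:
        obj, t_low, t_high = _best_ternary_thresholds(z, labels)
        return obj, DecisionRule(kind=RuleKind.TERNARY, t_high=t_high, t_low=t_low)
    pos = positive_label(endpoint)
    y = np.asarray([lab == pos for lab in labels])
    obj, t = _best_binary_threshold(z, y)
    return obj, DecisionRule(kind=RuleKind.BINARY, t_high=t)


def _fit_on_matrix(
    S: np.ndarray,
    labels: Sequence[str],
    endpoint: Endpoint,
    config: SearchConfig,
) -> FitResult:
    if len(set(labels)) < 2:
        raise CannotFitError("training set contains a single class")

    best_obj = -np.inf
    best: tuple[tuple[float, float, float], DecisionRule] | None = None
    grid = tuple(sorted(config.coef_grid))
    for coeffs in itertools.product(grid, grid, grid):
        obj, rule = _evaluate_coeffs(S, labels, endpoint, coeffs)
        if obj > best_obj:  # strictly better: first (lexicographically
            best_obj = obj  # smallest) optimum wins ties
            best = (coeffs, rule)
    assert best is not None

    if config.refine:
        base = best[0]
        axes = []
        for b in base:
            if b == 0.0:
                axes.append(tuple(sorted(set(config.zero_refine_candidates))))
            else:
                axes.append(tuple(sorted({b * f for f in config.refine_factors})))
        for coeffs in itertools.product(*axes):
            obj, rule = _evaluate_coeffs(S, labels, endpoint, coeffs)
            if obj > best_obj:
                best_obj = obj
                best = (coeffs, rule)

    (a0, a1, a2), rule = best
    return FitResult(
        params=ClassifierParams(a0=a0, a1=a1, a2=a2),
        rule=rule,
        objective=float(best_obj),
    )


def fit_params(
    training: Sequence,
    endpoint: Endpoint,
    config: SearchConfig | None = None,
) -> FitResult:
    """Fit (a0, a1, a2) and decision threshold(s) on a training set.

    Maximises balanced accuracy (binary) or the mean of per-direction
    one-vs-rest balanced accuracies (ternary) over a deterministic
    coefficient grid with exhaustive threshold sweep, then a local
    refinement.  Deterministic given the config.
    """
    config = config or SearchConfig()
    S = _profile_matrix(training)
    labels = [rec.label for rec in training]
    return _fit_on_matrix(S, labels, endpoint, config)


# --------------------------------------------------------------------------
# Metrics and LOOCV
# --------------------------------------------------------------------------

def metrics_from_counts(tp: int, fn: int, tn: int, fp: int
                        ) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) from confusion counts.

    Zero-denominator cases yield NaN (undefined marker), never an error.
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    sens = tp / (tp + fn) if (tp + fn) > 0 else UNDEFINED
    spec = tn / (tn + fp) if (tn + fp) > 0 else UNDEFINED
    bacc = (sens + spec) / 2.0
    return sens, spec, bacc


def metrics_from_confusion(
    confusion: Mapping[str, Mapping[str, int]], positive: str
) -> tuple[float, float, float]:
    """One-vs-rest metrics for ``positive`` from a class-by-class count table.

    ``confusion[true][predicted]`` holds counts; any class absent from a
    row is treated as zero.
    """
    tp = fn = tn = fp = 0
    for true_lab, row in confusion.items():
        for pred_lab, count in row.items():
            if true_lab == positive and pred_lab == positive:
                tp += count
            elif true_lab == positive:
                fn += count
            elif pred_lab == positive:
                fp += count
            else:
                tn += count
    return metrics_from_counts(tp, fn, tn, fp)


@dataclass(frozen=True)
class DirectionMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float


@dataclass(frozen=True)
class FoldResult:
    compound_id: str
    true_label: str
    predicted_label: str | None          # None when the fold was unpredicted
    params: ClassifierParams | None
    rule: DecisionRule | None


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation summary.

    ``directions`` holds per-direction one-vs-rest metrics (one entry for a
    binary endpoint; prolongation and shortening for a ternary endpoint);
    the scalar ``sensitivity``/``specificity``/``balanced_accuracy`` are
    their (mean) values, so balanced_accuracy = (sensitivity +
    specificity) / 2 always holds.
    """

    per_fold: tuple[FoldResult, ...]
    confusion: Mapping[str, Mapping[str, int]]
    directions: Mapping[str, DirectionMetrics]
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    n_excluded: int = 0


def _rule_label_to_endpoint(token: str, endpoint: Endpoint) -> str:
    if endpoint is Endpoint.APD_TERNARY:
        return token
    if token == _cls.POSITIVE:
        return positive_label(endpoint)
    return next(lab for lab in LABELS[endpoint]
                if lab != positive_label(endpoint))


def loocv(dataset: Dataset, config: SearchConfig | None = None) -> CVResult:
    """Leave-one-out cross-validation with per-fold parameter optimisation.

    Each compound is predicted by a rule fitted on the other n−1; the test
    compound never influences its fold's fit.  Folds whose training set
    collapses to a single class are recorded as unpredicted and excluded
    from the metrics, with the count reported.
    """
    if len(dataset.records) < 3:
        raise ValueError("leave-one-out cross-validation needs >= 3 compounds")
    if len(set(dataset.labels())) < 2:
        raise CannotFitError("dataset contains a single class overall")
    config = config or SearchConfig()

    S = _profile_matrix(dataset.records)
    labels = dataset.labels()
    n = len(labels)
    endpoint = dataset.endpoint
    class_order = list(LABELS[endpoint])

    folds: list[FoldResult] = []
    n_excluded = 0
    confusion: dict[str, dict[str, int]] = {
        t: {p: 0 for p in class_order} for t in class_order
    }
    mask = np.ones(n, dtype=bool)
    for i, rec in enumerate(dataset.records):
        mask[:] = True
        mask[i] = False
        train_labels = [labels[j] for j in range(n) if j != i]
        if len(set(train_labels)) < 2:
            logger.warning(
                "fold %r: training set single-class; fold excluded", rec.compound_id
            )
            n_excluded += 1
            folds.append(FoldResult(rec.compound_id, rec.label, None, None, None))
            continue
        fit = _fit_on_matrix(S[mask], train_labels, endpoint, config)
        a0, a1, a2 = fit.params.as_tuple()
        z_i = (1.0 + a0 * S[i, 0] + a1 * S[i, 1]) / (1.0 + a2 * S[i, 2])
        token = _cls.classify(z_i, fit.rule)
        predicted = _rule_label_to_endpoint(token, endpoint)
        confusion[rec.label][predicted] += 1
        folds.append(
            FoldResult(rec.compound_id, rec.label, predicted, fit.params, fit.rule)
        )

    directions: dict[str, DirectionMetrics] = {}
    if endpoint is Endpoint.APD_TERNARY:
        direction_targets = [("prolongation", _cls.PROLONG),
                             ("shortening", _cls.SHORTEN)]
    else:
        direction_targets = [(positive_label(endpoint), positive_label(endpoint))]
    for name, target in direction_targets:
        sens, spec, bacc = metrics_from_confusion(confusion, target)
        directions[name] = DirectionMetrics(sens, spec, bacc)

    sens_values = [m.sensitivity for m in directions.values()]
    spec_values = [m.specificity for m in directions.values()]
    sensitivity = float(np.mean(sens_values))
    specificity = float(np.mean(spec_values))
    return CVResult(
        per_fold=tuple(folds),
        confusion=confusion,
        directions=directions,
        sensitivity=sensitivity,
        specificity=specificity,
        balanced_accuracy=(sensitivity + specificity) / 2.0,
        n_excluded=n_excluded,
    )


def permutation_null(
    dataset: Dataset,
    config: SearchConfig | None = None,
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """LOOCV balanced accuracies under label permutation (the chance null).

    Permutes the endpoint labels across compounds (breaking any label–Z
    link while preserving class balance) and re-runs the full LOOCV per
    permutation.  The 95th percentile of the returned array is the usual
    reference a real LOOCV result should exceed.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels()
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(labels))
        shuffled = [labels[j] for j in perm]
        records = tuple(
            replace(rec, label=lab)
            for rec, lab in zip(dataset.records, shuffled)
        )
        permuted = Dataset(
            name=f"{dataset.name}-perm{b}",
            endpoint=dataset.endpoint,
            species=dataset.species,
            records=records,
        )
        out[b] = loocv(permuted, config).balanced_accuracy
    return out
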