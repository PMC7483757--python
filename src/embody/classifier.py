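"""Per-subject one-vs-rest penalized logistic decoding of IA states.

One binary L2-penalized logistic regression is fit per condition (that
condition vs. all others), yielding a continuous *evidence* value in (0, 1)
per condition per volume; the condition with the highest evidence is the
categorical decision. Accuracy is estimated by leave-one-block-out
cross-validation: train on all blocks but one, test on the held-out block,
rotate until every labeled volume has been tested exactly once.

Penalty convention
------------------
``penalty`` is the coefficient lambda multiplying ``||w||^2`` in the
regularized negative log-likelihood, ``sum(log-loss) + lambda * ||w||^2``
(the convention of classic neuroimaging MVPA toolboxes). scikit-learn
parameterizes the same objective as ``C * sum(log-loss) + ||w||^2 / 2``, so
the fits below use ``C = 1 / (2 * penalty)`` — e.g., the default
``penalty=0.01`` maps to ``C = 50``. Intercepts are unpenalized in both
conventions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chisquare, pearsonr, ttest_1samp
from sklearn.linear_model import LogisticRegression

from .containers import LabelSeries, VoxelTimeSeries
from .design import CONDITIONS, MEDITATION_STATES, TaskDesign

#: Evidence values are clipped into the open unit interval at this margin.
_EVIDENCE_EPS = 1e-12
#: Theoretical chance level for five conditions, as a proportion.
CHANCE_LEVEL = 0.2


class MissingClassError(ValueError):
    """A required condition has no labeled volumes where it is needed."""


@dataclass
class ClassifierModel:
    """Five one-vs-rest logistic models sharing one voxel grid.

    ``weights`` is conditions x voxels, rows ordered by ``condition_order``;
    ``penalty`` is the L2 coefficient on ``||w||^2`` (see module docstring).
    """

    weights: np.ndarray
    intercepts: np.ndarray
    penalty: float
    condition_order: tuple[str, ...]
    training_volume_count: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("classifier weights must be finite")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if len(set(self.condition_order)) != len(self.condition_order):
            raise ValueError("condition_order must be unique")
        if self.weights.shape[0] != len(self.condition_order):
            raise ValueError("one weight row per condition required")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]

    def evidence(self, ts: VoxelTimeSeries) -> np.ndarray:
        """Volumes x conditions evidence matrix, each value strictly in (0, 1)."""
        if ts.n_voxels != self.n_voxels:
            raise ValueError(
                f"run has {ts.n_voxels} voxels but model expects {self.n_voxels}"
            )
        scores = ts.data.T @ self.weights.T + self.intercepts
        return np.clip(expit(scores), _EVIDENCE_EPS, 1.0 - _EVIDENCE_EPS)


def train(
    ts: VoxelTimeSeries,
    labels: LabelSeries,
    penalty: float = 0.01,
    conditions: tuple[str, ...] = CONDITIONS,
) -> ClassifierModel:
    """Fit one-vs-rest L2 logistic models on the labeled volumes.

    Every condition in ``conditions`` must appear in the training labels.
    The fit is deterministic given the data (lbfgs, tolerance 1e-6).
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    mask = labels.labeled_mask
    n_labeled = int(mask.sum())
    if n_labeled < 10:
        raise ValueError("need at least 10 labeled volumes to train")
    y = labels.labels[mask]
    present = set(y.tolist())
    if len(present) < 2:
        raise ValueError("need at least 2 conditions present in training labels")
    for cond in conditions:
        if cond not in present:
            raise MissingClassError(f"condition {cond!r} absent from training labels")
    X = ts.data[:, mask].T
    C = 1.0 / (2.0 * penalty)
    weights = np.empty((len(conditions), ts.n_voxels))
    intercepts = np.empty(len(conditions))
    for i, cond in enumerate(conditions):
        # L2 penalty is sklearn's default; see module docstring for the C mapping.
        clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-6, max_iter=2000)
        clf.fit(X, (y == cond).astype(int))
        weights[i] = clf.coef_[0]
        intercepts[i] = clf.intercept_[0]
    return ClassifierModel(weights, intercepts, penalty, tuple(conditions), n_labeled)


def decide(
    evidence: np.ndarray,
    allowed: tuple[str, ...],
    condition_order: tuple[str, ...] = CONDITIONS,
) -> np.ndarray:
    """Argmax decision per volume, restricted to the ``allowed`` conditions.

    Exact ties are broken by position in ``condition_order`` (earliest wins)
    with a logged warning.
    """
    if len(allowed) == 0:
        raise ValueError("allowed condition set must be non-empty")
    idx = [condition_order.index(c) for c in allowed]
    order = np.argsort(idx)  # preserve declaration order for tie-breaking
    cols = np.asarray(idx)[order]
    names = np.asarray([condition_order[c] for c in cols], dtype=object)
    sub = np.asarray(evidence)[:, cols]
    n_ties = int(((sub == sub.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
    if n_ties:
        warnings.warn(
            f"{n_ties} volume(s) had tied evidence; broken by condition order"
        )
    return names[np.argmax(sub, axis=1)]


@dataclass
class CrossValResult:
    """Pooled test-set outputs of leave-one-block-out cross-validation.

    All arrays cover every labeled volume exactly once. ``volume_index`` is
    the within-block volume index of each decision, so decisions can be
    mapped back to trials.
    """

    evidence: np.ndarray
    decisions: np.ndarray
    true_labels: np.ndarray
    block_id: np.ndarray
    volume_index: np.ndarray
    condition_order: tuple[str, ...]

    @property
    def n_decisions(self) -> int:
        return self.decisions.shape[0]


def cross_validate(
    blocks: list[tuple[VoxelTimeSeries, LabelSeries]],
    penalty: float = 0.01,
    conditions: tuple[str, ...] = CONDITIONS,
) -> CrossValResult:
    """Leave-one-block-out cross-validation over labeled volumes.

    With the default six-block design this yields 2,160 decisions, each made
    by a model trained on the 1,800 labeled volumes of the other five blocks.
    """
    if len(blocks) < 2:
        raise ValueError("cross-validation requires at least 2 blocks")
    for k, (_, lab) in enumerate(blocks):
        present = set(lab.labels[lab.labeled_mask].tolist())
        for cond in conditions:
            if cond not in present:
                raise MissingClassError(
                    f"block {k} is missing condition {cond!r}"
                )
    ev_parts, dec_parts, lab_parts, blk_parts, vol_parts = [], [], [], [], []
    for k, (test_ts, test_lab) in enumerate(blocks):
        train_data = np.concatenate(
            [ts.data[:, lab.labeled_mask] for j, (ts, lab) in enumerate(blocks) if j != k],
            axis=1,
        )
        train_labels = np.concatenate(
            [lab.labels[lab.labeled_mask] for j, (_, lab) in enumerate(blocks) if j != k]
        )
        model = train(
            VoxelTimeSeries(train_data, test_ts.tr_seconds),
            LabelSeries(train_labels),
            penalty,
            conditions,
        )
        mask = test_lab.labeled_mask
        ev = model.evidence(test_ts)[mask]
        ev_parts.append(ev)
        dec_parts.append(decide(ev, conditions, conditions))
        lab_parts.append(test_lab.labels[mask])
        blk_parts.append(np.full(int(mask.sum()), k))
        vol_parts.append(np.flatnonzero(mask))
    return CrossValResult(
        evidence=np.concatenate(ev_parts),
        decisions=np.concatenate(dec_parts),
        true_labels=np.concatenate(lab_parts),
        block_id=np.concatenate(blk_parts),
        volume_index=np.concatenate(vol_parts),
        condition_order=tuple(conditions),
    )


@dataclass
class AccuracyReport:
    """Per-subject classification accuracy and individual-level significance."""

    per_condition_accuracy: dict[str, float]
    confusion: pd.DataFrame
    chi_square: dict[str, tuple[float, float]]
    included: bool
    n_per_condition: dict[str, int]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_condition_accuracy.values())))


def evaluate(
    decisions: np.ndarray,
    true_labels: np.ndarray,
    condition_order: tuple[str, ...] = CONDITIONS,
) -> AccuracyReport:
    """Score pooled cross-validation decisions for one subject.

    Per condition: accuracy (% correct of tested volumes) and a chi-square
    goodness-of-fit test of correct vs. incorrect counts against the chance
    split (0.2, 0.8). The subject-inclusion flag is set when at least two of
    the three meditation-relevant conditions (Breath, MW, Self) are
    classified above chance at p < 0.001.
    """
    decisions = np.asarray(decisions, dtype=object)
    true_labels = np.asarray(true_labels, dtype=object)
    if decisions.shape != true_labels.shape:
        raise ValueError("decisions and labels must be aligned")
    confusion = pd.crosstab(
        pd.Series(true_labels, name="true"),
        pd.Series(decisions, name="decided"),
    ).reindex(index=condition_order, columns=condition_order, fill_value=0)
    acc, chi, n_cond = {}, {}, {}
    for cond in condition_order:
        n = int(confusion.loc[cond].sum())
        if n == 0:
            raise ValueError(f"no tested volumes for condition {cond!r}: accuracy undefined")
        correct = int(confusion.loc[cond, cond])
        acc[cond] = 100.0 * correct / n
        stat, p = chisquare(
            [correct, n - correct],
            f_exp=[CHANCE_LEVEL * n, (1 - CHANCE_LEVEL) * n],
        )
        chi[cond] = (float(stat), float(p))
        n_cond[cond] = n
    n_sig = sum(
        1
        for cond in MEDITATION_STATES
        if chi[cond][1] < 0.001 and acc[cond] > 100.0 * CHANCE_LEVEL
    )
    return AccuracyReport(acc, confusion, chi, n_sig >= 2, n_cond)


@dataclass
class GroupAccuracyResult:
    t: float
    p: float
    cohens_d: float
    mean_accuracy: float
    n_subjects: int


def group_accuracy_test(
    accuracies: np.ndarray, chance: float = 100.0 * CHANCE_LEVEL
) -> GroupAccuracyResult:
    """One-sample two-sided t-test of subject accuracies against chance.

    Cohen's d is the mean deviation from chance over the sample SD; both are
    0 when every subject sits exactly at chance (degenerate zero-variance
    input).
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size < 2:
        raise ValueError("group test requires at least 2 subjects")
    sd = accuracies.std(ddof=1)
    diff = accuracies.mean() - chance
    if sd == 0.0:
        if diff == 0.0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p, d = float(np.sign(diff)) * np.inf, 0.0, float(np.sign(diff)) * np.inf
    else:
        t, p = ttest_1samp(accuracies, chance)
        t, p = float(t), float(p)
        d = float(diff / sd)
    return GroupAccuracyResult(t, p, d, float(accuracies.mean()), accuracies.size)


def per_trial_accuracy(
    cv: CrossValResult, design: TaskDesign, lag_seconds: float = 6.0
) -> pd.DataFrame:
    """Mean decision accuracy per trial, for correlating with ratings.

    Each trial's decisions are the cross-validated decisions on its shifted
    volumes. Returns one row per trial with block, trial index, condition,
    rating (may be missing), eligibility, and accuracy in percent.
    """
    lag_vols = int(round(lag_seconds / design.tr_seconds))
    rows = []
    for b, t, trial in design.trials():
        start = int(round(trial.onset_seconds / design.tr_seconds)) + lag_vols
        stop = start + int(round(trial.duration_seconds / design.tr_seconds))
        m = (cv.block_id == b) & (cv.volume_index >= start) & (cv.volume_index < stop)
        n = int(m.sum())
        accuracy = 100.0 * float(
            (cv.decisions[m] == trial.condition).mean()
        ) if n else np.nan
        rows.append(
            {
                "block": b,
                "trial": t,
                "condition": trial.condition,
                "rating": trial.rating,
                "rating_eligible": trial.rating_eligible,
                "n_volumes": n,
                "accuracy": accuracy,
            }
        )
    return pd.DataFrame(rows)


def rating_correlation(trials: pd.DataFrame, scope: str = "all") -> float:
    """Pearson correlation between trial-level accuracy and attention rating.

    ``scope`` is ``"all"`` (every rated non-MW trial) or ``"breath"``
    (Breath trials only). Returns NaN with a warning when either variable
    has zero variance (the subject is then excluded from the group test).
    """
    if scope not in ("all", "breath"):
        raise ValueError("scope must be 'all' or 'breath'")
    sel = trials[trials["rating"].notna() & (trials["condition"] != "MW")]
    if scope == "breath":
        sel = sel[sel["condition"] == "Breath"]
    sel = sel[np.isfinite(sel["accuracy"])]
    if len(sel) < 3:
        raise ValueError("need at least 3 rated trials in scope")
    x = sel["accuracy"].to_numpy(dtype=float)
    y = sel["rating"].to_numpy(dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        warnings.warn("zero variance in accuracy or ratings; correlation undefined")
        return float("nan")
    return float(pearsonr(x, y)[0])


@dataclass
class GroupRatingResult:
    mean_z: float
    t: float
    p: float
    n_subjects: int
    n_excluded: int


def group_rating_test(r_values: np.ndarray) -> GroupRatingResult:
    """Fisher r-to-Z transform of per-subject correlations, tested vs. 0."""
    r_values = np.asarray(r_values, dtype=float)
    finite = np.isfinite(r_values)
    n_excluded = int((~finite).sum())
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} subject(s) with undefined correlation")
    z = np.arctanh(r_values[finite])
    if z.size < 2:
        raise ValueError("group rating test requires at least 2 usable subjects")
    if z.std(ddof=1) == 0.0:
        t, p = (0.0, 1.0) if np.isclose(z.mean(), 0.0) else (np.inf, 0.0)
    else:
        t, p = ttest_1samp(z, 0.0)
    return GroupRatingResult(float(z.mean()), float(t), float(p), int(z.size), n_excluded)
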