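"""MCC-optimal thresholded classification.

The population-optimal classifier for the Matthews correlation coefficient
is a thresholded rule on the conditional probability eta(x) = P(Y=1|X=x):

    theta*(x) = sign[(TP - gamma*pi) * (eta(x) - delta*)],
    delta* = (TP* + gamma*(pi - 2*TP*)) / (2*gamma*(1 - gamma)),

where TP* = P(Y=1, theta*=1), gamma = P(theta*=1) and pi = P(Y=1).  Since
delta* depends on the optimum itself, it cannot be computed before fitting;
instead the estimation algorithm splits the training sample into two halves
S1/S2, fits a plug-in probability estimate eta_hat on S1 with a proper loss
(regularized logistic regression by default), and grid-searches the
threshold delta and the orientation sign on S2 by maximizing the empirical
MCC.  When the plug-in estimate is obtained with a proper loss this
procedure is consistent: its test MCC converges to the population optimum
as the sample grows.

Two interfaces are provided: plain functions (:func:`fit_mcc_classifier`,
:func:`fit_mcc_bayes`, :func:`evaluate`, :func:`repeat_protocol`) and a
model/results pair (:class:`MCCClassifierModel` -> ``fit()`` ->
:class:`MCCClassifierResults`) with a printable ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .metrics import (
    ConfusionCounts,
    MetricValue,
    PopulationRates,
    confusion_from_labels,
    mcc,
    metric_table,
)

__all__ = [
    "theorem_threshold",
    "ProbabilityEstimator",
    "LogisticProbabilityEstimator",
    "ThresholdClassifier",
    "FitReport",
    "default_grid",
    "fit_mcc_classifier",
    "fit_mcc_bayes",
    "predict",
    "evaluate",
    "repeat_protocol",
    "MCCClassifierModel",
    "MCCClassifierResults",
    "SplitError",
    "NotFittedError",
]


class SplitError(ValueError):
    """Raised when a train/validation split leaves a half with one class."""


class NotFittedError(RuntimeError):
    """Raised when predictions are requested from an unfitted estimator."""


def theorem_threshold(rates: PopulationRates) -> float:
    """Optimal threshold delta* implied by the rates of an optimal classifier.

    delta* = (TP + gamma*(pi - 2*TP)) / (2*gamma*(1-gamma)).  Degenerate
    predicted-positive rates (gamma of 0 or 1) admit no threshold.
    """
    g = rates.gamma
    if g <= 0.0 or g >= 1.0:
        raise ValueError(f"degenerate classifier: gamma={g} must lie strictly in (0, 1)")
    return (rates.tp + g * (rates.pi - 2.0 * rates.tp)) / (2.0 * g * (1.0 - g))


@runtime_checkable
class ProbabilityEstimator(Protocol):
    """Contract for the plug-in estimator of eta(x) = P(Y=1|X=x).

    Implementations must train with a proper loss (one minimized in
    population by the true conditional probability, e.g. log loss) for the
    threshold-search procedure to be consistent.
    """

    def fit(self, X, y, seed: int = 0) -> "ProbabilityEstimator": ...

    def predict_proba1(self, X) -> np.ndarray: ...


class LogisticProbabilityEstimator:
    """L2-regularized logistic regression estimate of eta(x).

    Trains by penalized log loss (a proper loss).  Coefficients are kept
    explicitly so fitted estimators serialize to plain JSON and reload
    without refitting.

    Parameters
    ----------
    c : float
        Inverse L2 penalty strength (sklearn's ``C``).  Default 1.0.
    max_iter : int
        lbfgs iteration cap.
    """

    loss = "log"

    def __init__(self, c: float = 1.0, max_iter: int = 1000):
        self.c = float(c)
        self.max_iter = int(max_iter)
        self.coef_: Optional[np.ndarray] = None
        self.intercept_: Optional[float] = None

    def fit(self, X, y, seed: int = 0) -> "LogisticProbabilityEstimator":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        # sklearn's default penalty is L2; C is the inverse strength
        lr = LogisticRegression(
            C=self.c, solver="lbfgs", max_iter=self.max_iter, random_state=seed
        )
        lr.fit(X, y)
        self.coef_ = lr.coef_.ravel().copy()
        self.intercept_ = float(lr.intercept_[0])
        return self

    def predict_proba1(self, X) -> np.ndarray:
        if self.coef_ is None:
            raise NotFittedError("probability estimator has not been fitted")
        X = np.asarray(X, dtype=float)
        return expit(X @ self.coef_ + self.intercept_)

    def to_dict(self) -> dict:
        if self.coef_ is None:
            raise NotFittedError("cannot serialize an unfitted estimator")
        return {
            "kind": "logistic",
            "c": self.c,
            "coef": [float(v) for v in self.coef_],
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticProbabilityEstimator":
        est = cls(c=d.get("c", 1.0))
        est.coef_ = np.asarray(d["coef"], dtype=float)
        est.intercept_ = float(d["intercept"])
        return est


@dataclass
class ThresholdClassifier:
    """Thresholded classifier on an estimated conditional probability.

    Predicts 1 iff ``orientation * (eta_hat(x) - delta) > 0``; an exact tie
    eta_hat(x) == delta predicts 0.  ``orientation`` is +1 (label high
    probabilities 1) or -1 (the reversed rule, which the optimality theorem
    cannot rule out a priori because the sign of TP - gamma*pi is unknown
    before fitting).
    """

    orientation: int
    delta: float
    estimator: ProbabilityEstimator

    def __post_init__(self) -> None:
        if self.orientation not in (+1, -1):
            raise ValueError(f"orientation must be +1 or -1, got {self.orientation}")
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must lie strictly in (0, 1), got {self.delta}")

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict_proba1(X), dtype=float)

    def predict(self, X) -> np.ndarray:
        eta = self.decision_scores(X)
        return (self.orientation * (eta - self.delta) > 0).astype(np.int64)

    def save(self, path, *, grid=None, seed=None) -> None:
        """Persist orientation, threshold and estimator coefficients as JSON."""
        doc = {
            "orientation": self.orientation,
            "delta": self.delta,
            "estimator": self.estimator.to_dict(),
            "grid": None if grid is None else [float(g) for g in grid],
            "seed": seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ThresholdClassifier":
        with open(path) as fh:
            doc = json.load(fh)
        est = LogisticProbabilityEstimator.from_dict(doc["estimator"])
        return cls(orientation=int(doc["orientation"]), delta=float(doc["delta"]), estimator=est)


@dataclass
class FitReport:
    """Diagnostics of the threshold grid search.

    ``mcc_on_s2`` is a 2 x len(grid) matrix of validation-half MCC values:
    row 0 for orientation +1, row 1 for orientation -1.  The chosen
    (orientation, delta) attains its maximum.
    """

    chosen_delta: float
    chosen_orientation: int
    grid: np.ndarray
    mcc_on_s2: np.ndarray
    split_seed: int
    n_s1: int = 0
    n_s2: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta": np.concatenate([self.grid, self.grid]),
                "orientation": np.repeat([1, -1], len(self.grid)),
                "mcc_s2": np.concatenate([self.mcc_on_s2[0], self.mcc_on_s2[1]]),
            }
        )


def default_grid(start: float = 0.01, stop: float = 0.99, step: float = 0.01) -> np.ndarray:
    """Threshold grid delta in {0.01, 0.02, ..., 0.99} by default."""
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    grid = grid[(grid > 0.0) & (grid < 1.0)]
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    return grid


def _check_two_class(y: np.ndarray, context: str) -> None:
    if y.size == 0 or y.min() == y.max():
        raise SplitError(
            f"{context} contains a single class; use a different seed or split fraction"
        )


def _mcc_curve(eta: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical MCC of both orientations at each grid threshold.

    Vectorized: sorting eta once gives, for every threshold, the counts of
    positives/predictions above it via a searchsorted lookup.
    """
    n = y.size
    order = np.argsort(eta, kind="mergesort")
    eta_sorted = eta[order]
    y_sorted = y[order]
    # suffix sums: number of positives with eta > t
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted[::-1])])[::-1]  # cum_pos[i] = positives in eta_sorted[i:]
    idx = np.searchsorted(eta_sorted, grid, side="right")
    n_pos = int(y.sum())
    pred_pos_plus = n - idx            # predicted 1 by orientation +1: eta > delta
    tp_plus = cum_pos[idx]
    # orientation -1 predicts 1 iff eta < delta (ties predict 0)
    idx_lo = np.searchsorted(eta_sorted, grid, side="left")
    pred_pos_minus = idx_lo
    tp_minus = n_pos - cum_pos[idx_lo]

    out = np.zeros((2, grid.size))
    for row, (tp, gpos) in enumerate(((tp_plus, pred_pos_plus), (tp_minus, pred_pos_minus))):
        fp = gpos - tp
        fn = n_pos - tp
        tn = n - gpos - fn
        denom2 = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (tp * tn - fp * fn) / np.sqrt(denom2.astype(float))
        vals[denom2 == 0] = 0.0  # undefined MCC falls back to 0 in the search
        out[row] = vals
    return out


def fit_mcc_classifier(
    features,
    labels,
    grid=None,
    split_fraction: float = 0.5,
    seed: int = 0,
    estimator: Optional[ProbabilityEstimator] = None,
    refit: bool = False,
) -> tuple[ThresholdClassifier, FitReport]:
    """Estimate the MCC-optimal thresholded classifier from training data.

    Procedure: (1) split the training set into disjoint stratified halves S1
    and S2; (2) fit the plug-in probability estimator on S1; (3) for every
    threshold in ``grid`` evaluate the empirical MCC on S2 of both oriented
    rules 1[eta_hat > delta] and 1[eta_hat < delta]; (4) return the
    maximizer, preferring the + orientation (and the smallest such delta)
    on exact ties.

    Parameters
    ----------
    features, labels : array-like
        Training sample; labels in {0,1} with the minority class coded 1.
    grid : array-like of float in (0,1), optional
        Candidate thresholds; defaults to 0.01..0.99 step 0.01.
    split_fraction : float
        Fraction of the sample assigned to S1 (the estimation half).
    seed : int
        Drives the stratified split and the estimator; the fit is a pure
        function of (data, grid, split_fraction, seed).
    estimator : ProbabilityEstimator, optional
        Plug-in model for eta(x); defaults to L2 logistic regression.
    refit : bool
        If True, refit the estimator on the full sample after threshold
        selection (off by default: the selected rule is returned as-is).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(np.int64)
    _check_two_class(y, "training labels")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() <= 0.0 or grid.max() >= 1.0:
        raise ValueError("grid must be non-empty with thresholds strictly inside (0, 1)")

    X1, X2, y1, y2 = train_test_split(
        X, y, train_size=split_fraction, random_state=seed, stratify=y
    )
    _check_two_class(y1, "estimation half S1")
    _check_two_class(y2, "validation half S2")

    est = estimator if estimator is not None else LogisticProbabilityEstimator()
    est.fit(X1, y1, seed=seed)
    eta2 = np.asarray(est.predict_proba1(X2), dtype=float)

    curve = _mcc_curve(eta2, y2, grid)
    # argmax over the flattened (orientation, delta) matrix; row-major order
    # makes ties prefer orientation +1 first, then the smallest delta.
    flat = int(np.argmax(curve))
    row, col = divmod(flat, grid.size)
    orientation = +1 if row == 0 else -1
    delta = float(grid[col])

    if refit:
        est.fit(X, y, seed=seed)

    clf = ThresholdClassifier(orientation=orientation, delta=delta, estimator=est)
    report = FitReport(
        chosen_delta=delta,
        chosen_orientation=orientation,
        grid=grid,
        mcc_on_s2=curve,
        split_seed=seed,
        n_s1=int(y1.size),
        n_s2=int(y2.size),
    )
    return clf, report


def fit_mcc_bayes(
    features, labels, seed: int = 0, estimator: Optional[ProbabilityEstimator] = None
) -> ThresholdClassifier:
    """Plug-in Bayes baseline: fit eta_hat on all data, threshold at 0.5."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(np.int64)
    _check_two_class(y, "training labels")
    est = estimator if estimator is not None else LogisticProbabilityEstimator()
    est.fit(X, y, seed=seed)
    return ThresholdClassifier(orientation=+1, delta=0.5, estimator=est)


def predict(clf: ThresholdClassifier, features) -> np.ndarray:
    """Apply the orientation/threshold rule elementwise."""
    return clf.predict(features)


def evaluate(clf: ThresholdClassifier, features, labels) -> pd.DataFrame:
    """Tidy metric table (MCC, F1, both accuracies, AUC, precision, recall).

    AUC uses the estimated probabilities as scores (flipped under the -1
    orientation so that higher score still means "more positive").
    Degenerate confusion cells yield undefined-flagged rows, never errors.
    """
    y = _as_labels(labels)
    preds = clf.predict(features)
    counts = confusion_from_labels(y, preds)
    scores = clf.decision_scores(features)
    if clf.orientation == -1:
        scores = 1.0 - scores
    return metric_table(counts, y_true=y, scores=scores)


def _as_labels(labels) -> np.ndarray:
    return np.asarray(labels).astype(np.int64)


def repeat_protocol(
    features,
    labels,
    repeats: int = 10,
    test_fraction: float = 0.3,
    seed: int = 0,
    grid=None,
    split_fraction: float = 0.5,
    max_redraws: int = 20,
) -> pd.DataFrame:
    """Repeated random train/test evaluation of the two MCC methods.

    For each of ``repeats`` seeded rounds the data is split into train and
    test; the threshold-search classifier and the delta=0.5 Bayes baseline
    are fitted on the train part and evaluated on the test part.  Returns a
    tidy table with one row per (method, metric): columns ``method, metric,
    mean, sd, n_repeats``, where sd is the across-repeat standard deviation
    (ddof=1; 0 when repeats == 1).  Rounds whose test half is single-class
    are redrawn with a fresh derived seed (bounded retries).

    The per-repeat rows are attached as ``result.attrs['repeats']``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(features, dtype=float)
    y = _as_labels(labels)
    ss = np.random.SeedSequence(seed)
    round_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(repeats * (max_redraws + 1))]
    seed_iter = iter(round_seeds)

    rows = []
    for rep in range(repeats):
        for _ in range(max_redraws + 1):
            rseed = next(seed_iter)
            try:
                Xtr, Xte, ytr, yte = train_test_split(
                    X, y, test_size=test_fraction, random_state=rseed, stratify=y
                )
                _check_two_class(yte, "test set")
                _check_two_class(ytr, "train set")
                clf, _ = fit_mcc_classifier(
                    Xtr, ytr, grid=grid, split_fraction=split_fraction, seed=rseed
                )
                bayes = fit_mcc_bayes(Xtr, ytr, seed=rseed)
            except SplitError:
                continue
            break
        else:
            raise SplitError(f"could not draw a two-class split in {max_redraws} attempts")
        for method, fitted in (("mcc_classifier", clf), ("mcc_bayes", bayes)):
            tab = evaluate(fitted, Xte, yte)
            for _, r in tab.iterrows():
                rows.append(
                    {"repeat": rep, "method": method, "metric": r["metric"], "value": r["value"]}
                )

    per_repeat = pd.DataFrame(rows)
    summary = (
        per_repeat.groupby(["method", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    summary["n_repeats"] = repeats
    summary.attrs["repeats"] = per_repeat
    return summary


class MCCClassifierModel:
    """Model object for MCC-maximizing thresholded classification.

    Construct from a feature matrix and 0/1 label vector (minority class
    coded 1), then call :meth:`fit` for the threshold-search estimator or
    :meth:`fit_bayes` for the fixed delta=0.5 baseline; both return an
    :class:`MCCClassifierResults`.

    Examples
    --------
    >>> model = MCCClassifierModel(X, y)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        features,
        labels,
        estimator: Optional[ProbabilityEstimator] = None,
        grid=None,
        split_fraction: float = 0.5,
    ):
        self.exog = np.asarray(features, dtype=float)
        self.endog = _as_labels(labels)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("features must be a 2-D matrix with one row per label")
        _check_two_class(self.endog, "labels")
        self.estimator = estimator
        self.grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
        self.split_fraction = float(split_fraction)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, label_column: str, positive_label=1, **kwargs
    ) -> "MCCClassifierModel":
        """Build from a DataFrame; ``positive_label`` is recoded to 1."""
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not found")
        y = (frame[label_column] == positive_label).astype(int).to_numpy()
        X = frame.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(X, y, **kwargs)

    def fit(self, seed: int = 0, refit: bool = False) -> "MCCClassifierResults":
        clf, report = fit_mcc_classifier(
            self.exog,
            self.endog,
            grid=self.grid,
            split_fraction=self.split_fraction,
            seed=seed,
            estimator=self.estimator,
            refit=refit,
        )
        return MCCClassifierResults(self, clf, report=report, method="mcc_classifier", seed=seed)

    def fit_bayes(self, seed: int = 0) -> "MCCClassifierResults":
        clf = fit_mcc_bayes(self.exog, self.endog, seed=seed, estimator=self.estimator)
        return MCCClassifierResults(self, clf, report=None, method="mcc_bayes", seed=seed)


@dataclass
class MCCClassifierResults:
    """Fitted MCC classifier with diagnostics.

    Attributes
    ----------
    classifier : ThresholdClassifier
        The fitted decision rule (orientation, threshold, estimator).
    report : FitReport or None
        Grid-search diagnostics (None for the Bayes baseline).
    """

    model: MCCClassifierModel
    classifier: ThresholdClassifier
    report: Optional[FitReport] = None
    method: str = "mcc_classifier"
    seed: int = 0
    _train_table: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def orientation(self) -> int:
        return self.classifier.orientation

    @property
    def delta(self) -> float:
        return self.classifier.delta

    def predict(self, features) -> np.ndarray:
        return self.classifier.predict(features)

    def evaluate(self, features, labels) -> pd.DataFrame:
        return evaluate(self.classifier, features, labels)

    def training_mcc(self) -> MetricValue:
        preds = self.predict(self.model.exog)
        return mcc(confusion_from_labels(self.model.endog, preds))

    def save(self, path) -> None:
        self.classifier.save(path, grid=self.model.grid, seed=self.seed)

    def summary(self) -> str:
        """Plain-text summary of the fitted decision rule."""
        n, d = self.model.exog.shape
        pi_hat = float(self.model.endog.mean())
        lines = [
            "MCC thresholded classifier results",
            "=" * 42,
            f"method:            {self.method}",
            f"n obs:             {n}",
            f"n features:        {d}",
            f"prevalence (pi):   {pi_hat:.4f}",
            f"orientation:       {self.orientation:+d}",
            f"threshold (delta): {self.delta:.4f}",
            f"seed:              {self.seed}",
        ]
        if self.report is not None:
            best = float(self.report.mcc_on_s2.max())
            lines += [
                f"grid size:         {self.report.grid.size}",
                f"S1/S2 sizes:       {self.report.n_s1}/{self.report.n_s2}",
                f"best MCC on S2:    {best:.4f}",
            ]
        tr = self.training_mcc()
        lines.append(f"training MCC:      {tr.value:.4f}" + ("" if tr.defined else " (undefined)"))
        return "\n".join(lines)
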