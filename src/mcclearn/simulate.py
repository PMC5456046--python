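"""Simulation studies: metric robustness under class imbalance, optimality
verification on discrete populations, and an empirical consistency check.

Three studies are implemented, each a pure function of its seed:

* **Robustness** — feature-blind baseline classifiers (stratified-random
  C1, constant-majority C2, coin-flip C3) are scored across a sweep of
  class proportions pi.  A metric suited to imbalanced data should judge
  all three equally badly at every pi; the plain proportion-correct
  accuracy instead tracks 1 - pi for the constant classifier.
* **Optimality** — random discrete populations are drawn and the
  threshold-form classifier is checked against the exhaustive search over
  all 2^K labelings.
* **Consistency** — on a logistic-link Gaussian-mixture generator whose
  population optimum is computable, the fitted classifier's test MCC is
  tracked as the training size grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .metrics import (
    MetricValue,
    accuracy_balanced,
    accuracy_plain,
    auc_rank,
    confusion_from_labels,
    f1,
    mcc,
)
from .model import fit_mcc_classifier
from .population import DiscretePopulation, exhaustive_optimal, theorem_classifier, random_population

__all__ = [
    "RobustnessConfig",
    "SyntheticTabularConfig",
    "generate_labels",
    "baseline_predictions",
    "robustness_experiment",
    "OptimalityReport",
    "optimality_experiment",
    "generate_tabular",
    "gaussian_population_optimum",
    "consistency_experiment",
    "class_weight_ratio",
]

DEFAULT_PI_GRID = tuple(np.round(np.arange(0.05, 0.46, 0.05), 2))


@dataclass(frozen=True)
class RobustnessConfig:
    """Settings for the imbalance-robustness sweep.

    n labels are drawn per condition; pi_grid lists minority proportions,
    each strictly inside (0, 0.5) so class 1 is always the minority.
    """

    n: int = 10_000
    pi_grid: tuple = DEFAULT_PI_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not all(0.0 < p < 0.5 for p in self.pi_grid):
            raise ValueError("pi values must lie strictly in (0, 0.5)")


@dataclass(frozen=True)
class SyntheticTabularConfig:
    """Logistic-link Gaussian-mixture generator settings.

    Features for class 0 are N(0, I_d); class 1 is shifted by a vector of
    Euclidean norm ``separation`` (along (1,..,1)/sqrt(d)), with mixing
    weight ``pi`` for class 1.  The induced conditional probability
    P(Y=1|x) is exactly logistic in x, so the default plug-in estimator is
    well-specified and the population-optimal MCC is computable.
    """

    n: int = 1000
    d: int = 4
    pi: float = 0.1
    separation: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n < 1 or self.d < 1:
            raise ValueError("n and d must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_labels(n: int, pi: float, seed) -> np.ndarray:
    """n independent Bernoulli(pi) class labels."""
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie strictly in (0, 1)")
    return (_rng(seed).uniform(size=n) < pi).astype(np.int64)


def baseline_predictions(kind: str, labels_train, n_test: int, seed) -> np.ndarray:
    """Feature-blind baseline predictions.

    C1 draws Bernoulli(pi_hat) with pi_hat the training prevalence;
    C2 constantly outputs the training majority label; C3 draws
    Bernoulli(0.5).
    """
    y = np.asarray(labels_train)
    if y.size == 0:
        raise ValueError("labels_train must be non-empty")
    rng = _rng(seed)
    pi_hat = float(y.mean())
    if kind == "C1":
        return (rng.uniform(size=n_test) < pi_hat).astype(np.int64)
    if kind == "C2":
        majority = 1 if pi_hat > 0.5 else 0
        return np.full(n_test, majority, dtype=np.int64)
    if kind == "C3":
        return (rng.uniform(size=n_test) < 0.5).astype(np.int64)
    raise ValueError(f"unknown baseline kind {kind!r}; expected 'C1', 'C2' or 'C3'")


def _score_baseline(y_test: np.ndarray, preds: np.ndarray) -> list[tuple[str, MetricValue]]:
    counts = confusion_from_labels(y_test, preds)
    rows = [
        ("mcc", mcc(counts)),
        ("f1", f1(counts)),
        ("accuracy_plain", accuracy_plain(counts)),
        ("accuracy_balanced", accuracy_balanced(counts)),
    ]
    # hard 0/1 predictions serve as two-valued scores (ties get half credit)
    try:
        rows.append(("auc", MetricValue(auc_rank(y_test, preds.astype(float)))))
    except ValueError:
        rows.append(("auc", MetricValue(0.5, defined=False)))
    return rows


def robustness_experiment(config: RobustnessConfig) -> pd.DataFrame:
    """Score the three baselines across the pi sweep.

    For each pi, a training draw of n labels fixes the empirical prevalence
    the baselines may use, and an independent test draw of n labels is
    scored.  Returns a tidy frame with columns
    ``classifier, metric, pi, value, defined``.
    """
    ss = np.random.SeedSequence(config.seed)
    rows = []
    for pi, child in zip(config.pi_grid, ss.spawn(len(config.pi_grid))):
        rng = np.random.default_rng(child)
        y_train = generate_labels(config.n, pi, rng)
        y_test = generate_labels(config.n, pi, rng)
        for kind in ("C1", "C2", "C3"):
            preds = baseline_predictions(kind, y_train, config.n, rng)
            for metric, mv in _score_baseline(y_test, preds):
                rows.append(
                    {
                        "classifier": kind,
                        "metric": metric,
                        "pi": float(pi),
                        "value": mv.value,
                        "defined": mv.defined,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class OptimalityReport:
    """Per-draw comparison of exhaustive search vs threshold rule.

    ``agreement_count`` counts non-degenerate draws whose two population
    MCCs agree to ``tol``; degenerate draws (constant eta or degenerate
    prevalence) are excluded from the denominator ``n_valid``.
    """

    agreement_count: int
    n_valid: int
    n_degenerate: int
    draws: pd.DataFrame
    curves: list = field(default_factory=list)

    @property
    def all_agree(self) -> bool:
        return self.agreement_count == self.n_valid


def optimality_experiment(
    draws: int = 20, k: int = 10, seed: int = 0, tol: float = 1e-12
) -> OptimalityReport:
    """Draw random populations and certify the threshold rule's optimality.

    Each draw builds a random K-point population, runs the exhaustive
    2^K search and the threshold sweep, and records whether their maxima
    agree to ``tol``.  ``curves`` holds one frame per draw with columns
    ``x, eta, mu, optimal_label, delta_star`` for plotting.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    curves = []
    for i, child in enumerate(ss.spawn(draws)):
        pop = random_population(k, np.random.default_rng(child))
        exh = exhaustive_optimal(pop)
        thm = theorem_classifier(pop)
        degenerate = exh.degenerate or thm.degenerate
        agree = (
            not degenerate
            and abs(exh.mcc.value - thm.mcc.value) <= tol
        )
        rows.append(
            {
                "draw": i,
                "degenerate": degenerate,
                "exhaustive_mcc": exh.mcc.value,
                "theorem_mcc": thm.mcc.value,
                "delta_star": thm.delta_star,
                "orientation": thm.orientation,
                "self_consistent": thm.self_consistent,
                "agree": bool(agree),
            }
        )
        curves.append(
            pd.DataFrame(
                {
                    "x": np.arange(1, k + 1),
                    "mu": pop.mu,
                    "eta": pop.eta,
                    "optimal_label": thm.labeling if not degenerate else np.zeros(k, dtype=int),
                    "delta_star": thm.delta_star if thm.delta_star is not None else np.nan,
                }
            )
        )
    frame = pd.DataFrame(rows)
    valid = frame[~frame["degenerate"]]
    return OptimalityReport(
        agreement_count=int(valid["agree"].sum()),
        n_valid=int(len(valid)),
        n_degenerate=int(frame["degenerate"].sum()),
        draws=frame,
        curves=curves,
    )


@lru_cache(maxsize=64)
def gaussian_population_optimum(pi: float, separation: float, n_grid: int = 4001) -> float:
    """Population-optimal MCC of the Gaussian-mixture generator.

    The optimal rule thresholds eta(x), which is monotone in the scalar
    discriminant s = m.x (m the class-1 mean shift).  Discretizing s onto a
    fine grid gives a discrete population (mu from the mixture density,
    eta from Bayes' rule) on which the oracle threshold sweep is exact up
    to the discretization.
    """
    if separation == 0.0:
        return 0.0
    d2 = separation * separation  # Var(s) = |m|^2; E[s|1] = |m|^2
    sd = separation
    lo = min(-8.0 * sd, d2 - 8.0 * sd)
    hi = max(8.0 * sd, d2 + 8.0 * sd)
    s = np.linspace(lo, hi, n_grid)
    f0 = norm.pdf(s, loc=0.0, scale=sd)
    f1_ = norm.pdf(s, loc=d2, scale=sd)
    dens = (1.0 - pi) * f0 + pi * f1_
    mu = dens / dens.sum()
    eta = expit(np.log(pi / (1.0 - pi)) + s - d2 / 2.0)  # Bayes posterior
    pop = DiscretePopulation(mu=mu, eta=eta)
    res = theorem_classifier(pop)
    return float(res.mcc.value)


def generate_tabular(config: SyntheticTabularConfig):
    """Draw a synthetic tabular dataset and its population-optimal MCC.

    Returns ``(features, labels, optimum)``: an (n, d) Gaussian feature
    matrix, 0/1 labels with class-1 weight pi, and the population MCC of
    the best possible classifier for this distribution.
    """
    rng = _rng(config.seed)
    n, d = config.n, config.d
    y = (rng.uniform(size=n) < config.pi).astype(np.int64)
    X = rng.standard_normal(size=(n, d))
    shift = config.separation / np.sqrt(d)
    X[y == 1] += shift
    optimum = gaussian_population_optimum(config.pi, config.separation)
    return X, y, optimum


def consistency_experiment(
    n_grid=(500, 5_000, 50_000),
    seeds=tuple(range(10)),
    generator: SyntheticTabularConfig = SyntheticTabularConfig(),
    n_test: int = 20_000,
    grid=None,
) -> pd.DataFrame:
    """Optimality gap of the fitted classifier as training size grows.

    For each training size n and seed, a fresh training sample of size n
    and an independent test sample of fixed size ``n_test`` are drawn from
    the generator; the threshold-search classifier is fitted and its test
    MCC subtracted from the population optimum.  Returns one row per n with
    columns ``n, mean_gap, sd_gap, n_seeds, optimum`` (per-seed gaps in
    ``attrs['gaps']``).
    """
    n_grid = tuple(n_grid)
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    optimum = gaussian_population_optimum(generator.pi, generator.separation)
    per_seed = []
    for seed in seeds:
        ss = np.random.SeedSequence([int(seed), generator.seed])
        for n, child in zip(n_grid, ss.spawn(len(n_grid))):
            data_ss, fit_ss = child.spawn(2)
            rng = np.random.default_rng(data_ss)
            cfg_train = SyntheticTabularConfig(
                n=n, d=generator.d, pi=generator.pi, separation=generator.separation, seed=rng
            )
            Xtr, ytr, _ = generate_tabular(cfg_train)
            cfg_test = SyntheticTabularConfig(
                n=n_test, d=generator.d, pi=generator.pi, separation=generator.separation, seed=rng
            )
            Xte, yte, _ = generate_tabular(cfg_test)
            clf, _ = fit_mcc_classifier(
                Xtr, ytr, grid=grid, seed=int(fit_ss.generate_state(1)[0] % (2**31 - 1))
            )
            test_mcc = mcc(confusion_from_labels(yte, clf.predict(Xte))).value
            per_seed.append({"n": n, "seed": seed, "gap": optimum - test_mcc})
    gaps = pd.DataFrame(per_seed)
    out = (
        gaps.groupby("n", sort=True)["gap"]
        .agg(mean_gap="mean", sd_gap=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    out["n_seeds"] = len(tuple(seeds))
    out["optimum"] = optimum
    out.attrs["gaps"] = gaps
    return out


def class_weight_ratio(labels) -> float:
    """Minority-to-majority count ratio, for configuring class-weighted SVMs.

    This is the standard rule of thumb for the slack-penalty ratio C+/C-
    in an imbalance-weighted SVM.  Requires both classes present.
    """
    y = np.asarray(labels)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("class_weight_ratio requires both classes present")
    return min(n0, n1) / max(n0, n1)
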