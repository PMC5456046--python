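"""Exact population-level computations on small discrete domains.

A :class:`DiscretePopulation` is a finite world: K points x = 1..K with
marginal probabilities mu(x) and conditional positive-class probabilities
eta(x) = P(Y=1|X=x).  On such a world every one of the 2^K deterministic
classifiers (bit vectors over the domain) has an exactly computable
population MCC, so the globally optimal classifier can be found by brute
force — and compared against the thresholded rule predicted by the
optimality theory.  That comparison is the correctness certificate for the
threshold characterization: on every non-degenerate draw the best
threshold-in-eta rule must attain the exhaustive maximum.

Random populations mirror the standard simulation design: mu from
normalized uniform draws, eta(x) = logistic(w*x) with a single standard
Gaussian weight w.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import MetricValue, PopulationRates, mcc_reduced
from .model import theorem_threshold

__all__ = [
    "DiscretePopulation",
    "population_rates",
    "population_mcc",
    "ExhaustiveResult",
    "exhaustive_optimal",
    "TheoremResult",
    "theorem_classifier",
    "random_population",
]

_MAX_ENUM_K = 24


@dataclass(frozen=True)
class DiscretePopulation:
    """Finite domain {1..K} with marginal mu and conditional eta.

    ``mu`` must be a probability vector (nonnegative, summing to 1 within
    1e-12); ``eta`` entries lie in [0, 1].  The prevalence is
    pi = sum_x mu(x) eta(x).
    """

    mu: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "eta", eta)
        if mu.ndim != 1 or eta.shape != mu.shape or mu.size < 1:
            raise ValueError("mu and eta must be 1-D vectors of equal positive length")
        if (mu < 0).any() or abs(mu.sum() - 1.0) > 1e-12:
            raise ValueError("mu must be nonnegative and sum to 1 within 1e-12")
        if (eta < 0).any() or (eta > 1).any():
            raise ValueError("eta entries must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.mu.size

    @property
    def pi(self) -> float:
        return float(self.mu @ self.eta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": np.arange(1, self.k + 1), "mu": self.mu, "eta": self.eta})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DiscretePopulation":
        return cls(mu=frame["mu"].to_numpy(float), eta=frame["eta"].to_numpy(float))


def population_rates(pop: DiscretePopulation, labeling) -> PopulationRates:
    """Exact (TP, gamma, pi) of a deterministic labeling on the population.

    TP = sum_x mu(x) eta(x) theta(x); gamma = sum_x mu(x) theta(x);
    pi = sum_x mu(x) eta(x).
    """
    theta = np.asarray(labeling)
    if theta.shape != pop.mu.shape:
        raise ValueError("labeling length must equal the domain size")
    theta = theta.astype(float)
    return PopulationRates(
        tp=float(pop.mu @ (pop.eta * theta)),
        gamma=float(pop.mu @ theta),
        pi=pop.pi,
    )


def population_mcc(pop: DiscretePopulation, labeling) -> MetricValue:
    """Population MCC of a labeling (undefined-flagged for degenerate gamma/pi)."""
    return mcc_reduced(population_rates(pop, labeling))


@dataclass
class ExhaustiveResult:
    """Outcome of the brute-force search over all 2^K labelings."""

    labeling: np.ndarray
    mcc: MetricValue
    n_enumerated: int
    degenerate: bool = False


def exhaustive_optimal(pop: DiscretePopulation) -> ExhaustiveResult:
    """Enumerate every labeling of the domain and return the MCC maximizer.

    All 2^K bit vectors are scored; labelings with a degenerate
    predicted-positive rate (all-zeros, all-ones) have undefined MCC and are
    excluded from the argmax.  Exact ties resolve to the lexicographically
    smallest bit vector.  Guarded to K <= 24; beyond that use
    :func:`theorem_classifier`, which scales.
    """
    k = pop.k
    if k > _MAX_ENUM_K:
        raise ValueError(
            f"K={k} labelings are too many to enumerate (limit {_MAX_ENUM_K}); "
            "use theorem_classifier for large domains"
        )
    n_total = 1 << k
    mu, eta = pop.mu, pop.eta
    pi = pop.pi
    if pi <= 0.0 or pi >= 1.0:
        return ExhaustiveResult(
            labeling=np.zeros(k, dtype=np.int64),
            mcc=MetricValue(0.0, defined=False),
            n_enumerated=n_total,
            degenerate=True,
        )
    best_val = -np.inf
    best_index: Optional[int] = None
    denom_pi = np.sqrt(pi * (1.0 - pi))
    # chunked enumeration; indices ascend so the first strict improvement is
    # the lexicographically smallest optimum (bit 0 of the index is the
    # leftmost element of the labeling? -- no: we map bit j of the index to
    # position j via most-significant-first, see _index_to_labeling).
    chunk = 1 << 16
    for start in range(0, n_total, chunk):
        idx = np.arange(start, min(start + chunk, n_total), dtype=np.int64)
        # bits[:, j] = value of labeling at domain position j (MSB first)
        shifts = np.arange(k - 1, -1, -1, dtype=np.int64)
        bits = (idx[:, None] >> shifts[None, :]) & 1
        tp = bits @ (mu * eta)
        gamma = bits @ mu
        valid = (gamma > 0.0) & (gamma < 1.0)
        vals = np.full(idx.size, -np.inf)
        g = gamma[valid]
        vals[valid] = (tp[valid] - g * pi) / (np.sqrt(g * (1.0 - g)) * denom_pi)
        j = int(np.argmax(vals))
        if vals[j] > best_val:
            best_val = float(vals[j])
            best_index = int(idx[j])
    if best_index is None:
        return ExhaustiveResult(
            labeling=np.zeros(k, dtype=np.int64),
            mcc=MetricValue(0.0, defined=False),
            n_enumerated=n_total,
            degenerate=True,
        )
    labeling = _index_to_labeling(best_index, k)
    return ExhaustiveResult(
        labeling=labeling,
        mcc=MetricValue(best_val, defined=True),
        n_enumerated=n_total,
    )


def _index_to_labeling(index: int, k: int) -> np.ndarray:
    shifts = np.arange(k - 1, -1, -1, dtype=np.int64)
    return ((index >> shifts) & 1).astype(np.int64)


@dataclass
class TheoremResult:
    """Best thresholded-in-eta classifier and its self-consistency check.

    ``delta`` is the sweep threshold that produced ``labeling``;
    ``delta_star`` is the threshold recomputed from the winner's own
    (TP, gamma, pi) by the closed-form optimality formula, and
    ``self_consistent`` records whether re-thresholding eta at delta_star
    (with the orientation implied by sign(TP - gamma*pi)) reproduces the
    same labeling.
    """

    labeling: np.ndarray
    delta: float
    orientation: int
    mcc: MetricValue
    delta_star: Optional[float] = None
    self_consistent: Optional[bool] = None
    degenerate: bool = False


def theorem_classifier(pop: DiscretePopulation) -> TheoremResult:
    """Best classifier of thresholded form, by sweeping thresholds on eta.

    Candidate thresholds are the midpoints between consecutive distinct eta
    values plus the two outer candidates below min(eta) and above max(eta);
    population MCC is piecewise constant in the threshold, so this sweep is
    exhaustive over the thresholded family.  Both orientations are scored.
    Degenerate populations (pi of 0 or 1, or constant eta making every
    defined labeling score 0) return a flagged result.
    """
    pi = pop.pi
    if pi <= 0.0 or pi >= 1.0:
        return TheoremResult(
            labeling=np.zeros(pop.k, dtype=np.int64),
            delta=0.5,
            orientation=+1,
            mcc=MetricValue(0.0, defined=False),
            degenerate=True,
        )
    eta = pop.eta
    distinct = np.unique(eta)
    if distinct.size == 1:
        return TheoremResult(
            labeling=np.zeros(pop.k, dtype=np.int64),
            delta=0.5,
            orientation=+1,
            mcc=MetricValue(0.0, defined=False),
            degenerate=True,
        )
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0] - max(distinct[0], 1e-6) / 2.0  # below every eta
    hi = (distinct[-1] + 1.0) / 2.0 if distinct[-1] < 1.0 else 1.0 + 1e-6
    candidates = np.concatenate([[lo], mids, [hi]])

    best: Optional[tuple[float, np.ndarray, float, int]] = None
    for delta in candidates:
        for orientation in (+1, -1):
            theta = (orientation * (eta - delta) > 0).astype(np.int64)
            val = population_mcc(pop, theta)
            if not val.defined:
                continue
            if best is None or val.value > best[0] + 0.0:
                best = (val.value, theta, float(delta), orientation)
    if best is None:
        return TheoremResult(
            labeling=np.zeros(pop.k, dtype=np.int64),
            delta=0.5,
            orientation=+1,
            mcc=MetricValue(0.0, defined=False),
            degenerate=True,
        )
    val, theta, delta, orientation = best
    rates = population_rates(pop, theta)
    delta_star = theorem_threshold(rates)
    sign = 1.0 if rates.tp - rates.gamma * rates.pi >= 0 else -1.0
    theta_star = (sign * (eta - delta_star) > 0).astype(np.int64)
    return TheoremResult(
        labeling=theta,
        delta=delta,
        orientation=orientation,
        mcc=MetricValue(val, defined=True),
        delta_star=float(delta_star),
        self_consistent=bool(np.array_equal(theta_star, theta)),
    )


def random_population(k: int, seed) -> DiscretePopulation:
    """Draw a random population: mu ~ normalized Uniform(0,1)^K, eta = logistic(w*x).

    ``w`` is a single standard-normal weight shared across the domain, so
    eta is monotone in x (increasing when w > 0).  ``seed`` may be an int or
    a ``numpy.random.Generator``.
    """
    if k < 2:
        raise ValueError("domain size must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.uniform(size=k)
    mu = raw / raw.sum()
    w = rng.standard_normal()
    x = np.arange(1, k + 1, dtype=float)
    eta = expit(w * x)
    return DiscretePopulation(mu=mu, eta=eta)
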