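"""Bayesian adaptive validation design.

The clinical validation follows a group-sequential Bayesian design
with (by default) three scheduled interim analyses — *looks* — at
one half, three quarters, and the full maximum sample size.  Each
class's agreement probability carries an independent Beta prior
(uniform by default); after x agreements in n specimens the posterior
is Beta(a + x, b + n - x).

At each look the study stops for **success** when, for *both*
classes, the posterior mean PPA is at least 80% and the lower bound
of the equal-tailed 95% credible interval is at least 65% (both
thresholds inclusive and configurable).  Otherwise it stops for
**futility** when the predictive probability of meeting those
criteria at the maximum sample size falls below 5%.  Success is
checked before futility; termination decisions are final.

Because the acceptance rule is monotone in each class's agreement
count at fixed n, the predictive probability has a closed form: a
product of beta-binomial tail probabilities over the per-class
minimal sufficient counts.  That exact path backs the design
evaluation and the operating-characteristic simulation; a
Monte-Carlo path over the posterior predictive is kept for
cross-checking and for configurations where enumeration is not
wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from math import ceil, sqrt
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .constants import ENDOMETRIAL, OVARIAN
from .errors import (
    DataExhaustedError,
    DegenerateLabelsError,
    ParameterError,
)

__all__ = [
    "DesignConfig",
    "TrialState",
    "posterior_ppa",
    "acceptance_decision",
    "predictive_probability_of_success",
    "run_trial",
    "OperatingCharacteristics",
    "operating_characteristics",
]

CONTINUE = "continue"
TERMINATE_SUCCESS = "terminate_success"
TERMINATE_FUTILITY = "terminate_futility"


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters of the adaptive validation study.

    ``n_max = 150`` is inferred from the executed study (Look 1 is
    half the maximum and analyzed 75 specimens); ``class_a_share`` is
    the endometrial fraction of enrollment (45 of 75 at Look 1).
    """

    n_max: int = 150
    look_fractions: tuple[float, ...] = (0.5, 0.75, 1.0)
    mean_ppa_threshold: float = 0.80
    lower_bound_threshold: float = 0.65
    credible_level: float = 0.95
    futility_threshold: float = 0.05
    prior_a: float = 1.0
    prior_b: float = 1.0
    class_a_share: float = 0.6

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise ParameterError("n_max must be >= 2")
        fr = self.look_fractions
        if not fr or any(f <= 0 or f > 1 for f in fr) or fr[-1] != 1.0:
            raise ParameterError(
                "look_fractions must lie in (0, 1] and end at 1")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ParameterError("look_fractions must be increasing")
        for name in ("mean_ppa_threshold", "lower_bound_threshold",
                     "credible_level", "futility_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0, 1)")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ParameterError("beta priors must be > 0")
        if not 0 < self.class_a_share < 1:
            raise ParameterError("class_a_share must be in (0, 1)")

    @property
    def look_sizes(self) -> tuple[int, ...]:
        return tuple(ceil(f * self.n_max) for f in self.look_fractions)

    @property
    def class_n_max(self) -> dict[str, int]:
        n_a = round(self.n_max * self.class_a_share)
        return {ENDOMETRIAL: n_a, OVARIAN: self.n_max - n_a}


@dataclass(frozen=True)
class TrialState:
    """Counts, posteriors, and decision at one look."""

    look_index: int  #: 1-based
    counts: dict  #: class -> (x, n)
    posteriors: dict  #: class -> (alpha, beta)
    decision: str = CONTINUE

    def __post_init__(self) -> None:
        for cls, (x, n) in self.counts.items():
            if not 0 <= x <= n:
                raise ParameterError(f"require 0 <= x <= n for {cls}")


def posterior_ppa(
    x: int, n: int, prior_a: float = 1.0, prior_b: float = 1.0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and equal-tailed credible interval for one class."""
    if prior_a <= 0 or prior_b <= 0:
        raise ParameterError("beta priors must be > 0")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    if not 0 <= x <= n:
        raise ParameterError("require 0 <= x <= n")
    a, b = prior_a + x, prior_b + n - x
    mean = a / (a + b)
    alpha = 1.0 - level
    lo = float(stats.beta.ppf(alpha / 2, a, b))
    hi = float(stats.beta.ppf(1 - alpha / 2, a, b))
    return mean, (lo, hi)


def _class_meets(x: int, n: int, config: DesignConfig) -> bool:
    mean, (lo, _) = posterior_ppa(
        x, n, config.prior_a, config.prior_b, config.credible_level)
    return (mean >= config.mean_ppa_threshold
            and lo >= config.lower_bound_threshold)


@lru_cache(maxsize=None)
def _min_successes(n: int, prior_a: float, prior_b: float,
                   mean_thr: float, lower_thr: float,
                   level: float) -> int:
    """Smallest x meeting the per-class criteria at sample size n.

    Both the posterior mean and the lower credible bound are
    non-decreasing in x at fixed n, so a single threshold exists;
    returns n + 1 when no x suffices.
    """
    config = DesignConfig(mean_ppa_threshold=mean_thr,
                          lower_bound_threshold=lower_thr,
                          credible_level=level,
                          prior_a=prior_a, prior_b=prior_b)
    lo, hi = 0, n + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if _class_meets(mid, n, config):
            hi = mid
        else:
            lo = mid + 1
    return lo


def _threshold(n: int, config: DesignConfig) -> int:
    return _min_successes(
        n, config.prior_a, config.prior_b, config.mean_ppa_threshold,
        config.lower_bound_threshold, config.credible_level)


def acceptance_decision(state: TrialState, config: DesignConfig) -> bool:
    """True when *both* classes meet the mean and lower-bound criteria."""
    for cls in (ENDOMETRIAL, OVARIAN):
        if cls not in state.counts:
            raise DegenerateLabelsError(f"missing class: {cls}")
        if state.counts[cls][1] < 1:
            raise DegenerateLabelsError(f"no specimens for class: {cls}")
    return all(x >= _threshold(n, config)
               for x, n in state.counts.values())


def _make_state(look_index: int, counts: dict, config: DesignConfig,
                decision: str = CONTINUE) -> TrialState:
    posts = {
        cls: (config.prior_a + x, config.prior_b + n - x)
        for cls, (x, n) in counts.items()
    }
    return TrialState(look_index, counts, posts, decision)


def predictive_probability_of_success(
    state: TrialState,
    config: DesignConfig,
    n_sims: int = 10000,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """Probability of meeting the acceptance criteria at n_max.

    Future agreements per class follow the beta-binomial posterior
    predictive.  ``method='exact'`` evaluates the product of tail
    probabilities in closed form; ``'mc'`` simulates ``n_sims``
    completions with a fixed seed; ``'auto'`` (default) enumerates
    exactly when at most 12 specimens remain per class and falls back
    to Monte-Carlo otherwise.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    if method not in {"auto", "exact", "mc"}:
        raise ParameterError(f"unknown method: {method}")

    remaining, needed, post = {}, {}, {}
    for cls, n_final in config.class_n_max.items():
        x, n = state.counts[cls]
        if n > n_final:
            raise ParameterError(
                f"{cls}: observed n = {n} exceeds final allocation "
                f"{n_final}")
        remaining[cls] = n_final - n
        needed[cls] = _threshold(n_final, config) - x
        post[cls] = (config.prior_a + x, config.prior_b + n - x)

    if method == "auto":
        method = "exact" if all(m <= 12 for m in remaining.values()) else "mc"

    if method == "exact":
        prob = 1.0
        for cls in config.class_n_max:
            m, need = remaining[cls], needed[cls]
            if need <= 0:
                continue
            if need > m:
                return 0.0
            a, b = post[cls]
            prob *= float(stats.betabinom.sf(need - 1, m, a, b))
        return prob

    rng = np.random.default_rng(seed)
    ok = np.ones(n_sims, dtype=bool)
    for cls in config.class_n_max:
        m, need = remaining[cls], needed[cls]
        if need <= 0:
            continue
        if need > m:
            return 0.0
        a, b = post[cls]
        p = rng.beta(a, b, size=n_sims)
        future = rng.binomial(m, p)
        ok &= future >= need
    return float(ok.mean())


def _counts_at(stream: Sequence[tuple[str, bool]], m: int) -> dict:
    counts = {ENDOMETRIAL: [0, 0], OVARIAN: [0, 0]}
    for cls, agree in stream[:m]:
        if cls not in counts:
            raise ParameterError(f"unknown class label: {cls!r}")
        counts[cls][1] += 1
        counts[cls][0] += int(bool(agree))
    return {cls: (x, n) for cls, (x, n) in counts.items()}


def run_trial(
    stream: Sequence[tuple[str, bool]],
    config: DesignConfig,
    n_sims: int = 10000,
    seed: int = 0,
    futility_method: str = "exact",
) -> list[TrialState]:
    """Execute the look schedule over a stream of (class, agree) outcomes.

    Looks are evaluated in order on the first ``look_size`` outcomes;
    the trial stops at the first terminal decision.  At every look the
    success criteria are checked first; at interim looks a predictive
    probability below the futility threshold terminates for futility,
    and a final look that does not meet the criteria is itself a
    futility termination.
    """
    stream = list(stream)
    sizes = config.look_sizes
    if len(stream) < sizes[0]:
        raise DataExhaustedError(
            f"stream has {len(stream)} outcomes; first look needs "
            f"{sizes[0]}")

    states: list[TrialState] = []
    for i, m in enumerate(sizes, start=1):
        if len(stream) < m:
            raise DataExhaustedError(
                f"stream has {len(stream)} outcomes; look {i} needs {m}")
        counts = _counts_at(stream, m)
        state = _make_state(i, counts, config)
        if acceptance_decision(state, config):
            state = replace(state, decision=TERMINATE_SUCCESS)
        elif i == len(sizes):
            state = replace(state, decision=TERMINATE_FUTILITY)
        else:
            pps = predictive_probability_of_success(
                state, config, n_sims=n_sims, seed=seed,
                method=futility_method)
            if pps < config.futility_threshold:
                state = replace(state, decision=TERMINATE_FUTILITY)
        states.append(state)
        if state.decision != CONTINUE:
            break
    return states


class OperatingCharacteristics(NamedTuple):
    success_probability: float
    mc_standard_error: float
    n_trials: int


def _interleaved_labels(config: DesignConfig) -> list[str]:
    """Deterministic enrollment order matching the class allocation."""
    share = config.class_a_share
    labels = []
    for i in range(config.n_max):
        if int((i + 1) * share) > int(i * share):
            labels.append(ENDOMETRIAL)
        else:
            labels.append(OVARIAN)
    return labels


def operating_characteristics(
    true_ppa_a: float,
    true_ppa_b: float,
    config: DesignConfig,
    n_trials: int = 2000,
    seed: int = 0,
) -> OperatingCharacteristics:
    """Simulated probability that the design terminates in success.

    Agreement indicators are thresholded uniforms (agree iff
    u < true PPA), with the uniforms drawn once from the seed; under
    a common seed the success probability is therefore exactly
    monotone in the true PPAs, trial by trial.
    """
    for v in (true_ppa_a, true_ppa_b):
        if not 0 <= v <= 1:
            raise ParameterError("true PPAs must be in [0, 1]")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")

    labels = _interleaved_labels(config)
    ppa_of = {ENDOMETRIAL: true_ppa_a, OVARIAN: true_ppa_b}
    thresholds = np.array([ppa_of[c] for c in labels])
    rng = np.random.default_rng(seed)
    u = rng.random((n_trials, config.n_max))

    successes = 0
    for t in range(n_trials):
        agrees = u[t] < thresholds
        stream = list(zip(labels, agrees))
        states = run_trial(stream, config, futility_method="exact")
        if states[-1].decision == TERMINATE_SUCCESS:
            successes += 1
    p = successes / n_trials
    se = sqrt(p * (1 - p) / n_trials)
    return OperatingCharacteristics(p, se, n_trials)
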