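"""Precision and reproducibility statistics for replicate test results.

Intra-site precision compares calls from adjacent sections of the same
block processed in one run; inter-site reproducibility compares calls
for adjacent sections processed at different laboratories.  Both
reduce to pairwise concordance of call vectors (with exact binomial
intervals), chance-corrected agreement (Cohen's kappa), and the
coefficient of variation of the similarity score for the known
diagnosis across replicates.

Call-handling conventions: a missing call in either vector drops the
pair from the denominator; an indeterminate call is discordant with
any definite call, and a pair that is indeterminate on both sides is
excluded.
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import CLASSES, INDETERMINATE
from .errors import ParameterError, UndefinedStatisticError
from .valstats import clopper_pearson, round_half_away

__all__ = [
    "ConcordanceResult",
    "pairwise_concordance",
    "pooled_concordance",
    "KappaResult",
    "cohen_kappa",
    "cv_percent",
    "reproducibility_table",
]


class ConcordanceResult(NamedTuple):
    x: int
    n: int
    percent: float
    ci: tuple[float, float]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def pairwise_concordance(calls_a: Sequence, calls_b: Sequence
                         ) -> ConcordanceResult:
    """Fraction of aligned call pairs that agree, with exact CI."""
    if len(calls_a) != len(calls_b):
        raise ParameterError("call vectors must be aligned (equal length)")
    x = n = 0
    for a, b in zip(calls_a, calls_b):
        if _is_missing(a) or _is_missing(b):
            continue
        if a == INDETERMINATE and b == INDETERMINATE:
            continue
        n += 1
        x += int(a == b)
    if n == 0:
        raise UndefinedStatisticError("no evaluable pairs")
    return ConcordanceResult(x, n, round_half_away(100.0 * x / n, 1),
                             clopper_pearson(x, n))


def pooled_concordance(pairs: Sequence[tuple[int, int]]) -> ConcordanceResult:
    """Pool (x, n) counts from several pairwise comparisons."""
    if not pairs:
        raise ParameterError("need at least one (x, n) pair")
    x = sum(int(p[0]) for p in pairs)
    n = sum(int(p[1]) for p in pairs)
    if n == 0:
        raise UndefinedStatisticError("no evaluable pairs")
    return ConcordanceResult(x, n, round_half_away(100.0 * x / n, 1),
                             clopper_pearson(x, n))


class KappaResult(NamedTuple):
    kappa: float
    ci: tuple[float, float]
    undefined: bool  #: expected agreement is 1; kappa has no value


def cohen_kappa(calls_a: Sequence, calls_b: Sequence) -> KappaResult:
    """Cohen's kappa for two call vectors over the two-class vocabulary.

    The 95% CI uses the standard asymptotic variance
    p_o(1 - p_o) / (n (1 - p_e)^2), clipped to [-1, 1].  When both
    raters are constant and identical, expected agreement is 1 and
    kappa is undefined (flagged, value NaN).
    """
    a = list(calls_a)
    b = list(calls_b)
    if len(a) != len(b):
        raise ParameterError("call vectors must be aligned (equal length)")
    if len(a) < 2:
        raise ParameterError("need n >= 2")
    if not (set(a) | set(b)) <= set(CLASSES):
        raise ParameterError(f"calls outside two-class vocabulary: "
                             f"{sorted((set(a) | set(b)) - set(CLASSES))}")
    n = len(a)
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    po = float(np.mean(a_arr == b_arr))
    pe = sum(
        float(np.mean(a_arr == c)) * float(np.mean(b_arr == c))
        for c in CLASSES
    )
    if pe >= 1.0:
        return KappaResult(float("nan"), (float("nan"), float("nan")), True)
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    lo = max(-1.0, kappa - 1.959963984540054 * se)
    hi = min(1.0, kappa + 1.959963984540054 * se)
    return KappaResult(float(kappa), (float(lo), float(hi)), False)


def cv_percent(replicate_scores: Sequence[float]) -> float:
    """CV% of the known-diagnosis similarity score across replicates.

    Sample (n-1) standard deviation over the mean, times 100.
    """
    scores = np.asarray(replicate_scores, dtype=float)
    if scores.size < 2:
        raise ParameterError("need >= 2 replicates")
    mean = scores.mean()
    if mean <= 0:
        raise UndefinedStatisticError("mean score must be > 0 for CV%")
    return float(100.0 * scores.std(ddof=1) / mean)


def reproducibility_table(
    results: pd.DataFrame,
    compare_on: str = "lab_id",
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise concordance report across sections or laboratories.

    ``results`` needs columns ``specimen_id``, ``call``,
    ``score_known`` (similarity score for the known diagnosis) and the
    ``compare_on`` key (``lab_id`` for inter-site, ``section_index``
    for intra-site).  Returns the pairwise + overall concordance table
    and per-specimen CV% of the known-diagnosis score.
    """
    for col in ("specimen_id", "call", "score_known", compare_on):
        if col not in results.columns:
            raise ParameterError(f"results missing column: {col}")

    wide_calls = results.pivot(index="specimen_id", columns=compare_on,
                               values="call")
    rows, counts = [], []
    for u, v in combinations(sorted(wide_calls.columns), 2):
        res = pairwise_concordance(wide_calls[u].tolist(),
                                   wide_calls[v].tolist())
        rows.append({
            "comparison": f"{u} versus {v}",
            "x": res.x, "n": res.n,
            "concordance_percent": res.percent,
            "ci_low_percent": res.ci[0], "ci_high_percent": res.ci[1],
            "discordance_percent": round_half_away(100.0 - res.percent, 1),
        })
        counts.append((res.x, res.n))
    overall = pooled_concordance(counts)
    rows.append({
        "comparison": "Overall",
        "x": overall.x, "n": overall.n,
        "concordance_percent": overall.percent,
        "ci_low_percent": overall.ci[0], "ci_high_percent": overall.ci[1],
        "discordance_percent": round_half_away(100.0 - overall.percent, 1),
    })

    cv = results.groupby("specimen_id")["score_known"].apply(
        lambda s: cv_percent(s.to_numpy()))
    cv.name = "cv_percent"
    return pd.DataFrame(rows), cv
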