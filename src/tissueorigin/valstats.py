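"""Accuracy statistics for test-versus-diagnosis agreement.

Everything a two-class diagnostic validation reports: positive percent
agreement (PPA) with exact Clopper-Pearson intervals, the diagnostic
odds ratio, rank-based ROC AUC, Fisher exact subgroup comparisons,
similarity-score bin / rule-out analysis, and attribute-stratified
performance tables.

Display rounding is half-away-from-zero to one decimal throughout, and
a row's percent non-agreement is reported as the rounded complement
(100 - PPA) so the pair always sums to 100.0 exactly.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateLabelsError,
    ParameterError,
    SchemaError,
    UndefinedStatisticError,
)

__all__ = [
    "round_half_away",
    "ppa",
    "clopper_pearson",
    "DiagnosticOddsRatio",
    "diagnostic_odds_ratio",
    "roc_auc",
    "fisher_exact",
    "score_bin_analysis",
    "subgroup_table",
    "performance_row",
]


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (printed-table convention)."""
    factor = 10.0 ** decimals
    scaled = value * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


def ppa(x: int, n: int) -> float:
    """Positive percent agreement, 100*x/n to one decimal."""
    if n < 1:
        raise UndefinedStatisticError("PPA undefined for n = 0")
    if not 0 <= x <= n:
        raise ParameterError("require 0 <= x <= n")
    return round_half_away(100.0 * x / n, 1)


def clopper_pearson(
    x: int, n: int, level: float = 0.95, decimals: int | None = 1
) -> tuple[float, float]:
    """Exact two-sided binomial interval, in percent.

    Beta-quantile form: lower = B(alpha/2; x, n-x+1), upper =
    B(1-alpha/2; x+1, n-x), with the conventional 0 and 100 endpoints
    at x = 0 and x = n.  ``decimals=None`` skips display rounding.
    """
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    if n < 1 or not 0 <= x <= n:
        raise ParameterError("require n >= 1 and 0 <= x <= n")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    lo, hi = 100.0 * lower, 100.0 * upper
    if decimals is not None:
        lo, hi = round_half_away(lo, decimals), round_half_away(hi, decimals)
    return lo, hi


class DiagnosticOddsRatio(NamedTuple):
    value: float
    corrected: bool  #: Haldane-Anscombe +0.5 applied to a zero cell


def diagnostic_odds_ratio(tp: int, fn: int, fp: int, tn: int
                          ) -> DiagnosticOddsRatio:
    """(tp*tn)/(fn*fp) from the 2x2 agreement table.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to
    every cell), flagged in the result.
    """
    cells = [tp, fn, fp, tn]
    if any(c < 0 for c in cells):
        raise ParameterError("counts must be >= 0")
    if sum(cells) == 0:
        raise UndefinedStatisticError("DOR undefined for an empty table")
    corrected = any(c == 0 for c in cells)
    if corrected:
        tp, fn, fp, tn = (c + 0.5 for c in cells)
    return DiagnosticOddsRatio((tp * tn) / (fn * fp), corrected)


def roc_auc(scores: Sequence[float], labels: Sequence, positive) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    ``scores`` are scores for the ``positive`` class; ties contribute
    one half, matching the trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness by summing hypergeometric probabilities no larger
    than the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ParameterError("counts must be >= 0")
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def performance_row(group_label: str, x: int, n: int,
                    level: float = 0.95) -> dict:
    """One row of a performance table: PPA, exact CI, complement."""
    est = ppa(x, n)
    lo, hi = clopper_pearson(x, n, level)
    return {
        "group_label": group_label,
        "x": int(x),
        "n": int(n),
        "ppa_percent": est,
        "ci_low_percent": lo,
        "ci_high_percent": hi,
        "non_agreement_percent": round_half_away(100.0 - est, 1),
    }


def score_bin_analysis(
    top_scores: Sequence[float],
    agreements: Sequence[bool],
    threshold: float = 80.0,
) -> tuple[pd.DataFrame, dict]:
    """Distribution of the higher similarity score in bins of 10.

    Bins are half-open [0,10), ..., [80,90) with a closed top bin
    [90,100].  The threshold summary uses the strict rule "higher
    score > threshold": within that stratum it reports the share of
    specimens, the agreement probability, and its exact interval —
    the rule-in / rule-out analysis (a higher score > 80 for one
    tissue is a score <= 20 for the other).
    """
    scores = np.asarray(top_scores, dtype=float)
    agree = np.asarray(agreements, dtype=bool)
    if scores.size == 0 or scores.size != agree.size:
        raise ParameterError("need equal-length, non-empty inputs")

    idx = np.minimum((scores // 10).astype(int), 9)
    rows = []
    for b in range(10):
        lo, hi = 10 * b, 10 * (b + 1)
        label = f"[{lo},{hi})" if b < 9 else f"[{lo},{hi}]"
        in_bin = idx == b
        rows.append({
            "bin": label,
            "n": int(in_bin.sum()),
            "agreements": int((in_bin & agree).sum()),
        })
    bins = pd.DataFrame(rows)

    above = scores > threshold
    n_above, x_above = int(above.sum()), int((above & agree).sum())
    summary = {
        "threshold": threshold,
        "n_total": int(scores.size),
        "n_above": n_above,
        "share_above_percent": round_half_away(
            100.0 * n_above / scores.size, 1),
        "agreements_above": x_above,
    }
    if n_above:
        summary["agreement_above_percent"] = ppa(x_above, n_above)
        lo, hi = clopper_pearson(x_above, n_above)
        summary["agreement_above_ci"] = (lo, hi)
        # score <= 100 - threshold for the other tissue rules it out
        # with at least this probability
        summary["rule_out_lower_percent"] = lo
    return bins, summary


def subgroup_table(
    agree: pd.Series,
    metadata: pd.DataFrame,
    attribute: str,
    bins: Sequence[float] | None = None,
    bin_labels: Sequence[str] | None = None,
    diagnosis: pd.Series | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-level agreement table for one specimen/patient attribute.

    ``agree`` is a boolean Series aligned with ``metadata``.  With
    ``bins`` the attribute is cut into intervals first.  With
    ``diagnosis`` a per-level two-sided Fisher p compares the two
    classes' agreement counts.  Empty levels are omitted.
    """
    if attribute not in metadata.columns:
        raise SchemaError(f"attribute not in metadata: {attribute}")
    values = metadata[attribute]
    if bins is not None:
        values = pd.cut(values, bins=bins, labels=bin_labels)

    rows = []
    for label, members in values.groupby(values, observed=True).groups.items():
        sub = agree.loc[members]
        if len(sub) == 0:
            continue
        row = performance_row(str(label), int(sub.sum()), len(sub), level)
        if diagnosis is not None:
            diag = diagnosis.loc[members]
            classes = sorted(diag.unique())
            if len(classes) == 2:
                g0, g1 = (sub[diag == c] for c in classes)
                row["fisher_p"] = round(fisher_exact(
                    int(g0.sum()), int(len(g0) - g0.sum()),
                    int(g1.sum()), int(len(g1) - g1.sum())), 4)
            else:
                row["fisher_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
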