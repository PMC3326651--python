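"""Standardization against stable probesets.

The test runs two locked algorithms in sequence; the first is a
standardization step that anchors every profile to a fixed reference
using a small panel of *stable probesets* — probesets whose expression
barely varies across specimens and processing conditions (the
housekeeping notion).  Because laboratory/batch artifacts on raw
intensities are well modeled as global multiplicative factors, the
correction is a single rescaling of the whole profile:

    standardized = raw * 2 ** (reference_summary - stable_summary(raw))

where ``stable_summary`` is the log2 of the median raw intensity of
the stable panel.  Applied on the raw scale, before any pseudocount,
the correction is exactly scale-invariant (``c * x`` standardizes to
the same profile as ``x`` for any ``c > 0``) and idempotent, and the
standardized stable summary equals the reference exactly.

The log2 view handed to the classifier is ``log2(standardized + 1)``;
the pseudocount only matters near zero intensity and never disturbs
the invariances above because it is applied after rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import N_STABLE_PROBESETS
from .errors import ParameterError, SchemaError

__all__ = [
    "StandardizationReference",
    "select_stable_probesets",
    "fit_reference",
    "stable_summary",
    "standardize_raw",
    "standardize_profile",
    "standardize_matrix",
    "log2p",
]


def log2p(x):
    """log2(x + 1), the display/classification scale."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


@dataclass
class StandardizationReference:
    """Frozen normalization target fitted on training data."""

    stable_probeset_ids: list[str]
    reference_summary: float  #: log2 of the target median stable intensity
    per_probeset_reference: dict[str, float] | None = None

    def __post_init__(self) -> None:
        ids = self.stable_probeset_ids
        if len(ids) != len(set(ids)):
            raise ParameterError("stable probeset ids must be unique")
        if not np.isfinite(self.reference_summary):
            raise ParameterError("reference_summary must be finite")

    def to_json(self) -> str:
        return json.dumps({
            "stable_probeset_ids": list(self.stable_probeset_ids),
            "reference_summary": self.reference_summary,
            "per_probeset_reference": self.per_probeset_reference,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StandardizationReference":
        d = json.loads(text)
        return cls(d["stable_probeset_ids"], d["reference_summary"],
                   d.get("per_probeset_reference"))


def select_stable_probesets(
    train: pd.DataFrame, k: int = N_STABLE_PROBESETS
) -> list[str]:
    """Pick the ``k`` most stable probesets of a training matrix.

    Stability is the coefficient of variation of log2(x+1) across
    specimens (lower is more stable); ties break on probeset id so the
    selection is fully deterministic.
    """
    if k < 1 or k > train.shape[0]:
        raise ParameterError(
            f"k must be in [1, {train.shape[0]}], got {k}"
        )
    if train.shape[1] < 2:
        raise ParameterError("need at least 2 specimens to assess stability")

    log2v = log2p(train.to_numpy())
    mean = log2v.mean(axis=1)
    sd = log2v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(sd == 0, 0.0, np.where(mean > 0, sd / mean, np.inf))
    order = pd.DataFrame({"cv": cv}, index=train.index.astype(str))
    # stable sort on cv after an index sort -> ties broken by probeset id
    order = order.sort_index(kind="mergesort").sort_values(
        "cv", kind="mergesort")
    return list(order.index[:k])


def fit_reference(
    train: pd.DataFrame, stable_ids: Sequence[str]
) -> StandardizationReference:
    """Fix the normalization target from training specimens.

    The reference summary is the median, across training specimens, of
    each specimen's stable-probeset summary (log2 of the median raw
    stable intensity).
    """
    stable_ids = list(stable_ids)
    if not stable_ids:
        raise ParameterError("stable set must be non-empty")
    missing = set(stable_ids) - set(train.index)
    if missing:
        raise SchemaError(f"stable probesets absent from matrix: "
                          f"{sorted(missing)[:5]}")
    sub = train.loc[stable_ids]
    per_specimen = np.log2(sub.median(axis=0).to_numpy())
    per_probeset = np.log2(sub.median(axis=1))
    return StandardizationReference(
        stable_probeset_ids=stable_ids,
        reference_summary=float(np.median(per_specimen)),
        per_probeset_reference=per_probeset.to_dict(),
    )


def stable_summary(raw_profile: pd.Series,
                   ref: StandardizationReference) -> float:
    """log2 of the median raw intensity over the reference's stable panel."""
    missing = set(ref.stable_probeset_ids) - set(raw_profile.index)
    if missing:
        raise SchemaError(f"profile missing stable probesets: "
                          f"{sorted(missing)[:5]}")
    med = float(raw_profile.loc[ref.stable_probeset_ids].median())
    if med <= 0:
        raise ParameterError("stable-probeset median must be positive")
    return float(np.log2(med))


def standardize_raw(raw_profile: pd.Series,
                    ref: StandardizationReference) -> pd.Series:
    """Rescale a raw profile so its stable summary hits the reference."""
    if (raw_profile < 0).any():
        raise ParameterError("intensities must be >= 0")
    shift = ref.reference_summary - stable_summary(raw_profile, ref)
    return raw_profile * float(2.0 ** shift)


def standardize_profile(raw_profile: pd.Series,
                        ref: StandardizationReference) -> pd.Series:
    """Standardize one profile; returns the log2(x+1) view."""
    scaled = standardize_raw(raw_profile, ref)
    return pd.Series(log2p(scaled.to_numpy()), index=scaled.index,
                     name=raw_profile.name)


def standardize_matrix(raw: pd.DataFrame,
                       ref: StandardizationReference) -> pd.DataFrame:
    """Column-wise standardization of a probesets x specimens matrix."""
    missing = set(ref.stable_probeset_ids) - set(raw.index)
    if missing:
        raise SchemaError(f"matrix missing stable probesets: "
                          f"{sorted(missing)[:5]}")
    meds = raw.loc[ref.stable_probeset_ids].median(axis=0).to_numpy()
    if np.any(meds <= 0):
        raise ParameterError("stable-probeset medians must be positive")
    factors = 2.0 ** (ref.reference_summary - np.log2(meds))
    return pd.DataFrame(log2p(raw.to_numpy() * factors[None, :]),
                        index=raw.index, columns=raw.columns)
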