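"""Specimen- and array-level quality gates.

Laboratory gates are applied in processing order — RNA extraction,
cDNA labeling, array data quality — and a specimen that fails an
earlier stage is never evaluated at a later one, matching how a
failed extraction never reaches the hybridization step.  All
thresholds are inclusive.

The three array data-quality metrics (overall signal, percent
present, regional discontinuity) are operationalized here as:

* ``overall_signal`` — mean of log2(intensity + 1) over the array;
* ``percent_present`` — percentage of probesets whose log2 intensity
  exceeds a detection threshold (background + 1 log2 unit);
* ``regional_discontinuity`` — largest relative deviation of any
  spatial block's mean log2 intensity from the array-wide mean, on a
  coarse partition of the physical probe grid (default 4 x 4 blocks).

The pass thresholds (>= 10, >= 5, <= 0.84) are applied verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    A260_A280_MIN,
    CDNA_YIELD_MIN_UG,
    OVERALL_SIGNAL_MIN,
    PERCENT_PRESENT_MIN,
    REGIONAL_DISCONTINUITY_MAX,
    RNA_CONC_MIN_NG_PER_UL,
    RNA_YIELD_MIN_NG,
)
from .errors import ParameterError, SchemaError

__all__ = ["ArrayQCMetrics", "array_qc", "apply_specimen_gates",
           "apply_entry_criteria", "STAGE_RNA", "STAGE_CDNA", "STAGE_ARRAY"]

STAGE_RNA = "rna"
STAGE_CDNA = "cdna"
STAGE_ARRAY = "array"

_RNA_FIELDS = ["rna_yield_ng", "rna_conc_ng_per_ul", "a260_a280"]
_CDNA_FIELDS = ["cdna_yield_ug"]
_ARRAY_FIELDS = ["overall_signal", "percent_present", "regional_discontinuity"]


@dataclass(frozen=True)
class ArrayQCMetrics:
    overall_signal: float
    percent_present: float
    regional_discontinuity: float
    passed: bool


def array_qc(
    profile,
    grid_shape: tuple[int, int],
    *,
    background_log2: float = 0.0,
    detection_offset: float = 1.0,
    block_grid: tuple[int, int] = (4, 4),
) -> ArrayQCMetrics:
    """Compute array data-quality metrics for one hybridization.

    ``profile`` is the vector of raw probeset intensities in physical
    scan order; ``grid_shape`` is the (rows, cols) layout of the chip.
    Overall signal and percent present are order-invariant; regional
    discontinuity depends on the grid layout by design.
    """
    values = np.asarray(profile, dtype=float)
    rows, cols = grid_shape
    if values.size != rows * cols:
        raise SchemaError(
            f"profile length {values.size} does not match grid "
            f"{rows}x{cols}"
        )
    if np.any(values < 0):
        raise ParameterError("intensities must be >= 0")

    log2v = np.log2(values + 1.0)
    overall = float(log2v.mean())
    threshold = background_log2 + detection_offset
    percent_present = float(100.0 * np.mean(log2v >= threshold))

    grid = log2v.reshape(rows, cols)
    block_means = [
        blk.mean()
        for row_band in np.array_split(grid, block_grid[0], axis=0)
        for blk in np.array_split(row_band, block_grid[1], axis=1)
        if blk.size
    ]
    if overall > 0:
        discontinuity = float(
            max(abs(bm - overall) for bm in block_means) / overall
        )
    else:
        discontinuity = 0.0

    passed = (
        overall >= OVERALL_SIGNAL_MIN
        and percent_present >= PERCENT_PRESENT_MIN
        and discontinuity <= REGIONAL_DISCONTINUITY_MAX
    )
    return ArrayQCMetrics(overall, percent_present, discontinuity, passed)


def _require(records: pd.DataFrame, fields) -> None:
    for name in fields:
        if name not in records.columns:
            raise SchemaError(f"missing required field: {name}")


def apply_specimen_gates(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate each specimen with the processing stage it failed, if any.

    Returns a copy of ``records`` with a ``qc_stage_failed`` column
    (``None`` for specimens passing all stages) and the count of
    survivors after each stage.
    """
    _require(records, _RNA_FIELDS + _CDNA_FIELDS + _ARRAY_FIELDS)
    out = records.copy()

    rna_ok = (
        (out["rna_yield_ng"] >= RNA_YIELD_MIN_NG)
        & (out["rna_conc_ng_per_ul"] >= RNA_CONC_MIN_NG_PER_UL)
        & (out["a260_a280"] >= A260_A280_MIN)
    )
    cdna_ok = out["cdna_yield_ug"] >= CDNA_YIELD_MIN_UG
    array_ok = (
        (out["overall_signal"] >= OVERALL_SIGNAL_MIN)
        & (out["percent_present"] >= PERCENT_PRESENT_MIN)
        & (out["regional_discontinuity"] <= REGIONAL_DISCONTINUITY_MAX)
    )

    stage = pd.Series([None] * len(out), index=out.index, dtype=object)
    stage[~rna_ok] = STAGE_RNA
    stage[rna_ok & ~cdna_ok] = STAGE_CDNA
    stage[rna_ok & cdna_ok & ~array_ok] = STAGE_ARRAY
    out["qc_stage_failed"] = stage

    n = len(out)
    counts = {
        "input": n,
        "after_rna": int(rna_ok.sum()),
        "after_cdna": int((rna_ok & cdna_ok).sum()),
        "after_array": int((rna_ok & cdna_ok & array_ok).sum()),
    }
    return out, counts


def apply_entry_criteria(gated: pd.DataFrame) -> pd.DataFrame:
    """Keep specimens that passed every laboratory gate and meet entry criteria.

    Entry criteria (a known two-class clinical diagnosis, vendor QC in
    order) are recorded as the boolean ``entry_criteria_ok`` flag and
    applied after the laboratory gates, matching the study's order of
    exclusions.
    """
    _require(gated, ["qc_stage_failed", "entry_criteria_ok"])
    keep = gated["qc_stage_failed"].isna() & gated["entry_criteria_ok"]
    return gated.loc[keep].copy()
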