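"""Shared vocabulary and locked defaults for the tissue-of-origin test."""

# Two-class vocabulary. Endometrial is the "positive" class throughout:
# the reported similarity score pair is (endometrial, ovarian).
ENDOMETRIAL = "endometrial"
OVARIAN = "ovarian"
INDETERMINATE = "indeterminate"
CLASSES = (ENDOMETRIAL, OVARIAN)

# Locked panel sizes of the production assay; both are configurable
# everywhere they appear.
N_CLASSIFIER_PROBESETS = 375
N_STABLE_PROBESETS = 61

# Specimen-level laboratory gates (all inclusive).
RNA_YIELD_MIN_NG = 30.0
RNA_CONC_MIN_NG_PER_UL = 9.5
A260_A280_MIN = 1.0
CDNA_YIELD_MIN_UG = 2.5

# Array data-quality gates (all inclusive).
OVERALL_SIGNAL_MIN = 10.0
PERCENT_PRESENT_MIN = 5.0
REGIONAL_DISCONTINUITY_MAX = 0.84

# Entry criterion: minimum viable tumor content of the biopsy.
PCT_TUMOR_MIN = 60.0
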