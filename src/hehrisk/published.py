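"""Published summary counts for the UKALL high-hyperdiploidy cohorts.

These are the printed cohort-level counts from the UKALL97/99 (discovery)
and UKALL2003 (validation) trial reports of the high-hyperdiploid risk
profile.  Patient-level data are not public; these counts are the inputs
to the count-arithmetic operations in :mod:`hehrisk.report` (group
proportions, relapse-capture fractions).
"""

#: UKALL97/99 discovery cohort.
DISCOVERY = {
    "total": 456,
    "good_risk": 373,
    "poor_risk": 83,
    "relapses": 67,
}

#: UKALL2003 validation cohort.
VALIDATION = {
    "total": 725,
    "good_risk": 579,
    "poor_risk": 146,
    "relapses": 47,
    "high_risk_relapses": 5,
    "triple_trisomy": 299,
    "double_trisomy": 395,
    "mrd_available": 632,
    "good_and_mrd_below_003": 377,
    # relapses captured by each risk grouping (of the 47 total)
    "relapses_in_good_risk": 25,
    "relapses_in_good_and_mrd_below_003": 13,
    "relapses_in_triple_trisomy": 10,
    "relapses_in_double_trisomy": 18,
}
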