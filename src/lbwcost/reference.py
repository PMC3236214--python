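"""Published benchmark estimates for the Manhiça (Mozambique) LBW cohort.

These are the figures the original cost study reported for its 2007
birth cohort; the pipeline recomputes each quantity from the printed
model inputs and the CLI report compares the reproduction against these
benchmarks at the stated tolerance.  They are validation targets only —
nothing in the models reads them.
"""

from __future__ import annotations

#: Health-system cost components for 1000 live births (US$ 2007).
TABLE4_COMPONENTS = {
    "iron": 19.52,
    "multivitamins": 301.87,
    "admission_after_delivery": 4145.43,
    "transport_referral": 4869.48,
    "admission_referral": 29937.60,
    "routine_visits": 49.71,
    "excess_admissions": 11612.16,
    "kmc_training": 17.13,
}
TABLE4_TOTAL = 50_953.68
#: Live births in the study area during 2007 and the scaled total.
N_BIRTHS_2007 = 3322
TOTAL_2007 = 169_957.61

#: DALYs per 1000 live births from LBW-attributable infant deaths.
DALY_PER_1000 = 826.63
DALY_VLBW_PER_1000 = 257.44
DALY_2007 = 2746.06

#: Household costs (US$ per baby).
HOUSEHOLD_ROUTINE_MC = 24.12
HOUSEHOLD_ROUTINE_SAMPLE_MEAN = 23.04
HOUSEHOLD_ROUTINE_MEDIAN = 4.06
HOUSEHOLD_ADMISSION_MC = 8.50
HOUSEHOLD_ADMISSION_INDIRECT_SHARE = 0.75

#: Regression benchmarks.
LOGLINEAR_INTERCEPT = 13.58
LOGLINEAR_SLOPE_PER_KG = -5.30
ADMISSION_RATE_RATIO = 1.52

#: Average cost per baby (US$, rounded as reported).
PER_BABY_NON_LBW = 121
PER_BABY_INCREMENTAL_LBW = 425
PER_BABY_LBW = 546
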