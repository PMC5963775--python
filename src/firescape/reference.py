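"""Published national burned-area statistics used as reference inputs.

These are the printed summary statistics of a 30 m Landsat-derived
burned-area product for Canada's forested ecozones, 1985-2015: average
and standard deviation of annual area burned, percent annual area burned
(PAAB), significant Theil-Sen slopes, and fitted fire return intervals.
They serve as inputs for arithmetic consistency checks of the regime
statistics and for worked examples; they are not recomputable at desk
scale from imagery.
"""

from __future__ import annotations

import math

import pandas as pd

#: Analysis period (inclusive) of the national record.
RECORD_PERIOD = (1985, 2015)
N_RECORD_YEARS = 31

#: Per-ecozone summary rows.  ``fri_yr`` is NaN where the record only
#: supports a censored lower bound (``fri_censored_bound_yr``).
ECOZONE_STATS = pd.DataFrame([
    # zone, mean ha/yr, sd ha/yr, PAAB %/yr, FRI yr, censored bound yr
    ("Atlantic Maritime",   875.5,     1_671.3,   0.01, math.nan, 5_000.0),
    ("Boreal Cordillera",   94_360.0,  138_114.7, 0.23, 439.0,    math.nan),
    ("Boreal Plains",       158_449.4, 198_607.5, 0.30, 369.0,    math.nan),
    ("Boreal Shield East",  136_875.5, 145_672.9, 0.15, 685.0,    math.nan),
    ("Boreal Shield West",  432_440.6, 319_983.3, 0.67, 141.0,    math.nan),
    ("Hudson Plains",       75_545.1,  96_601.0,  0.22, 429.0,    math.nan),
    ("Montane Cordillera",  29_332.3,  40_335.6,  0.07, math.nan, 2_000.0),
    ("Pacific Maritime",    1_401.7,   2_590.1,   0.01, math.nan, 5_000.0),
    ("Taiga Cordillera",    33_619.7,  73_066.8,  0.14, 709.0,    math.nan),
    ("Taiga Plains",        269_631.2, 446_484.9, 0.52, 188.0,    math.nan),
    ("Taiga Shield East",   136_524.7, 197_415.5, 0.24, 340.0,    math.nan),
    ("Taiga Shield West",   282_762.3, 270_592.2, 0.68, 139.0,    math.nan),
], columns=["zone", "mean_burned_ha", "sd_burned_ha", "paab_pct",
            "fri_yr", "fri_censored_bound_yr"])

#: National (all forested ecozones) summary.
NATIONAL = {
    "mean_burned_ha": 1_651_818.1,
    "sd_burned_ha": 1_116_119.4,
    "paab_pct": 0.31,
    "fri_yr": 321.0,
    "total_burned_ha": 51_206_361.0,
}

#: Significant Theil-Sen trends (zone, period, slope ha/yr, printed %/yr).
SIGNIFICANT_TRENDS = pd.DataFrame([
    ("Atlantic Maritime",  1985, 2015, -20.6,     -2.4),
    ("Montane Cordillera", 1985, 2015, 709.3,      2.4),
    ("Montane Cordillera", 1996, 2015, 3_207.23,   8.1),
    ("Pacific Maritime",   1996, 2015, 46.49,      3.2),
    ("Taiga Plains",       2006, 2015, 66_548.5,  26.1),
    ("Taiga Shield East",  1996, 2015, -4_990.73, -4.8),
    ("Taiga Shield West",  2006, 2015, 36_129.83, 12.7),
    ("Total",              2006, 2015, 186_158.0, 11.2),
], columns=["zone", "period_start", "period_end", "slope_ha_yr",
            "printed_slope_pct"])

#: Share of the 31-year total burned area contributed by the three
#: largest fire years (percent).
BIG_FIRE_YEAR_SHARES_PCT = {1989: 6.8, 1995: 11.6, 2015: 6.1}
BIG_FIRE_YEARS_COMBINED_PCT = 25.0  # printed headline

#: Share of patches above 200 ha and of burned area they account for.
LARGE_PATCH_COUNT_SHARE_PCT = 3.0
LARGE_PATCH_AREA_SHARE_PCT = 63.0
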