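"""Published county loyalty-card marginal counts and ACS comparison margins.

These are the printed household counts from the study county's loyalty-card
program (January 2016 - October 2018) and the 2017 American Community
Survey (ACS) county margins.  They serve two purposes: demonstration inputs
for the descriptive-table operations, and anchors for the synthetic
generator's demographic share defaults.

Totals differ across tables because complete-case denominators differ by
which demographic fields each table requires.
"""

from __future__ import annotations

import pandas as pd

from .labels import ACS_INCOME_LABELS, AGE_LABELS, HOUSEHOLD_SIZE_LABELS, INCOME_LABELS

#: Households by collapsed age (rows) x income (columns) group.
AGE_INCOME_COUNTS = pd.DataFrame(
    [
        [997, 1054, 1573, 1559, 804, 1280],
        [3909, 5021, 7252, 8709, 4625, 7190],
        [5105, 8605, 17346, 27166, 14641, 18007],
        [3638, 7326, 16667, 26331, 18385, 23015],
        [1704, 3675, 7069, 8518, 3856, 3950],
    ],
    index=pd.Index(AGE_LABELS, name="age_group"),
    columns=pd.Index(INCOME_LABELS, name="income_group"),
)

#: Households by age group x family status (is the household a family?).
AGE_FAMILY_COUNTS = pd.DataFrame(
    [
        [2258, 2787],
        [16937, 14990],
        [34919, 51584],
        [48919, 43851],
        [20154, 8116],
    ],
    index=pd.Index(AGE_LABELS, name="age_group"),
    columns=pd.Index(["no", "yes"], name="family"),
)

#: Households by age group x household size category.
AGE_SIZE_COUNTS = pd.DataFrame(
    [
        [1400, 691, 814, 751, 566, 823],
        [10041, 6300, 6045, 3817, 2722, 3002],
        [16467, 18653, 20759, 13745, 8897, 7982],
        [13236, 22369, 23006, 15785, 9726, 8648],
        [3658, 9943, 7814, 3927, 1773, 1155],
    ],
    index=pd.Index(AGE_LABELS, name="age_group"),
    columns=pd.Index(HOUSEHOLD_SIZE_LABELS, name="household_size"),
)

#: Loyalty-card vs ACS county households by five-level income group.
COUNTY_INCOME_COUNTS = pd.DataFrame(
    {
        "loyalty": [16233, 77691, 73276, 42785, 54074],
        "acs": [37056, 100056, 53308, 37354, 72722],
    },
    index=pd.Index(ACS_INCOME_LABELS, name="income_group"),
)

#: Loyalty-card households vs ACS county *population* by age group (the ACS
#: does not publish age of head of household, so the comparison is
#: households against people, as printed).
COUNTY_AGE_COUNTS = pd.DataFrame(
    {
        "loyalty": [10246, 41048, 97378, 100248, 30215],
        "acs": [79001, 103767, 187328, 166797, 52183],
    },
    index=pd.Index(AGE_LABELS, name="age_group"),
)

#: All loyalty-card households in the county database, before any
#: complete-case restriction.
TOTAL_DATABASE_HOUSEHOLDS = 290_098
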