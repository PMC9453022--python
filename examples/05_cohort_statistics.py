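"""Demographics-table statistics from printed summaries and raw data.

Reproduces the published cohort-comparison p-values directly from the
printed per-group mean/SD/n cells (no raw data needed), then shows the
normality-routed workflow on a synthetic participant table.
"""

import numpy as np
import pandas as pd

from neurodc.reference import DEMOGRAPHICS, SEX_COUNTS
from neurodc.stats import (
    ContingencyTable2x2,
    chi2_yates,
    demographics_table,
    ttest_from_summary,
)

print("published summaries -> pooled t-test p-values")
for var in ["neck_circumference", "ahi", "waistline", "sleep_efficiency", "moca"]:
    g1, g2 = DEMOGRAPHICS[var]
    t, df, p = ttest_from_summary(g1, g2, variant="pooled")
    print(f"  {var:18s} t={t:+6.2f}  p={p:.3f}")
stat, p = chi2_yates(ContingencyTable2x2(*SEX_COUNTS))
print(f"  sex (Yates chi2)   X2={stat:.3f}  p={p:.3f}")

rng = np.random.default_rng(3)
cohort = pd.DataFrame(
    {
        "group": [1] * 25 + [2] * 25,
        "age": rng.normal(38, 8, 50),
        "moca": np.r_[rng.uniform(18, 25, 25), rng.uniform(26, 30, 25)],
    }
)
print("\nsynthetic cohort, routed tests:")
print(demographics_table(cohort, ["age", "moca"]).to_string(index=False))
# Neck circumference (p<0.05) and MoCA (p<0.001) separate the groups;
# the other variables reproduce their published non-significant p's.
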