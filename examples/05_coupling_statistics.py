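"""Gyrification-diffusivity coupling statistics on a synthetic cohort.

Generates the scalar case-control cohort (51 cases / 48 controls, two
centres) with short-tract axial diffusivity coupled to gyrification,
then runs the group GLMs, moderation models, SURE cross-equation tests
and partial correlations.
"""

import numpy as np

from gyriconn import CohortSpec, generate_cohort
from gyriconn.coupling import bonferroni_threshold, fit_group_glm, fit_moderation_glm, partial_correlation, sure_compare, sure_fit, zscore

table = generate_cohort(CohortSpec(seed=0))
glm = fit_group_glm(table, ["ad_short", "ad_long"])
thr = bonferroni_threshold(0.05, 8)
print("group GLM (F, p):")
for m in ("ad_short", "ad_long"):
    row = glm.loc[m]
    star = "*" if row.p < thr else ""
    print(f"  {m:9s} F = {row.F:5.2f}  p = {row.p:.4f} {star}")

mod = fit_moderation_glm(table, "ad_short", "lgi")
print(f"moderation AD ~ lGI: slope beta = {mod.loc['predictor','beta']:.3f} "
      f"(p = {mod.loc['predictor','p']:.4f}), group p = {mod.loc['group','p']:.3f}")

zl, za = zscore(table.lgi.to_numpy()), zscore(table.ad_short.to_numpy())
g = table.group.to_numpy(float)
c = table.center.to_numpy(float)
X = np.column_stack([np.ones(len(table)), g, c])
res = sure_fit(zl, X, za, X, ["c", "group", "center"], ["c", "group", "center"])
chi2, p = sure_compare(res, "group", "group")
print(f"SURE: group effect on lGI vs on AD, chi2(1) = {chi2:.2f}, p = {p:.4f}")

r, p = partial_correlation(table.lgi, table.ad_short, table.ct)
print(f"partial r(lGI, AD | CT) = {r:.3f}, p = {p:.4f}")
print("AD tracks gyrification more than diagnosis; the association survives")
print("partialling out cortical thickness.")
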