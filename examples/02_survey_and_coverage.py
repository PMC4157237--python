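"""Benthic cover from line-point-intercept transects, plus rugosity and
2D->3D conversion factors, with the classical cover ANOVA.

A 50 m transect read every 0.5 m yields 101 points; the proportion of
points over each category estimates its planar seafloor cover.
"""

import pandas as pd

import reefmetab as rm

scen = rm.default_scenario(seed=2)
transects = pd.concat(
    [rm.gen_transects(scen, site, season, n_transects=3)
     for site in rm.SITES for season in rm.SEASONS], ignore_index=True)

cover = rm.coverage_from_transects(transects)
df = pd.DataFrame([{"group": c.category, "site": c.site, "season": c.season,
                    "cover_pct": 100 * c.b} for c in cover])
print(df.pivot_table(index="group", columns=["site", "season"],
                     values="cover_pct").round(1))

for site in rm.SITES:
    r = rm.rugosity_factor(rm.gen_rugosity(scen, site, n=9), site)
    print(f"rugosity {site}: {r.r:.2f} (chain length / linear length, >= 1)")

cf = rm.conversion_factor_estimate(
    rm.gen_surface_pairs(scen, "coral_diploria", n=10), "coral_diploria")
print(f"Diploria 2D->3D conversion factor: {cf.s:.2f} "
      "(3D skeletal surface per planar projected area)")

# site/season effects on coral cover (two-way ANOVA + Bonferroni)
coral = df_rows = pd.DataFrame(
    [{"site": c.site, "season": c.season, "prop": p}
     for c in cover if c.category == "coral"
     for p in c.per_transect])
res = rm.classic_cover_tests(coral)
print("\ntwo-way ANOVA on coral cover (type II):")
print(res["anova"].round(3))
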