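"""Build the benefit and cost aggregates and intersect them.

The benefit surface ranks cells by (extra food energy attainable on
existing cropland) x (isolation); the cost surface averages vertebrate
importance, carbon at risk, and local climate regulation. Their joint
classification shows where roads could raise production cheaply
(high benefit / low cost) and where they would do most harm.
"""

import numpy as np

import roadscape as rs

bundle = rs.generate_landscape(rs.LandscapeParams(seed=1))

gap = rs.production_gap(bundle.crops, bundle.grid)
print(f"production gap: {np.nansum(gap.values) / 1e9:.2f} billion GJ/y "
      f"attainable without cropland expansion")

benefit = rs.benefit_surface(gap, bundle.travel_time)
cost, layers = rs.build_cost(bundle, rule="mean")

m = benefit.defined_mask & cost.defined_mask
r = np.corrcoef(benefit.values[m], cost.values[m])[0, 1]
print(f"benefit-cost Pearson r = {r:.2f} -> broadly negative association: "
      f"converted, gap-rich cells hold little habitat value")

classified = rs.bivariate_classify(benefit, cost, n_bins=10)
total = bundle.grid.n_valid
for quadrant, count in classified.quadrant_counts().items():
    print(f"  {quadrant:<28s} {count:5d} cells ({count / total:5.1%})")
print("high-benefit/low-cost cells are the candidates for road investment;")
print("high/high cells are potential conflict zones needing protection.")
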