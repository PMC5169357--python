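"""Assess individual road proposals with 10 km buffer statistics.

For each proposed road: mean benefit and cost, current travel time,
population and existing-road density over all cells within 10 km of the
route -- the per-road evidence table -- plus an along-route profile for
the first proposal showing how benefit and cost vary along its length.
"""

import roadscape as rs

bundle = rs.generate_landscape(rs.LandscapeParams(seed=1))
grid = bundle.grid

benefit = rs.benefit_surface(rs.production_gap(bundle.crops, grid),
                             bundle.travel_time)
cost, _ = rs.build_cost(bundle)
density = rs.road_density(bundle.roads_existing, grid, bundle.areas)

surfaces = {"benefit": benefit, "cost": cost,
            "travel_time": bundle.travel_time,
            "population": bundle.population, "road_density": density}
table = rs.summarize_proposals(bundle.road_proposals, surfaces, grid,
                               width_km=10.0)
print(table.round(3).to_string(index=False))
print("\nroads with high mean benefit and low mean cost are the strongest")
print("candidates; high cost flags likely habitat and carbon losses.\n")

road = bundle.road_proposals[0]
profile = rs.road_profile(road, benefit, cost, grid)
print(f"profile of {road.road_id} ({road.length_km():.0f} km, "
      f"{len(profile)} cells):")
print(profile[["order", "benefit", "cost"]].head(8).round(3).to_string(index=False))
print("benefit/cost per traversed cell, in order along the route --")
print("impacts are rarely uniform along a road's length.")
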