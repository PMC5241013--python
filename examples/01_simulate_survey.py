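"""Simulate one point-intercept plot and look at its raw records.

Builds the standard survey layout (10 transects x 101 points), draws a
12-species community from a Pareto abundance distribution totalling ~60%
cover, and walks the vertical line over every point.
"""

import coversad as cs

layout = cs.generate_plot_layout(10, 100, 1)
print(f"layout: {layout.n_transects} transects x {layout.points_per_transect} "
      f"points = {layout.total_points} intercepts")

community = cs.simulate_community(n_species=12, pareto_shape=1.0,
                                  total_cover_target=60.0, seed=42)
print(f"community: {community.n_species} species, summed cover probability "
      f"{community.cover_probs.sum():.2f}")

records = cs.simulate_point_intercepts(community, layout, seed=43)
n_bare = sum(1 for r in records if not r.hits)
n_sky = sum(1 for r in records for h in r.hits if h.is_sky)
print(f"records: {len(records)} points, {n_bare} substrate-only, "
      f"{n_sky} in-canopy-sky hits")
print("first record:", records[0].transect, records[0].position_m,
      [h.species_code for h in records[0].hits], records[0].substrate)

# Each point either intercepts nothing (substrate only) or one/more plant
# layers; sky hits mark canopy gaps and name the enclosing woody species.
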