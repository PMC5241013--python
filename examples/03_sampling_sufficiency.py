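"""Is 1010 points enough?  Accumulation curves and cover trajectories.

The rarefied accumulation curve shows how fast species are found with
increasing points; the cumulative cover trajectory replays the points in
field (zigzag) order and recomputes FPC after each one, showing when the
cover estimate stabilises.
"""

import coversad as cs

layout = cs.generate_plot_layout()
community = cs.simulate_community(15, 0.8, 60.0, seed=7)
records = cs.simulate_point_intercepts(community, layout, seed=8)

curve = cs.species_accumulation(records, n_replicates=1000, seed=9)
for n in (50, 100, 250, 500, 1010):
    i = n - 1
    print(f"after {n:4d} points: {curve.mean_richness[i]:5.2f} +/- "
          f"{curve.sd_richness[i]:.2f} species")
print(f"(the final value equals the observed point-intercept richness exactly)")

trajs = cs.cumulative_cover(records)
top = trajs[0]
print(f"\nmost abundant species {top.species_code}: cumulative FPC")
for k in (25, 100, 500, 1010):
    print(f"  after {k:4d} points: {top.values[k - 1]:6.2f}%")
print(f"  whole-plot FPC: {cs.foliage_projective_cover(records, top.species_code):.2f}% "
      "(identical to the trajectory endpoint)")
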