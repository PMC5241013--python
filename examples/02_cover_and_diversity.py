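"""Percent cover (FPC vs OCC), fractional cover and diversity for one plot.

FPC counts only direct foliage hits; OCC also credits within-canopy sky
gaps to the canopy species, so OCC >= FPC and the gap between them is the
canopy porosity.
"""

import coversad as cs

layout = cs.generate_plot_layout()
community = cs.simulate_community(12, 1.0, 60.0, seed=42)
records = cs.simulate_point_intercepts(community, layout, seed=43)

fpc = cs.species_cover_vector(records, "FPC")
occ = cs.species_cover_vector(records, "OCC")
print("top species by FPC (percent):")
for sp, v in fpc.sort_values(ascending=False).head(5).items():
    print(f"  {sp}: FPC={v:6.2f}  OCC={occ.get(sp, 0.0):6.2f}")

pv, npv, bare = cs.fractional_cover(records)
print(f"fractional cover: photosynthetic={pv:.1f}%  dead={npv:.1f}%  "
      f"bare={bare:.1f}%  (sums to {pv + npv + bare:.0f})")

covers = fpc.to_numpy()
print(f"richness={len(covers)}  Shannon H'={cs.shannon_diversity(covers):.3f} nats  "
      f"Gini-Simpson={cs.simpson_index(covers):.3f}")
# H' is 0 for a monoculture and at most ln(richness); the Gini-Simpson
# index is the chance two random cover units belong to different species.
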