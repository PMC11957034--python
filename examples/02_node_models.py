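"""Node-wise developmental models: age effects, trajectories, maturation.

Fits the GAM (unpenalized thin-plate age smooth + sex + motion) at every
retained node of one tract, then reports the age-effect magnitude
(delta adjusted R^2), FDR-corrected significance, and the age of
maturation from the simultaneous derivative band.
"""

import alongtract as at

cfg = at.SimulationConfig(n_subjects=300, n_tracts=4, seed=7)
cohort, _, _, profiles, truth = at.generate_dataset(cfg)
tract = at.trim_end_nodes(profiles["tract01_heterotopic"])  # nodes 5-94

fit = at.fit_tract(tract, cohort, seed=7)
table = fit.table.set_index("node")

for node in (5, 30, 50, 94):
    row = table.loc[node]
    print(f"node {node:2d}: dR2adj={row.delta_r2_adj:.3f}  Q={row.q_age:.2e}  "
          f"maturation={row.maturation_age:.1f} y  matured={row.matured}")

sig = (table.q_age < 0.05).mean()
print(f"\n{sig:.0%} of nodes show a significant age effect (Q < 0.05).")
print("Age effects are largest at the superficial nodes (5, 94) and smallest")
print("deep in the tract (50); the high-rank end (94) matures latest.")

# single-node API: full/reduced fits, ANOVA, trajectory, band
y = tract.values[:, 0]
full, reduced = at.fit_node(y, cohort)
delta, p = at.age_effect(full, reduced)
band = at.derivative_band(full, seed=7)
age, matured = at.age_of_maturation(band, cohort.age.max())
print(f"\nnode 5 by hand: dR2adj={delta:.3f}, partial-F p={p:.2e}, "
      f"maturation {age:.1f} y (simultaneous crit {band.crit:.2f})")
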