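"""Multi-site mean harmonization preserving the nonlinear age effect.

Two sites differing by an additive offset and a noise-scale factor are
harmonized node-by-node with a ComBat-style location/scale model whose
covariate design includes the same unpenalized age smooth as the node
models, so the developmental signal is not removed along with the site
effect.
"""

import numpy as np

import alongtract as at
from alongtract.synthetic import Site

cfg = at.SimulationConfig(
    n_subjects=240,
    n_tracts=2,
    sites=(Site("scannerA", 0.0, 1.0), Site("scannerB", 0.05, 1.4)),
    seed=5,
)
cohort, _, _, profiles, _ = at.generate_dataset(cfg)
tract = at.trim_end_nodes(profiles["tract00_homotopic"])

model = at.fit_mean_harmonization(tract, cohort)
print("estimated site parameters at node 5 (true offset gap 0.05, scale 1.4):")
print(model.to_frame().query("node == 5").round(4).to_string(index=False))

corrected = at.apply_harmonization(tract, model)
for label, ps in (("before", tract), ("after ", corrected)):
    a = ps.values[(cohort.site == "scannerA").to_numpy()].mean()
    b = ps.values[(cohort.site == "scannerB").to_numpy()].mean()
    print(f"{label}: site means {a:.4f} vs {b:.4f} (gap {b - a:+.4f})")

ages = cohort.age.to_numpy()
r_before = np.corrcoef(ages, tract.values[:, 0])[0, 1]
r_after = np.corrcoef(ages, corrected.values[:, 0])[0, 1]
print(f"\nage-metric correlation at node 5: {r_before:.3f} before, "
      f"{r_after:.3f} after — the developmental signal survives.")
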