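"""Biogeographic provenance: supervised admixture, map placement, and
convex decomposition into reference populations.

A sample's AIM genotypes are projected onto K=9 fixed ancestral components
(EM, convex); the admixture vector is placed on the map by inverse-square-
distance spherical interpolation over the nearest reference populations and
decomposed into a sparse weighted sum of population means.
"""

import numpy as np

from arrayqc import ancestry, simcohort

components = simcohort.simulate_frequencies(2000, simcohort.default_components(fst=0.15), seed=1)
pops = simcohort.default_populations(components)
panel = ancestry.ReferencePanel.from_components(components, pops)
rng = np.random.default_rng(2)

# an unadmixed Peruvian-like individual and a 50/50 Norwegian/Yoruba mix
for label, q_true in [
    ("Peruvian-like", pops[4].mean_admixture),
    ("Norwegian/Yoruba 50:50", 0.5 * pops[7].mean_admixture + 0.5 * pops[8].mean_admixture),
]:
    g = rng.binomial(2, q_true @ panel.component_freqs).astype(float)
    result = ancestry.provenance(label, g, panel)
    top = sorted(
        zip(result.admixture.components, result.admixture.proportions),
        key=lambda t: -t[1],
    )[:3]
    print(f"{label}:")
    print("  admixture:", ", ".join(f"{c}={p:.2f}" for c, p in top))
    print(f"  placed at ({result.predicted_lat:.1f}, {result.predicted_lon:.1f}),"
          f" nearest population {result.nearest_population} [{result.nearest_region}]")
    print(f"  decomposition: { {k: round(v, 2) for k, v in result.readmix_weights.items()} }"
          f" ({result.n_assignments} assignment(s))")
# The unadmixed sample decomposes onto a single population; the 50/50 mix
# needs two, with weights near 0.5 each - the signature of recent admixture.
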