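"""KING-robust kinship and relationship classification on a trio.

phi ~ 0.5 for duplicates, 0.25 for parent-child and full siblings, 0.125
for half sibs, ~0 for unrelated pairs.  Parent-child vs siblings is
resolved by IBS0 (opposite homozygotes): exactly 0 for error-free
parent-child, ~0.017 for siblings.
"""

from arrayqc import kinrel, simcohort

manifest = simcohort.default_manifest(n_autosomal=5000, n_x=0, n_y=0, n_mt=0, n_par=0)
components = simcohort.simulate_frequencies(5000, simcohort.default_components(fst=0.15), seed=1)
pops = simcohort.default_populations(components)
cohort = simcohort.simulate_individuals(components, pops[:1], n_per_pop=6, seed=2, manifest=manifest)
simcohort.add_family(cohort, "Yakut_0000", "Yakut_0001", n_children=2, seed=3)

results, discrepancies = kinrel.kinship_matrix(cohort.truth, pedigree=cohort.pedigree)
print(kinrel.results_to_frame(results).to_string(index=False, float_format="%.4f"))
print(f"pedigree discrepancies: {discrepancies or 'none'}")
# Parent-child pairs show phi ~ 0.25 with IBS0 = 0; the two children show
# phi ~ 0.25 with IBS0 ~ 0.017 (siblings); founder pairs sit near 0.
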