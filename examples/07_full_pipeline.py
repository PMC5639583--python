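"""The full QC pipeline on a cohort with three planted errors.

One sample swap, one sex-label clerical error, and one pedigree record
claiming two unrelated people are siblings.  The consolidated report finds
exactly those three problems and nothing else.
"""

from arrayqc import qcreport, simcohort

manifest = simcohort.default_manifest(n_autosomal=600, n_x=60, n_y=30, n_mt=34, n_par=6)
components = simcohort.simulate_frequencies(
    len(manifest.autosomal_ids()), simcohort.default_components(fst=0.15), seed=1
)
pops = simcohort.default_populations(components)
cohort = simcohort.simulate_individuals(components, pops, n_per_pop=6, seed=2, manifest=manifest)
simcohort.add_family(cohort, "Peruvian_0000", "Peruvian_0001", 2, seed=3)
simcohort.genotype_on_platform(cohort, "alpha", 0.002, 0.01, seed=4)
simcohort.genotype_on_platform(cohort, "beta", 0.002, 0.01, seed=5)

simcohort.plant_swap(cohort, "alpha", "Yoruba_0000", "Yoruba_0002")
metadata = {s: {"sex": cohort.truth_sex[s]} for s in cohort.sample_ids}
metadata["Gujarati_0001"]["sex"] = "male"  # truth is female
pedigree = cohort.pedigree + [
    ("Vanuatan_0000", "ghost_f", "ghost_m"),
    ("Vanuatan_0002", "ghost_f", "ghost_m"),  # unrelated, mislabeled as sibs
]

report = qcreport.run_pipeline(
    qcreport.QCConfig(
        manifest=manifest,
        platforms=dict(cohort.genotypes_by_platform),
        pedigree=pedigree,
        metadata=metadata,
        run_ancestry=False,
    )
)
print(report.summary_text())
print(f"\nexit code: {report.exit_code}")
# Expected: the two swapped Yoruba samples suspected, the Gujarati sex
# mismatch, and one pedigree discrepancy (the fake sibling pair) - exactly
# the three planted errors.
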