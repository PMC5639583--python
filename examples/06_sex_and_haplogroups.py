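"""Genetic sex inference and mitochondrial haplogroup matching.

Sex: males are hemizygous on X (no true heterozygotes) and genotype on Y;
females show HWE-level X heterozygosity and no Y calls.  Haplogroups: sparse
mitochondrial panels support only the general branches of the phylogeny, so
calls truncate to the deepest ancestor the panel can see.
"""

from arrayqc import sexmito, simcohort

manifest = simcohort.default_manifest(n_autosomal=500, n_x=100, n_y=50, n_mt=40)
components = simcohort.simulate_frequencies(500, simcohort.default_components(fst=0.15), seed=1)
pops = simcohort.default_populations(components)
cohort = simcohort.simulate_individuals(components, pops[:3], n_per_pop=4, seed=2, manifest=manifest)

reported = dict(cohort.truth_sex)
reported["Sardinian_0002"] = "female"  # a clerical error: truth is male

print("sample            x_het  y_call  inferred  mismatch")
for r in sexmito.infer_sex(cohort.truth, manifest, self_reported=reported):
    print(f"{r.sample:17s} {r.x_heterozygosity:5.2f} {r.y_callrate:6.2f}  "
          f"{r.inferred:8s} {'<-- check metadata' if r.mismatch_flag else ''}")

tree = sexmito.toy_phylotree()
print("\nsample            truth     panel call")
for s in cohort.sample_ids[:6]:
    calls = sexmito.mt_calls_from_matrix(cohort.truth, manifest, s)
    hg = sexmito.assign_haplogroup(calls, tree)
    print(f"{s:17s} {cohort.truth_haplogroup[s]:9s} {hg.node} (score {hg.score:.2f})")
# The flagged sample is the planted clerical error.  Fine haplogroups like
# H5a3b call as their ancestor H: the panel lacks the deeper defining SNPs.
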