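# Methods

## The generative model behind the simulator

The synthetic cohort is drawn from exactly the model the downstream
analyses assume, so that every estimator can be checked against known
truth.

**Population structure (Balding–Nichols).**  For each autosomal marker m an
ancestral allele frequency p_m ~ U[0.05, 0.95]; each of K ancestral
components k (default K = 9, named after the canonical continental
components: North East Asian, Mediterranean, South African, South West
Asian, Native American, Oceanian, South East Asian, Northern European,
Sub-Saharan African) draws

    f_km ~ Beta( p_m (1−F_k)/F_k , (1−p_m)(1−F_k)/F_k ),

i.e. mean p_m and variance F_k p_m (1−p_m), clipped to [0.001, 0.999].
F_k is the component's fixation index; the default 0.15 is a standard
continental-scale differentiation figure.  Unconditionally this gives
Var(f) = Var(p) + F·E[p(1−p)] = 0.0675 + 0.1825·F, the moment identity the
tests check.

**Individuals.**  Each reference population carries a mean admixture
vector on the K-simplex (default: 0.9 on its own component, the remainder
spread evenly) and map coordinates of a representative population.
A founder's admixture q is its population mean (optionally
Dirichlet-jittered); autosomal genotypes are Binomial(2, q·f_m) — HWE
within the admixed individual.  Sexes alternate male/female.

**Sex chromosomes and mtDNA.**  Male X (non-PAR) is hemizygous and, as
array software does, reported as a homozygous diploid call (0 or 2); Y is
male-only and haploid (0/1), maternally silent; PAR markers transmit
autosomally; mtDNA is copied from the mother.  Founder haplogroups are
cycled from a fixed list of fine-grained nodes of the bundled toy
phylotree (see below).

**Families.**  Children draw one allele from each parent per autosomal
marker (a heterozygous parent transmits either allele with probability ½);
sons get the maternal X allele and the paternal Y row; daughters one X
allele from each parent.  Half-siblings and deeper structures are built
compositionally by repeated `add_family` calls with shared parents.

**Platforms.**  A platform is an independent noisy copy of the truth:
each call is dropped with probability `missing_rate`, otherwise corrupted
with probability `error_rate` (a diploid code is replaced by one of the two
other codes uniformly; a haploid code flips).  Genotype-level (rather than
allele-level) errors are used because concordance and KING statistics
depend only on genotype mismatch rates.  The defaults 0.2 % error / 1 %
missingness are calibration choices for a well-behaved array platform, not
measured values.

**What the simulator does not emulate** — linkage disequilibrium between
markers, mutation/genealogy, CNVs and chromosome loss, batch effects or
allele-specific (strand/cluster) error structure.  Tests passing on this
cohort therefore validate the estimators under their own model
assumptions; they do not certify behaviour under LD or structured error.

## Concordance and the blacklist

Concordance of a sample pair = exactly matching genotype codes / positions
non-missing in both call sets; pairs with an empty denominator are flagged
undefined, never 0.  Y markers are analysed separately (their call
behaviour differs by sex; female Y rows are structurally missing).
Markers whose two-platform calls disagree for **at least 10 %** of matched
samples (inclusive threshold) are blacklisted, together with all
extended-MHC markers, whose array calls are unreliable due to the region's
sequence similarity.  Excluding a systematically discordant marker raises
the *mean* matched concordance, though an individual pair that happened to
be concordant there can dip — the invariant holds in aggregate, not
pairwise.

## Swap detection

For every sample the cross-platform "self" concordance is compared to the
cohort's mismatched-pair distribution.  The decision threshold defaults to
the midpoint between the maximum mismatched concordance and the minimum
matched concordance, clamped into [0.80, 0.99]; the clamp keeps the rule
robust when a planted swap drags the minimum "self" value into the
background band, and when close relatives push the background maximum up.
Samples with fewer than 200 jointly observed markers are `undetermined`
rather than judged on noise.  Self-vs-mismatch separation is quantified
with the exact two-sample KS statistic (asymptotic p-value as auxiliary
output), reported per relatedness stratum when a pedigree is supplied.
A swap between genetically identical samples is invisible to concordance
by construction and is documented as such.

## Kinship

The between-family KING-robust estimator is used (cohort-wide screening is
the use case; the within-family variant differs):

    φ̂ = (N_AaAa − 2 N_AAaa) / (2 min(N_Aa^i, N_Aa^j))
         − (N_Aa^i + N_Aa^j) / (4 min(N_Aa^i, N_Aa^j)) + ½

on autosomal, bi-allelic, blacklist-filtered markers, with guards for
pairs with < 100 joint markers or no heterozygotes.  For unrelated HWE
pairs the numerator cancels in expectation for *any* allele-frequency
spectrum (E[N_AaAa] = Σ4p²q² = E[2N_AAaa]) — the estimator's robustness to
structure.  One caveat the tests make explicit: because the correction
term uses min(het_i, het_j), it is strictly negative whenever the two
heterozygote counts differ, giving a small finite-marker bias of order
−E|Δhet|/(4·min het) ≈ −0.005 at 5000 markers.  The mean over unrelated
pairs is therefore near, but measurably below, zero.

Degree bands use the standard powers-of-two midpoints on φ̂ (> 2^−3/2
duplicate/MZ; (2^−5/2, 2^−3/2] first degree; (2^−7/2, 2^−5/2] second
order; (2^−9/2, 2^−7/2] third order; ≤ 2^−9/2 unrelated).  Within the
first-degree band, IBS0 (opposite-homozygote fraction) separates
parent–child (exactly 0 without genotyping error; threshold 0.012) from
siblings (≈ p²q²/2 per marker, ≈ 0.017–0.018 on a uniform spectrum).  The
two classes genuinely overlap in the window ≈ [0.0114, 0.0157]; pairs
there may be miscalled by any fixed threshold, which is why the
`first_degree_ambiguous` call exists.  Its upper IBS0 guard defaults to
0.04 — about ten standard deviations above the sibling mean at 5000
markers — because placing the guard at the top of the *observed* sibling
range would misclassify ~0.4 % of genuine sibling pairs; the guard is a
parameter for users who prefer the tighter setting.

## Ancestry

**Supervised projection.**  With component frequencies f fixed from the
reference panel, a sample's admixture q maximizes the binomial
log-likelihood ℓ(q) = Σ_m [g_m log(q·f_m) + (2−g_m) log(q·(1−f_m))] over
the K-simplex via EM.  The problem is convex in q, so the single uniform
start suffices; ℓ is non-decreasing every iteration (asserted in tests
against an exact SLSQP solution).  Missing genotypes are skipped, and
fewer than 100 usable markers yields an undetermined vector.

**Placement.**  Euclidean distance between admixture vectors picks the
nearest reference populations; predicted coordinates are the
inverse-square-distance weighted spherical centroid (unit-vector average,
ε = 1e−9 regularizer) of the 10 nearest, with an exact-coordinate
shortcut at zero distance.  This is a transparent surrogate for
geographic-placement algorithms whose genetic-vs-geographic calibration is
described only by citation; it preserves the zero-distance and
nearest-neighbor behaviour and is rotation-consistent in longitude.

**Decomposition.**  The admixture vector (not the raw genotypes) is
expressed as a convex combination of population mean vectors by
non-negative least squares on a sum-constraint-augmented system
(penalty 1e4, agreeing with an exhaustive simplex grid to < 1e−4), with
weights < 0.01 pruned and renormalized.  Unadmixed samples come out as a
single assignment; recent admixture as a short weighted list.

**Leave-one-out accuracy** removes the test *sample* (not its population)
from the panel.  Synthetic panel means are independent of the test
samples, so placement against the full panel is the honest leave-one-out
analogue; deleting the whole population would make population-level
accuracy identically zero and measure nothing.

**Subset stability.**  Re-projecting on random marker subsets measures the
panel-size sensitivity of the admixture vector.  At Balding–Nichols
Fst 0.15 the per-component sampling noise of a 500-marker projection is
~3–7 %, so the maximum difference from the full 2000-marker vector across
many repeats is ~0.15–0.25.  Real curated AIM panels, whose markers are
near-fixed between components, carry roughly an order of magnitude more
information per marker and achieve the few-percent stability reported for
them; the simulator's random Fst-0.15 markers cannot, and the acceptance
measurement reports this honestly.

## Sex and haplogroups

Sex calls combine X heterozygosity (excluding PAR) and Y call rate:
male iff x_het ≤ 0.05 and y_call ≥ 0.8; female iff x_het ≥ 0.15 and
y_call ≤ 0.2; anything between — including insufficient markers (< 20 X
or < 10 Y) — is `ambiguous`.  The wide ambiguous band is deliberate: a
silent wrong call is worse than a flagged indeterminate one.  Thresholds
are parameters.

Haplogroup matching scores each tree node by matched / observable defining
variants along its root path, ranking by score, then matched count, then
shallower depth.  A node whose own defining variants are all off the panel
can never beat its deepest observable ancestor, so sparse panels produce
exactly the truncation seen in practice (a fine haplogroup calls as its
general branch).  Back-mutations are ignored and all variants weigh
equally — the phenomenon of interest is panel sparsity, not scorer
subtleties.  The bundled ~26-node phylotree is synthetic (positions and
alleles invented, structure realistic) and is the documented extension
point for loading a real tree.

## Pipeline

`run_pipeline` executes I/O → concordance/blacklist → identity → kinship →
sex → ancestry/haplogroups and renders a consolidated report; the exit
status is nonzero iff any swap suspicion, sex mismatch or pedigree
discrepancy was found.  All thresholds live in a single declarative
config with the defaults above.  Reports are byte-reproducible for a
fixed config and seeds.

## Problem sizes used in validation

Module tests run on compact cohorts (~400–600 autosomal markers, ≤ 100
samples).  The cohort-scale suite and `scripts/acceptance.py` use 5000
autosomal markers with 100 families / 500 unrelated pairs for kinship and
IBS0, 50 samples for replicate concordance, and a 2000-AIM K = 9 panel
with 20 individuals × 20 repeats for subset stability — sizes at which
the Monte-Carlo error of each reported mean is well below its tolerance.
All randomness flows from explicit seeds; there is no hidden global RNG
state.
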