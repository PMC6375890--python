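# Methods

## Problem setting

Ancestry-informative markers (AIMs) are SNPs whose allele frequencies differ
strongly between source populations, so a small panel of them can stand in
for whole-genome data when estimating an individual's ancestry proportions.
This package implements a complete AIMs-discovery-and-validation workflow
for a cohort of labelled diploid genotypes: score every SNP four ways,
extract candidate panels, build a consensus, and measure — against the
complete SNP set — how much ancestry information each reduced panel retains.

## Data model

Genotypes are alternate-allele counts in {0, 1, 2} with a dedicated
out-of-band missing sentinel (never 0: silently treating missing calls as
reference homozygotes biases every allele frequency downstream). The
alternate allele is a per-SNP metadata choice; every statistic computed here
(informativeness, F_ST, PCA after centring, the admixture likelihood) is
symmetric under allele relabelling, which the tests assert, so orientation
flips are harmless. Family IDs double as population labels, the common
convention for PLINK-era cohorts; any explicit individual→population mapping
can be supplied instead. Positions are 1-based as in `.map`/`.bim`.

## Scoring

**Informativeness for assignment.** Natural logarithm, `0 ln 0 := 0`, and
`p_j` is the *unweighted* mean of the per-population frequencies (the
sample-size-weighted pooled frequency is available behind a flag, but the
unweighted mean is the statistic's defining convention). SNPs for which any
population has no non-missing call are NaN — flagged unscorable, never
silently dropped — and are excluded before ranking.

**Weir–Cockerham F_ST.** The 1984 two-level θ̂ per locus from observed
allele frequencies and heterozygote proportions, the quantity PLINK 1.9's
`--fst` reports per marker. Negative estimates are retained by default
because they carry ranking information; a clamp to 0 and a two-population
Hudson estimator are options. For *calibration* (does simulated data carry
the differentiation the generator was asked for?) the right aggregate is the
multi-locus ratio-of-sums `Σa / Σ(a+b+c)` (`genome_fst`): the mean of
per-locus ratios is a ratio-of-sums vs mean-of-ratios (Jensen) situation and
sits well below the generating F even when every per-locus value is correct
(≈0.148 at F = 0.2 in our checks, versus 0.200 for the weighted form).

**PCA weights.** smartpca-style normalisation: centre each SNP column by its
observed mean, scale by `sqrt(p̂(1−p̂))` with the small-sample-corrected
`p̂ = (1 + Σg)/(2 + 2·n_obs)`, mean-impute missing cells (zero after
centring). Weights are right-singular-vector loadings. A principal
component's sign is arbitrary, so ranking uses |weight|; "highest weight"
could also be read as the signed loading, but that would make the panel
depend on an arbitrary sign convention, so the absolute value is the only
defensible reading. Monomorphic SNPs get weight exactly 0 and can never be
selected.

**K-variance.** Sample variance (denominator K−1) of each SNP's row of the
fitted P matrix. The selection rule for this method is a fixed threshold
(default 0.15) rather than top-N — this keeps the variance-thresholded set's size
data-driven, so it typically differs slightly from the top-N sets of the
other methods. Whether the original threshold used
denominator K or K−1 is not recoverable; K−1 (the standard sample variance)
was chosen and exposed as a parameter.

**Ranking.** All selections break ties by (score desc, chromosome, position,
snp_id), so every panel is bit-reproducible.

## Admixture model and fitting

The likelihood is the standard binomial admixture factorisation:
`g_il ~ Binomial(2, f_il)`, `f_il = Σ_k q_ik p_kl`, with missing cells
contributing nothing. Fitting uses plain EM (the classic multiplicative
updates) rather than quasi-Newton block relaxation: the stationary points
are identical, the monotone-likelihood guarantee makes every fit cheap to
verify (the suite asserts a non-decreasing trace on every test fit), and at
desk scale (tens of individuals, 10³–10⁵ SNPs) the extra iterations cost
seconds. Defaults: frequency clipping ε = 1e-6, relative log-likelihood
tolerance 1e-6, max 2,000 iterations, 3 seeded restarts keeping the best
likelihood; Q initialised Dirichlet(1), P Uniform(0.05, 0.95); all
randomness flows from one integer seed through `numpy.random.SeedSequence`,
so identical seeds give bit-identical fits. K = 1 short-circuits to the
closed-form MLE (Q ≡ 1, P = pooled frequencies). Non-convergence returns the
fit with `converged=False` plus a warning, never silently.

Independent fits suffer label switching, so Q matrices are compared only
after aligning components: the permutation of test columns minimising total
squared difference to the reference, found by optimal assignment on the K×K
column-distance matrix (exhaustive search over K! permutations is the test
oracle). Alignment is on Q, not P, because evaluation operates on Q.

## Panel evaluation

A panel's quality is the per-individual Euclidean distance between its
aligned admixture proportions and those of the complete-set reference fit.
Reference and panel fits use identical K, tolerance, restart count and seed,
so distance differences reflect the panel, not optimizer noise; with the
full SNP set as the "panel" the distance is exactly 0 by construction, a
tested identity. Distances below 1e-3 count as "zero" (individuals whose
ancestry the panel recovers exactly). Panels are compared by one-way ANOVA
over per-individual distances followed by Tukey's HSD (scipy's
studentized-range implementation; statsmodels is the independent oracle in
tests). Caveat, documented rather than repaired to stay comparable with
common practice: the distance vectors of different panels share individuals,
violating the independence assumption, so these p-values are descriptive.

## Synthetic cohorts

The generator is the minimal standard model for F_ST-controlled structure:
ancestral frequency π ~ Uniform(0.05, 0.95) (bounded away from fixation so
SNPs stay polymorphic), Balding–Nichols population frequencies
`p_k ~ Beta(π(1−F_k)/F_k, (1−π)(1−F_k)/F_k)`, Dirichlet or fixed (one-hot =
pure-bred) ancestry rows, binomial genotypes under the same likelihood the
inference fits, and uniform random missingness (default 0 — real missingness
is never uniform, but none of the statistics here model it). No linkage
disequilibrium is simulated: none of the scores or the admixture model uses
it. Consequently a green end-to-end test establishes that the workflow
recovers structure of the stated strength from unlinked markers — it says
nothing about LD-induced redundancy between selected SNPs, batch effects, or
call-rate artefacts of real assays.

`gorilla_cohort` fixes the gorilla-shaped world: 31 individuals, K = 3
sources — one strongly diverged (F = 0.30, three pure individuals; chosen to
mirror a species-level split where almost any marker separates the groups)
and two weakly diverged (F = 0.05 each; a within-subspecies split whose fine
structure is what the AIMs panel must resolve) — six and two pure
individuals of the two weak sources, 19 admixed individuals
(Dirichlet(0.05, 1.5, 1.5), so a few carry trace ancestry from the diverged
source), and one outlier at q = (0.15, 0.70, 0.15). Default m = 50,000 SNPs.

## Scale choices for the test and acceptance budgets

The end-to-end replicate property (consensus panel beats a size-matched
random panel in ≥19 of 20 replicate cohorts) runs at m = 15,000 SNPs with
per-method top-N = 500, preserving a ~2.8% per-method selection fraction
while fitting a single-CPU time budget; the workflow itself defaults to the
full m = 50,000. These are compute-scale choices fixed before measuring
outcomes, not tuning knobs.

## Known limitations

* Plain EM converges slowly near flat ridges of the likelihood; for
  weakly differentiated sources the tolerance matters more than the restart
  count.
* Exact admixture proportions from any particular external tool are not
  reproducible in principle (unreported seeds); all validation is therefore
  property-based (recovery of known truth, oracle equivalence, ordering
  claims), not value matching.
* The compact re-ranked sub-panel (`rerank_panel`) is a generic
  highest-score-within-panel operation; the original genotyping-subset
  construction it stands in for used unstated assay-feasibility criteria.
* VCF input, multi-allelic sites, phased data and LD-aware thinning are out
  of scope.
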