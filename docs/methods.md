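# Methods

This note documents the model and procedure implemented by `hetloop`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, the numerical conventions, and known limitations.

## The half-loop model of disease-specific heterogeneity

The object of inference is a *bicluster*: a subset of case subjects that
share a pattern over a subset of allele-combinations which is not similarly
present among controls. Genotypes enter as 0/1/2 minor-allele counts over
common SNPs (analysis restricted to maf > 0.25, strict; rare-variant signal
is deliberately out of reach of the method and depleting it this way avoids
spurious low-frequency structure). Each SNP is expanded into three binary
allele-combinations (homozygous major / heterozygous / homozygous minor),
encoded +1 = exhibits, −1 = does not. The signed encoding makes agreement
between two subjects symmetric in presence and absence — two subjects "agree"
at a combination when they are in the same state — which is the notion of
sharing the loop-counting family of scores approximates.

For case *j* and combination *k* the differential-expression score is

    Q(j,k) = [D←D](j,k) − [D←X](j,k),

where `[D←D]` is the weighted fraction of *other* cases agreeing with case
*j*'s state at *k* (self excluded, weights renormalized after exclusion) and
`[D←X]` the weighted fraction of controls. Contrasting against controls
means structure present equally in both populations — notably linkage
disequilibrium — cancels and is implicitly corrected. Row sums, column sums
and the trace aggregate `Q`; at every iteration the `max(1, round(γ·size))`
rows (cases) and columns (combinations) with the lowest scores are removed
(rounding is half-away-from-zero; score ties break toward the lower original
index). The trajectory ends when fewer than two cases remain (a single case
has no reference set, so its score is undefined; the final singleton carries
no usable trace value).

γ defaults to 0.5⁸ ≈ 0.0039 per iteration: small enough that the removal
order effectively tracks the score ranking, large enough that a cohort of a
few thousand cases finishes in a few hundred iterations. The reported trace
is size-normalized (`Q̄(i) = ΣQ/(M(i)·N(i))`), a choice that is immaterial
for inference because the null trajectories below share the elimination
schedule exactly.

### Permutation null and significance

The null hypothesis is that heterogeneity is independent of case/control
labels. Null samples permute the labels within covariate strata (k-means on
the selected covariates; per-stratum case/control counts preserved), rebuild
D and X, and rerun the elimination *on the data run's schedule*. Because the
removal counts depend only on (M(0), N(0), γ), all runs share the schedule
and per-iteration trace distributions are size-matched; under label
exchangeability the data trace and the null traces are exactly exchangeable,
which is what makes the add-one permutation p-values honest.

Per iteration, `z(i)` standardizes the data trace against the null ensemble
and `p(i)` is the add-one upper-tail count. The overall p-value uses the
maximum of `z(i)` over iterations as the summary statistic, each null trial
z-scored leave-one-out against the remaining trials, with add-one counting;
its smallest achievable value is 1/(1+n_shuffles). n_shuffles defaults
to 128; the calibration tests use 32, which suffices for a 0.05-level
decision.

### Covariate correction

Continuous covariates (genome-wide principal components in the motivating
application) enter in three places:

* **selection** — forward likelihood-ratio testing (deviance χ², 1 df,
  α = 0.05) of status on covariates picks the discovery covariates when none
  are configured; replication and PRS stages use a configured evaluation set,
  keeping the discovery-arm convention separate from the multi-arm one;
* **score reweighting** — the agreement fractions are computed under Gaussian
  kernel weights `w(j,s) ∝ exp(−‖c_j−c_s‖²/2h²)` with bandwidth
  `h = bandwidth_scale × median pairwise distance`, so each case is compared
  mostly against covariate-local cases and controls and differential
  expression contributed by structures unevenly distributed in covariate
  space is suppressed;
* **stratified shuffling** — the permutation null preserves the
  covariate-label association by shuffling within strata, so whatever
  covariate-driven elevation survives the reweighting is also present in the
  null and does not register as signal.

The suppression contract (purely covariate-driven case/control structure is
rejected by the uncorrected analysis and not by the corrected one) holds in
the acceptance tests with `bandwidth_scale = 0.25` and 8 strata at the tested
sizes; wider bandwidths trade suppression for statistical efficiency.
Covariate-corrected AUCs residualize scores on an intercept plus the selected
covariates by OLS and then rank (Mann-Whitney with ties at ½); the mechanism
is isolated in `covariates.residualize` so a stratified alternative can be
swapped in.

## Replication

For iteration *i*, the retained combinations are intersected with the
replication arm's panel (`K′(i)`), and the dominant right singular vector
`v(i)` of the training bicluster submatrix summarizes the signature. Columns
are centered, before the SVD, by their means over **all training cases** —
not by the bicluster's own means, which would make the bicluster's mean
projection identically zero and leave the component unable to separate
signature carriers from anyone (the within-bicluster principal direction is
variance around the signature, not the signature itself). The stored centers
are reused verbatim when projecting replication subjects, so no replication
information leaks into the score definition; the sign of `v(i)` is fixed so
the bicluster rows' mean projection is nonnegative. Combinations are not
variance-standardized before the SVD (centering only).

`A(i)`/`A′(i)` are covariate-corrected AUCs of case vs control bicluster
scores in the training and replication arm; `Ā′` averages `A′` over an
iteration interval. The interval is a configuration input; when absent it is
chosen as the maximal contiguous run where both the trace p and the
training-AUC p are ≤ 0.05. Replication significance permutes replication-arm
labels (within strata when provided), recomputes `Ā′` with `v(i)` and centers
fixed, and counts add-one.

Overlap degradation removes SNPs uniformly *from the intersection with the
training panel* until the Szymkiewicz–Simpson coefficient first reaches the
target. Removing non-shared SNPs cannot reduce that coefficient (numerator
and min-denominator shrink together), so the intersection is the only pool
under which the operation terminates; it is also the only removal that
matters functionally, since non-shared SNPs never enter `K′(i)`.

## Polygenic risk scores

The GWAS is a per-SNP logistic regression of status on minor-allele count
plus the evaluation covariates, fit by a batched Newton solver (a per-SNP
loop through a generic GLM library is an order of magnitude slower at
identical estimates; the solver is validated against statsmodels in the
tests). Separated or non-converged fits are refit with a ridge penalty of
1e-3 (intercept unpenalized) and flagged; zero-variance SNPs are emitted with
β = 0, p = 1 and flagged. Clumping is greedy: smallest-p unclaimed SNP
becomes an index (ties by position then SNP id), claiming maf-passing
neighbors on the same chromosome within ±500 kb whose r² with the index
exceeds 0.1 in the supplied reference genotypes. Scoring sums β × call over
model SNPs with p ≤ p̃; model SNPs missing from an arm contribute zero and
missing calls contribute the arm-mean call. Raw 0/1/2 calls stand in for
imputed dosages (imputation is out of scope), so no imputation info-score
filter applies; output metadata records the flags instead.

The bicluster-informed score contrasts only the retained cases `J(i)` with
all controls; at iteration 0 it coincides with the population-wide score by
construction. Its advantage concentrates where the population-wide GWAS is
underpowered per SNP — the per-SNP z of the wide scan scales with (planted
case fraction) × (frequency shift) while the bicluster scan's scales with the
full shift over the homogeneous subset — i.e. at small SNP-count thresholds,
which is exactly where the acceptance test compares the two.

### Liability-scale R²

AUC converts to variance explained on the liability scale under the
threshold model: liability ℓ ~ N(0,1), case ⇔ ℓ > t = Φ⁻¹(1−K) for
prevalence K, predictor correlating ρ with ℓ. The standardized case/control
score difference is d = ρ·z/(K(1−K)) with z = φ(t), and the normal
approximation of the two score distributions gives Φ⁻¹(AUC) = d/√(V₁+V₀).
The implementation inverts this relation exactly in ρ (Brent's method), using
the exact truncated-normal group variances rather than the weak-predictor
value V₁+V₀ = 2, and returns R² = ρ². Against a numerical-integration oracle
of the threshold model the round trip errs by under ~2% relative for
R² ≤ 0.3 at prevalences of 1–10%. The AUC of the threshold model is
invariant to case/control ascertainment, so the sample case fraction does not
enter this route (the argument is accepted for interface compatibility).
One consequence of mapping into [0,1]: above the AUC a perfect liability
predictor can attain (≈0.986 at K = 0.02), R² saturates at 1, so strict
monotonicity in AUC holds only below that point — any mapping bounded by 1
must plateau there.

## Gene-set over-representation

A gene is retained at iteration *i* when strictly more than half of its
annotated allele-combinations on the analysis panel survive in `K(i)`
("half" itself is not enough). Per pathway, the retained-gene overlap count
gets an upper hypergeometric tail over the annotated-and-in-universe gene
universe, and a permutation z against the gene counts of the label-shuffled
trajectories (the same null ensemble used for the trace — no fresh shuffles);
the interval-and-pathway average z̄ gets an add-one leave-one-out permutation
p. Gene-to-SNP annotation is an input; the generator's `make_gene_sets`
builds block annotations and signal/background pathways for synthetic
studies. Gene-level retention only becomes selective once column elimination
is deep (N(i) down near the planted scale), so enrichment analyses of short
trajectories benefit from a larger γ.

## The synthetic generator

Per SNP, a maf is drawn uniformly from [0.25, 0.5] and a loading vector from
N(0, ancestry_loading_sd²) per covariate; per subject, covariates are
standard normal and the minor-allele probability is
`logit⁻¹(logit(maf) + loading·covariates)`; genotypes are Binomial(2, p) per
subject (per-haplotype draws, optionally thresholding an AR(1) latent field
to induce adjacent-SNP LD while preserving Hardy–Weinberg marginals). The
planted bicluster shifts the minor-allele probability of a case subset ×
SNP subset by `effect_delta` (clipped to [0.01, 0.99]); controls never carry
the shift; an optional mirrored control-side bicluster supports the
role-reversed search. Subtype labels are Bernoulli with a higher rate inside
the planted set, solved so the marginal matches the configured base rate
(defaults 69% type-I overall, 74% inside the bicluster, mirroring the
motivating cohort's composition). Replication arms draw fresh subjects on
panels constructed by intersecting a master SNP panel so the overlap
coefficient with the training panel hits the configured targets (defaults
0.85/0.50/0.30) within rounding; the planted SNP set is a subset of the
training panel, so its presence in replication arms scales with the overlap.

Default sizes are 300 cases / 300 controls / 2000 SNPs with a 30% × 10%
planted bicluster at `effect_delta = 0.4` — the conditions under which the
planted-recovery acceptance test runs. `ancestry_loading_sd` defaults
to 0.1: on the logit scale this moves individual SNP frequencies by a few
percent per covariate SD, the magnitude of within-continental principal
component structure that the covariate correction is meant to absorb; 0.3 or
more corresponds to continental-scale gradients and makes an *uncorrected*
analysis dominated by ancestry rather than by the planted signal. The
confounding scenario (`case_covariate_shift`) samples case covariates with a
mean shift so case/control differences arise purely through ancestry.

What the generator does **not** emulate, and what passing tests therefore do
not establish about real data: realistic LD block structure (only optional
AR(1) adjacency), platform batch effects and missingness patterns (synthetic
data is complete by default), genotyping error, related individuals, rare
variants, and imputation uncertainty. Conclusions about calibration and
recovery transfer to real cohorts only to the extent that label-shuffled
nulls and PC-style covariates capture those cohorts' confounding.

## Recovery geometry of the shared elimination fraction

Rows and columns are eliminated at the same fraction γ per iteration, so
their retained *fractions* move in lockstep (rows step at least one per
iteration once round(γM) < 1). A planted bicluster occupying different
fractions of the two axes — 30% of cases but 10% of combinations, say —
therefore cannot be matched on both axes at any single iteration: when the
case set has shrunk to the planted 30%, the combination set is still at
roughly 45%, and by the time combinations would reach 10% the case rows are
exhausted. At the peak-z iteration the case-side recovery is essentially
exact (precision ≈ 1, recall ≈ 0.9+ for strong effects) while the
combination set remains a superset several times the planted size (column
precision ≈ 0.13 at the default geometry). This is a structural property of
the shared-γ schedule, not an estimation error; recovering both axes exactly
would require axis-specific elimination rates, which the algorithm
deliberately does not use. Downstream stages are insensitive to it — the
principal-component projection and the bicluster-informed GWAS both tolerate
the extra columns — but consumers of `K(i)` should treat it as an enriched
superset, not a point estimate, of the signature's combinations.

## Numerical conventions and degenerate inputs

* Uniform-weight, complete-data elimination ranks rows/columns by integer
  rescalings of the scores (exact in float64), so score ties are detected
  exactly and break by original index, reproducibly across platforms.
* Missing calls propagate as missing combinations, excluded from agreement
  numerators and denominators; a case×combination cell with no usable
  reference scores 0. Projection treats missing entries as contributing 0;
  PRS scoring imputes the arm-mean call.
* All randomness flows from explicit integer seeds; per-shuffle generators
  are seeded `[seed, trial_index]`. Fixed seed ⇒ bit-identical outputs,
  independent of thread count.
* Empty panels, single-case arrays, all-constant submatrices, rank-deficient
  covariate designs, zero-variance SNPs and infeasible overlap targets all
  raise (or flag) rather than return silently degraded results.

## Problem sizes used by the shipped tests

The acceptance tests run at desk scale chosen to finish in minutes on one
CPU: null calibration at 100/100/500 over 200 replicates, planted recovery at
the generator defaults (300/300/2000), effect-size monotonicity at
120/120/800 over 10 replicates per effect size, confound suppression at
60/60/120 over 50 replicates, replication and overlap degradation at
120–150 cases/controls over 600 SNPs with 20 replicates, and the PRS
comparison at 300/300/1600 over 20 replicates. The acceptance script repeats
the same computations at slightly reduced replicate counts.
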