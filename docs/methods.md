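# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-engineer.

## Weighted spectral counting

Evidence is pooled across **all** samples before grouping (experiment-wide
grouping): accessions whose accepted-peptide sets are identical are collapsed
into one protein group, named and ordered by the lexicographically smallest
member accession so output is deterministic. A peptide mapping to exactly one
group is *unique*; unique sets are recomputed whenever the group list changes,
because a peptide shared only with removed groups becomes unique.

Acceptance filters (all configurable via `FilterConfig`):

| parameter | default | note |
|---|---|---|
| `min_peptide_probability` | 0.90 | strict inequality: a PSM at exactly 0.90 is rejected |
| `min_protein_probability` | 0.99 | strict; protein probability is an input column from upstream identification software, defaulting to 1.0 when absent |
| `min_peptides` | 2 | distinct accepted peptides per group |
| `require_unique_peptide` | True | groups with no unique peptide are removed |

Subset proteins (peptide set strictly contained in another's) are kept as
separate groups only while they retain a unique peptide; otherwise the
unique-peptide filter removes them. No parsimony absorption is attempted —
the unique-peptide requirement is the only inference rule.

A group's **PPS** is the sum of peptide probabilities over its *distinct*
accepted peptides, each contributing its best (maximum) probability across
spectra. This makes PPS stable under resampling depth: observing the same
peptide in 50 spectra instead of 5 does not change the normalizer. A
`pps_mode="per_spectrum"` switch sums every spectrum's probability instead,
for users who want the exclusive-count-style normalizer.

Each accepted target spectrum of peptide *i* contributes
PPS(*j*)/Σ<sub>k∈n(i)</sub>PPS(*k*) to every surviving group *j* containing
*i*, in closed form (no iterative reweighting). Shares per spectrum sum to
one, so per-sample column sums equal assigned-spectrum counts to 1e-9 — this
conservation is asserted in tests and in the acceptance experiments. Spectra
whose peptide maps to no surviving group are dropped and tallied in the run
report, never redistributed. Decoy matches are retained through the peptide
filter (the FDR numerator needs them), used for peptide- and group-level
FDR = #accepted decoys / #accepted targets, and removed before counting.

## TMM normalization

Factors follow the published TMM recipe: reference sample = the one whose
75th-percentile count fraction is closest to the across-sample mean; per
sample, log-ratios M and abundances A over proteins positive in both sample
and reference; double trimming (30% of M each side, 5% of A each side, by
average ranks); factor = 2^(Σ wM / Σ w) with inverse delta-method-variance
weights w = 1/[(N−y)/(Ny) + (N_r−y_r)/(N_r y_r)]; geometric-mean
standardization so factors multiply to one. Zeros are excluded from M/A
(log undefined); no pseudo-counts. The implementation is verified to 1e-6
against edgeR 4.0.16 and to 1e-9 against an independently coded step-by-step
oracle.

`apply_normalization` offers two conventions: `divide` (counts divided by
the factor, literally, with an optional effective-library-size variant
dividing by factor × relative column sum) and `offset` (per-sample
log(N × factor) for use as a model offset, leaving counts intact).
Normalization is computed once for the entire data set and reused by every
analysis.

## Count models

All three fitters use the log link and accept the non-negative real weighted
counts; quasi-likelihood score equations are well defined for continuous
responses, and only the lognormal-Poisson model (a true likelihood) rounds
to the nearest integer by default (`round_counts=False` to disable).

**Quasi-Poisson GLM** (`fit_od_poisson_glm`). Newton/IRLS on the Poisson
quasi-likelihood with step-halving; φ = Pearson χ²/(n−p) scales the
coefficient covariance; Wald t inference with n−p degrees of freedom.

**Overdispersed Poisson GLMM** (`fit_od_poisson_glmm`). Subject random
intercept, Laplace-approximated likelihood. Fixed effects are solved at the
penalized joint mode inside the inner Newton iteration and the outer bounded
search runs over log σ_subject only — the strategy lme4 calls nAGQ=0, which
the test suite verifies against `glmer(..., nAGQ=0)` to 2e-3. Residual
dispersion φ comes from conditional Pearson residuals. The coefficient
covariance is the generalized-least-squares form under working variance
φ/µ + σ²_subject within subject: φ inflates only the *conditional* part.
Inflating the whole covariance would double-count the between-subject term —
a delta-method calculation puts the resulting null rejection rate near 1%
at nominal 5% for a typical 20-subject design, so the PQL-style covariance
is the deliberate choice here.

**Inference reference.** Contrasts use a t reference with *containment*
degrees of freedom: effects constant within subjects are tested against
subject-level replication (q − rank of the subject-level design), effects
varying within subjects against n − q − p_w. With ~20 subjects the
asymptotic normal reference rejects ≈6.7% at nominal 5% in simulation;
containment df brings this to ≈5.5%, and it degrades gracefully to the
normal as subjects grow.

**Lognormal-Poisson GLMM** (`fit_lognormal_poisson_glmm`). Adds an
observation-level Gaussian intercept to the subject intercept — the standard
construction giving negative-binomial-like marginal overdispersion. Both
random-effect vectors are handled by one joint Laplace approximation (dense
Newton over (β, u, e); the log-determinant uses the Schur complement of the
observation block). The outer Nelder–Mead runs over (log σ_subject,
log σ_obs) from a (0.3, 0.3) start. `fix_sigma_obs=0` collapses the model to
the Poisson GLMM likelihood exactly (asserted to 1e-4 in tests), and the fit
is cross-checked against glmmTMB's `(1|subj) + (1|obs)` parameterization to
0.02. Simulation at the design used for hair-vs-cuticle comparisons
(10 subjects × 2 fractions × 3 replicates, counts ≈ 30) recovers
β to well within Monte-Carlo error and both SDs with the expected mild
(≈10–15%) small-sample ML shrinkage.

**Tukey HSD.** For the complete family of k(k−1)/2 pairwise contrasts of a
factor, p_adj = P(Q_{k,df} ≥ √2·|t|) under the studentized range
distribution, using each contrast's own df (a finite-df cap of 1e6 stands in
for ∞). For k = 2 this reduces to the unadjusted two-sided p; monotonicity
p_adj ≥ p_raw is enforced. Familywise error measures 4.7% at nominal 5% in
a 1000-rep 4-level null simulation.

Numerical guard-rails: linear predictors are clipped at ±30; coefficient
magnitudes above 10 (separation, e.g. an all-zero cell) flag the fit as
boundary with a warning rather than raising; Hessians carry a 1e-10 ridge;
gradient tolerance 1e-6 (relative to total count), 200 iterations;
variance-component searches run on [1e-4, 5] with estimates below 1e-3
reported as boundary. Designs in which every subject occupies its own
fixed-effect cell are rejected as confounded before fitting.

## Comparisons, distinguishability, clustering

`pairwise_differential` fits one model per protein and tests all factor-level
pairs from that single fit. Per-protein failures are recorded, not fatal;
levels with a single sample are excluded with a warning. Proteins enter a
comparison when "present in sufficient amounts" — the criterion is not
externally defined, so the default stand-in is mean weighted count ≥ 5 **and**
nonzero in ≥ 50% of samples, both configurable and reported in the census.

Multiplicity: within a protein's pairwise family, Tukey for the site
analysis and none for subject/group/fraction analyses (mirroring per-protein
testing practice); Benjamini–Hochberg across the whole protein × pair table
is available via `multiplicity="bh"`. α defaults to 0.05 and is echoed into
every output.

The distinguishability matrix counts proteins with p_adj < α per level pair;
it is symmetric with a zero diagonal by construction and invariant to
protein and pair ordering. Its entries are used **directly** as distances
for complete-linkage agglomeration (fewer differing proteins = more
related); SciPy's linkage provides deterministic tie-breaking by entity
order. Dendrograms serialize to Newick with merge heights as node depths.

## Synthetic cohorts

`simulate_count_matrix` draws, for protein *j* in sample *k* of subject *s*,

y ~ Poisson( depth_k · λ_j · exp(u_js + δ_j(k) + ε_jk) ),

u ~ N(0, σ²_subject) per protein × subject, ε ~ N(0, σ²_obs) per
observation (mean-corrected so E exp(ε) = 1), δ the planted log-fold
effects. Defaults and what they emulate:

| field | default | emulates |
|---|---|---|
| groups × subjects × reps | 4 × 5 × 3 | four ethnic-like groups, scalp triplicates |
| `n_proteins` | 90 | the ~76–100 quantifiable hair proteins |
| `baseline_log10_sd` | 0.5 | ≈2 decades of abundance (95% range) |
| `sigma_subject` | 0.3 | inter-individual keratin variation |
| `sigma_obs` | 0.17 | φ ≈ 2 at the typical count of ~35 |
| `depth`, `depth_cv` | 3000, 0.2 | spectra per sample; enough depth variation that TMM has real work to do |
| `shared_peptide_fraction` | 0.3 | keratin-family peptide sharing within 6 blocks of 3 |
| peptide probabilities | Beta(40, 1) truncated > 0.9 | the accepted-PSM probability range |
| `decoy_rate` | 0.01 | reversed-database matches |

The lognormal ε matches the lognormal-Poisson model class; `obs_noise="gamma"`
substitutes a variance-matched gamma mixture to probe robustness under
misspecification. `identical_subject_pairs` forces two subjects to share
their entire true profile (null pairs for calibration);
`subject_blocks`/`sigma_block` add a shared family effect so relatedness
clustering has a planted truth. `simulate_cohort` then explodes each count
into PSMs assigned multinomially to the protein's peptides, with a fraction
ρ of each family member's peptides drawn from a shared block pool (capped so
every protein keeps ≥ 2 private peptides and survives the unique-peptide
filter).

What the generator does **not** emulate: peptide physicochemistry and
detectability differences, dynamic-exclusion and saturation effects,
between-run retention drift, protein probabilities below 1, and correlated
(structured) subject effects across proteins. Passing tests therefore show
the *statistical* chain is correct and calibrated under its stated model,
not that the model captures every feature of real LC-MS/MS data.

## Acceptance experiments

`scripts/acceptance.py` (also driven by `tests/test_acceptance.py`) fixes the
problem sizes: 200 random instances for the counting and grouping oracles;
100 random 50 × 4 matrices for TMM; 1000 simulated proteins for each type-I
path (subject-fixed GLM: 6 subjects × 3; GLMM: 2 groups × 10 subjects × 3,
σ_subject = 0.3, φ ≈ 2); 1000 reps for Tukey FWER (4 × 10 balanced); 300
reps for lognormal-Poisson recovery; one 4 × 5 × 3 cohort for end-to-end
sensitivity; 100 cohorts of 8 subjects for clustering recovery. The whole
script completes in about two minutes on one CPU.

The end-to-end experiment plants twenty 2-fold effects between an
otherwise-identical subject pair, ten up in each direction, on proteins with
expected counts between 25 and 120. Splitting directions keeps the planted
mass a small fraction of the library, respecting TMM's
majority-not-differential assumption — planting all effects one way on the
most abundant proteins shifts ≈half the library mass and no normalization
method can (or should) fully separate that from a depth change. Subject
comparisons use the quasi-Poisson model with TMM effective-size offsets;
without the offsets, the generator's 20% depth variation leaks into
between-subject contrasts and inflates the null pair's count well past the
binomial band.

## Known limitations

* Grouping collapses only *identical* peptide sets; Scaffold-style cluster
  analysis of near-identical groups is out of scope.
* Protein probabilities are inputs; no PeptideProphet/ProteinProphet
  reimplementation.
* GLMM confidence intervals are Wald-type with containment df — no
  profile-likelihood or Kenward–Roger adjustment.
* Dispersion is estimated per protein; pooling across proteins
  (empirical-Bayes style) is not implemented.
* The lognormal-Poisson fit rounds weighted counts; for heavily shared
  peptides at very low counts this loses sub-integer information.
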