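# Methods

This note documents the models, the synthetic-data generator, the numerical
machinery, and the design choices behind `schoolgxe`, in the spirit of a
statistical package's model documentation.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The outcome model

Achievement for child *i* (grade *t* ∈ {5, 8, 9}, coded −4/−1/0) in school
*s*, neighbourhood *n*, district *d*, municipality *m*:

y = x'β + γ·g + u0_s + u1_s·g + v_n + v_d + v_m + a_i + e_it

with g the child's standardized EA-PGI, (u0, u1) a correlated school
intercept/slope pair, independent normal intercepts at the residential
levels, a stable individual intercept a_i pooling the three grades, and an
occasion residual.  Schools are cross-classified with neighbourhoods and
districts; the residential levels are strictly nested.  The fixed part
always contains the mid-parent PGI — so γ is a *within-family* direct
genetic effect — plus parental education (years), parental income rank
(within-cohort, in [0, 1]), grade code, and 10 ancestry PCs.

Interaction readouts derived from a fit:

* slope distribution: school slopes are N(γ, σ²₁); the 2.5%/97.5% band is
  γ ∓ 1.96·σ₁, and (with standardized g and y) a school's slope² is the
  variance in achievement its PGI gradient explains;
* variance profile: Var_school(g) = σ²₀ + 2gσ₀₁ + g²σ²₁, reported as a share
  of the total fitted variance at g (all random components with slope
  levels evaluated at g, plus the individual and residual variances).  The
  denominator convention matters and is fixed here: total *random* variance,
  excluding the fixed-part variance;
* ICC at level ℓ: that level's variance at g = 0 over the same total.

## 2. Model ladder and selection

The ladder fits, by full ML so AICs are comparable across different fixed
and random parts: Model 1 (individual intercept only); 2a–2d adding school,
then neighbourhood, district, municipality intercepts; 3a–3d adding child-PGI
slopes for school, then the residential levels (cumulative); Models 4 and 5
extend 3a's structure with five school sociodemographic measures (means of
parental education and income rank, Gini of education and income, proportion
of non-western immigrant origin; standardized across schools) and their five
interactions with the child PGI.  Eleven models in total.

Selection is strictly lowest AIC among converged fits; ties below 1e-6 go to
the model with fewer parameters.  The ladder is fail-soft (a model that
errors is recorded and skipped).  Nested pairs also get LRTs with both the
naive χ² p-value and the 50:50 mixture (boundary-corrected) p-value, since
variance parameters sit on the edge of their space under the null.  The AIC
parameter count is fixed effects + relative-covariance parameters + the
residual variance; AIC = −2·loglik + 2·k exactly.  REML is available behind
a flag for variance-focused refits but is not used for ladder comparison.

Slope-variance attenuation is reported as σ²₁(Model 5) / σ²₁(Model 3a): ≈1
when the measured school covariates are unrelated to the slopes, <1 when
they explain them.

## 3. Estimation

Profiled ML in the penalised-least-squares form used by lme4: with
b = Λ(θ)u, u spherical, each evaluation solves the sparse Henderson system
for (u, β), giving the profiled deviance
log|Λ'Z'ZΛ + I| + n(1 + log(2π·pwrss/n)).  Per-level relative Cholesky
factors have their diagonal bounded at zero (not log-transformed): positive
semidefiniteness holds by construction *and* exact-zero variance components
remain attainable, which boundary LRTs and null-truth recovery need.

Sparse factorisation: SuperLU with the natural ordering over a deliberate
column order — intercept factors by decreasing cluster count first, slope
factors last.  Because every observation belongs to exactly one cluster per
factor, this ordering mimics a fill-minimising block elimination (the
individual block is diagonal, then each residential level stays diagonal at
its turn), and one evaluation at 60k rows / 30k random effects takes tens of
milliseconds.

Optimisation: L-BFGS-B with chained restarts (refreshing the Hessian
approximation escapes the flat ridges these likelihoods produce), falling
back to Nelder-Mead when line searches fail near a boundary; convergence
tolerance 1e-8 on the relative deviance.  Starting values are
structure-informed: subject-level intercept factors start near the residual
SD, coarser factors small, and slope blocks start with a *small* slope SD —
approaching a random-slope optimum from implausibly large slope variances is
the classic way to stall on a ridge.  On two full-scale datasets the fitted
deviance matched `lme4::lmer` to <1e-4 (and once exceeded it); the test
suite checks the deviance against a dense multivariate-normal oracle to 1e-6
for every ladder structure and against statsmodels' MixedLM for the
one-level case under ML and REML.

Degenerate inputs: missing values in model variables raise with the column
names; collinear fixed effects raise naming the dependent columns (QR with
pivoting); a random factor needs ≥2 clusters; singleton clusters are
retained and handled by shrinkage.  A stalled optimiser returns
`converged=False` on the results object instead of raising; ladder selection
skips non-converged fits with a warning.

## 4. The synthetic cohort generator

The generator emulates the register-linked trio cohort the analysis targets;
defaults are the cohort's own descriptives and the published effect sizes.

**Geography.**  408 municipalities / 1440 districts / 7700 neighbourhoods /
2578 schools for 23,471 students.  Cluster sizes use Dirichlet-perturbed
multinomial allocation (concentration α: schools 1.5, neighbourhoods 0.7),
which reproduces the long right tails (school sizes ~1–70, mean ≈ 9–11,
median ≈ 8; neighbourhood mean ≈ 3) without targeting them directly.  School
counts per municipality track population mass, so expected school size is
roughly constant across municipalities.  Schools are municipal —
realistically nested in municipalities — while feeder-set mixing across
districts makes them cross-classified with neighbourhoods and districts.
Some configured clusters end up empty; descriptives refer to occupied
clusters, as register counts do.

**Trios.**  Parents are standard normal with spousal PGI correlation r
(default 0.2, a typical assortative-mating value for education-linked
scores); mid-parent = (mother+father)/2 exactly; child = mid-parent + an
independent Mendelian deviation whose default variance 1 − (1+r)/2
standardizes the child PGI.

**Sorting and concordance — calibrated, not tuned.**  Two mechanisms have
analytically solved parameters so the *configured* value is the *realised*
value:

* neighbourhood-school concordance: a neighbourhood is cohesive (all
  students attend its primary school) with probability
  p = (c − π̄)/(1 − π̄), where π̄ is the chance that independent scatter
  over the feeder set coincides anyway (size-1 neighbourhoods always
  coincide); the realised single-school fraction then matches c = 0.84 in
  expectation;
* school sorting: schools draw sorting effects δ_s ~ N(0, s) with
  s = 0.026; families are rank-matched to school slots on mid-parent PGI
  against δ_s plus within-school noise (a Gaussian-copula assignment), so
  the between-school mid-parent variance is s by construction.  The child's
  Mendelian deviation never enters the assignment, which is what makes the
  within-family design's conditional-randomisation property hold exactly in
  the generator: child PGI residual on mid-parent PGI has zero expected
  school-level variance for *any* sorting strength.

**Variance components.**  School intercept 0.0254, slope 0.001156 (SD
0.034), covariance −0.0025 (correlation ≈ −0.46 — the published material
states only that the correlation is negative; this magnitude is the unique
value consistent with the reported variance shares of ~4% at PGI −2 SD and
~2% at +2 SD given the other components, and is therefore a derived
calibration, not a free choice).  Residential intercepts: neighbourhood
0.01, district 0.005, municipality 0.01.  The remaining variance is split
individual 0.45 / residual 0.4996, summing all components to 1 at g = 0.
The split is not published; 0.45/0.50 implies a cross-grade achievement
stability of ~0.5–0.6 (with the fixed part), in line with standardized-test
stability over a four-year span.  Subject outcomes reuse the school
intercept but draw subject-specific slope effects (SDs 0.035 maths, 0.027
reading, 0.004 English) and subject residuals; English is missing at
grade 9.

**Covariates.**  Parental education and income correlate moderately with the
mid-parent PGI (so sorting induces school-level SES differences); income is
right-skewed and ranked within birth cohort; an immigrant-origin label has
school-varying prevalence; PCs are i.i.d. standard-normal noise controls
with zero default effects.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no SNPs, LD, or allele frequencies (the PGI is a
direct Gaussian draw); no measurement model for test scores (composites are
generated directly); school and residential memberships are constant across
grades (no moves); no school covariate genuinely moderates the slopes unless
a test plants one; participation is complete (no selective attrition).

## 5. Simulation studies and their resolution

The acceptance script runs recovery studies at ~20,000 students over ~2,000
schools (16 replicates for the slope model, 10 for the residential
decomposition, 5 for the sorting proof-of-concept); the test suite runs
half-scale versions (≈10k students / 1k schools, 2–4 replicates) with
3-sigma Monte-Carlo tolerance bands derived from the measured per-replicate
spread (SE of the slope-variance estimate scales as √(2/m_schools) times
the per-school noise).  The replicate summary of the slope SD is the mean of
per-replicate square roots; at this information level the ML slope-variance
estimate carries a modest upward skew (PSD-boundary and zero-truncation
effects), which the concavity of the square root largely offsets, so this
summary is the better-centred of the two natural conventions (measured over
30 replicates at full scale).

Two readouts sit at the edge of what these study conditions can resolve, and
the package reports them without pretending otherwise:

* *AIC selection of the slope model.*  With slope SD 0.034, covariance
  −0.0025, ~10 students per school and the between-student noise implied by
  the component split, the information for (σ₀₁, σ²₁) yields a 2-df LRT
  noncentrality of only ~3–5 even at full scale, against an AIC penalty
  of 4: the slope model wins roughly half the replicates (5/10 in a
  full-scale study), not a large majority.  Detecting this interaction
  decisively requires more slope information than the printed summary
  parameters imply.
* *Subject ordering.*  The maths-reading slope-SD gap (5e-4 on the variance
  scale) is a fraction of one Monte-Carlo SE per replicate at full scale;
  the ordering of point estimates between those two subjects is
  noise-level, while English's near-zero slope SD separates cleanly.

## 6. Preprocessing conventions

Fixed order: residualise subject scores on sex, current age and test age
(constant covariates dropped with a warning) → grade-wise composite (mean of
available subjects; grade 9 uses maths + reading only, ignoring any English
value) → standardize composites within grade and PGIs over the analysis
sample (post-exclusion — the standardization sample is a declared,
configurable convention).  Income ranks are within-cohort mid-ranks
(i − 0.5)/n, ties averaged, chosen for a uniform marginal.  Identifier
harmonisation maps merged area codes to their target; splits are unmappable
and left unchanged with a warning; chained or cyclic maps are rejected at
load so applying a map is idempotent.  Rows disappear only through explicit,
logged exclusions.

The Gini coefficient is the mean-absolute-pairwise-difference estimator
G = Δ/(2μ) in its O(n log n) sorted form, with no small-sample correction;
zero values are retained (all-zero input is an error), and education years
in practice are strictly positive.

## 7. Known limitations

* The school-slope variance is weakly identified at realistic school sizes;
  single fits can return a boundary zero, and only replicate averages are
  meaningful at these scales.
* The variance-profile denominator excludes fixed-part variance by
  convention; shares would be ~8–10% smaller relative terms if the fixed
  part were included.
* REML AICs are reported with the same parameter count as ML but are not
  comparable across different fixed-effect sets; use ML for the ladder.
* The CLI's analyze path rebuilds school covariates from the analysis sample
  when no full peer-parent table is supplied (logged as a downgrade);
  register-grade covariates should come from the full parent population.
* No generalized (non-Gaussian) outcomes; no random slopes beyond the
  ladder's specification.
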