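# Methods

## The progression model

PDAC progression is modeled as a three-type logistic branching process
starting from a single type-0 cell in the primary site. Writing w and x for
the type-0 and type-1 cell counts in the primary and yᵢ for the cells of
metastatic colony i:

- type-0 cells divide at rate r₀(1 − (w+x)/LAI) and die at rate d₀ per
  month; each division yields a type-1 daughter with probability u;
- type-1 cells divide/die at r₁(1 − (w+x)/LAI) / d₁ and establish new
  colonies at rate q per cell per month; each colony starts from one cell
  with its own capacity MAIᵢ drawn i.i.d. at seeding;
- type-2 cells in colony i divide/die at r₂(1 − yᵢ/MAIᵢ) / d₂; colonies
  never re-seed the primary or each other.

Diagnosis occurs when the total burden w + x + Σyᵢ reaches M_diag, death
when it reaches M_death. Defaults are the published simulation settings:
u = 6.31×10⁻⁵, q = 6.31×10⁻⁷, r₀ = r₁ = 0.28/month, r₂ = 1.16/month,
dₖ = rₖ/100, M_diag = 10^N(9.47, 0.29), M_death = 10^10.6. Volumes convert
to cells at 10⁹ cells/cm³; the primary is taken to be 80% stroma (so
M_diag ≈ 3 cm primary diameter), metastases stroma-free by default
(configurable — the stromal content of metastases is not specified by the
source data).

Two reading choices are worth stating. The seeding rate q acts per type-1
cell per unit time (not per division); a per-division variant can be
obtained by scaling q by the division rate. The diagnosis/death thresholds
count cancer cells only; stroma enters volume reporting.

## Hybrid stochastic–deterministic integration

Exact event-by-event simulation to 4×10¹⁰ cells is infeasible, so each
compartment (w, x, each yᵢ) is advanced on a micro-step dt ≤ 1/30 month:

- at or below the hybrid threshold C = 10⁴ cells, by Poisson tau-leaping:
  division and death counts are drawn as Poisson variates of the current
  propensities, and mutant daughters as a binomial thinning of the division
  count. With r·dt ≤ 0.04 the leap preserves the mean exactly and the
  branching-process variance to O(r·dt); the unit test comparing the
  stochastic-regime mean of 500 runs against the deterministic trajectory
  bounds the discrepancy below 2%.
- above C, deterministically: the coupled (w, x) pair by classical RK4 on
  the logistic birth–death ODEs, and each colony by the exact one-step
  solution of its logistic ODE (colonies are independent given MAIᵢ).

Negative effective rates (on-treatment shrinkage) are handled by clamping
the division propensity at zero and carrying the negative part as
additional death, which matches the ODE drift in both regimes. New type-1
lineages and new colonies arrive as Poisson streams with intensities
u·max(0, r₀(1−(w+x)/LAI))·w and q·x per month. Threshold crossings are
located by linear interpolation within the crossing step. Founder lineages
that go extinct are restarted with a fresh seed — the modeled population is
patients who developed tumors — and this conditioning is switchable.

The kernel is JIT-compiled (numba); a typical natural-history run costs a
few milliseconds, which is what makes the replicate-heavy calibration
studies below tractable on one CPU.

## Mixed-effects growth-curve inference

The observation model is log-normal: log V_ij ~ N(log f(t_ij; θᵢ), σ),
where f is the exponential, logistic or linear law. Volumes are positive
and CT segmentation error grows with lesion size, hence multiplicative
noise; AIC is therefore computed on log-volume residuals. Random effects
are independent normals centered at zero on each law's two patient-level
parameters; the logistic shape B carries a fixed effect only (it is not
identifiable per patient from short series) and is bounded to (10⁻³, 10⁶)
for sampling stability.

Priors: growth rate N(0.16, 0.14) for primary cohorts and N(0.58, 2.72)
for metastatic cohorts (read as mean/sd); capacity and B are LN(0, 10);
the residual sd is half-normal(1). Random-effect sds get half-normal
hyperpriors with scales set on each effect's own measurement scale
(1 /month for rates and log-scale intercepts, 20 cm³ for
capacity/intercept levels, 5 cm³/month for slopes): a unit-scale cap on a
cm³-scale effect would contradict the inter-patient capacity spread the
generator itself produces.

Sampling is adaptive Metropolis-within-Gibbs. The per-patient blocks are
conditionally independent given the fixed effects and are proposed and
accepted in parallel; fixed effects update coordinate-wise and jointly
(empirical-covariance proposal built during warmup); two extra move types
fix the slow directions of hierarchical posteriors — likelihood-invariant
translations (shift a fixed effect, counter-shift its random effects) and
a directional shape/rate move that shifts log B while compensating the
rate so B·e^(−rt) is unchanged at the central observation time. Proposal
scales adapt only during warmup (first half of each chain), so the kept
draws form a valid Markov chain. Convergence is flagged at split-R̂ > 1.05
on any fixed effect (arviz); defaults are 4 chains × 4000 iterations,
about five seconds for 50 lesions.

AIC = 2k − 2·logL with logL the data log-likelihood at the
maximum-posterior sampled draw (a MAP plug-in; no separate optimizer is
run) and k the fixed effects plus variance components (logistic 6,
exponential and linear 5). All three laws carry two random effects per
patient, so the conditional-likelihood comparison is on one scale.

## Synthetic cohorts

The clinical restaging series this model class was built around are not
publicly available, so cohorts are generated synthetically: per-lesion logistic parameters drawn from configurable
distributions, volumes observed under i.i.d. log-normal noise (default
10%), ≥3 scans per lesion. Log-normal capacity samplers are specified by
their (q1, median, q3) via μ = ln median, σ = ln(q3/q1)/(2·0.6745), so a
summary-table row converts directly into a sampler.

Three canonical configurations:

- `default_cohort_config` — clinical-like: all eight context × lesion-class
  groups; primary capacity quartiles 30/60/120 cm³ (i.e. LAI quartiles
  6×10⁹/1.2×10¹⁰/2.4×10¹⁰ cells, which reproduce the reported clinical LAI
  strata frequencies), metastasis capacity quartiles 0.5/2/8 cm³; rates per
  context echoing the reported treatment-effect ordering (untreated primary
  0.28/month, metastasis 1.16; FOLFIRINOX shrinking the primary, mean
  −0.10, and slowing metastases to 0.25; gemcitabine close to untreated for
  the primary). These are synthetic stand-ins chosen once for
  plausibility — not the unpublished per-patient estimates.
- `recovery_cohort_config` — the parameter-recovery benchmark: n = 50
  lesions, 5 scans at 2-month spacing, 10% noise, moderate spread (capacity
  quartiles 50/60/72 cm³, rate sd 0.05, B fixed at 3). The moderate spread
  makes the benchmark measure estimator bias rather than the √n sampling
  noise of the population mean; fixing B matches the fitted model's
  fixed-effect-only treatment of B.
- `model_selection_cohort_config` — growth-law comparison: as above but 9
  scans through 16 months. Over a short early window the mid-section of a
  logistic curve is empirically indistinguishable from linear growth in log
  space (verified by per-patient least squares), so only series that
  approach capacity can discriminate the laws; the longer window reflects
  the saturating clinical series on which the comparison is meaningful.

What the generator does not emulate: CT segmentation error structure
beyond i.i.d. log-normal noise, missed or irregular visits, correlated
lesions within a patient, or treatment switching within a series. Passing
recovery and selection tests therefore demonstrates correctness of the
estimator under its stated model, not robustness to those real-data
features.

## Treatment operators

**Chemotherapy** replaces (r₀, r₁) with a per-patient on-treatment primary
draw and r₂ with a metastasis draw for each drug interval; one draw per
patient per drug, held across intervals of the same drug (re-drawing per
interval is switchable). Death rates stay at their baseline values: only
growth rates are modified. After discontinuation, rates ramp linearly from
the on-treatment values to recovery_level × baseline over recovery_time:
scenario 1 (0, 100%) — instantaneous full reversal, the default; 2–4
(2 weeks/1 month/2 months, 100%); 5–6 (instantaneous, 95%/90%). The linear
ramp shape is this package's choice; only the recovery times and levels
are externally specified.

**Radiotherapy** is local therapy: each fraction of dose D multiplies w and
x by e^(−(ωD+ξD²)) with ξ = ω/10 enforced; metastases are unaffected.
Default course: 30 fractions × 1.8 Gy (54 Gy), 5 fractions/week,
fractions evenly spaced over the course duration. The absolute ω is a free
clinical parameter (only ω = 10ξ is specified); the default ω = 0.3/Gy is
a standard tumor α and is exposed in `RTxCourse` — results involving
absolute radiotherapy kill depend on it.

**Surgery** is instantaneous: w, x → ε·(w, x), metastases untouched, with
ε drawn log-uniformly from [10⁻⁵, 10⁻¹]. The sampling law on that interval
is not externally specified; log-uniform spreads remnants across the four
decades and yields the characteristic two-peaked post-surgical size
distribution, whereas a linear-uniform draw would concentrate at ~0.1.

## Trial engine

Virtual cases are drawn from a population model (LAI and MAI log-normal
samplers as above, M_diag = 10^N(9.47, 0.29) clipped below M_death,
on-treatment rate normals per drug), simulated from a founder cell to
diagnosis, triaged — any colony at or above the detection threshold
(default 10⁸ cells ≈ 0.1 cm³, a CT-detectability proxy) makes the case
metastatic; otherwise primary volume above 20 cm³ means locally advanced
(LAPC), else resectable — filtered by the design's eligibility, randomized
to an arm still recruiting, treated per the arm's regimen and run to
death. OS is months from diagnosis to M_death; there is no censoring
in-model except the 600-month horizon (cured/never-dying cases are
censored there). Surgery arms require resectable eligibility and
radiotherapy arms non-metastatic eligibility, enforced at design
validation.

The nine standard regimens are encoded on the post-diagnosis clock:
1 = drug 0–3, long-course RTx, drug 4.5–7.5; 2 = drug 0–6; 3 = drug 0–4,
surgery at 4, drug 4–10; 4 = surgery at 0, drug 0–6; 5 = observation;
6 = drug 0–2 and 4–6 (two-month holiday); 7 = drug 0–4; 8 = drug 0–6;
9 = first-line 0–4, second-line 4–6. All are config-overridable; the
"final scan" endpoint is the state at death (switchable to death − 2
months).

Phenotype summaries: log₁₀ primary burden histograms; detectable-met
counts binned ≤10 / 10–50 / ≥50; LAI strata at 5/10/20 ×10⁹ cells; a
local-complication proxy (primary volume > 65 cm³); Spearman correlation
of LAI with metastasis count; and maximum-likelihood polyserial
correlations between LAI and bin membership (two-step estimator: normal
thresholds from the category frequencies, ρ by bounded likelihood
maximization; verified against a brute-force grid oracle).

## Calibration studies and their scales

The acceptance script and test suite recompute, at desk scale on one CPU:

- deterministic-oracle equivalence (u = q = 0): < 1% relative error at all
  grid points (measured ~10⁻⁹);
- seeding calibration: mean colonies over 1 month with x clamped at 10⁶
  and q = 6.31×10⁻⁷ within 3 SE of 0.631 (1000 replicates);
- recovery of the fixed-effect rate and capacity within 15% on the n = 50
  benchmark (measured ~6% and ~1%);
- AIC selection of the generating law in ≥ 90% of 50 logistic cohorts
  (measured 100%), and of the linear law on linear cohorts;
- null calibration: two identical observation arms at n = 12/arm, 1000
  replicate trials, log-rank rejection within 3 SE of 5%;
- phenotype directions: negative LAI/metastasis-count Spearman; the
  chemoradiation (regimen 1 vs 2) benefit present in the LAPC subgroup
  with LAI above the cohort median and absent below it;
- reversibility: scenarios 1–4 indistinguishable at n = 100/arm. Six
  simultaneous pairwise log-rank tests at per-pair α = 0.05 would
  false-alarm ~25% of the time under the null, and the slow-recovery
  scenarios carry a real sub-month effect, so indistinguishability is
  asserted familywise: all pairwise p above the Bonferroni-corrected
  0.05/6;
- the radiotherapy course: 54 Gy total, per-fraction surviving fraction
  e^(−0.6372) ≈ 0.5288, course log₁₀ surviving fraction ≈ −8.30.

Replicate counts and per-arm sizes are the package's own desk-scale
choices; the same experiments scale up by raising `n_per_arm` and
replicate counts.

## Known limitations

No spatial structure, vasculature or immune interaction; no back-seeding
of the primary or metastasis-to-metastasis seeding; no
toxicity/adverse-event or quality-of-life modeling; chemotherapy
pharmacokinetics reduced to rate substitution with drug holidays; the
empirical per-patient LAI/MAI and on-treatment rate distributions of the
source cohorts are replaced by synthetic stand-ins, so absolute simulated
survival times should be read as model-consistent magnitudes, not
clinical predictions.
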