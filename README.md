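# pdacsim

Stochastic modeling of pancreatic ductal adenocarcinoma (PDAC) progression:
a three-cell-type logistic branching-process simulator of primary tumor
growth and metastasis, treatment operators (chemotherapy, linear-quadratic
radiotherapy, surgical resection), an in silico clinical-trial engine with
survival endpoints, and Bayesian mixed-effects growth-curve inference that
estimates per-patient growth rates and carrying capacities from
longitudinal tumor-volume series.

The package is aimed at mathematical oncologists and biostatisticians who
want to (i) fit growth laws to serial CT volumetry of primary and
metastatic lesions, (ii) simulate the natural history of PDAC from a single
founder cell through diagnosis to death, and (iii) compare treatment
schedules in virtual trials when the corresponding randomized trial is
impractical.

## The model

**Growth laws.** A lesion's volume follows one of

- exponential: V(t) = e^(β+bᵢ) · e^((β_r+b_rᵢ)·t)
- logistic:  V(t) = (β_K+b_Kᵢ) / (1 + B·e^(−(β_r+b_rᵢ)·t))
- linear:   V(t) = (α+aᵢ)·t + (β+bᵢ)

with fixed effects (Greek) and per-patient random effects, multiplicative
log-normal measurement noise, and priors N(0.16, 0.14) / N(0.58, 2.72) on
the growth rate of primary / metastatic lesions and LN(0, 10) on capacity
and shape B.  The logistic capacity is the Local Advancement Index (LAI)
for the primary and the Metastatic Advancement Index (MAI) for a
metastasis — the size the lesion converges to.  Fitting is by MCMC
(adaptive Metropolis-within-Gibbs) with split-R̂/ESS diagnostics; growth
laws are compared by AIC.

**Branching process.** The primary holds type-0 cells (division rate
r₀(1−(w+x)/LAI), death rate d₀) and type-1 cells able to disseminate
(arising with probability u per type-0 division).  Type-1 cells seed
metastatic colonies at rate q per cell per month; colony i grows at
r₂(1−yᵢ/MAIᵢ) with its own capacity drawn at seeding.  Death rates are 1%
of the division rates.  Diagnosis occurs when the total burden reaches
M_diag = 10^9.47 cells (≈3 cm primary at 80% stroma and 10⁹ cells/cm³),
death at M_death = 10^10.6.  Small compartments are simulated
stochastically, large ones deterministically.

**Treatment.** Chemotherapy substitutes growth rates with per-patient
on-treatment draws and reverses at discontinuation under six reversibility
scenarios; radiotherapy applies the linear-quadratic surviving fraction
e^(−(ωD+ξD²)), ξ = ω/10, per fraction (default 30 × 1.8 Gy = 54 Gy) to the
primary; surgery reduces the primary to a remnant fraction ε ∈ [10⁻⁵, 10⁻¹].
Virtual trials triage cases at diagnosis (metastatic → systemic therapy
only; otherwise resectable vs locally advanced), randomize eligible cases
across arms, and report Kaplan–Meier curves and log-rank tests.

## Worked example

```bash
python examples/simulate_patient.py
```

```
diagnosis at 81.1 months after the founder cell
  primary burden      2.95e+09 cells (14.8 cm^3 at 80% stroma)
  type-1 (disseminating) cells 2.59e+06
  metastatic colonies seeded   11, detectable (>=1e8 cells) 0

death at 97.9 months; overall survival 16.8 months
  total burden     4.04e+10 cells
  metastases       87 seeded, 9 detectable, largest 1.87e+10 cells
```

The case is diagnosed ~81 months after the founder cell with a ~15 cm³
primary and only occult micrometastases; death follows 16.8 months later
when accumulated metastatic growth pushes the total burden to 10^10.6
cells — the typical untreated course in this model.

```bash
python examples/run_trial.py
```

```
                n  median_os_months  mean_det_mets_final  complication_rate
arm
FFX x4 months  50         20.700833                10.24               0.42
observation    50         16.864940                12.48               0.40

log-rank comparison:
      arm_a         arm_b  statistic  p_value
observation FFX x4 months   6.972043 0.008279

Spearman correlation of LAI with final metastasis count: -0.32
```

Four months of FOLFIRINOX extends median survival by ~4 months (log-rank
p = 0.008), and the negative LAI/metastasis correlation reproduces the
central phenotype: cases whose primary saturates at a small carrying
capacity disseminate the most.

Other examples: `examples/fit_growth_curves.py` (Bayesian fitting and AIC
growth-law comparison) and `examples/reversibility_scenarios.py`
(sensitivity to post-treatment rate recovery).  A thin CLI mirrors the
main workflows: `pdacsim fit|simulate|trial --help`.

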