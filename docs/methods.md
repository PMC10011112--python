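# Methods

## The score

The genetic risk score is multiplicative and population standardized.  For
SNP i with per-allele odds ratio ORᵢ, risk-allele frequency fᵢ and subject
dosage gᵢ ∈ {0,1,2}:

    GRS = ∏ᵢ ORᵢ^gᵢ / Wᵢ,    Wᵢ = fᵢ²ORᵢ² + 2fᵢ(1−fᵢ)ORᵢ + (1−fᵢ)².

Wᵢ is the expectation of ORᵢ^gᵢ when gᵢ ~ Binomial(2, fᵢ) (Hardy–Weinberg
genotypes at the reference frequency).  Each factor then has population
mean exactly 1, so the product is interpretable as relative risk versus the
general population and `mean(GRS) → 1` in any HWE population, for any
panel.  This identity is the package's central invariant and is tested both
per SNP and for whole panels at n = 200,000.

Assumptions worth stating: SNPs are treated as independent (the panel is
LD-pruned first); ORs are taken from external studies at face value; and
the frequencies must describe the population the subject is compared
against — which is why score computation is restricted to subjects matching
the panels' source ancestry (a `white_only` switch, on by default, liftable
for simulations).

**Missing genotypes** contribute a factor of exactly 1.  Since 1 is the
HWE expectation of the factor being replaced, missingness shrinks a
subject's score toward the population mean instead of biasing it in either
direction.  A subject with all SNPs missing scores 1 and carries an
`all_missing` flag.

**Risk groups.** low < 0.5 ≤ intermediate < 2.0 ≤ high.  The boundary 2.0
belongs to the high group; "0.5–1.99" in display contexts is read as the
half-open interval [0.5, 2.0).  The cross-trait summary uses all three
scores: `any_high` if any GRS ≥ 2.0, `all_low` if all < 1.0, else
`remaining`.

## Panel selection

Panels are filtered to genome-wide significance with a strict inequality
(p < 5×10⁻⁸) and LD-pruned greedily: SNPs are visited in decreasing-W order
(ties broken lexicographically by rsID for reproducibility) and accepted
iff r² < 0.2 with every SNP already accepted.  The retained set therefore
has all pairwise r² < 0.2, and within any correlated cluster the highest-W
member survives.  The greedy order makes the result independent of input
row order and idempotent; both properties are tested.  The r² matrix is
supplied as an explicit file — the package does not compute LD from
genotype data.

## Phenotyping

Codes are compared after stripping dots and upper-casing, by prefix (so the
rule `A41` matches `A41.5` and `A415` alike).  A subject is a case iff they
have at least one include-matching event; the case date is the earliest
match.  VTE adds a subject-level, time-agnostic exclusion list: any
occurrence of a superficial/other-thrombosis or coagulopathy code (I81,
I82.0, I80.0, I80.3, I80.8, I80.9, D68) disqualifies the subject outright.
Baseline self-reported VTE marks prevalent disease.

Cohort assembly removes subjects with sepsis coded on or before
recruitment.  Subjects with a pre-recruitment occurrence of an *outcome*
are retained in the cohort but dropped from that outcome's incident
analysis (prevalent-disease flag) — a design choice, since only the sepsis
exclusion is forced by the study design; the alternative (dropping them
from the whole cohort) would distort the other outcomes' denominators.

## Survival analysis

Time origins follow the design: sepsis patients are timed from diagnosis,
sepsis-free subjects from recruitment.  Death from any cause censors.

* Kaplan–Meier and the k-group log-rank statistic are computed directly
  from risk-set bookkeeping (events at a time are processed before
  censorings at the same instant; hypergeometric variance).  Both are
  validated against brute-force enumeration on hundreds of random small
  instances and against lifelines.
* Cox proportional-hazards fits delegate to lifelines with Efron tie
  handling.  Covariates are standardized internally for Newton stability
  and coefficients back-transformed; if the default fit diverges the step
  size is damped progressively (0.25, then 0.1) before declaring the fit
  inestimable.  Monotone likelihoods and zero-event strata yield an
  `inestimable` flag rather than an exception; CI bounds above 999 flag
  `unstable` and display as ">999".
* The landmark analysis uses windows (0, 30], (30, 730], (730, ∞) days
  (2 years = 730 days; day 31 opens the mid window).  A window's risk set
  is subjects event-free, alive and under follow-up at the window start,
  each contributing time from the window start to the first of event,
  death, censoring or window end.  Window event counts partition total
  events, and with no censoring each risk set equals the previous one minus
  the previous window's events — both tested exactly.
* The trend test across ordered GRS groups is reported two ways: a
  log-rank trend test with scores (0, 1, 2) and a Cox Wald test on the
  ordinal score.  The two answer slightly different questions and neither
  is privileged.
* Race enters as a categorical covariate only when more than one level is
  present, so ancestry-restricted analyses drop it automatically.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study-like conditions and are not tuned per experiment.

* **Genotypes**: i.i.d. Binomial(2, fᵢ) per SNP — HWE, no LD, no
  population structure.  Panel sizes default to 78 (MI), 30 (IS), 22 (VTE).
  Synthetic panels draw |log OR| from half-normals with per-trait spread
  (0.075 MI, 0.105 IS, 0.19 VTE) so the resulting GRS distributions occupy
  the low/intermediate/high bins in realistic proportions (VTE panels carry
  a few large-effect variants; MI panels many small ones); frequencies are
  uniform on (0.05, 0.95).
* **Covariates**: age ~ U(40, 69); male ~ Bernoulli(0.45); race
  (0.94 White / 0.02 / 0.02 / 0.02); a log-normal 10-year baseline
  cardiovascular risk score (median 5%, log-sd 0.5) standing in for a
  pooled-cohort-equation estimate; 10 standard-normal PCs.
* **Sepsis onset**: exponential with log-rate linear in age (+0.04/y),
  male (+0.35) and standardized log baseline risk (+0.35), all centered.
  The rate constant is solved numerically (Brent) so the realized-covariate
  mean of 1 − exp(−rate·T) equals the configured cumulative incidence
  (default 2.2% over T = 12.6 years) exactly.
* **Event times**: piecewise-constant hazard λ(t) = λ₀ · GRSᵞ · exp(β'x) ·
  m(t), sampled by inversion of the piecewise cumulative hazard.  m(t) = 1
  before sepsis onset and (w₁, w₂, w₃) in the three post-onset windows.
  Baseline hazards (0.00256 MI, 0.00110 IS, 0.00137 VTE per person-year)
  match non-sepsis cumulative incidences of ~3.2/1.4/1.7% over 12.6 years.
  Default multipliers are (100, 3.70, 0.40) MI, (50, 4.92, 0.40) IS,
  (80, 11.03, 0.63) VTE; the mid/long values are realistic point estimates
  for this design, while the short-term values are deliberate large finite
  placeholders — short-window estimates are unstable or inestimable at
  realistic event counts, and no reliable reference magnitude exists for
  the VTE short-term effect.  Event-hazard covariate effects (age 0.02/y,
  male 0.20, log-risk 0.25) overlap the sepsis-model effects so covariate
  adjustment is genuinely load-bearing downstream.
* **Death**: independent exponential (0.0045/person-year), treated as
  censoring.  Competing-risks modelling is out of scope.
* **Dates**: a fixed synthetic recruitment epoch (2008-01-01) plus
  real-valued year offsets rounded to days, to exercise the calendar-date
  plumbing; 1% of subjects get a pre-recruitment sepsis code and must be
  excluded by cohort assembly.
* With γ = 0 the GRS factor is identically 1 and genotype simulation is
  skipped unless requested.

Everything flows from one seeded NumPy generator: a config reproduces its
cohort bit for bit.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: LD within panels, ancestry-specific allele
frequencies and effect sizes, informative censoring, misclassification and
incomplete capture of ICD coding, type-2-MI contamination of early
post-sepsis events, frailty/unmeasured confounding, and non-proportional
hazards beyond the planted window structure.

## Numerical and reporting choices

* Cox Newton iterations run to precision 1e-9 (the library default can stop
  one step short on very small datasets).
* Printed percentages are reproduced with round-half-to-even at
  representable ties (the behaviour of R's `round`), which matches every
  cell of the published tables the package re-checks — including cells that
  fall exactly on a half (e.g. 17/544 = 3.125% printing as 3.12).
* Parameter-recovery studies run at γ = 0 so the sepsis-effect estimand
  equals the planted multiplier exactly; with γ = 1 an unadjusted GRS acts
  as an independent frailty and attenuates marginal hazard ratios — that
  attenuation is a property of Cox marginalization, not an estimator
  defect.
* Problem sizes used by the test suite and acceptance script — 50,000
  subjects × 50 replicates for coverage checks, 100,000 × 20 for the
  headline recovery, 200,000 for the standardization invariant — were
  chosen as the smallest scales at which the targeted event counts make the
  checks informative.

## Known limitations

* The comparator alignment for window-specific hazard ratios (non-sepsis
  subjects timed from recruitment vs sepsis subjects from diagnosis) is an
  asymmetry of origins inherited from the design; alternatives such as
  matched landmark dates are not implemented.
* No BGEN/PLINK input, no imputation, no phasing; hard-call diploid
  autosomal GT only.
* Additive (log-scale) polygenic scores and LD-aware scores are
  deliberately out of scope; the multiplicative standardized score *is* the
  object of study.
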