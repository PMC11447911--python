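# Methods

This note documents the models implemented in `killitox`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Movement model and HMM endpoints

Larval swimming is modelled as a correlated random walk driven by a hidden
K-state Markov chain (default K = 3, states ordered slow < medium < fast by
mean step length).  Given the state at frame *t*, the step length is gamma
distributed and the turning angle von Mises distributed, conditionally
independent — the standard emission choice for animal-movement HMMs, used
both by the generator (`synthetic_data.gen_trajectory`) and the fitter
(`movement_hmm.fit_movement_hmm`).  The frame cadence `dt` defaults to
1/30 s (a typical tracking frame rate) and positions are in mm; both are
parameters, not constants, because assay hardware varies.

Fitting is Baum–Welch EM with parameters pooled across larvae: one shared
transition matrix and emission set, larvae as independent chains.  Pooling
is the default because transition probabilities are reported as group-level
treatment endpoints; per-larva fits are obtained by passing single series.
Details that matter:

* **Scaled forward–backward** (numba-compiled) with per-row rescaling of
  the emission likelihoods, so 20,000-step series pose no underflow risk.
  The forward log-likelihood and the Viterbi decoder are verified against
  exhaustive enumeration over all K^T paths on short series (tolerance
  1e-8).
* **M-step MLEs**: weighted gamma MLE via Newton iteration on
  log k − ψ(k) = log(weighted mean) − weighted mean log; weighted von Mises
  MLE with the concentration solved from I₁(κ)/I₀(κ) = R̄ by bracketed
  root-finding (κ capped at 10⁴; R̄ → 0 maps to κ = 0).
* **Initialization/restarts**: moment estimates from step-magnitude
  quantile bins, lognormally jittered; default 10 restarts (tests and the
  acceptance script use 2–3, which recovery experiments show is ample for
  well-separated states), best final log-likelihood wins.
* **Convergence**: relative log-likelihood change < 1e-6 or 500
  iterations; non-convergence is flagged and the best iterate returned.
  The EM trace is stored and asserted nondecreasing.
* **Degenerate inputs**: zero step lengths (outside gamma support) are
  floored at 1e-6 mm and logged; turning angles are undefined at the first
  step and around zero-length displacements and are treated as missing
  (their emission term is marginalized out).  Viterbi ties resolve to the
  lowest state index.
* **Label canonicalization**: after fitting, states are permuted so step
  means increase; the permutation is applied consistently to the start
  distribution, transition matrix and emissions, which leaves the
  likelihood invariant (tested).

HMM behavior endpoints are the staying probabilities P(i→i), all
off-diagonal P(i→j), and per-state step mean/SD and turning-angle
mean/variation, with angle variation reported as circular variance
1 − I₁(κ)/I₀(κ).

## Trajectory and feeding endpoints

Time is 0-based and period windows are half-open [start, end).  The
endpoint catalogue: total distance (sum of consecutive Euclidean
displacements), swimming bouts (maximal intervals with speed ≥ threshold
after merging pauses shorter than `min_pause`, default 0.2 s; speed is
displacement/dt and the threshold is a configuration value because assays
differ), bout count/frequency/mean duration/total time swimming, step-length
mean and SD, turning-angle circular mean and circular variance (a linear SD
is wrong for wrapped angles), and startle magnitude.  Startle is defined as
the distance traveled in the window after a light transition minus the
distance in the equal window before it (default window 2 s, may be
negative); the two windows are closed and share the transition point so
every step is counted exactly once.  An endpoint that cannot be computed
(fewer than 2 positions, zero feeding attempts) is NaN, never 0.

Feeding endpoints from event records: capture attempts, capture
probability (captures/attempts), capture attempt ratio
(attempts/encounters), mean reaction distance over attempted prey, mean
handling time over captured prey.  The endpoint registry is extensible;
the occasionally reported "feeding lunge ratio" has no fixed definition
here and must be registered by the user if wanted.

The default VMR design is five equal periods, dark–light–dark–light–dark;
period length is configurable.

## Trend calling

**Behavior.**  For each endpoint and ordered treatment pair (first, second)
the arm means are compared on a configurable scale (identity/log/logit).
Under a noninformative normal-inverse-gamma reference prior the marginal
posterior of each arm mean is a scaled Student t; the posterior of the
difference is sampled (8000 draws, seed-controlled) and the comparison is
significant when the central 95% credible interval excludes zero.  The
call's direction comes from the back-transformed treatment means: Pos when
the second treatment exceeds the first.  This reference-prior choice makes
the type-I rate of the caller land at the nominal 5% (verified by
simulation), which is the property the downstream chance-significance
arithmetic (0.05 × 83 = 4.15) relies on.  A Welch-t variant
(`method="welch"`) gives the same call semantics without Monte Carlo and is
exactly antisymmetric under pair reversal.  Zero-variance ties are called
NS with a warning.  Deliberately, no multiplicity correction is applied
across behavior endpoints — each test runs at alpha 0.05 and the expected
number of chance calls is reported instead.

**Genes.**  Per-gene negative-binomial GLM with log link and log
size-factor offsets; size factors are median-of-ratios (total-count factors
are biased when differential expression is asymmetric, and this bias was
measurable in simulation).  The NB dispersion is estimated per gene by
Cox–Reid adjusted profile maximum likelihood — the unadjusted plug-in MLE
is biased low at n = 6/6 and makes the Wald test anticonservative — and the
Wald statistic is referred to a t distribution with residual degrees of
freedom.  With these two corrections the null p-values are uniform at the
5% level and BH at FDR 0.05 controls the realized false-discovery
proportion in simulation.  Genes with mean count below 1 (including
all-zero genes) are filtered before testing and reported as such.  Calls:
Pos/Neg by the sign of log2 fold-change at q < 0.05, else NS.

**Gene sets.**  Direction-aware hypergeometric over-representation of Pos
(separately Neg) genes per set against the universe, BH across sets within
a direction; the GMT description field is kept as the set's functional
category label.

## Pattern concordance

Trend vectors are the ordered ±/0 calls over the comparison plan.  Vectors
with no significant entry are ineligible: an all-NS endpoint carries no
pattern.  Grouping is exact vector equality; matching genes to behaviors is
element-wise equality ("original") or element-wise negation ("opposite",
behind a flag).  Strict matching — equality on every position including
zeros — is the default because the object being compared is the full
treatment pattern; a relaxed mode restricted to positions significant in at
least one of the two vectors is available.  Single-entry vectors are
eligible.

## Individual-based model

The cohort simulator tracks 2500 larvae per replicate (10 replicates) daily
from hatch (5 mm) to juvenile length (default 15 mm, a configuration
parameter flagged in output metadata) or 100 days.  Treatment effects enter
only through the four behavior multipliers.  Units: length mm, dry weight
mg, time days.

* **Encounters**: Poisson with mean prey_density × π RD² × SS × t_forage —
  a 2-D search-disc model, RD = 1.0 body length × its multiplier,
  SS = 2.0 BL/s × its multiplier, 12 foraging h/day, volume converted
  mm³ → L.
* **Consumption**: binomial captures at 0.4 × capture multiplier (clipped
  to 1); intake hard-capped by the handling budget t_forage/(30 s × handling
  multiplier) and by C_max = 0.33 W^0.8 e^{0.05(T−20)} mg/day.
* **Growth**: ΔW = 0.7 C − 0.08 W^0.8 e^{0.05(T−20)}; length from the
  allometry W = 0.004 L³ and never decreasing.
* **Mortality**: daily predation probability 1 − exp(−1.95 L^−1.3) plus
  certain starvation when W < 0.7 × expected weight-at-length.
* **Individual stochasticity**: Poisson/binomial foraging, Bernoulli
  mortality, and a fixed per-larva lognormal foraging ability (σ = 0.3).
  No parameter uncertainty is simulated — replicate spread is individual
  stochasticity only, by design.
* **Seasons**: a rising sinusoidal temperature segment (16→22 °C over the
  run) for spring; summer is the same shape 4 °C warmer; prey density
  constant at 4.4 L⁻¹ by default.
* **RNG**: the root seed spawns one independent `SeedSequence` child per
  replicate; within a replicate draws are vectorized across the cohort in a
  fixed order, so every result is bit-reproducible from (config, scenario,
  multipliers, seed).

**Calibration stand-in.**  The governing equations above are a concrete,
documented parameterization in the lineage of generalized larval-fish
foraging/bioenergetics IBMs; the coefficient values are *not* measured
killifish constants.  They were calibrated, once, to the published
behaviour of such cohorts: control survival to the juvenile stage in the
1–2% band with survivor growth near 0.3 mm/day, and the treatment
orderings that follow from the assay results (PCB cohorts below their
controls in both populations, the reference-site PCB cohort worst with
near-total loss, tolerant-site PCB growth essentially unchanged, a slight
survival benefit of parental MeHg via improved feeding metrics offsetting
slower swimming).  Every coefficient sits in `IBMConfig`/`make_scenario`
so a measured parameter table can be dropped in verbatim.  The default
treatment multiplier sets (`DEFAULT_MULTIPLIERS`) encode the sign structure
of the assay findings — PCB126: swimming speed down, handling time up in
every PCB treatment, capture success down; MeHg: capture success and
reaction distance up, swimming slightly down; NBH lineage baseline: less
swimming, better capture — with magnitudes fixed during the same one-off
calibration.

Mechanistically, survival differences are driven by time-to-juvenile: the
size-dependent hazard integrates over the larval period, so any multiplier
set that slows growth lengthens exposure to high larval mortality and
collapses survival nonlinearly, while survivor growth (conditioned on the
high-ability tail) moves much less — which is why the tolerant-site PCB
cohort loses roughly half its survival at essentially unchanged survivor
growth.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume —
hidden-state switching with state-dependent gamma/von Mises emissions,
regime switching at light/dark boundaries, Poisson encounter processes with
Bernoulli attempt/capture hierarchies, NB counts with planted log2
fold-changes, optional lognormal library-size variation and per-gene
dispersion spread.  They do not emulate tracking artifacts (pixel noise,
dropped frames, reflections), arena-wall interactions, within-larva
behavioral drift, batch effects in sequencing, or correlated
gene-expression modules.  Passing tests therefore demonstrate correctness
of the estimators and callers under the assumed data-generating
mechanisms, not robustness to instrument-specific artifacts of real assay
data.

Study-condition defaults of the generators (counts: 2000 genes, 6 vs 6
samples, baseline mean 100, dispersion 0.1; assay durations, frame rate and
arena scale free parameters) are fixed in the dataclass defaults and used
unchanged by the test suite and acceptance script; problem sizes for the
heavier checks are 20,000 steps for HMM recovery, 200 simulated datasets
for caller calibration, and full scale (2500 × 10) for every cohort run.

## Known limitations

* The Bayesian behavior caller is a two-arm location model; it does not
  model the full multi-treatment hierarchy jointly, and repeated per-pair
  calls share no partial pooling.
* The DE caller estimates dispersion per gene with no shrinkage across
  genes; at very small counts it is conservative rather than powerful.
  Replicating any specific published DE tool's gene lists is a non-goal.
* BH adjustment is not idempotent (no step-up procedure is); the tested
  guarantees are q ≥ p, monotonicity in sorted p, and FDR control in
  simulation.
* The IBM has no spatial arena, no reproduction or density dependence, a
  single cohort, and daily time aggregation; its absolute survival numbers
  are only as meaningful as the calibration stand-in behind them, and the
  intended use is relative comparison across treatments under identical
  conditions.
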