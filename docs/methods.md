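# Methods

## The damage model

Four state variables describe the normalized brain: myelinated axons `Am`,
demyelinated axons `Ad`, cumulative degenerated axons `D` (volume fractions
of the healthy brain) and the myelination capacity `M` (healthy-adult-brain
units).  Inflammatory attack λ(t) (1/day) demyelinates intact axons;
remyelination returns demyelinated volume to the myelinated pool at rate
`km·M`; demyelinated axons degenerate at `kd` (chronic plaques) and intact
axons are transected at `kmd` (acute plaques); the capacity is consumed by
remyelination and regrows sub-linearly (`δ·Ad·M^q`, `q < 1`, reflecting
myelin production by sheet elongation).  `Am + Ad + D` is conserved exactly
by construction; `M` is a resource outside the conservation law and is
allowed to exceed 1 (no cap by default; a cap is available via `m_cap`).

Assumptions worth making explicit: the attack forcing is exogenous (no
feedback from accumulated damage to the immune system); severity enters
only through pulse amplitudes, not through different damage mechanisms; all
brain regions are treated as equally eloquent, so disability is read from
global volume fractions; and disability is the *maximum* of `Ad` and `D`
rather than their sum, because demyelination-driven and degeneration-driven
deficits are not additive on the EDSS.

### Parameters

| name | meaning | unit | biological range | typical values used here |
|------|---------|------|------------------|--------------------------|
| `km` | remyelination rate | 1/day | 0–100 | 0.002–0.05 (effective rate is `km·M`) |
| `kmd` | myelinated-axon transection | 1/day | 0–0.01 | 1e-5–7e-4 |
| `kd` | demyelinated-axon degeneration | 1/day | 0–1 | 0.01–0.2 |
| `q` | capacity-growth cooperativity | – | 0–1 | 0.5 |
| `δ` | capacity growth rate | 1/day | 0–1 | 0.003–0.1 |

Clinical time is in months; the model runs in days (1 month = 30.4375
days).  EDSS<sub>max</sub> = 10.  The initial myelinated fraction is 1
below onset age 20 and declines 1% per year of onset age above 20 (floored
at 0.5); when per-patient ages are unavailable the cohort-average 0.9 is
used.

### Calibration algebra

From the ordinary-least-squares line `BV = Bi·EDSS + Ci` over a patient's
out-of-relapse visits: `kei = EDSSmax/Am(0)`, `kbi = −kei·Bi`,
`Vdi = Ci + EDSSmax·Bi`.  The forward maps (simulation → EDSS, BV) and
inverse maps are exposed on `PatientCalibration` and are exact mutual
inverses; a property test asserts the round trip at 1e-12.

## Numerical integration

Classical fixed-step RK4 (default step 0.25 day; 1 day for cohort-scale
work), implemented as a batch kernel vectorized over parameter sets and
JIT-compiled with numba (a plain-numpy fallback exists).  Two policies make
the integrator robust across the whole biological box:

- **Positivity / conservation.**  After each step, negative `Am` or `Ad` is
  clipped to zero with the clipped mass routed to `D`, so the conservation
  law survives aggressive steps; `M` is clipped at zero.  Conservation
  drift over 20 simulated years at step 0.1 day is ~1e-14 (tested < 1e-8).
- **Stiffness refinement.**  The fastest local timescale is the
  demyelinated-pool turnover `km·M + kd` (+ forcing).  When it is too fast
  for the nominal step, the step is refined locally for that parameter row
  (target `h·rate ≤ 2`, at most 16-fold).  Within a refined macro-step the
  piecewise-constant forcing is evaluated at the nearest macro stage time,
  an approximation only visible when a pulse edge falls inside a macro
  step of a stiff row.  Rows stiffer than the refinement cap diverge and
  are either reported (`nan_policy="raise"`) or marked NaN and penalized by
  the caller (`"propagate"`, used by the fitter).  Gross single-step
  positivity violations (> 0.25 volume fraction) are treated as divergence;
  dead rows are skipped thereafter, so infeasible corners of a search
  population cost almost nothing.

A convergence test asserts that halving the step changes the 10-year final
state by < 1e-6 in the non-stiff regime, where the kernel is exact
classical RK4.

## Inflammatory input

Confirmed progression events are extracted with a rolling confirmed
baseline: an event fires at a visit where EDSS has risen ≥ 1 point above
the baseline and some visit ≥ 3 months later still shows the increase; the
baseline then resets to the event's EDSS.  With irregular visits,
confirmation is read at the first qualifying later visit.  Inter-event
intervals ΔT are fitted by maximum likelihood in five candidate families
(GEV, inverse-Gaussian, logistic, exponential, t location-scale; scipy
implementations) and ranked by BIC (AIC by flag), mirroring standard
distribution-fitting practice for rare-event intervals.  GEV parameters are
reported in the standard extreme-value convention (shape ξ = −c of scipy's
`genextreme`).

Attack trains are renewal processes: i.i.d. ΔT draws (negative draws
rejected) cumulated into event times, each pulse rectangular with default
width 30 days and peak `amp_scale · ΔEDSS/EDSSmax`, with ΔEDSS drawn from
the empirical attack-size distribution.  `amp_scale` converts score points
into demyelination intensity and is a study-design constant (0.015–0.08/day
in the presets; chosen so one attack demyelinates roughly 5–30% of the
myelinated pool, producing EDSS relapses of one to three points).  The
optional smooth mode adds zero-mean normal jitter whose variance is drawn
once per train from a scaled inverse-chi-squared law (df = 3 default),
fits a smoothing spline through the jittered knots and clips at zero —
emulating between-train baseline diversity.

## Trajectory clustering

EDSS series are snapped to a common month grid (nearest grid month, visits
averaging within a bin), normalized per time point by the column maximum,
and missing cells are imputed by K-nearest-neighbour over observed columns
(scikit-learn `KNNImputer`).  For each candidate k (3–8), multi-start
k-means proposes the best-inertia partition; fuzzy c-means (Bezdek updates,
fuzzifier m = 2) refines centers into soft memberships; the average
silhouette over hard labels selects k.  Rows are canonicalized
(lexicographic sort) before initialization and clusters relabelled by
ascending center severity, making the fit invariant to patient order.
Short-series assignment is nearest-center over the observed, truncated
columns only; the per-cluster error rate compares truncated to full-series
labels under the optimal label permutation (exhaustive for k ≤ 6, Hungarian
otherwise).

## Parameter estimation

The objective is the summed squared EDSS error between cluster data points
and the simulation read at the observation months, averaged over the
supplied attack trains (5 by default when fitting with stochastic trains).
Data points are split at random into equal train/test halves (seeded); the
paper-scale cap of 120 fitted points is the default and is configurable.

The genetic algorithm is real-coded on the unit cube: tournament selection
(size 3), blend crossover (rate 0.8), per-gene Gaussian mutation whose sd
shrinks linearly over the generations (adaptive mutation), and elitism
(2).  Rate constants (`km`, `kmd`, `kd`, `δ`) are decoded on a log axis
spanning six decades below their upper bounds, `q` linearly — rate
constants identifiable from decades-long dynamics span orders of magnitude,
and uniform linear sampling would never propose the small values that
matter.  Runs stop early after 30 stale generations ("up to" the
generation budget).  All evaluated candidates are archived; the ensemble is
the top-10 by training objective with test objectives attached.  Diverged
candidates receive a large finite penalty.

**Identifiability.**  Pooled, sparsely sampled EDSS series constrain mainly
the damage envelope: with visits every 6 months, relapse decay (timescale
`1/(km·M + kd)`, typically 2–8 weeks) is invisible, and (`km`, `kd`,
`kmd`) trade off along a near-degenerate manifold — which is exactly why
ensembles of parameter sets, not point estimates, are the fitting output.
The parameter-recovery experiment therefore uses a cluster whose design
makes the question well-posed: relapse-resolved monthly visits, a shared
known attack schedule (the archetype's deterministic median-interval
train, also supplied to the objective), a common onset age, and rates with
decay tails on the visit timescale.  Under those conditions the GA
recovers `kd` within 25% (top-10 median) in ≥ 8 of 10 seeds at population
50 and ≤ 100 generations; `kmd` is recovered comparably well, `km` and `δ`
more loosely (they enter through the weakly observed recovery phase), and
`q` is essentially unidentified — consistent with the sensitivity ranking.

Subtype-specific ensembles are rank-wise count-weighted linear
combinations of cluster ensembles; pairwise comparisons use the two-sided
rank-sum test (exact null for groups ≤ 25 without ties), raw p-values.

## Sensitivity analysis

eFAST with interference factor M = 4 and 5 random-phase resample curves.
Each factor (five parameters plus an inert dummy) is driven along
`x = 0.5 + arcsin(sin(ω s + φ))/π` search curves through a uniform range
`mean·(1 ± cv·√3)` clipped to the biological bounds (cv = 1 by default);
1000 model evaluations per curve.  The output is the time-averaged EDSS
(or BV) over a 10-year horizon under a fixed reference attack train, so
that runs differ only through the search-curve phases.  First-order
indices sum the output spectrum at the driving frequency's first M
harmonics; total-order indices subtract the complementary low-frequency
band (≤ ω_max/2).  Factor significance is a Welch test of its per-curve
total-order indices against the dummy's, with a 0.01 index floor.  The
estimator is verified against analytically known variance splits
(single-factor and equal-additive harnesses).

## Milestones, Hill fits and brain-volume validation

The milestone curve is the fraction of patients having *reached*
EDSS ≥ threshold by each grid month (last observation carried forward;
reaching is absorbing, hence monotone).  Identifiable curves (spanning
below 0.4 and above 0.6) are summarized by a least-squares Hill fit
`p(x) = x^b/(x^b + a)` whose inflection `a^(1/b)` is the characteristic
half-time.  Brain-volume validation simulates `n` stochastic trains per
ensemble parameter set with the patient's age-adjusted initial state, maps
`Vs` through the patient's calibration, and reports the distribution and
median of Pearson correlations with the observed BV series; patients with
fewer than 3 BV points are excluded.

## Synthetic cohorts

The generator runs the forward model per patient: archetype draw, onset
age (normal, clipped 10–55), GEV attack train, ODE integration, irregular
visit schedule (normal spacing with jitter), EDSS = quantized
`kei·max(Ad, D)` + noise clipped to [0, 10], optional BV through a
per-patient line (`Bi ~ N(−0.05, 0.01)`, `Ci ~ N(1.2, 0.03)`) + noise, and
visit-level missingness.  Defaults emulate a discovery-style cohort: 66
patients, 20-year follow-up, 6 ± 1.5-month visits, EDSS noise 0.25 points,
10% missing visits.  Ground truth (archetype, parameters, train,
calibration, age) is returned with the cohort.

The subtype presets encode the qualitative ordering the model implies —
`km` and `δ` fall, `kd` and `kmd` rise from RRMS to SPMS to PPMS, with
`kmd ≪ kd` throughout; the PPMS preset is degeneration-dominated
(`D ≥ Ad` at all times), the RRMS preset relapse-dominated in intervals.
The four-cluster presets separate mild-relapsing, slow, fast and severe
early progression in time-to-milestone profile.

Two generator regimes serve different questions.  The fully stochastic
regime (default) carries renewal-process attack variability and age-driven
scaling spread; severity there forms a continuum, and adjacent archetypes
can merge under clustering — as real progressive phenotypes do.  The
archetype-curve regime (`deterministic_trains=True`, fixed onset age)
realizes each archetype's characteristic curve with observational noise
only, and is the stated condition for the cluster-recovery guarantees
(silhouette k = 4 and ≥ 0.8 label agreement in ≥ 90% of seeded runs at
noise σ = 0.05 normalized units).  What passing these tests shows about
real data is correspondingly bounded: recovery is guaranteed when the
group structure is present at the stated separation and noise, not that
any clinical cohort has four clusters.

The generator emulates visit irregularity, quantization, noise and
missingness, but not rater effects, treatment eras, dropout correlated
with severity, or measurement error in brain volume beyond additive noise.

## Problem sizes

Default experiment sizes were chosen to make each question statistically
answerable at interactive cost on one CPU: 10 GA seeds × (population 50,
≤ 100 generations) for parameter recovery; 50 seeded runs for clustering
recovery; 1000 eFAST evaluations per search curve × 5 curves × 6 factors
per readout; 20-year horizons at 1-day steps (0.1-day for the conservation
check); 48–66-patient cohorts.  The acceptance script runs the full set in
about two minutes.

## Known limitations

- Individual rate constants are only weakly identified from sparse pooled
  EDSS data (see above); ensembles, not point estimates, are the honest
  output, and `q` is effectively unconstrained by disability data alone.
- The nearest-stage forcing approximation inside stiffness-refined steps
  trades pulse-edge accuracy for robustness; analyses needing exact edge
  handling should lower the nominal step instead.
- The numpy fallback integrator lacks the stiffness refinement; without
  numba, stiff search regions abort rather than being penalized.
- Event extraction applies one confirmation rule uniformly; no separate
  handling of relapse-associated versus progression-associated worsening.
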