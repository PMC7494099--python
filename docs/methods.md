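# Methods

`leakyclock` studies how transcriptional leakage (residual promoter
activity) destabilizes repressilator-based circadian oscillators, and how
coupling a post-translational layer — targeted protein degradation of the
E3-ligase/26S-proteasome kind — restores robustness. This note documents
the models, the estimators, every tunable that matters, and the places
where the design was genuinely open.

## Deterministic models

Every gene product follows

    dP/dt = β·Hill(...) − γ_total(...)·P

with activating and repressing Hill functions
`v^n/(κ^n+v^n)` and `κ^n/(κ^n+v^n)`. Concentrations are nondimensionalized
so that the maximal steady state of every species is `p_max = 1000`
molecules per cell; production rates are therefore never free parameters
but always `β = 1000 × (total basal degradation rate)`.

Nine variants share a three-gene repression ring X ⊣ Z ⊣ Y ⊣ X:

| id | production of a ring gene | degradation of a ring gene |
|----|---------------------------|----------------------------|
| M1 | repressed by upstream gene | basal γ |
| M2 | constant | basal + γ_deg·Hill_act(upstream) |
| M3 | as M1 + positive auto-feedback term | basal γ |
| M4 | as M2 production + auto-feedback | as M2 |
| M5 | as M1 | as M2 (same regulator, independent κ, n) |
| CFFL | as M1 | γ_deg controlled by E gene *activated* by the upstream gene |
| IFFL | as M1 | E gene *repressed* by the upstream gene |
| NF | as M1 | E gene activated by the *target* gene itself |
| PF | as M1 | E gene repressed by the target gene |

The four motif variants add three controller genes (Ex, Ey, Ez) with
first-order kinetics, giving six species.

For M3/M4 the two production terms of a gene must still respect the
`p_max` ceiling; the package splits the total production
`β_main + β_pos = 1000·γ` by an auto-activation share ρ ~ Uniform(0, 1),
sampled with the other parameters. (Setting both terms independently to
`1000·γ` would put the ceiling at 2000 and break the
nondimensionalization.)

**Leakage.** Basal promoter activity replaces every transcriptional Hill
product H of a *core ring gene* by `basal·(1−H) + H`, keeping the maximum
at 1. The controller genes carry no basal floor: the E layer is the
*sensor* of the clock state, and giving it a leak floor would hold the
degradation machinery constitutively on and erase the feed-forward gating
that the motif comparison is about (in the partial-motif analysis below,
leakage is likewise applied to the input and output genes only).

**Perturbations.** The null mutant zeroes one targeted degradation rate
exactly. Controller overexpression adds a constant `magnitude × p_max`
molecules to the regulator seen by one degradation Hill (3–30% of
`p_max`), leaving the transcriptional Hill of the same regulator
untouched. For the six-species variants, perturbations scale the relevant
E gene's production rate instead, with degradation rates fixed.

## Parameter search (the synthetic-input generator)

There is no external data; cohorts of oscillating parameter sets are the
study's input. Rates and thresholds are drawn log10-uniformly over three
orders of magnitude — basal degradation 0.01–10 /h, targeted degradation
1–1000 /h, Hill thresholds 1–1000 — and Hill coefficients uniformly over
the integers 2–8. Each draw is integrated from 10% of `p_max` and kept
only if every species oscillates *regularly*: more than 10 complete
cycles whose consecutive-cycle relative changes of period and amplitude
(|x₁−x₂|/min(x₁,x₂)) all stay below 5%. Accepted sets are rescaled in
time (all rates multiplied by T₀/24) so the limit cycle has a 24 h
period; thresholds and Hill coefficients are untouched, and β rescales
implicitly through γ.

Numerical choices:

* LSODA with rtol 1e-6 / atol 1e-3 (halving the tolerance moves detected
  periods by ~1e-5 relative — far below the 0.1% requirement).
* Screening is staged: a 120 h probe discards draws that settle to a
  fixed point; survivors get a 400 h window at 0.05 h resolution;
  candidates too slow for >10 cycles there are re-screened over a
  2000 h horizon at 0.25 h. Oscillators needing more than 2000 h for 11
  cycles (periods ≳ 170 h) are rejected with the horizon. Fast
  oscillators (periods under ~2 h, common for the degradation-coupled
  variants before rescaling) are re-recorded on a period-scaled grid —
  on any fixed coarse grid their cycle statistics are aliasing artifacts.
* Peaks are grid local maxima with a prominence floor of 1% of `p_max`,
  refined by quadratic interpolation. *Periods*, however, are measured
  between upward mid-level crossings, one per cycle: relaxation-type
  limit cycles spend much of the cycle on a plateau within ~1e-4 counts
  of `p_max`, where the location of the grid argmax is numerical noise
  and peak-to-peak periods jitter by hours. The rising edge pins the
  phase; this also makes screening idempotent (accepted sets re-pass the
  screen after rescaling).
* The first 20% of the window or the first 5 cycles (whichever is more)
  are excluded as transient.

Acceptance rates at these settings: M1 ≈ 15%, M5 ≈ 15–20%, CFFL ≈ 10%,
M2 ≈ 2%, IFFL ≈ 0.3%, NF and PF below 1%. The search is the dominant
compute cost of every experiment.

## Stochastic simulation

Each gene expands into promoter state G ∈ {0,1}, mRNA count M and protein
count P, with fixed bursting statistics: burst frequency Bm = 2 and burst
size Bp = 10. All kinetic constants derive from the ODE parameters:
γ_p = γ, γ_m = 10 γ_p, γ_g = 100 γ_p, k_g = β/(Bm·Bp),
k_m = Bm(k_g+γ_g), k_p = Bp·γ_m — so the maximal mean protein level is
again β/γ = 1000 and no new parameters are searched. Hill thresholds act
directly on protein counts. By construction mean mRNA counts are at most
~10 molecules, so trajectories are strongly bursty; that is the intended
noise regime, not an artifact.

Simulation is the exact direct-method Gillespie algorithm (numba kernel),
recorded every 0.1 h for 30 days after a 5-day burn-in. The initial
protein state is a point on the deterministic limit cycle (after 240 h of
settling); promoters start at their stationary activation probability and
mRNAs at their conditional means. Leakage enters the transcription
propensity as `k_m·G·(basal(1−H)+H)`; perturbations enter exactly as in
the ODE analogues, keeping deterministic screening and stochastic runs
consistent.

Because rescaling to 24 h divides most rates by large factors (raw
periods cluster at 0.5–15 h), typical trajectories cost well under 0.1 s;
a full search-plus-simulate experiment is search-bound.

## Oscillation scoring

The score of a trajectory is built on the autocorrelation of the protein
of gene X,

    ACF(nΔt) = 1/(M−n) · Σᵢ (Pᵢ−μ)(Pᵢ₊ₙ−μ)/σ²,

computed for lags up to 10 days (Δt = 0.1 h, M = 7200). ACF peaks are
local maxima above the sampling floor 2/√M, at lags beyond half the
expected period, spaced at least half a period apart. Peak values are
fitted with `A + exp(−b·k)` where k is the *period count* of each peak
(`round(lag/T̂)`, not detection order — peaks that dip below the floor
are simply skipped) and the lag-0 peak (ACF(0)=1) anchors the envelope.
Without the anchor, b is unidentifiable whenever the peaks carry no decay
structure: any b ≳ 3 fits flat noise remnants equally well, and the
optimizer's answer is an initialization artifact. The fitted b is the
**normalized decay rate**: dimensionless, per oscillation period
(equivalent to fitting the envelope in hours and multiplying by the
period).

Stochastic oscillation periods come out 1.2–2.5× the deterministic 24 h:
with ~1–10 mRNA molecules, switching of the ring is slowed by the wait
for bursts. The decay rate is defined per *stochastic* period, so this
does not bias the metric.

**Classification.** A trajectory is *sustained* when (i) the fit
succeeded on at least 3 above-floor peaks, (ii) b ≤ threshold, and
(iii) the full damped-cosine fit `A + cos(2πx/T)·exp(−bx)` over every lag
agrees — same period within 25% and per-period decay below the same
threshold. The cross-check is what separates slow genuine oscillations
from aperiodic wander (e.g. a leakage-locked gene whose protein has a
100 h correlation time): a 720 h record contains only a handful of
independent samples of such a process, its finite-sample ACF shows
spurious bumps at plausible lags, and the peak-envelope fit alone cannot
tell the difference — but the full-curve fit then lands on a wildly
different period (2–10× off) or a large decay.

**Threshold calibration.** No cutoff between sustained and broken decay
rates is published for this metric, so the package calibrates it once on
a reference cohort — 200 wild-type M1 sets, fixed seed — and freezes it
for every other model, leakage level and perturbation. On that cohort
the classification statistic (the larger of the two fitted rates, where
the fits agree) is sharply bimodal: an oscillating mode up to 5.4 and a
broken mode from 21.6, with the sustained fraction plateauing at 86%
across the gap. The default threshold is the log-scale midpoint of the
gap, `DEFAULT_DECAY_THRESHOLD = 10.8`; any value inside the gap gives
the identical reference fraction.

**Distribution shifts.** Per-set KL divergences compare post-burn-in
histograms (50 equal-width bins over the pooled range) of mRNA, protein
and transcriptional-Hill activity of gene X between two conditions, with
add-one smoothing on the reference histogram. Conditions are re-simulated
from the stored per-task seeds, so the compared trajectories are exactly
the scored ones.

## Partial-motif analysis

To explain *why* the feed-forward couplings filter leakage, a three-node
reduction (input I, controller E, output O) is integrated with all rates
fixed at 1, Hill coefficient 8, E-input threshold 0.5, and a 20% leak on
I and O when enabled. I is driven as a square pulse (on for t ∈ [0, 40),
off to t = 80); O is read at t = 40 (I:ON) and t = 80 (I:OFF). The
filtering statistic is

    normalized ΔO = (O_basalON − O_basalOFF)/0.2,

and the difference between its value under pure-transcriptional control
and under combined transcription+degradation control is positive exactly
where the degradation layer pushes the leaked output back. Scans run over
the I→O and E→O thresholds on a grid in (0.01, 1] (the default 101×101
takes ~2 min; tests use 41×41); integration is fixed-step RK4 (dt 0.02)
vectorized over the grid.

Reproduced patterns: CFFL filters only in the I:ON state; IFFL only in
the I:OFF state; NF shows none (its controller only accumulates when the
output is already on); PF latches its output off unless the E→O
threshold is weak (> 0.8), and a weak edge cannot filter.

## Experiment orchestration and reproducibility

Per-task random streams derive from `SeedSequence(master_seed,
spawn_key=(set_index, crc32(condition_label)))`, so results are
reproducible under any execution order and adding conditions never
perturbs existing ones. Records are written incrementally as a flat CSV
plus a JSON of cohort summaries (fraction sustained; median, quartiles
and 1.5·IQR whiskers of decay rates over the sustained subset), and a
partial run resumes from the records file.

## Cohort sizes and what the tests show

The reference study uses 1000-set cohorts per model and condition. The
package's test suite and acceptance script run desk-scale cohorts (8–50
sets per model), sized so the whole suite completes on one CPU in tens
of minutes; sustained fractions then carry binomial noise of several
percentage points, and tests use tolerances of
max(10 points, 2 binomial SE) around the reference values.

What passing tests do show: the architecture ordering (M1 > M5 > M2 in
noise robustness), the collapse of the pure transcriptional ring under
5% leakage, the dose-dependent retention of oscillation by the coupled
and feed-forward architectures, the null-mutant and overexpression
degradation of M5, the protein/Hill-specific suppression of distribution
shifts, and the deterministic motif-filtering mechanism. What they do
not show: tail quantiles of the decay distributions, small (<10-point)
differences between conditions, or anything about real transcriptomes —
the generator emulates idealized bursting kinetics with fixed burst
statistics, no extrinsic noise, no cell division, and no entrainment
input.

## Known limitations

* Cohort composition depends on the (unpublished) screening horizon:
  only oscillators with free-running periods between roughly 0.1 h and
  170 h can pass the screen, and the mix of fast relaxation-type versus
  smooth oscillators shifts the cohort's noise robustness by a few
  percentage points.
* The sustained/not-sustained cutoff is calibrated, not derived; all
  fractions inherit its reference-cohort anchoring (the M1 wild-type
  fraction is close to the target by construction and is not
  independent evidence).
* The decay fit assumes a single-exponential envelope; strongly
  non-stationary trajectories (e.g. intermittent oscillators) are
  summarized poorly by any single rate.
* M3/M4's production split (ρ uniform) is a modeling choice the source
  ranges do not determine.
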