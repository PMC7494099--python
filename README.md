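# leakyclock

Circadian clocks keep time with transcription–translation feedback loops,
but the core clock proteins of plants and mammals are also removed by
targeted (E3-ligase / 26S-proteasome) degradation. Why carry both layers
of control? `leakyclock` implements a simulation study of that question
on repressilator-based minimal oscillators: it shows that a purely
transcriptional ring oscillates beautifully until its promoters leak —
a few percent of basal transcription is enough to lock the ring — while
coupling a targeted-degradation layer, especially through a coherent
feed-forward loop, lets the oscillator push leaked protein back and keep
time.

The package is aimed at systems-biology modelers: it provides the model
family, the random parameter search, an exact stochastic simulator, the
oscillation-quality metric, and the experiment orchestration, all as a
library with a thin CLI.

## The models and the metric

Each gene product follows `dP/dt = β·Hill − γ_total·P` with Hill
regulation (`κ`, integer `n`), nondimensionalized so every species'
maximal steady state is 1000 molecules (`β = 1000·γ`). Nine variants
couple a three-gene repression ring (X ⊣ Z ⊣ Y ⊣ X) to different control
layers: transcription only (M1), targeted degradation only (M2),
auto-positive feedback (M3/M4), both controls on the same edge (M5), and
degradation routed through dedicated controller genes forming coherent /
incoherent feed-forward loops, negative or positive feedback (CFFL,
IFFL, NF, PF).

Parameter sets are drawn log-uniformly over three decades, screened for
regular deterministic oscillation (>10 cycles, <5% cycle-to-cycle change
in period and amplitude), rescaled to a 24 h period, then expanded into
promoter/mRNA/protein reactions with fixed bursting statistics
(burst frequency 2, burst size 10) and simulated exactly with the
Gillespie algorithm for 30 days. Transcriptional leakage enters the
transcription propensity as `k_m·G·(basal·(1−Hill) + Hill)`.

Oscillation quality is the **normalized decay rate**: the autocorrelation
function of a protein trace is computed out to 10-day lags, its peak
values are fitted with `A + exp(−b·k)` against the number of periods
elapsed, and the fitted `b` (dimensionless, per period) measures how fast
phase noise destroys the rhythm — small is robust. A trajectory counts
as *sustained* when the fit succeeds on at least three peaks, `b` stays
below a calibrated threshold, and a damped-cosine fit of the full ACF
agrees. See `docs/methods.md` for the estimators and all defaults.

## Worked example

Search ten oscillating parameter sets for the coupled model M5, simulate
each one with and without 10% transcriptional leakage, and summarize:

```python
from leakyclock.pipeline import Condition, ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    model_id="M5",
    n_parameter_sets=10,
    conditions=[Condition("wild-type", 0.0), Condition("leak-10", 0.10)],
    master_seed=7,
)
result = run_experiment(cfg)
print(f"accepted {len(result.sets)} sets in {result.search.n_attempts} draws "
      f"(acceptance {result.search.acceptance_rate:.1%})")
for label, s in result.summaries.items():
    print(f"{label:10s} sustained {s['n_sustained']}/{s['n']} "
          f"median decay {s['median_decay']:.2f}")
```

Output:

```
accepted 10 sets in 116 draws (acceptance 8.6%)
wild-type  sustained 7/10 median decay 1.60
leak-10    sustained 6/10 median decay 2.26
```

Seven of ten deterministic oscillators keep a clean 24 h-class rhythm
under intrinsic molecular noise (median envelope decay 1.60 per period);
adding 10% promoter leakage costs one more set and visibly degrades the
survivors' decay rates. Run the same experiment with `model_id="M1"` and
the leak-10 fraction collapses instead of dipping — that contrast is the
study's central result. `result.records` holds the per-set metrics as a
DataFrame.

The same pipeline is scriptable from the shell:

```
leakyclock run --model M5 --n 10 --seed 7 --leakage 0.10 --out runs/m5
leakyclock motifs --resolution 41 --out runs/motifs
```

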