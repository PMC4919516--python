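# aobt — stimulus–response tuning analysis for single-unit recordings

`aobt` is an analysis toolkit for trial-structured single-unit
electrophysiology of chemosensory neurons, modelled on the standard workflow
for ex vivo accessory olfactory bulb (AOB) recordings: a stimulus panel
(urine, faecal extracts, pure bile acids, sulfated steroids, …) is delivered
to the vomeronasal organ in randomized interleaved trials while sorted
mitral-cell spike trains are recorded, and each cell's tuning across the
panel is quantified and compared at the population level.

The package implements, as tested reusable code:

- **ΔR response quantification** — for every trial, the change in firing
  rate `ΔR = R_response − R_baseline`, where `R_response` is the rate in a
  4 s window starting 1 s after stimulus onset and `R_baseline` the rate in
  the 5 s before onset.
- **Response-significance calling** — a cell×stimulus pair is a responder
  iff a two-sample Student's t-test of its per-trial ΔR values against the
  solvent-control (Ringer's) ΔR values gives *p* < 0.05 **and** the mean
  rate increase exceeds 1 Hz. Cells responding to the control, or to
  nothing, are excluded.
- **PSTHs** — trial-averaged peristimulus histograms over
  [−5 s, +15 s] in 1 s bins, with across-trial s.e.m.
- **Tuning normalization and population summaries** — per-cell ΔR scaled by
  the maximum absolute response; exclusive/both/other category percentages,
  response-overlap (Venn) region counts, and pairwise co-response matrices.
- **Consensus mean-shift clustering** — hundreds of non-deterministic
  k-means runs (random k, random init) compiled into a cell×cell
  co-assignment similarity matrix, which is then clustered by mean shift
  and optionally embedded with nonmetric 3-D MDS.
- **The d′ discriminability index and its population shuffle test** —

  ```
  d′ = |ΔR̄₁ − ΔR̄₂| / sqrt((σ₁² + σ₂²) / 2)
  ```

  with `ΔR̄ᵢ` the mean and `σᵢ²` the across-trial variance of ΔR for the two
  compared stimuli. The shuffle test builds (by default) 100,000 model
  populations in which each model cell pairs the stimulus-1 responses of one
  randomly drawn cell with the stimulus-2 responses of another, computes
  the model d′ distribution, and reports the fraction of model populations
  that a Kruskal–Wallis test finds statistically *lower* than the observed
  one — a high fraction means discriminability reflects systematic
  within-cell tuning rather than chance pairing of independent responses.
- **A Poisson spike-train simulator** with planted per-cell × per-stimulus
  effect sizes, so every stage has an exact parameter-recovery oracle.

See `docs/methods.md` for the full statistical specification, parameter
defaults and limitations.

## Worked example

Simulate a 12-cell session with three planted tuning archetypes
(urine-responsive, faeces-responsive, both; Δ = 9 Hz over a 1 Hz baseline),
then run the full chain:

```python
import aobt

cfg = aobt.GeneratorConfig(
    n_cells=12,
    stimulus_ids=["urine", "faeces"],
    effects={c: ({"urine": 9.0} if c % 3 == 0 else
                 {"faeces": 9.0} if c % 3 == 1 else
                 {"urine": 9.0, "faeces": 9.0}) for c in range(12)},
    baseline_rate=1.0,
    seed=5,
)
session = aobt.simulate_session(cfg)
results = aobt.ResponseModel(session).fit()
print(results.summary())

spec = aobt.TuningCategorySpec("urine", ("urine",), "faeces", ("faeces",))
print(aobt.classify_tuning(results.significance_table(), spec))

clusters = aobt.ConsensusClusterModel(results.tuning_matrix(),
                                      n_runs=200, seed=1).fit()
print(clusters.summary())

disc = aobt.DiscriminationModel.from_results(results, "urine", "faeces",
                                             n_model=10_000, seed=2).fit()
print(disc.summary())
```

Output:

```
Stimulus-response analysis
========================================
cells analysed:        12
cells included:        12
responders per stimulus (included cells):
  urine            9
  faeces           8
  ringers          0 (control)

             count  percent
urine_only       4     33.3
faeces_only      3     25.0
both             5     41.7
other            0      0.0

Consensus mean-shift clustering
========================================
cells:       12
base runs:   200 (k in (2, 12))
bandwidth:   1.236
clusters:    3
  cluster 0: 4 cells
  cluster 1: 4 cells
  cluster 2: 4 cells

Discriminability: urine vs faeces
========================================
cells:                  12
median observed d':     5.321
mean observed d':       4.889
model populations:      10000 (unit=trials)
fraction stat. lower:   24.1%
```

Reading the numbers: the significance caller recovers all 12 planted
responders with one extra co-response (9 + 8 calls vs the planted 8 + 8;
one faeces-only cell crossed threshold for urine as well) and no control
responses; classification therefore reports 4/3/5 cells ≈ 33.3 / 25.0 /
41.7 %. The consensus clustering recovers the three archetypes exactly.
The population's urine-vs-faeces d′ values are high (median 5.3) and 24.1%
of shuffled model populations are statistically lower — a small population
of 12 cells limits the power of the Kruskal–Wallis comparison.

The same chain is available from the shell:

```
aobt simulate --config generator.yaml --out session/
aobt analyze --session session/ --out results/
aobt cluster --tuning results/tuning.csv --runs 1000 --seed 0 --out results/
aobt discriminate --responses results/responses.csv \
    --stim-a urine --stim-b faeces --n-model 100000 --seed 0 --out results/
aobt report --config pipeline.yaml     # everything, plus figures + manifest
```

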