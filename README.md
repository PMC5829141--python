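# audlfp — auditory-LFP analysis: 40-Hz ASSR and paired-pulse inhibitory gating

`audlfp` is an analysis pipeline for epoched local field potentials (LFPs)
recorded during two classic auditory paradigms, built for the question of how
general anesthesia affects each read-out across brain regions (auditory
cortex AC, hippocampus HP, amygdala AMY, prefrontal cortex PFC):

* **Auditory steady-state response (ASSR).** A 0.5-s, 40-Hz click train
  entrains a gamma oscillation. From the per-trial complex Morlet
  coefficients `W_n(f, t)` the pipeline computes

  - *mean trial power* `MTP(f, t) = (1/N) Σ_n |W_n(f, t)|²`, and
  - *phase-locking factor* `PLF(f, t) = |(1/N) Σ_n W_n(f, t) / |W_n(f, t)||`
    (inter-trial coherence: 1 = perfect phase consistency, ≈ `√π/2·N^{-1/2}`
    for random phases),

  each summarized over the 35–45 Hz × 50–550 ms box.

* **Inhibitory gating (IG).** Two identical 80-ms noise bursts 500 ms apart
  (conditioning C, test T) evoke a biphasic deflection (AC: N25/P40;
  HP/AMY/PFC: N35/P70). Peaks are located in predefined windows of the
  120-trial average, measured relative to the waveform value at their
  stimulus onset, accepted only if they differ from a 1-s pre-stimulus
  control period (3 s before C) in a sliding-window t-test at p < 0.01, and
  summarized as the ratio `T/C = T-amp / C-amp` — values < 1 mean the
  response to the repeated stimulus is suppressed (gating).

Because no public recordings exist for this paradigm set, the package ships
a first-class synthetic-LFP generator (`audlfp.simulate`): 1/f background
noise plus a phase-jittered entrained oscillation (click trains) or Gaussian
evoked bumps with per-polarity gate factors (sound pairs). The region ×
condition presets encode the published representative values — gating
ratios 0.75/0.90 (AC conscious) down to 0.25/0.28 (PFC), ASSR strength
ordered AC > HP > AMY > PFC ≈ 0 — so every pipeline stage can be validated
by parameter recovery. Group statistics (one-way region ANOVA + Tukey HSD,
paired conscious-vs-anesthetized t-tests) complete the pipeline.

## Worked example

```python
from audlfp import RunConfig, make_session, assr_summary, compute_ig

config = RunConfig()                                   # analysis constants
clicks, pairs = make_session("AC", "conscious", seed=1)  # one synthetic session

mtp40, plf40 = assr_summary(clicks, config)
print(f"40-Hz ASSR summary (35-45 Hz x 50-550 ms): "
      f"MTP = {mtp40:.1f} uV^2, PLF = {plf40:.3f}")

ig = compute_ig(pairs, config)
for label, ratio in ig.tc_ratio.items():
    c, t = ig.peaks[label]["C"], ig.peaks[label]["T"]
    print(f"{label}: C-amp = {c.amplitude:+.1f} uV @ {c.latency*1e3:.0f} ms, "
          f"T-amp = {t.amplitude:+.1f} uV @ {t.latency*1e3:.0f} ms, "
          f"T/C = {ratio:.2f}")
```

prints

```
40-Hz ASSR summary (35-45 Hz x 50-550 ms): MTP = 294.9 uV^2, PLF = 0.846
N25: C-amp = -31.3 uV @ 25 ms, T-amp = -24.6 uV @ 25 ms, T/C = 0.79
P40: C-amp = +21.3 uV @ 40 ms, T-amp = +21.5 uV @ 41 ms, T/C = 1.01
```

The strong 40-Hz power and phase locking are the entrained steady-state
response of an awake auditory-cortex site; the N25 ratio of 0.79 shows mild
gating around this session's generative value of 0.75, while single-session
scatter (here P40 at 1.01 vs a generative 0.90) is why ratios are averaged
over sessions before any comparison.

## The analysis, step by step

The numbered drivers under `analysis/` rebuild the full study on a synthetic
cohort (10 sessions per region × condition cell, seed 1) and write plain-TSV
tables under `results/`:

1. `01_simulate_cohort.py` — simulate the cohort (epoch containers go to
   `scratch/`, the generative preset table to `results/presets.tsv`),
2. `02_assr_summaries.py` — wavelet MTP/PLF band summaries per session,
3. `03_gating_ratios.py` — evoked peaks and T/C ratios per session,
4. `04_group_stats.py` — region ANOVA + Tukey and paired condition tests,
   plus `results/report.txt`.

On the shipped seed the chain reproduces the three qualitative findings:
conscious 40-Hz MTP/PLF ordered AC > HP > AMY > PFC; anesthesia
significantly reduces MTP and PLF in AC, HP and AMY; no T/C ratio differs
significantly between conditions in any region.

The same chain is available as a CLI (`audlfp run --synthetic --sessions 10
--seed 1 --outdir out/`), with subcommands `simulate`, `assr`, `gating` and
`stats` for the individual stages.

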