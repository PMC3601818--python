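# vmsync

Quantification of Ca²⁺ transient synchrony in the *C. elegans* egg-laying
vulval muscles from dual-channel ratiometric imaging.

The vulval muscles form anterior (A) and posterior (P) compartments that
contract together during egg laying. In wild-type animals the vm2 muscle
arms couple the compartments electrically, so Ca²⁺ transients appear on
both sides at once; mutants lacking the arms (e.g. Notch-pathway mutants)
fire the two compartments independently, with more peaks and a long A/P
delay. `vmsync` measures exactly that, end to end:

- **synthgen** — a ground-truthed simulator of two-compartment recordings
  (event logs → ideal ΔR/R traces → rendered GCaMP/mCherry voxel movies),
  with wild-type and decoupled-mutant scenarios calibrated to the published
  physiology;
- **ratiometry** — movie → ΔR/R: background estimation, per-frame selection
  of voxels with mCherry 2 sd above background, mean per-voxel GCaMP/mCherry
  ratio, 150 ms (3-point) rolling average, baseline from the lowest 10% of
  smoothed ratio values (ΔR/R = (R − R₀)/R₀);
- **transients** — peak detection (ΔR/R ≥ 15%, prominence ≥ 0.10, ≥ 250 ms
  apart), greedy chronological A/P pairing within a 2 s body-bend window,
  classification into `single_A` / `single_P` / `double_sync` (pairs closer
  than 250 ms, delay defined as 0) / `double_delayed` (delay = |t_P − t_A|),
  twitch vs egg-laying magnitude split at 150% ΔR/R, and per-recording
  summaries (merged peaks/min, synchronous fraction, mean delay);
- **stats** — genotype aggregation with 95% CIs (t for animal-level means,
  Wilson for pooled proportions), one-way ANOVA, chi-squared, and a
  Fisher–Freeman–Halton exact test for egg developmental-stage tables;
- **morphometry** — shoelace polygon areas, vm2/vm1 size ratios, and
  muscle-axis/vulval-slit intersection angles folded into [0°, 90°].

See `docs/methods.md` for the model, conventions and calibration, and
`examples/` for one short script per capability.

## Worked example

Simulate a wild-type animal (6 min at 20 Hz) and classify its transients
(`examples/01_simulate_and_classify.py`):

```python
import vmsync as v

cfg = v.wildtype(seed=1)
events = v.sample_events(cfg)
traces = v.render_traces(events, cfg)
dA = v.DeltaTrace(traces.time_s, traces.dRR_A, baseline_R0=1.0, compartment="A")
dP = v.DeltaTrace(traces.time_s, traces.dRR_P, baseline_R0=1.0, compartment="P")
transients, summary = v.analyze_recording(dA, dP)
```

prints

```
ground-truth events:        33
classified transients:      33
  synchronous doubles:      32
  delayed doubles:          1
  singles:                  0
merged peaks / min:         5.67
mean A/P delay:             41 ms
```

Every simulated event was recovered and classified; 32 of 33 doubles were
unresolvable (<250 ms apart) and contribute 0 s to the mean delay, so this
coupled recording shows a mean A/P delay of tens of milliseconds. Across a
cohort (`examples/03_genotype_comparison.py`, 11 wild-type + 12 mutant
animals):

```
wild type         n=11  peaks/min  5.38  sync fraction 0.92  mean delay  86.3 ms (95% CI 53.8-118.7)
decoupled mutant  n=12  peaks/min 11.03  sync fraction 0.00  mean delay 818.3 ms (95% CI 790.0-846.5)
peak-frequency fold change (mutant/wt): 2.05
```

— the decoupled scenario doubles the peak frequency (each double now
resolves into two peaks) and shifts the pooled mean delay from ~0.1 s to
~0.8 s, with the synchronous-double fraction collapsing to zero.

## Command line

A thin CLI wraps the library for shell use:

```sh
vmsync simulate --scenario wildtype --mode movie --seed 1 --out run1/
vmsync extract  --gcamp run1/gcamp.tif --mcherry run1/mcherry.tif \
                --rois run1/rois.json --fps 20 --out run1/traces_extracted.csv
vmsync analyze  --traces run1/traces_extracted.csv --out run1/
vmsync summarize --summaries runs/ --out genotypes.json
vmsync eggstats --table eggs.csv --out eggstats.json
vmsync morpho   --polygons polygons.csv --landmarks landmarks.csv --out morpho.csv
vmsync all      --scenario mutant --mode trace --seed 3 --out run3/
```

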