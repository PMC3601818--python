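"""Compare a wild-type and a decoupled-mutant cohort.

Simulates 11 wild-type and 12 mutant animals (6 min each, trace mode),
aggregates per-animal summaries into genotype statistics with 95%
confidence intervals, and runs the cohort-level hypothesis tests.
"""

import vmsync as v


def cohort(make_config, seeds, label):
    summaries, delays = [], []
    for seed in seeds:
        cfg = make_config(seed=seed)
        events = v.sample_events(cfg)
        tr = v.render_traces(events, cfg)
        dA = v.DeltaTrace(tr.time_s, tr.dRR_A, 1.0, "A")
        dP = v.DeltaTrace(tr.time_s, tr.dRR_P, 1.0, "P")
        transients, s = v.analyze_recording(dA, dP)
        summaries.append(s)
        delays.append([t.delay_s for t in transients if t.category == "double_delayed"])
    return v.aggregate_genotype(summaries, label, per_recording_delays=delays), summaries


wt, wt_s = cohort(v.wildtype, range(1, 12), "wild type")
mut, mut_s = cohort(v.mutant, range(1, 13), "decoupled mutant")

for g in (wt, mut):
    lo, hi = g.ci_delay_s
    print(
        f"{g.label:17s} n={g.n_animals:2d}  "
        f"peaks/min {g.mean_peaks_per_min:5.2f}  "
        f"sync fraction {g.frac_sync_double:.2f}  "
        f"mean delay {1000 * g.mean_delay_s:5.1f} ms "
        f"(95% CI {1000 * lo:.1f}-{1000 * hi:.1f})"
    )

fold = mut.mean_peaks_per_min / wt.mean_peaks_per_min
print(f"peak-frequency fold change (mutant/wt): {fold:.2f}")

p_anova = v.compare_frequencies(
    [[s.peaks_per_min for s in wt_s], [s.peaks_per_min for s in mut_s]]
)
wt_sync = sum(s.n_double_sync for s in wt_s)
mut_sync = sum(s.n_double_sync for s in mut_s)
table = [
    [wt_sync, wt.n_transients - wt_sync],
    [mut_sync, mut.n_transients - mut_sync],
]
p_chi2 = v.compare_sync_fractions(table)
print(f"one-way ANOVA on peaks/min: p = {p_anova:.2e}")
print(f"chi-squared on sync vs non-sync counts: p = {p_chi2:.2e}")

# Decoupling doubles the peak frequency (every double now resolves into
# two peaks) and moves the pooled mean delay from ~0.1 s to ~0.8 s.
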