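"""Simulate one wild-type animal and classify its Ca2+ transients.

Generates a 6-minute, 20 Hz two-compartment recording in trace mode,
detects dR/R peaks above 15%, pairs anterior/posterior peaks, and prints
the per-recording summary.
"""

import vmsync as v

cfg = v.wildtype(seed=1)
events = v.sample_events(cfg)
traces = v.render_traces(events, cfg)
dA = v.DeltaTrace(traces.time_s, traces.dRR_A, baseline_R0=1.0, compartment="A")
dP = v.DeltaTrace(traces.time_s, traces.dRR_P, baseline_R0=1.0, compartment="P")
transients, summary = v.analyze_recording(dA, dP)

print(f"ground-truth events:        {len(events)}")
print(f"classified transients:      {summary.n_transients}")
print(f"  synchronous doubles:      {summary.n_double_sync}")
print(f"  delayed doubles:          {summary.n_double_delayed}")
print(f"  singles:                  {summary.n_single_A + summary.n_single_P}")
print(f"merged peaks / min:         {summary.peaks_per_min:.2f}")
print(f"mean A/P delay:             {summary.mean_delay_s * 1000:.0f} ms")

# In a coupled (wild-type-like) muscle pair nearly every transient involves
# both compartments and is unresolvable (<250 ms apart), so the synchronous
# fraction is high and the mean delay is tens of milliseconds: unresolved
# doubles are defined to contribute 0 s.
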