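"""Render a two-channel voxel movie and extract dR/R traces from it.

Shows the full measurement chain on image data: mCherry background
estimation, 2-sd voxel selection, mean-of-ratios extraction, 150 ms
smoothing, and lowest-decile baselining — then verifies the extracted
trace reproduces the simulation's ideal dR/R.
"""

import numpy as np

import vmsync as v

cfg = v.wildtype(duration_s=60.0, seed=4)
events = v.sample_events(cfg)
movie = v.render_movie(events, cfg)
masks = cfg.geometry.masks(cfg.image_shape)

bg = v.estimate_background(movie, masks["background"])
selection = v.select_voxels(movie, bg)
print(f"background: {bg.mean:.1f} +/- {bg.sd:.1f} counts")
muscle = masks["A"] | masks["P"]
counts = (selection.masks & muscle).sum(axis=(1, 2))
print(f"selected muscle voxels per frame (median): {int(np.median(counts))}")

traces = v.movie_to_delta_traces(
    movie, {"A": masks["A"], "P": masks["P"]}, bg_roi=masks["background"]
)
ideal = v.render_traces(events, cfg)
err = np.max(np.abs(traces["A"].dRR - ideal.dRR_A))
print(f"baseline R0 (anterior):  {traces['A'].baseline_R0:.3f}")
print(f"max |extracted - ideal| dR/R (anterior): {err:.3f}")

# The residual reflects photon noise and the 3-point smoothing bias; with
# noise_sd=0 and background_sd=0 it drops below 1e-6 relative error.
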