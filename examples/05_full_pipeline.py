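"""End-to-end pipelines: trace-based and image-based analysis paths.

`run_traces` reproduces the whole-nucleolus fluctuation analysis (CV,
periodogram, dominant period, nucleoplasm correlation) from a simulated
measurement table; `run_images` renders stacks per fixation time point,
detects units and reports the 15->30 min burst statistics.  Outputs (CSVs,
summary JSON, manifest) land in the chosen output directories.
"""

import json

import nucleoflux as nf
from nucleoflux.pipeline import preset_config, run_images, run_traces

summary = run_traces(preset_config("hela_sync", seed=1, outdir="scratch/example_traces"))
print("trace pipeline (hela_sync):")
print(json.dumps({k: summary[k] for k in
                  ("cv_nucleolar", "cv_nucleoplasmic", "dominant_period_min",
                   "period_interval_min", "correlation_nucleolus_nucleoplasm",
                   "fold_change_15_30")}, indent=2))

img_cfg = preset_config(
    "hela_sync",
    seed=1,
    outdir="scratch/example_images",
    scene=nf.SceneConfig(shape=(11, 96, 96), units_per_cell=8, nucleoplasmic_foci=10),
    kinetics=nf.hela_config(timepoints=(15, 30, 45, 60)),
)
img = run_images(img_cfg)
print("image pipeline (4 time points, small fields):")
print(json.dumps({
    "mean_unit_intensity": {k: round(v, 1) for k, v in img["mean_unit_intensity"].items()},
    "mean_unit_count": img["mean_unit_count"],
    "fold_change_15_30": round(img["unit_intensity_fold_change_15_30"], 2),
    "t_test_p": img["students_t_15_vs_30"]["p"],
}, indent=2))
print()
print("The unit intensities rise ~3x from 15 to 30 min while the unit count")
print("stays flat - the undulation modulates per-gene output, not the number")
print("of active transcription units.")
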