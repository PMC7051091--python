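"""Render a synthetic confocal stack and detect/quantify FC/DFC units.

Renders one default field (nucleus, two nucleoli, 30 diffraction-limited
units, dim nucleoplasmic foci, Poisson + read noise), runs the detection
pipeline, and scores it against the planted ground truth.  A second pair of
scenes at the cold-block residual level (60%) vs normal shows that the
measured mean unit intensity recovers the planted ratio.
"""

import numpy as np

import nucleoflux as nf

scene = nf.SceneConfig()
params = nf.DetectionParams()

stack, truth = nf.render_scene(scene, level=1.0, seed=7)
records = nf.detect_units(stack, params)
match = nf.match_to_ground_truth(records, truth, radius=2.0, z_aspect=scene.z_aspect)

print(f"planted units: {match['n_true']}, detected: {match['n_detected']}")
print(f"recall {match['recall']:.2f}, precision {match['precision']:.2f}, "
      f"localization error {match['mean_localization_error']:.2f} px")
best = records[0]
print(f"brightest unit: x={best.x:.1f} y={best.y:.1f} z={best.z:.1f}, "
      f"FWHM {best.fwhm:.2f} px, chi2 {best.chi2:.3f}, I(1.5px) {best.integral(1.5):.0f}")

means = {}
for name, level in (("normal", 1.0), ("cold", 0.6)):
    st, _ = nf.render_scene(scene, level=level, seed=11)
    recs = nf.detect_units(st, params)
    means[name] = np.mean([r.integral(params.report_radius) for r in recs])
print(f"cold/normal mean unit intensity: {means['cold'] / means['normal']:.2f} "
      "(planted 0.60: pol I signal drops to ~60% at +4 C)")
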