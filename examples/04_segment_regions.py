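"""Segment nucleus / nucleoli / nucleoplasm and measure the compartments.

Works on the maximum intensity projection: nuclei by blurred multi-Otsu,
nucleoli by a second Otsu restricted to within-nucleus pixels; the
nucleoplasm is the nucleus minus its nucleoli.  Integral intensities are
additive across the partition, and the nucleolar average is far above the
nucleoplasmic one, as in real transcription-signal images.
"""

import nucleoflux as nf

stack, _ = nf.render_scene(nf.SceneConfig(), level=1.0, seed=7)
nucleus = nf.segment_nucleus(stack)
nucleoli = nf.segment_nucleoli(stack, nucleus)
nplasm = nf.nucleoplasm_mask(nucleus, nucleoli)

m_nucleus = nf.measure_region(stack, nucleus, 1)
print(f"nucleus:      area {m_nucleus.area} px, integral {m_nucleus.integral:.0f}, "
      f"average {m_nucleus.average:.1f}")
total_parts = 0.0
for label in nucleoli.label_ids:
    m = nf.measure_region(stack, nucleoli, label)
    total_parts += m.integral
    print(f"nucleolus {label}:  area {m.area} px, integral {m.integral:.0f}, "
          f"average {m.average:.1f}")
m_np = nf.measure_region(stack, nplasm, 1)
total_parts += m_np.integral
print(f"nucleoplasm:  area {m_np.area} px, integral {m_np.integral:.0f}, "
      f"average {m_np.average:.1f}")
print(f"additivity: nucleoli + nucleoplasm = {total_parts:.0f} "
      f"(nucleus integral {m_nucleus.integral:.0f})")
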