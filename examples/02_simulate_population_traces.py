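"""Population simulation: synchronized release vs untreated control.

Simulates the fixed-cell design (8 experiments x 50 fresh cells per
fixation time point) for the synchronized HeLa preset and for the
random-phase control, and compares the fluctuation statistics that
distinguish them: the trace CV and the periodogram amplitude.  Also shows
the coupled nucleoplasmic signal and its correlation with the nucleoli.
"""

import nucleoflux as nf

SEED = 1

for name, cfg in (
    ("synchronized (HeLa)", nf.hela_config()),
    ("control (random phase)", nf.hela_config(phase_mode="random")),
):
    table = nf.simulate_traces(cfg, nf.NucleoplasmConfig(), seed=SEED)
    tc = nf.assemble_timecourse(table, "nucleolar")
    pg = nf.periodogram(tc)
    print(f"{name}:")
    print(f"  nucleolar trace CV     {nf.coefficient_of_variation(tc):.3f}")
    print(f"  max Fourier amplitude  {pg.amplitudes.max():.1f}")
    if name.startswith("synchronized"):
        print(f"  dominant period        {nf.dominant_period(pg):.0f} min")
        tc_np = nf.assemble_timecourse(table, "nucleoplasmic")
        r = nf.pearson_correlation(tc, tc_np)
        print(f"  nucleoplasm trace CV   {nf.coefficient_of_variation(tc_np):.3f}")
        print(f"  nucleolus-nucleoplasm r {r:.2f}")

print()
print("Synchronized populations undulate coherently (CV ~0.26-0.29, strong")
print("periodogram peak); in the control the per-cell phases average out and")
print("only batch noise remains (CV ~0.07, weak flat periodogram).")
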