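"""Simulation of per-cell intensity measurements under the fixed-cell design.

Each fixation time point samples *fresh* cells (the real cells were fixed
and immunostained), so the simulated table is a population snapshot per
time point, not a set of single-cell trajectories.  Noise model:

* per-cell multiplicative lognormal brightness (staining/expression
  heterogeneity), mean 1, CV ``cell_brightness_cv``;
* per-cell additive Gaussian measurement noise, CV ``cell_noise_cv``;
* per-time-point multiplicative batch factor, SD ``batch_sd`` — one
  fixation/staining session per time point, shared by every cell measured
  at it;
* nucleoplasmic signal: coupled mean ``B*(1 + beta*(M(t)-1))`` with its own
  shared per-time-point noise (SD ``shared_noise_sd``) and per-cell noise.

In ``phase_mode="random"`` (untreated control) each cell oscillates with
its own uniform phase and there is no recovery ramp, so per-time-point
means fluctuate only through the noise terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import check_seed, substream
from .kinetics import KineticsConfig, NucleoplasmConfig, damping_amplitude, mean_kinetics

__all__ = ["simulate_traces", "MEASUREMENT_COLUMNS"]

#: Column layout of a MeasurementTable.
MEASUREMENT_COLUMNS = ["experiment", "cell", "timepoint_min", "compartment", "intensity"]


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def simulate_traces(
    cfg: KineticsConfig | None = None,
    np_cfg: NucleoplasmConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a measurement table of per-cell compartment intensities.

    Returns a long-format :class:`pandas.DataFrame` with columns
    ``experiment, cell, timepoint_min, compartment, intensity`` where
    compartment is ``"nucleolar"`` or ``"nucleoplasmic"``.  Identical
    (cfg, np_cfg, seed) always gives a bit-identical table.
    """
    cfg = cfg or KineticsConfig()
    np_cfg = np_cfg or NucleoplasmConfig()
    seed = check_seed(seed)

    tps = np.asarray(cfg.timepoints)
    n_t, n_e, n_c = len(tps), cfg.experiments, cfg.cells_per_experiment
    shape = (n_e, n_t, n_c)

    r_bright = substream(seed, "brightness")
    r_noise = substream(seed, "cell-noise")
    r_batch = substream(seed, "batch")
    r_phase = substream(seed, "phase")
    r_shared = substream(seed, "np-shared")
    r_npnoise = substream(seed, "np-cell-noise")

    # one staining/imaging session per fixation time point
    batch = r_batch.normal(0.0, cfg.batch_sd, size=n_t)
    np_shared = r_shared.normal(0.0, np_cfg.shared_noise_sd, size=n_t)

    if cfg.phase_mode == "synchronized":
        m = np.broadcast_to(mean_kinetics(tps, cfg)[None, :, None], shape)
    else:
        # each cell has its own phase; no recovery ramp
        phi = r_phase.uniform(0.0, 2.0 * np.pi, size=shape)
        amp = damping_amplitude(tps, cfg)[None, :, None]
        m = 1.0 + amp * np.cos(phi)

    bright = _lognormal_unit_mean(r_bright, cfg.cell_brightness_cv, shape)
    meas = r_noise.normal(0.0, cfg.cell_noise_cv, size=shape)
    nucleolar = (
        cfg.baseline * m * bright * (1.0 + meas) * (1.0 + batch[None, :, None])
    )

    np_meas = r_npnoise.normal(0.0, np_cfg.cell_noise_cv, size=shape)
    nucleoplasmic = (
        cfg.baseline
        * (1.0 + np_cfg.coupling * (m - 1.0))
        * (1.0 + np_shared[None, :, None])
        * (1.0 + np_meas)
    )

    exp_idx, tp_idx, cell_idx = np.meshgrid(
        np.arange(1, n_e + 1), np.arange(n_t), np.arange(1, n_c + 1), indexing="ij"
    )
    base = pd.DataFrame(
        {
            "experiment": exp_idx.ravel(),
            "cell": cell_idx.ravel(),
            "timepoint_min": tps[tp_idx.ravel()],
        }
    )
    frames = []
    for comp, values in (("nucleolar", nucleolar), ("nucleoplasmic", nucleoplasmic)):
        f = base.copy()
        f["compartment"] = comp
        f["intensity"] = values.ravel()
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    return table[MEASUREMENT_COLUMNS]
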