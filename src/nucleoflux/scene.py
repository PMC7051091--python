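"""Synthetic confocal scene renderer with ground truth.

Emulates the appearance of FU/pol I immunofluorescence stacks: a dim
nuclear background, 1-3 bright nucleoli containing diffraction-limited
FC/DFC "beads" (3D Gaussian spots), many much dimmer nucleoplasmic foci,
and Poisson + Gaussian read noise.  Spot amplitudes scale linearly with a
relative intensity ``level`` (normally the kinetics value M(t)), and every
planted spot is listed in a ground-truth table, so detection and
quantification can be scored exactly.

The renderer is a stand-in for image acquisition, not an optics model: no
PSF tails beyond a Gaussian, no depth-dependent aberration, no bleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from ._rng import check_seed, substream
from .image import ImageStack
from .kinetics import KineticsConfig, mean_kinetics

__all__ = [
    "SceneConfig",
    "GROUND_TRUTH_COLUMNS",
    "StackSample",
    "render_scene",
    "simulate_timecourse_stacks",
]

GROUND_TRUTH_COLUMNS = ["cell", "x", "y", "z", "amplitude"]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, photometry and noise of one rendered field.

    ``shape`` is (nz, ny, nx); z is the slowest axis as stored in multi-page
    TIFFs.  Amplitudes are in the same arbitrary units as the camera offset.
    """

    shape: tuple = (21, 256, 256)
    z_aspect: float = 3.0
    n_cells: int = 1
    nucleoli_per_cell: int = 2
    units_per_cell: int = 30
    nucleolus_radius: float = 24.0
    spot_sigma_xy: float = 1.3
    spot_sigma_z: float = 0.8
    spot_amplitude: float = 150.0
    unit_brightness_cv: float = 0.3
    nucleolar_diffuse_frac: float = 0.15
    nucleus_glow_frac: float = 0.05
    nucleoplasmic_foci: int = 100
    focus_amplitude_frac: float = 0.10
    offset: float = 10.0
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0
    min_spot_separation: float = 7.0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be a positive (nz, ny, nx) triple")
        if self.z_aspect <= 0:
            raise ValueError("z_aspect must be positive")
        if self.spot_sigma_xy <= 0 or self.spot_sigma_z <= 0:
            raise ValueError("spot sigmas must be positive")
        for name in ("nucleolar_diffuse_frac", "nucleus_glow_frac", "focus_amplitude_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 1 or self.nucleoli_per_cell < 1 or self.units_per_cell < 0:
            raise ValueError("counts must be positive")


def _cell_layout(scene: SceneConfig):
    """Tile the field into per-cell regions; returns (tile_h, tile_w, origins)."""
    nz, ny, nx = scene.shape
    grid = int(np.ceil(np.sqrt(scene.n_cells)))
    tile_h, tile_w = ny // grid, nx // grid
    if min(tile_h, tile_w) < 48:
        raise ValueError("shape too small to contain a nucleus per cell")
    origins = []
    for c in range(scene.n_cells):
        gy, gx = divmod(c, grid)
        origins.append((gy * tile_h, gx * tile_w))
    return tile_h, tile_w, origins


def _add_gaussian_spot(signal, x0, y0, z0, amp, sxy, sz):
    """Accumulate a 3D Gaussian of peak *amp* centred at (x0, y0, z0)."""
    nz, ny, nx = signal.shape
    hw, hz = int(np.ceil(4 * sxy)) + 1, int(np.ceil(4 * sz)) + 1
    xlo, xhi = max(0, int(x0) - hw), min(nx, int(x0) + hw + 1)
    ylo, yhi = max(0, int(y0) - hw), min(ny, int(y0) + hw + 1)
    zlo, zhi = max(0, int(z0) - hz), min(nz, int(z0) + hz + 1)
    if xlo >= xhi or ylo >= yhi or zlo >= zhi:
        return
    gx = np.exp(-0.5 * ((np.arange(xlo, xhi) - x0) / sxy) ** 2)
    gy = np.exp(-0.5 * ((np.arange(ylo, yhi) - y0) / sxy) ** 2)
    gz = np.exp(-0.5 * ((np.arange(zlo, zhi) - z0) / sz) ** 2)
    signal[zlo:zhi, ylo:yhi, xlo:xhi] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _place_units(rng, centers, radius, z_center, z_half, n_units, min_sep):
    """Sample unit positions inside the nucleolar volumes with a minimum
    pairwise *lateral* distance: units are distinct beads, and beads that
    coincide in xy are indistinguishable on a maximum intensity projection
    regardless of their z separation."""
    placed = []
    inner = 0.8 * radius
    for k in range(n_units):
        cy, cx = centers[k % len(centers)]
        best = None
        best_d = -1.0
        for _ in range(400):
            r = inner * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(th), cy + r * np.sin(th)
            z = z_center + rng.uniform(-z_half, z_half)
            if placed:
                d = min(
                    np.sqrt((x - px) ** 2 + (y - py) ** 2) for px, py, pz in placed
                )
            else:
                d = np.inf
            if d >= min_sep:
                best = (x, y, z)
                break
            if d > best_d:
                best_d, best = d, (x, y, z)
        placed.append(best)
    return placed


def render_scene(
    scene: SceneConfig | None = None, level: float = 1.0, seed: int = 0
):
    """Render one field at relative intensity *level*.

    Returns ``(ImageStack, ground_truth)`` where the ground truth is a
    DataFrame with one row per planted FC/DFC unit (columns
    ``cell, x, y, z, amplitude``; coordinates 0-based, x = column,
    y = row, z = slice).  All spot amplitudes are proportional to *level*;
    the amplitude random draws do not depend on *level*, so two scenes with
    the same seed at different levels have exactly proportional truths.
    """
    scene = scene or SceneConfig()
    if level < 0:
        raise ValueError("level must be non-negative")
    seed = check_seed(seed)

    nz, ny, nx = scene.shape
    tile_h, tile_w, origins = _cell_layout(scene)
    r_geom = substream(seed, "geometry")
    r_amp = substream(seed, "amplitude")
    r_noise = substream(seed, "noise")

    signal = np.zeros(scene.shape, dtype=float)
    yy, xx = np.mgrid[0:ny, 0:nx]
    zc_n = (nz - 1) / 2.0
    truth_rows = []

    for cell_id, (oy, ox) in enumerate(origins, start=1):
        cy = oy + tile_h / 2.0 + r_geom.uniform(-3, 3)
        cx = ox + tile_w / 2.0 + r_geom.uniform(-3, 3)
        ay, ax = 0.40 * tile_h, 0.42 * tile_w
        nucleus = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

        # nucleoli on a ring around the nucleus centre, non-touching
        rad = min(scene.nucleolus_radius, 0.30 * min(ay, ax))
        k = scene.nucleoli_per_cell
        ring = 0.45 * min(ay, ax) if k > 1 else 0.0
        phase0 = r_geom.uniform(0, 2 * np.pi)
        centers = [
            (
                cy + ring * np.sin(phase0 + 2 * np.pi * j / k),
                cx + ring * np.cos(phase0 + 2 * np.pi * j / k),
            )
            for j in range(k)
        ]
        z_half_vox = rad / scene.z_aspect
        nucleolus_2d = np.zeros((ny, nx), dtype=bool)
        for ncy, ncx in centers:
            nucleolus_2d |= (yy - ncy) ** 2 + (xx - ncx) ** 2 <= rad**2

        # diffuse structures
        glow = scene.nucleus_glow_frac * scene.spot_amplitude * level
        signal[:, nucleus] += glow
        diffuse = scene.nucleolar_diffuse_frac * scene.spot_amplitude * level
        for z in range(nz):
            dz = (z - zc_n) / max(z_half_vox, 1e-9)
            if abs(dz) <= 1.0:
                shrink = np.sqrt(max(0.0, 1.0 - dz**2))
                for ncy, ncx in centers:
                    disk = (yy - ncy) ** 2 + (xx - ncx) ** 2 <= (rad * shrink) ** 2
                    signal[z][disk] += diffuse

        # FC/DFC units: bright separated beads inside the nucleoli
        spots = _place_units(
            r_geom,
            centers,
            rad,
            zc_n,
            0.6 * z_half_vox,
            scene.units_per_cell,
            scene.min_spot_separation,
        )
        draws = _lognormal_unit_mean(r_amp, scene.unit_brightness_cv, len(spots))
        for (x, y, z), d in zip(spots, draws):
            amp = scene.spot_amplitude * level * d
            _add_gaussian_spot(
                signal, x, y, z, amp, scene.spot_sigma_xy, scene.spot_sigma_z
            )
            truth_rows.append((cell_id, x, y, z, amp))

        # dim nucleoplasmic foci (appearance only; not ground-truth units)
        focus_amp = scene.focus_amplitude_frac * scene.spot_amplitude * level
        n_foci = scene.nucleoplasmic_foci
        placed = 0
        while placed < n_foci:
            y = r_geom.uniform(cy - ay, cy + ay)
            x = r_geom.uniform(cx - ax, cx + ax)
            if ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 > 1.0:
                continue
            if any((y - ncy) ** 2 + (x - ncx) ** 2 <= (rad + 3) ** 2 for ncy, ncx in centers):
                continue
            z = r_geom.uniform(0, nz - 1)
            _add_gaussian_spot(
                signal, x, y, z, focus_amp, scene.spot_sigma_xy, scene.spot_sigma_z
            )
            placed += 1

    clean = signal + scene.offset
    if scene.poisson_gain > 0:
        noisy = r_noise.poisson(clean * scene.poisson_gain) / scene.poisson_gain
    else:
        noisy = clean
    if scene.read_noise_sd > 0:
        noisy = noisy + r_noise.normal(0.0, scene.read_noise_sd, size=clean.shape)
    voxels = np.clip(noisy, 0.0, None)

    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return ImageStack(voxels, z_aspect=scene.z_aspect), truth


def _lognormal_unit_mean(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


@dataclass
class StackSample:
    """One rendered fixation sample: time point, stack and its ground truth."""

    timepoint_min: float
    stack: ImageStack
    truth: pd.DataFrame


def simulate_timecourse_stacks(
    cfg: KineticsConfig | None = None,
    scene: SceneConfig | None = None,
    seed: int = 0,
    stacks_per_timepoint: int = 1,
    cold: bool = False,
) -> List[StackSample]:
    """Render stacks for every fixation time point of the kinetics design.

    Spot amplitudes follow ``M(t)`` (times ``cfg.cold_factor`` when *cold*),
    emulating fixation of fresh fields at each time point.  Per-stack seeds
    are derived from the root seed only, so a cold and a normal run with the
    same seed are voxel-wise paired except for the amplitude scale.
    """
    cfg = cfg or KineticsConfig()
    scene = scene or SceneConfig()
    seed = check_seed(seed)
    if stacks_per_timepoint < 1:
        raise ValueError("stacks_per_timepoint must be >= 1")
    if len(cfg.timepoints) == 0:
        raise ValueError("timepoints must be non-empty")

    child = substream(seed, "stack-seeds").integers(
        0, 2**31 - 1, size=(len(cfg.timepoints), stacks_per_timepoint)
    )
    samples = []
    for j, t in enumerate(cfg.timepoints):
        level = mean_kinetics(t, cfg) * (cfg.cold_factor if cold else 1.0)
        for k in range(stacks_per_timepoint):
            stack, truth = render_scene(scene, level=level, seed=int(child[j, k]))
            truth = truth.copy()
            truth.insert(0, "timepoint_min", float(t))
            samples.append(StackSample(float(t), stack, truth))
    return samples
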