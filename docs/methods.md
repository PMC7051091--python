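# Methods

This note documents the models, calibrations and numerical choices behind
`nucleoflux`, in the spirit of a methods appendix: what is simulated, what
is measured, and where the design was genuinely open.

## 1. Mean kinetics of cold-released transcription

Cold block arrests pol I transcription and partially depletes pol I from
the FC/DFC units; release restarts transcription nearly in phase across
the population. The population-mean signal is modelled as

    M(t) = ramp(t) * (1 + a(t) * cos(2*pi*(t - t_peak)/T))
    ramp(t) = min(t / ramp_end, 1)
    a(t)    = a0                            t <= t_peak
            = a0 * exp(-(t - t_peak)/tau)   t >  t_peak

This is the *minimal* parametric form consistent with the observed facts:
an initial recovery limited to the first ~30 min, maxima of the sampled
trace at 30/90/150 min, a threefold rise between 15 and 30 min, and loss of
population synchrony (damping) after roughly two cycles. No mechanistic
claim is attached to the cosine; it is a phase-averaged description of an
undulating population.

Parameter defaults and their provenance:

| parameter | default | units | fixed by |
|---|---|---|---|
| T (period) | 60 | min | dominant periodogram peak |
| t_peak | 30 | min | first observed maximum |
| ramp_end | 30 | min | recovery complete by ~30 min |
| a0 (amplitude) | 0.5 | – | threefold 15→30 ratio: with the ramp at 0.5 and the cosine at quadrature, M(15) = 0.5; M(30) = 1 + a0 = 1.5 requires a0 = 0.5 |
| tau (HeLa) | 75 | min | trace CV ≈ 0.26 (computed CV of the noiseless ten-point trace: 0.2676) |
| tau (LEC) | 120 | min | trace CV ≈ 0.29 (computed: 0.2924) — the more pronounced undulation of limbal cells |
| B (baseline) | 100 | a.u. | arbitrary intensity scale |
| cold_factor | 0.6 | – | pol I signal retained at +4 °C (~60% of control) |

Note a0 and the two tau values are *jointly* pinned by the fold change and
the CVs; they were fixed once from those closed-form identities, not fitted.

## 2. Fixed-cell population simulator

Cells are fixed, so each fixation time draws **fresh** cells; simulated
traces are population snapshots, never single-cell trajectories. Noise
model (all multiplicative factors have mean 1):

* per-cell lognormal brightness, CV 0.2 — staining/expression
  heterogeneity;
* per-cell Gaussian measurement noise, CV 0.1;
* per-time-point batch factor, SD 0.07, shared by **all** cells measured at
  that time point (one fixation/staining session per time point). This
  term is what gives the unsynchronized control its residual trace CV of
  ~0.07: with 400 cells per point, cell-level noise averages to ~0.01 and
  only the session factor survives pooling. Drawing it per experiment
  instead would shrink its pooled contribution by sqrt(8) and make the
  control CV ~0.025, inconsistent with the observed control.
* random-phase control: each cell gets its own Uniform(0, 2pi) cosine phase
  and the ramp is dropped (untreated cells were never arrested).

The nucleoplasmic (pol II) signal is coupled to the nucleolar kinetics
with attenuation beta plus its own shared per-time-point noise:

    N(t) = B * (1 + beta*(M(t) - 1)) * (1 + shared_t) * (1 + cell noise)

Calibration: writing CV_nuc for the noiseless nucleolar trace CV (0.2676),
the pooled-trace identities

    r      = beta * CV_nuc / CV_np
    CV_np^2 = (beta * CV_nuc)^2 + sigma_np^2

invert to beta = r*CV_np/CV_nuc = 0.414 and
sigma_np = CV_np*sqrt(1-r^2) = 0.13 for the target correlation r = 0.65
and nucleoplasmic CV = 0.17. Monte-Carlo means over 200 seeds land at
r ≈ 0.64 and CV_np ≈ 0.163 (slightly low because the measured nucleolar CV
includes batch noise and the finite-sample CV has a (N-1)/N bias); both are
inside the tolerance used for acceptance.

## 3. Scene renderer

The renderer emulates the *appearance* of FU/pol I immunofluorescence
confocal stacks, not the optics: one nucleus (ellipse, dim glow), 2
nucleoli (disks with diffuse signal, 15% of spot amplitude), 30 FC/DFC
units per cell (3D Gaussians, sigma_xy = 1.3 px, sigma_z = 0.8 slices,
z step = 3 px), 100 nucleoplasmic foci at 10% amplitude, camera offset 10,
Poisson noise (gain 1) and Gaussian read noise (SD 2). Spot amplitudes are
`150 * level * lognormal(CV 0.3)`; the lognormal draws are independent of
`level`, so paired scenes at two levels share geometry and per-unit draws
and their planted amplitude ratio is exact.

Units are placed with a minimum pairwise **lateral** (xy) distance of 7 px:
the detection pipeline works on a maximum intensity projection, where beads
coincident in xy are fundamentally unresolvable regardless of their z
separation, so "distinct beads" must mean xy-separated. Deliberately not
simulated: PSF tails beyond a Gaussian, depth-dependent aberrations,
bleaching, drift, scratch-labelling artefacts, and touching nuclei. Passing
tests therefore demonstrate correctness of the measurement chain under a
realistic noise/contrast regime, not robustness to every optical artefact
of real microscopes.

## 4. Unit detection and quantification

Pipeline: MIP → Gaussian blur (sigma 9 px, working range 8–10) → Otsu →
coarse foreground mask → strict local maxima of the *unblurred* MIP inside
the mask (non-maximum suppression to 3 px) → per candidate, the optical
section of maximal intensity → sub-voxel refinement and quantification.
Numerical choices:

* **Mask dilation.** The heavy blur erodes bright blobs toward their
  cores; the binary mask is dilated back by the blur radius so units near
  nucleolar edges stay inside the coarse foreground.
* **Peak acceptance.** Candidates must exceed the in-mask median of a
  difference-of-Gaussians response (sigma 1.0 / 2.5 px) by
  `min_peak_snr = 6` robust (MAD-based) noise SDs. The DoG cancels local
  background; its MAD inside the mask is a per-image noise scale that is
  not inflated by diffuse structure. This keeps spurious detections on
  signal-free stacks at zero-to-two per field while detecting >90% of
  units at the weakest study level. A small absolute floor additionally
  rejects exact intensity plateaus, which in noise-free synthetic images
  are wall-to-wall non-strict maxima.
* **Strict maxima.** A candidate must be strictly greater than every
  neighbour in its suppression window; peaks in continuous-valued images
  are strict almost surely, while plateau ties are never genuine spots.
  Near-ties within the suppression distance are resolved brightest-first,
  then by smallest (y, x).
* **Sub-voxel centre, FWHM, chi^2.** An isotropic 2D Gaussian + constant
  offset is fitted (least squares) on a 7x7 crop of the unit's optimal
  section; FWHM = 2*sqrt(2 ln 2)*sigma_fit; z is refined by parabolic
  interpolation through the three slices at the peak. chi^2 is defined as
  residual energy over model energy, `sum(res^2)/sum((model-offset)^2)` —
  dimensionless and invariant to intensity rescaling (the historical
  tool's exact normalization is not documented; this one is stated and
  configurable in the record). Fit failures keep the unit with an
  intensity-weighted centroid and are flagged.
* **Integral intensities.** For each radius r in {1.0 … 4.0} px, the sum of
  `max(voxel - background, 0)` over voxels within *physical* distance r
  (z displacements scaled by the z-aspect, default 3.0). Background is the
  median of a 5–7 px scaled annulus. The per-voxel clamp makes integrals
  non-decreasing in radius by construction. If a small sphere around a
  sub-voxel centre contains no voxel centre (possible at r = 1 with a 3-px
  z step), the nearest voxel is used. The 1.5 px integral is the reporting
  and sorting radius.

Detection operates on raw (noisy) stacks; no deconvolution is applied
before counting.

## 5. Region segmentation

Nuclei: blurred MIP (sigma 9), **three-class multi-Otsu** taking the lower
threshold, hole filling, and a 500 px minimum size. A plain two-class Otsu
is unsuitable here: in images whose brightest class (nucleoli) dominates
the inter-class variance it returns the nucleoli as "nuclei". The
multi-Otsu reflects the three genuine intensity populations (background,
nucleoplasm, nucleoli); plain Otsu remains the fallback for bimodal images.

Nucleoli: second Otsu restricted to within-nucleus pixels of a lightly
blurred MIP (sigma 4), with two plausibility guards — the candidate
foreground must be at least 1.5x brighter on average than the remaining
nucleoplasm, and must not cover more than half the nucleus (nucleoli are
minority structures; without the guards, smoothing gradients in a
flat nucleus get promoted to "nucleoli"). Nucleoplasm = nucleus minus
nucleoli, inheriting nucleus labels. All measurements (area in px,
integral, average = integral/area exactly) are taken on the MIP;
3D volumes are out of scope, and the generator places non-touching nuclei
so no watershed is needed.

## 6. Fluctuation statistics

* CV uses the population SD (divisor N) of the per-time-point means; at
  ten points the divisor choice shifts the CV by ~5%, well inside every
  tolerance used.
* Means pool all cells of all experiments at a time point (400 cells);
  per-experiment assembly is available by filtering the measurement table.
* The periodogram is a direct complex sum on a dense **period** grid
  (30–150 min, 1-min steps), not an FFT: the periods of interest are not
  Fourier periods of a 150-min span sampled ten times. Mean subtraction is
  mandatory (shift invariance). Dominant-period ties break toward the
  smaller period. No significance test is attached to periodogram peaks,
  and sub-Nyquist periods (< 30 min for 15-min sampling) are outside the
  grid by construction.
* A known small bias, documented rather than corrected: on the noiseless
  default trace the argmax lies at 55 min, not 60 — the recovery ramp makes
  the low 15-min point act as a half-cycle of a slightly shorter period.
  The recovered period is within the ±15 min sampling uncertainty (and
  within 5 min of the nominal period); under full noise the recovered
  period falls in the 45–75 min band in >95% of runs.
* Student's t is the pooled-variance two-sample variant, two-sided.
  Degenerate zero-variance groups with equal means return (t=0, p=1);
  zero variance with unequal means is an error rather than an infinite t.

## 7. Reproducibility and problem sizes

All randomness flows from one root integer seed through named substreams
(CRC32 of the stream name folded into a numpy `SeedSequence`), so any stage
can be re-run in isolation with identical draws; tables are bit-identical
and stacks voxel-identical under a fixed seed. Pipeline runs write a
manifest (config SHA-256, package version, file list, timestamps).

Monte-Carlo summaries in tests and in `scripts/acceptance.py` use 100–200
seeded population simulations at the study design (8 experiments × 50
cells × 10 time points), 20 paired rendered scenes for the burst-amplitude
statistics and 10 pairs for the cold-recovery ratio — sizes at which the
Monte-Carlo error of every reported mean is several times smaller than the
tolerance it is compared against.

## 8. Known limitations

* The cosine model is phenomenological; it cannot distinguish undulation
  from other oscillatory mixtures that match the same ten-point trace.
* Single-cell trajectories (live imaging) are represented only as repeated
  population sampling; no per-cell temporal autocorrelation is simulated.
* Detection assumes diffraction-limited, laterally separated units;
  merged or highly elongated units are quantified as single spots.
* Segmentation assumes non-touching nuclei and roughly convex nucleoli.
* The renderer's noise is Poisson + Gaussian read noise with a linear
  detector; EMCCD excess noise and fixed-pattern noise are not modelled.
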