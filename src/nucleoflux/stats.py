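"""Population time-course statistics of the transcription signal.

The fluctuation analysis quantifies how strongly and how periodically the
per-time-point population means undulate after release from the cold block:

* **CV** — population SD (divisor N) of the per-time-point means divided by
  their grand mean; the fluctuation-strength statistic.
* **Periodogram** — Fourier amplitude A(T) = |sum_j (x_j - mean) *
  exp(-2*pi*i*t_j / T)| evaluated by direct summation on a dense *period*
  grid (default 30-150 min, 1-min step).  A direct sum is used instead of
  an FFT because the grid of interest (a 60-min period within a 150-min
  span sampled every 15 min) does not coincide with the DFT periods of a
  ten-sample series.  Mean subtraction makes A invariant to additive
  offsets.
* **Dominant period** — argmax of A, with sampling uncertainty +-Delta_t
  (the fixation interval), giving the reported 45-75 min band for a 60-min
  peak sampled every 15 min.
* Pearson correlation between compartment traces, fold changes between
  time points, and the pooled-variance two-sample Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TimeCourse",
    "Periodogram",
    "PeakReport",
    "assemble_timecourse",
    "coefficient_of_variation",
    "periodogram",
    "dominant_period",
    "period_interval",
    "peak_report",
    "pearson_correlation",
    "fold_change",
    "students_t",
]


@dataclass(frozen=True)
class TimeCourse:
    """Per-time-point population summary: mean, SEM (= SD/sqrt(n)) and n.

    Time points must be strictly increasing with constant spacing (the
    sampling-interval uncertainty of the dominant period assumes it).
    """

    timepoints: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        tp = np.asarray(self.timepoints, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        sem = np.asarray(self.sem, dtype=float)
        n = np.asarray(self.n, dtype=int)
        if tp.ndim != 1 or len(tp) < 3:
            raise ValueError("a time course needs at least 3 time points")
        if not (len(tp) == len(mean) == len(sem) == len(n)):
            raise ValueError("timepoints, mean, sem, n must have equal length")
        d = np.diff(tp)
        if np.any(d <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.allclose(d, d[0]):
            raise ValueError("timepoints must be equally spaced")
        if np.any(sem < 0):
            raise ValueError("sem must be non-negative")
        for name, arr in (("timepoints", tp), ("mean", mean), ("sem", sem), ("n", n)):
            object.__setattr__(self, name, arr)

    @property
    def interval(self) -> float:
        """Sampling interval Delta_t in minutes."""
        return float(self.timepoints[1] - self.timepoints[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint_min": self.timepoints,
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
            }
        )


@dataclass(frozen=True)
class Periodogram:
    """Fourier amplitudes on an ascending period grid (minutes)."""

    periods: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.periods, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if p.ndim != 1 or len(p) == 0 or len(p) != len(a):
            raise ValueError("periods and amplitudes must be equal-length 1D arrays")
        if np.any(p <= 0):
            raise ValueError("periods must be positive")
        if np.any(np.diff(p) <= 0):
            raise ValueError("period grid must be ascending")
        if np.any(a < -1e-12):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "periods", p)
        object.__setattr__(self, "amplitudes", np.maximum(a, 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_min": self.periods, "amplitude": self.amplitudes})


@dataclass(frozen=True)
class PeakReport:
    """Dominant period with its sampling-interval uncertainty band."""

    period: float
    low: float
    high: float


def assemble_timecourse(table: pd.DataFrame, compartment: str) -> TimeCourse:
    """Pool a measurement table into a per-time-point mean/SEM time course.

    Cells from all experiments at a time point are pooled; SEM uses the
    sample SD (ddof=1).  Raises if any time point has fewer than two cells.
    """
    if compartment not in ("nucleolar", "nucleoplasmic"):
        raise ValueError(f"unknown compartment {compartment!r}")
    sub = table[table["compartment"] == compartment]
    if sub.empty:
        raise ValueError(f"no rows for compartment {compartment!r}")
    grouped = sub.groupby("timepoint_min")["intensity"]
    n = grouped.size()
    if (n < 2).any():
        bad = n[n < 2].index.tolist()
        raise ValueError(f"time points with fewer than 2 cells: {bad}")
    mean = grouped.mean()
    sem = grouped.std(ddof=1) / np.sqrt(n)
    tp = mean.index.to_numpy(dtype=float)
    return TimeCourse(tp, mean.to_numpy(), sem.to_numpy(), n.to_numpy())


def coefficient_of_variation(tc: TimeCourse) -> float:
    """CV of the per-time-point means: population SD (divisor N) over mean.

    Raises ``ValueError`` if the grand mean is not positive.
    """
    grand = float(np.mean(tc.mean))
    if grand <= 0:
        raise ValueError("grand mean must be positive for a CV")
    return float(np.std(tc.mean) / grand)


def periodogram(tc: TimeCourse, periods=None) -> Periodogram:
    """Fourier-amplitude periodogram of the mean trace by direct summation.

    ``A(T) = | sum_j (x_j - x_bar) exp(-2*pi*i*t_j/T) |`` on the given
    period grid (default 30-150 min, step 1).  Mean subtraction is
    mandatory, which makes A invariant to additive constants.
    """
    if periods is None:
        periods = np.arange(30.0, 151.0, 1.0)
    periods = np.asarray(periods, dtype=float)
    if np.any(periods <= 0):
        raise ValueError("grid periods must be positive")
    x = tc.mean - np.mean(tc.mean)
    phase = -2.0j * np.pi * np.outer(1.0 / periods, tc.timepoints)
    amplitudes = np.abs(np.exp(phase) @ x)
    return Periodogram(periods, amplitudes)


def dominant_period(pg: Periodogram) -> float:
    """Period of maximal amplitude; ties break toward the smaller period.

    Raises ``ValueError`` when all amplitudes are zero (no peak).
    """
    if np.all(pg.amplitudes == 0):
        raise ValueError("all amplitudes are zero; no dominant period")
    return float(pg.periods[int(np.argmax(pg.amplitudes))])


def period_interval(period: float, interval: float) -> tuple:
    """Sampling-interval uncertainty band (P - Delta_t, P + Delta_t).

    With a 15-min fixation interval, a 60-min peak may correspond to true
    periods anywhere in 45-75 min.  Requires P > Delta_t > 0.
    """
    if interval <= 0:
        raise ValueError("sampling interval must be positive")
    if period <= interval:
        raise ValueError("period must exceed the sampling interval")
    return (period - interval, period + interval)


def peak_report(pg: Periodogram, interval: float) -> PeakReport:
    """Dominant period plus its uncertainty band, as one record."""
    p = dominant_period(pg)
    low, high = period_interval(p, interval)
    return PeakReport(period=p, low=low, high=high)


def pearson_correlation(tc1: TimeCourse, tc2: TimeCourse) -> float:
    """Pearson r between the two mean traces (same time points required)."""
    if not np.array_equal(tc1.timepoints, tc2.timepoints):
        raise ValueError("time courses are on different time points")
    if np.std(tc1.mean) == 0 or np.std(tc2.mean) == 0:
        raise ValueError("correlation undefined for a zero-variance trace")
    r, _ = sps.pearsonr(tc1.mean, tc2.mean)
    return float(r)


def fold_change(tc: TimeCourse, t_a: float, t_b: float) -> float:
    """mean(t_b) / mean(t_a); both time points must exist, mean(t_a) > 0."""
    tp = list(tc.timepoints)
    try:
        ia, ib = tp.index(float(t_a)), tp.index(float(t_b))
    except ValueError as exc:
        raise ValueError(f"time point missing from time course: {exc}") from None
    if tc.mean[ia] <= 0:
        raise ValueError("reference mean must be positive")
    return float(tc.mean[ib] / tc.mean[ia])


def students_t(group_a, group_b) -> tuple:
    """Two-sample Student's t-test (pooled variance), two-sided p.

    Degenerate groups with zero pooled variance return (0.0, 1.0) when the
    means are equal and raise otherwise (an infinite t is not meaningful).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return (0.0, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return (float(t), float(p))
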