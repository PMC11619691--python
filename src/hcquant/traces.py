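"""Fluorescence time-series containers and preprocessing.

The processing chain mirrors a standard GCaMP hemichannel-assay workflow:
a cell-free background ROI is subtracted from each cell ROI, the slow
photobleaching trend of the baseline is removed by an exponential fit,
traces are normalized to the maximum response evoked by ionomycin
(dF/dF_max), and spontaneous/evoked Ca2+ peaks are characterized by
amplitude, full width at half maximum (FWHM) and inter-peak intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar


class TraceExcluded(Exception):
    """Raised when an ROI cannot be normalized (e.g. no ionomycin response).

    Carries the ROI id and a human-readable reason so callers can log the
    exclusion instead of silently dropping the cell.
    """

    def __init__(self, roi_id: str, reason: str):
        self.roi_id = roi_id
        self.reason = reason
        super().__init__(f"ROI {roi_id!r} excluded: {reason}")


@dataclass(frozen=True)
class FluorescenceTrace:
    """One ROI's fluorescence (or luminescence) time series.

    Parameters
    ----------
    times : array of float
        Acquisition times in seconds, strictly increasing.
    values : array of float
        Fluorescence in arbitrary units; negative values are legal (they
        arise after background subtraction and are deliberately not clamped
        so that areas under curves remain linear operations).
    roi_id : str
        Identifier of the ROI / well.
    stimulus_time, ionomycin_time : float, optional
        Landmarks of the acquisition protocol, in seconds.
    """

    times: np.ndarray
    values: np.ndarray
    roi_id: str = "roi"
    stimulus_time: float | None = None
    ionomycin_time: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size < 4:
            raise ValueError("a trace needs at least 4 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class NormalizedTrace:
    """dF/dF_max trace: baseline-subtracted, ionomycin-normalized."""

    times: np.ndarray
    dff: np.ndarray
    dfmax: float
    roi_id: str = "roi"
    stimulus_time: float = 0.0

    def __post_init__(self):
        if self.dfmax <= 0:
            raise ValueError("dfmax must be positive")


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks of one trace."""

    peak_times: np.ndarray
    amplitudes: np.ndarray
    fwhms: np.ndarray
    inter_peak_intervals: np.ndarray

    def __post_init__(self):
        n = len(self.peak_times)
        if len(self.inter_peak_intervals) != max(0, n - 1):
            raise ValueError("inter_peak_intervals length mismatch")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class BleachModel:
    """Exponential photobleaching model a*exp(-t/tau) + c.

    ``degenerate`` flags traces where no decay could be fitted (a is set to 0
    and the correction is a no-op); ``method`` records whether the exponential
    fit converged or the linear-detrend fallback was used.
    """

    amplitude: float
    tau: float
    offset: float
    degenerate: bool = False
    method: str = "exp"

    def trend(self, times: np.ndarray) -> np.ndarray:
        if self.method == "linear":
            # amplitude is reused as the linear slope in the fallback
            return self.amplitude * np.asarray(times) + self.offset
        if self.degenerate:
            return np.full_like(np.asarray(times, dtype=float), self.offset)
        return self.amplitude * np.exp(-np.asarray(times) / self.tau) + self.offset


def subtract_background(trace: FluorescenceTrace,
                        background: FluorescenceTrace) -> FluorescenceTrace:
    """Subtract a cell-free background ROI, point by point.

    Both traces must be on the identical time grid. Negative results are
    preserved.
    """
    if trace.times.shape != background.times.shape or not np.allclose(
            trace.times, background.times, rtol=0, atol=1e-9):
        raise ValueError("trace and background must share the same time grid")
    return replace(trace, values=trace.values - background.values)


def fit_bleach(trace: FluorescenceTrace,
               fit_window=None,
               min_tau: float | None = None,
               ) -> tuple[BleachModel, FluorescenceTrace]:
    """Fit a*exp(-t/tau)+c on quiescent segments and remove the trend.

    ``fit_window`` is one (lo, hi) interval or a list of them; the default
    is the pre-stimulus interval, so that evoked signal cannot bias the
    bleaching estimate. A slow decay is poorly identified from a short
    baseline alone, so pipelines typically pass the pre-stimulus interval
    together with a late quiescent segment (after the evoked transient has
    settled, before ionomycin). The fitted trend is extrapolated over the
    whole trace; the corrected trace is ``F - a*exp(-t/tau)`` (trend
    removed, offset retained).

    Returns the model and the corrected trace. If the exponential fit cannot
    converge, a linear detrend is applied instead and flagged via
    ``BleachModel.method == 'linear'``.
    """
    t, v = trace.times, trace.values
    if fit_window is None:
        if trace.stimulus_time is None:
            fit_window = (t[0], t[-1])
        else:
            fit_window = (t[0], trace.stimulus_time)
    windows = ([fit_window] if isinstance(fit_window[0], (int, float))
               else list(fit_window))
    m = np.zeros(t.size, dtype=bool)
    for lo, hi in windows:
        m |= (t >= lo) & (t < hi)
    if m.sum() < 4:
        raise ValueError("fit window must contain at least 4 samples")
    tw, vw = t[m], v[m]

    spread = vw.max() - vw.min()
    if spread == 0.0:
        model = BleachModel(0.0, math.inf, float(vw[0]), degenerate=True)
        return model, trace

    # profile tau: (a, c) are linear given tau, so solve them exactly by
    # least squares on a tau grid and refine the best tau; this avoids the
    # a/tau ridge that defeats joint 3-parameter optimization when the
    # decay is slow relative to the fit window
    span = tw[-1] - tw[0]

    def _profiled_sse(log_tau: float):
        tau = math.exp(log_tau)
        basis = np.column_stack([np.exp(-tw / tau), np.ones_like(tw)])
        coef, *_ = np.linalg.lstsq(basis, vw, rcond=None)
        resid = vw - basis @ coef
        return float(resid @ resid), coef

    # tau far beyond the window span makes exp(-t/tau) collinear with the
    # intercept (the a/c split becomes arbitrary); such trends are
    # indistinguishable from linear anyway, so the grid stops at 5*span
    tau_lo = span / 50.0 if min_tau is None else float(min_tau)
    grid = np.log(np.geomspace(tau_lo, span * 5.0, 40))
    sses = [_profiled_sse(g)[0] for g in grid]
    i_best = int(np.argmin(sses))
    lo_i, hi_i = max(0, i_best - 1), min(len(grid) - 1, i_best + 1)
    res = minimize_scalar(lambda g: _profiled_sse(g)[0],
                          bounds=(grid[lo_i], grid[hi_i]), method="bounded",
                          options={"xatol": 1e-12})
    sse, (a, c) = _profiled_sse(res.x)
    tau = math.exp(res.x)

    # no resolvable decay: fall back to linear detrend, flagged
    flat_resid = vw - vw.mean()
    if not np.isfinite(sse) or sse >= float(flat_resid @ flat_resid):
        slope, intercept = np.polyfit(tw, vw, 1)
        model = BleachModel(float(slope), math.inf, float(intercept),
                            degenerate=False, method="linear")
        corrected = replace(trace, values=v - slope * t)
        return model, corrected

    model = BleachModel(float(a), float(tau), float(c))
    corrected = replace(trace, values=v - a * np.exp(-t / tau))
    return model, corrected


def normalize_dff(trace: FluorescenceTrace,
                  dfmax_smooth: int = 1) -> NormalizedTrace:
    """Compute dF/dF_max.

    F0 is the mean of the pre-stimulus samples; dF(t) = F(t) - F0; dF_max is
    the maximum dF within the ionomycin window (from ``ionomycin_time`` to
    the end of the trace). ``dfmax_smooth`` > 1 takes the maximum of a
    moving average of that many samples instead of the raw maximum: on a
    saturated ionomycin plateau the raw maximum rides on the largest of
    many noise excursions, which would bias dF_max upward. ROIs whose
    ionomycin response is non-positive are excluded with
    :class:`TraceExcluded`.
    """
    if trace.stimulus_time is None:
        raise ValueError("stimulus_time must be set to normalize")
    if trace.ionomycin_time is None:
        raise ValueError("ionomycin_time must be set to normalize")
    pre = trace.times < trace.stimulus_time
    if not pre.any():
        raise ValueError("no pre-stimulus samples to estimate F0")
    f0 = float(trace.values[pre].mean())
    df = trace.values - f0
    iono = trace.times >= trace.ionomycin_time
    if not iono.any():
        raise TraceExcluded(trace.roi_id, "no samples in ionomycin window")
    window = df[iono]
    if dfmax_smooth > 1 and window.size >= dfmax_smooth:
        kernel = np.full(dfmax_smooth, 1.0 / dfmax_smooth)
        window = np.convolve(window, kernel, mode="valid")
    dfmax = float(window.max())
    if dfmax <= 0:
        raise TraceExcluded(trace.roi_id, "non-positive ionomycin response")
    return NormalizedTrace(times=trace.times, dff=df / dfmax, dfmax=dfmax,
                           roi_id=trace.roi_id,
                           stimulus_time=float(trace.stimulus_time))


def _half_crossing(t: np.ndarray, v: np.ndarray, i_peak: int, level: float,
                   direction: int) -> float | None:
    """Time where v crosses ``level`` walking from i_peak in ``direction``."""
    i = i_peak
    while 0 <= i + direction < len(v):
        j = i + direction
        if v[j] <= level:
            # linear interpolation between samples i and j
            if v[i] == v[j]:
                return float(t[j])
            frac = (v[i] - level) / (v[i] - v[j])
            return float(t[i] + frac * (t[j] - t[i]))
        i = j
    return None


def detect_peaks(trace: FluorescenceTrace | NormalizedTrace,
                 threshold_k: float = 3.0) -> PeakSet:
    """Detect peaks above a robust noise threshold.

    The detection level is ``baseline + k * 1.4826 * MAD`` where the baseline
    is the trace median and the MAD is taken over residuals from it. Peaks
    closer than 3 samples are merged (highest wins; ties break to the
    earliest). Amplitude is peak value minus baseline; FWHM comes from linear
    interpolation of the half-amplitude crossings on both flanks (flanks that
    never cross fall back to the trace edge).
    """
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(getattr(trace, "dff", getattr(trace, "values", None)),
                   dtype=float)
    if t.size < 8:
        raise ValueError("peak detection needs at least 8 samples")
    baseline = float(np.median(v))
    mad = float(np.median(np.abs(v - baseline)))
    level = baseline + threshold_k * 1.4826 * mad

    # local maxima strictly above both neighbours (plateaus: first sample)
    idx = [i for i in range(1, len(v) - 1)
           if v[i] > level and v[i] >= v[i - 1] and v[i] > v[i + 1]]

    # merge peaks closer than 3 samples: highest wins, ties -> earliest
    merged: list[int] = []
    for i in idx:
        if merged and i - merged[-1] < 3:
            if v[i] > v[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)

    peak_times, amps, fwhms = [], [], []
    for i in merged:
        amp = v[i] - baseline
        half = baseline + 0.5 * amp
        left = _half_crossing(t, v, i, half, -1)
        right = _half_crossing(t, v, i, half, +1)
        if left is None:
            left = float(t[0])
        if right is None:
            right = float(t[-1])
        peak_times.append(float(t[i]))
        amps.append(float(amp))
        fwhms.append(right - left)

    pt = np.asarray(peak_times)
    return PeakSet(peak_times=pt,
                   amplitudes=np.asarray(amps),
                   fwhms=np.asarray(fwhms),
                   inter_peak_intervals=np.diff(pt))
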