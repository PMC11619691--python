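"""End-to-end synthetic study: simulate -> traces -> assays -> stats
(-> energetics), with a single JSON-able report.

Every stage is also callable on its own, so files produced by one stage can
feed the next through the CLI. All randomness flows from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._util import substream
from . import synthdata as sd
from .traces import (FluorescenceTrace, TraceExcluded, detect_peaks,
                     fit_bleach, normalize_dff, subtract_background,
                     _half_crossing)
from .assays import atp_release, compute_ccl, fit_dose_response
from .energetics import (aggregate_protomers, contact_fraction, estimate_leg,
                         rmsd_series, thermo_cycle)
from .stats import compare_groups


@dataclass
class RunConfig:
    """Parameters of the full synthetic study (defaults = study conditions)."""

    seed: int = 0
    # Ca2+ imaging
    n_rois: int = 30
    frame_interval: float = 1.3
    duration: float = 360.0
    stimulus_time: float = 10.0
    ionomycin_time: float = 190.0
    noise_sd: float = 1.0
    oscillation_rate: float = 2.0
    ccl_window: tuple = (0.0, 100.0)
    # dose-response
    concentrations: tuple = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 5e-6)
    n_rois_dose: int = 15
    # DAPI
    dapi_n: int = 40
    dapi_duration: float = 300.0
    dapi_offset: float = 50.0
    dapi_inhibition: dict = field(default_factory=lambda: {
        "control": 1.0, "antibody": 0.35, "ffa": 0.30})
    # ATP
    atp_n_wells: int = 5
    atp_baseline: float = 1000.0
    atp_stimulus_time: float = 120.0
    atp_gap_mask: tuple = (5, 6)
    atp_folds: dict = field(default_factory=lambda: {
        "control": 4.0, "antibody": 1.6, "ffa": 1.5, "lacl3": 1.4,
        "no_dox": 1.05})
    # FEP
    fep_work_sd: float = 0.25
    fep_n_samples: int = 750
    fep_n_replicas: int = 5
    fep_n_windows: int = 32
    fep_temperature: float = 310.0
    ddg_per_protomer: tuple = (1.43, 0.50, -0.37, -0.08, -0.08, -0.08)
    free_leg_total: float = 0.68
    # contacts
    contact_n_frames: int = 100
    contact_fraction_wt: float = 0.79
    contact_fraction_mut: float = 0.19
    run_energetics: bool = True

    def validate(self) -> None:
        sd.SynthConfig(n_rois=self.n_rois, frame_interval=self.frame_interval,
                       duration=self.duration,
                       stimulus_time=self.stimulus_time,
                       ionomycin_time=self.ionomycin_time)
        if len(self.ddg_per_protomer) != 6:
            raise ValueError("ddg_per_protomer needs six entries")

    def synth_config(self, n_rois=None, noise_sd=None) -> sd.SynthConfig:
        return sd.SynthConfig(
            n_rois=self.n_rois if n_rois is None else n_rois,
            frame_interval=self.frame_interval, duration=self.duration,
            stimulus_time=self.stimulus_time,
            ionomycin_time=self.ionomycin_time,
            noise_sd=self.noise_sd if noise_sd is None else noise_sd,
            oscillation_rate=self.oscillation_rate)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k in ("ccl_window", "concentrations", "atp_gap_mask",
                  "ddg_per_protomer"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("ccl_window", "concentrations", "atp_gap_mask",
                  "ddg_per_protomer"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# trace preprocessing
# ---------------------------------------------------------------------------

def _quiescent_windows(tr, settle):
    windows = [(tr.times[0], tr.stimulus_time)]
    if (tr.ionomycin_time is not None
            and tr.stimulus_time + settle < tr.ionomycin_time):
        windows.append((tr.stimulus_time + settle, tr.ionomycin_time))
    return windows


def _smooth_background(bg: FluorescenceTrace) -> FluorescenceTrace:
    """Replace the cell-free background ROI by a smooth model of itself.

    The background carries no indicator -- it is an electronic offset plus
    back-reflection that is constant or drifts slowly -- so it is fitted
    with the same offset+exponential model used for bleaching trends.
    Subtracting the raw background would inject one shared noise
    realization into every cell ROI of the ensemble.
    """
    span = bg.times[-1] - bg.times[0]
    model, _ = fit_bleach(bg, fit_window=(bg.times[0], bg.times[-1] + 1.0),
                          min_tau=span / 2.0)
    return FluorescenceTrace(times=bg.times, values=model.trend(bg.times),
                             roi_id=bg.roi_id,
                             stimulus_time=bg.stimulus_time,
                             ionomycin_time=bg.ionomycin_time)


def _subtracted_traces(ens: sd.TraceEnsemble):
    background = (_smooth_background(ens.background)
                  if ens.background is not None else None)
    return [subtract_background(tr, background)
            if background is not None else tr
            for tr in ens.traces]


def fit_shared_bleach(ensembles, settle: float = sd.TAPER_END):
    """Bleach model of the shared illumination, fitted on pooled ROIs.

    Ensembles acquired under the same protocol (e.g. the concentrations of
    a dose series) share the photobleaching decay; pooling their ROI-mean
    trace makes the time constant far better determined than any single
    ensemble allows. Evoked epochs are excluded via the quiescent
    segments, so differing transient amplitudes cannot bias the fit.
    """
    all_traces = [tr for ens in ensembles for tr in _subtracted_traces(ens)]
    first = all_traces[0]
    windows = _quiescent_windows(first, settle)
    mean_trace = FluorescenceTrace(
        times=first.times,
        values=np.mean([tr.values for tr in all_traces], axis=0),
        roi_id="pooled-mean", stimulus_time=first.stimulus_time,
        ionomycin_time=first.ionomycin_time)
    model, _ = fit_bleach(mean_trace, fit_window=windows)
    return model


def preprocess_ensemble(ens: sd.TraceEnsemble,
                        settle: float = sd.TAPER_END,
                        shared=None):
    """Background-subtract, bleach-correct and dF/dF_max-normalize.

    The cell-free background is smoothed before subtraction (it varies
    slowly; its raw noise would be shared by every ROI). Bleaching is
    driven by the shared illumination, so the decay time
    constant is estimated once on the ensemble-mean trace over the
    quiescent segments (pre-stimulus, plus the interval from
    ``stimulus + settle`` -- after the evoked transient has decayed -- to
    ionomycin), where ROI averaging suppresses the noise; a model fitted
    across several ensembles (:func:`fit_shared_bleach`) can be passed in
    instead. Each ROI then gets its own amplitude and offset for that
    shared decay by linear least squares, which is well conditioned even
    on short segments. Returns (normalized traces, exclusion log).
    """
    subtracted = _subtracted_traces(ens)
    first = subtracted[0]
    windows = _quiescent_windows(first, settle)
    shared = shared if shared is not None else fit_shared_bleach(
        [ens], settle=settle)

    t = first.times
    m = np.zeros(t.size, dtype=bool)
    for lo, hi in windows:
        m |= (t >= lo) & (t < hi)

    norms, exclusions = [], []
    for tr in subtracted:
        if shared.degenerate or shared.method == "linear":
            _, corrected = fit_bleach(tr, fit_window=windows)
        else:
            # per-ROI amplitude/offset of the shared decay, linear lsq
            basis = np.column_stack([np.exp(-t[m] / shared.tau),
                                     np.ones(m.sum())])
            coef, *_ = np.linalg.lstsq(basis, tr.values[m], rcond=None)
            corrected = FluorescenceTrace(
                times=t, values=tr.values - coef[0] * np.exp(-t / shared.tau),
                roi_id=tr.roi_id, stimulus_time=tr.stimulus_time,
                ionomycin_time=tr.ionomycin_time)
        try:
            norms.append(normalize_dff(corrected, dfmax_smooth=5))
        except TraceExcluded as exc:
            exclusions.append({"roi_id": exc.roi_id, "reason": exc.reason})
    return norms, exclusions


def ccl_values(norms, window=(0.0, 100.0)) -> np.ndarray:
    return np.array([compute_ccl(n, *window).area for n in norms])


def evoked_transient_stats(ens: sd.TraceEnsemble):
    """Amplitude and FWHM of the evoked transient, per ROI.

    Works on background-subtracted, bleach-corrected dF restricted to the
    pre-ionomycin epoch. The apex is a 3-point local average around the
    maximum (suppressing single-sample noise); the FWHM comes from linear
    interpolation of the half-amplitude crossings.
    """
    amps, fwhms = [], []
    for tr in ens.traces:
        if ens.background is not None:
            tr = subtract_background(tr, ens.background)
        windows = [(tr.times[0], tr.stimulus_time)]
        if tr.ionomycin_time is not None:
            windows.append((tr.stimulus_time + sd.TAPER_END,
                            tr.ionomycin_time))
        _, corr = fit_bleach(tr, fit_window=windows)
        m = corr.times < (tr.ionomycin_time or corr.times[-1])
        t, v = corr.times[m], corr.values[m]
        f0 = v[t < tr.stimulus_time].mean()
        dv = v - f0
        i = int(np.argmax(dv))
        lo, hi = max(0, i - 1), min(len(dv), i + 2)
        amp = float(dv[lo:hi].mean())
        half = 0.5 * amp
        left = _half_crossing(t, dv, i, half, -1)
        right = _half_crossing(t, dv, i, half, +1)
        if left is None or right is None:
            continue
        amps.append(amp)
        fwhms.append(right - left)
    return np.array(amps), np.array(fwhms)


def _gaussian_kernel(sigma_samples: float) -> np.ndarray:
    half = max(1, int(math.ceil(3 * sigma_samples)))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma_samples) ** 2)
    return kernel / kernel.sum()


def _gaussian_smooth(v: np.ndarray, sigma_samples: float) -> np.ndarray:
    kernel = _gaussian_kernel(sigma_samples)
    half = (kernel.size - 1) // 2
    padded = np.concatenate([v[half:0:-1], v, v[-2:-half - 2:-1]])
    return np.convolve(padded, kernel, mode="valid")


def _matched_filter_events(t, v, sigma_t, dt, n_sigma: float = 4.0):
    """Event candidate times by band-passed matched filtering.

    The trace is convolved with a Gaussian template at the event
    timescale and a much broader Gaussian is subtracted (difference of
    Gaussians), removing both shot noise and slow baseline residuals.
    Candidates are local maxima exceeding ``n_sigma`` times the filtered
    noise level, which is propagated from the raw high-frequency noise
    estimate (median absolute first difference).
    """
    narrow = sigma_t / dt
    bp = _gaussian_smooth(v, narrow) - _gaussian_smooth(v, 8.0 * narrow)
    sigma_raw = 1.4826 * float(np.median(np.abs(np.diff(v)))) / math.sqrt(2)
    kernel = _gaussian_kernel(narrow)
    sigma_bp = sigma_raw * math.sqrt(float(np.sum(kernel ** 2)))
    level = n_sigma * sigma_bp
    idx = [i for i in range(1, len(bp) - 1)
           if bp[i] > level and bp[i] >= bp[i - 1] and bp[i] > bp[i + 1]]
    merged = []
    for i in idx:
        if merged and i - merged[-1] < 3:
            if bp[i] > bp[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return t[merged]


def oscillation_stats(ens: sd.TraceEnsemble, threshold_k: float = 3.5,
                      fit_halfwidth: int = 5):
    """Amplitudes and FWHMs of spontaneous events across an ensemble.

    Detection is matched-filtered: the bleach-corrected dF (pre-ionomycin
    epoch) is smoothed with a Gaussian template at the event timescale,
    which raises the event-to-noise ratio by roughly the square root of
    the samples per event and lets the detection threshold sit far below
    the event amplitude distribution -- naive single-sample thresholding
    misses a large fraction of small events and badly inflates the mean
    amplitude of the survivors. The template width is self-calibrated
    from a first, high-threshold pass. Each detected event is then
    characterized by a local Gaussian least-squares fit to the *raw*
    trace (amplitude unbiased by the smoothing; FWHM = sqrt(8 ln 2) *
    sigma).

    Returns (amplitudes, fwhms).
    """
    from scipy.optimize import curve_fit

    from scipy.stats import chi2

    def fit_events(t, v, baseline, peak_times, dt, screen=False):
        # offset fixed at the robust baseline: a free offset is degenerate
        # with a near-flat (large-sigma) Gaussian on a short window
        def bump(x, a, mu, sig):
            return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + baseline

        sigma_noise = (1.4826 * float(np.median(np.abs(np.diff(v))))
                       / math.sqrt(2))
        out = []
        for pt in peak_times:
            i = int(np.argmin(np.abs(t - pt)))
            lo = max(0, i - fit_halfwidth)
            hi = min(len(v), i + fit_halfwidth + 1)
            try:
                popt, _ = curve_fit(
                    bump, t[lo:hi], v[lo:hi],
                    p0=(max(v[i] - baseline, 0.1), t[i], 2.0 * dt),
                    bounds=([0.0, t[lo], 0.5 * dt],
                            [np.inf, t[hi - 1], 4.0 * dt]),
                    maxfev=2000)
            except RuntimeError:
                continue
            if screen:
                # single-event goodness of fit: unresolved multi-event
                # pile-ups leave residuals far above the noise floor, and
                # this rejection is independent of the event's amplitude
                resid = v[lo:hi] - bump(t[lo:hi], *popt)
                sse_bound = (chi2.ppf(0.99, hi - lo - 3)
                             * sigma_noise ** 2)
                if float(resid @ resid) > sse_bound:
                    continue
            out.append((float(popt[0]), float(popt[2])))
        return out

    prepared = []
    sigmas = []
    for tr in ens.traces:
        if ens.background is not None:
            tr = subtract_background(tr, ens.background)
        _, corr = fit_bleach(tr, fit_window=(tr.times[0], tr.times[-1])
                             if tr.ionomycin_time is None
                             else (tr.times[0], tr.ionomycin_time))
        m = corr.times < (tr.ionomycin_time or corr.times[-1])
        t, v = corr.times[m], corr.values[m]
        baseline = float(np.median(v))
        dt = float(np.median(np.diff(t)))
        prepared.append((t, v, baseline, dt))
        # template calibration: high-threshold pass on the raw trace
        peaks = detect_peaks(FluorescenceTrace(times=t, values=v,
                                               roi_id=tr.roi_id),
                             threshold_k=3.0)
        sigmas.extend(s for _, s in fit_events(t, v, baseline,
                                               peaks.peak_times, dt))
    sigma_t = float(np.median(sigmas)) if len(sigmas) >= 5 else None

    amps, fwhms = [], []
    n_detections = 0
    total_time = 0.0
    for t, v, baseline, dt in prepared:
        if sigma_t is not None:
            peak_times = _matched_filter_events(t, v, sigma_t, dt,
                                                n_sigma=threshold_k)
        else:
            peak_times = detect_peaks(
                FluorescenceTrace(times=t, values=v, roi_id="raw"),
                threshold_k=threshold_k).peak_times
        n_detections += len(peak_times)
        total_time += float(t[-1] - t[0])
        # amplitude/width statistics use isolated events only: a neighbour
        # inside the fit window contaminates the local Gaussian fit
        min_gap = 5.0 * (sigma_t if sigma_t is not None else 2.0 * dt)
        isolated = [pt for pt in peak_times
                    if np.sum(np.abs(peak_times - pt) < min_gap) == 1]
        for a, s in fit_events(t, v, baseline, isolated, dt, screen=True):
            amps.append(a)
            fwhms.append(2.0 * math.sqrt(2.0 * math.log(2.0)) * s)
    diag = {"n_detections": n_detections, "total_time_s": total_time,
            "sigma_template": sigma_t}
    return np.array(amps), np.array(fwhms), diag


def pileup_corrected_mean(amps: np.ndarray, diag: dict) -> float:
    """Mean event amplitude corrected for unresolvable pile-up.

    Two Gaussian bumps closer than twice their width merge into a single
    maximum, so every detection is really a cluster of one or more events
    within that resolution limit. Detection runs on the matched-filtered
    trace, where an event of width sigma convolved with the sigma-wide
    template has width sqrt(2)*sigma; the resolution limit is therefore
    w = 2*sqrt(2)*sigma_template. For Poisson-timed events of rate lambda
    the observed cluster rate is lambda*exp(-lambda*w) and the mean
    cluster size is exp(lambda*w); the raw mean of detected amplitudes
    overestimates the per-event mean by that factor. lambda is recovered
    from the measured cluster rate by fixed-point iteration and the
    correction applied.
    """
    if not len(amps):
        return float("nan")
    raw_mean = float(np.mean(amps))
    sigma_t = diag.get("sigma_template")
    total_time = diag.get("total_time_s", 0.0)
    if sigma_t is None or total_time <= 0:
        return raw_mean
    w = 2.0 * math.sqrt(2.0) * sigma_t
    cluster_rate = diag["n_detections"] / total_time
    lam = cluster_rate
    for _ in range(50):
        lam = cluster_rate * math.exp(lam * w)
    return raw_mean / math.exp(lam * w)



def bootstrap_ratio(a: np.ndarray, b: np.ndarray, n_boot: int = 500,
                    seed: int = 0):
    """Ratio mean(a)/mean(b) with a percentile bootstrap CI."""
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        ratios[i] = (rng.choice(a, a.size).mean()
                     / rng.choice(b, b.size).mean())
    point = float(a.mean() / b.mean())
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return point, (float(lo), float(hi))


def _resample_ensemble(ens: sd.TraceEnsemble,
                       rng: np.random.Generator) -> sd.TraceEnsemble:
    idx = rng.integers(0, len(ens.traces), len(ens.traces))
    return sd.TraceEnsemble(traces=[ens.traces[i] for i in idx],
                            condition=ens.condition,
                            antibody_conc_molar=ens.antibody_conc_molar,
                            kind=ens.kind, background=ens.background)


def ccl_ratio_with_ci(ens_num: sd.TraceEnsemble, ens_den: sd.TraceEnsemble,
                      window=(0.0, 100.0), n_boot: int = 200, seed: int = 0):
    """Ratio of mean CCLs with a full-pipeline bootstrap CI.

    Each bootstrap replicate resamples ROIs and reruns the whole
    preprocessing chain -- including the shared bleach fit on the
    resampled ensemble mean -- so the CI reflects the sampling
    uncertainty of every estimation step, not just of the per-ROI areas.
    """
    shared = fit_shared_bleach([ens_num, ens_den])
    num = ccl_values(preprocess_ensemble(ens_num, shared=shared)[0], window)
    den = ccl_values(preprocess_ensemble(ens_den, shared=shared)[0], window)
    point = float(num.mean() / den.mean())
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        ens_n = _resample_ensemble(ens_num, rng)
        ens_d = _resample_ensemble(ens_den, rng)
        shared_b = fit_shared_bleach([ens_n, ens_d])
        n_b = ccl_values(
            preprocess_ensemble(ens_n, shared=shared_b)[0], window)
        d_b = ccl_values(
            preprocess_ensemble(ens_d, shared=shared_b)[0], window)
        if d_b.size and n_b.size and d_b.mean() != 0:
            reps.append(n_b.mean() / d_b.mean())
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# study stages
# ---------------------------------------------------------------------------

def run_calcium_study(config: RunConfig) -> dict:
    """WT vs mutant CCL, plus the 9-fold evoked/spontaneous comparison."""
    truth = sd.GroundTruth(seed=config.seed)
    sc = config.synth_config()
    ens_wt, _ = sd.gen_gcamp_ensemble(sc, truth, condition="wt")
    ens_mut, _ = sd.gen_gcamp_ensemble(sc, truth, condition="mutant")
    ccl_wt = ccl_values(preprocess_ensemble(ens_wt)[0], config.ccl_window)
    ccl_mut = ccl_values(preprocess_ensemble(ens_mut)[0], config.ccl_window)
    ratio, ci = ccl_ratio_with_ci(ens_mut, ens_wt, config.ccl_window,
                                  seed=config.seed)
    comparison = compare_groups({"wt": ccl_wt, "mutant": ccl_mut})

    ens_spont, _ = sd.gen_gcamp_ensemble(sc, truth, condition="wt",
                                         stimulated=False,
                                         oscillations="full")
    ens_evoked, _ = sd.gen_gcamp_ensemble(sc, truth, condition="wt",
                                          oscillations="none")
    amp_ev, fwhm_ev = evoked_transient_stats(ens_evoked)
    amp_sp, fwhm_sp, sp_diag = oscillation_stats(ens_spont)
    amp_sp_mean = pileup_corrected_mean(amp_sp, sp_diag)
    return {
        "ccl_wt_mean": float(ccl_wt.mean()),
        "ccl_mut_mean": float(ccl_mut.mean()),
        "ccl_ratio_mut_wt": ratio,
        "ccl_ratio_ci": ci,
        "ccl_ratio_true": truth.effect_ratio_ccl,
        "omnibus_test": comparison.omnibus_test,
        "omnibus_p": comparison.omnibus_p,
        "amplitude_fold": float(amp_ev.mean() / amp_sp_mean)
        if amp_sp.size else float("nan"),
        "fwhm_fold": float(fwhm_ev.mean() / fwhm_sp.mean())
        if fwhm_sp.size else float("nan"),
        "n_spontaneous_events": int(amp_sp.size),
    }


def run_dose_study(config: RunConfig, condition: str) -> dict:
    """Antibody dose-response for one condition; returns the Hill fit."""
    truth = sd.GroundTruth(seed=config.seed)
    sc = config.synth_config(n_rois=config.n_rois_dose)
    ensembles = [sd.gen_gcamp_ensemble(sc, truth, condition=condition,
                                       antibody_conc=float(c))[0]
                 for c in config.concentrations]
    shared = fit_shared_bleach(ensembles)
    ccls = [ccl_values(preprocess_ensemble(ens, shared=shared)[0],
                       config.ccl_window) for ens in ensembles]
    fit = fit_dose_response(config.concentrations, ccls,
                            seed=config.seed)
    return {
        "condition": condition,
        "ic50_molar": fit.ic50,
        "ic50_nm": fit.ic50 * 1e9,
        "ic50_ci_molar": list(fit.ic50_ci),
        "hill_h": fit.hill_h,
        "floor": fit.floor,
        "flagged": fit.flagged,
        "ic50_true_molar": truth.ic50_per_condition[condition],
    }


def run_dapi_study(config: RunConfig) -> dict:
    """DAPI uptake rates per pharmacological condition."""
    from .assays import dapi_rate
    truth = sd.GroundTruth(seed=config.seed)
    rates = {}
    for cond, factor in config.dapi_inhibition.items():
        ens = sd.gen_dapi_traces(
            n=config.dapi_n, slope=truth.dapi_slope_true * factor,
            dead_cell_offset=config.dapi_offset,
            duration=config.dapi_duration,
            seed=config.seed, stream=f"dapi/{cond}")
        rates[cond] = np.array([dapi_rate(tr) for tr in ens.traces])
    comparison = compare_groups(rates)
    return {
        "rates_mean": {k: float(v.mean()) for k, v in rates.items()},
        "slope_true": truth.dapi_slope_true,
        "omnibus_test": comparison.omnibus_test,
        "omnibus_p": comparison.omnibus_p,
        "pairwise": comparison.pairwise,
    }


def run_atp_study(config: RunConfig) -> dict:
    """ATP release AUC and peak fold per condition."""
    aucs, peak_folds = {}, {}
    for cond, fold in config.atp_folds.items():
        ens = sd.gen_atp_traces(
            n_wells=config.atp_n_wells, baseline=config.atp_baseline,
            fold_peak=fold, stimulus_time=config.atp_stimulus_time,
            gap_mask=config.atp_gap_mask,
            seed=config.seed, stream=f"atp/{cond}")
        res = [atp_release(tr, config.atp_stimulus_time) for tr in ens.traces]
        aucs[cond] = np.array([r.auc for r in res])
        peak_folds[cond] = np.array([r.peak_fold for r in res])
    comparison = compare_groups(aucs)
    return {
        "auc_mean": {k: float(v.mean()) for k, v in aucs.items()},
        "peak_fold_control": float(peak_folds["control"].mean()),
        "omnibus_test": comparison.omnibus_test,
        "omnibus_p": comparison.omnibus_p,
    }


def run_fep_study(config: RunConfig) -> dict:
    """Per-protomer ddG by BAR over replicas, thermodynamic cycle, total.

    For each protomer and each cycle leg (complex / free), work samples are
    generated per replica and per lambda window, each window's dG estimated
    by BAR, windows summed into the leg, and the cycle closed per replica;
    the protomer ddG is the replica mean with the replica-scatter s.e.
    """
    truth = sd.GroundTruth(seed=config.seed)
    nw = config.fep_n_windows
    ddg_est, ddg_se = [], []
    for p, ddg_true in enumerate(config.ddg_per_protomer):
        complex_total = config.free_leg_total + ddg_true
        per_rep = []
        for rep in range(config.fep_n_replicas):
            legs = {}
            for label, total in (("complex", complex_total),
                                 ("free", config.free_leg_total)):
                samples = sd.gen_fep_samples(
                    [total / nw] * nw, config.fep_work_sd,
                    config.fep_n_samples,
                    temperature=config.fep_temperature, seed=config.seed,
                    stream=f"fep/p{p}/{label}/rep{rep}")
                legs[label] = estimate_leg(samples, label=label, n_boot=0)
            per_rep.append(thermo_cycle(legs["complex"], legs["free"])[0])
        per_rep = np.asarray(per_rep)
        ddg_est.append(float(per_rep.mean()))
        ddg_se.append(float(per_rep.std(ddof=1)
                            / np.sqrt(config.fep_n_replicas)))
    agg = aggregate_protomers(ddg_est, temperature=config.fep_temperature,
                              se_list=ddg_se)
    return {
        "ddg_per_protomer": list(agg.ddg_per_protomer),
        "ddg_se_per_protomer": list(agg.se_per_protomer),
        "ddg_true_per_protomer": list(config.ddg_per_protomer),
        "total_ddg": agg.total_ddg,
        "total_se": agg.total_se,
        "fold_change": agg.fold_change,
        "fold_change_power_of_ten": agg.fold_change_power_of_ten,
        "temperature_k": config.fep_temperature,
    }


def run_contact_study(config: RunConfig) -> dict:
    """Contact fractions of residue 178 with the Fab for WT and mutant."""
    out = {}
    for cond, frac in (("wt", config.contact_fraction_wt),
                       ("mutant", config.contact_fraction_mut)):
        n_contact = int(round(frac * config.contact_n_frames))
        schedule = np.zeros(config.contact_n_frames, dtype=bool)
        schedule[:n_contact] = True
        rng = substream(config.seed, f"schedule/{cond}")
        rng.shuffle(schedule)
        traj = sd.gen_toy_trajectory(schedule, seed=config.seed)
        res = contact_fraction(traj, {"chain": "A", "res_number": 178},
                               {"chain": "H", "res_number": 56})
        rmsd = rmsd_series(traj, align=True)
        out[cond] = {"fraction": res.fraction,
                     "fraction_true": float(schedule.mean()),
                     "rmsd_max": float(rmsd.max())}
    return out


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Run the whole synthetic study and return (optionally write) a report."""
    config.validate()
    report = {
        "seed": config.seed,
        "calcium": run_calcium_study(config),
        "dose_response": {
            cond: run_dose_study(config, cond) for cond in ("wt", "mutant")},
        "dapi": run_dapi_study(config),
        "atp": run_atp_study(config),
    }
    if config.run_energetics:
        report["fep"] = run_fep_study(config)
        report["contacts"] = run_contact_study(config)
    if outdir is not None:
        from .io import write_report
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(outdir / "report.json", report)
    return report
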