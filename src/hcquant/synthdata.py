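"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study's raw inputs:

* GCaMP6s fluorescence ensembles — baseline with optional exponential
  photobleaching, spontaneous Ca2+ oscillations (Poisson-timed Gaussian
  bumps with log-normal amplitudes), a stimulus-evoked transient whose
  amplitude carries the condition effect (mutant vs wild type) and the
  antibody inhibition 1/(1+(c/IC50)^h), an ionomycin saturation plateau,
  and additive i.i.d. Gaussian noise.
* DAPI uptake traces — linear uptake plus a constant dead-cell offset.
* ATP-release luminescence — flat baseline, then a rise peaking ~300 s
  after the ionophore stimulus, with instrument gaps.
* Per-lambda-window work samples consistent with the Crooks relation.
* Toy trajectories with a prescribed per-frame contact schedule.

Every generator takes an explicit seed; one global seed is propagated to
independent per-stream sub-seeds, so adding a generator never perturbs
another's draws. Defaults are the study conditions: mutant CCL 1.58x the
wild type, evoked transients 9-fold larger/wider than spontaneous
oscillations, IC50 10 nM (WT) / 80 nM (mutant), ATP peaking 4-fold over
baseline, and a 79% contact fraction for the wild-type complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import kt, substream
from .traces import FluorescenceTrace
from .energetics import TrajectoryFrames, WindowWorkSamples

# fixed generator geometry/scale constants (arbitrary fluorescence units)
BASELINE_F0 = 100.0       # GCaMP baseline fluorescence
BACKGROUND_OFFSET = 10.0  # electronic offset / back-reflection, cell-free ROI
TRANSIENT_AMP_WT = 50.0   # evoked transient amplitude, wild type, a.u.
IONO_LEVEL = 200.0        # ionomycin saturation level, a.u.
IONO_RISE_TAU = 3.0       # s
RISE_TAU = 10.0           # transient rise time constant, s
DECAY_TAU = 40.0          # transient decay time constant, s
TAPER_START = 120.0       # transient support taper, s after stimulus
TAPER_END = 150.0         # transient is exactly 0 beyond this point
OSC_AMP_SIGMA = 0.3       # log-normal shape parameter of oscillation amps


@dataclass(frozen=True)
class GroundTruth:
    """The generator's ground-truth record, returned alongside every output."""

    effect_ratio_ccl: float = 1.58          # mutant/WT CCL
    transient_fold: float = 9.0             # evoked vs spontaneous amp & FWHM
    ic50_per_condition: dict = field(
        default_factory=lambda: {"wt": 10e-9, "mutant": 80e-9})  # molar
    hill_h: float = 1.0
    atp_fold: float = 4.0
    bleach_tau: float | None = 600.0        # s; None disables bleaching
    per_window_dg: tuple = tuple([0.05] * 32)  # kcal/mol
    contact_fraction_true: float = 0.79
    dapi_slope_true: float = 1.0            # a.u./s
    seed: int = 0

    def __post_init__(self):
        if self.effect_ratio_ccl <= 0 or self.transient_fold <= 0:
            raise ValueError("folds/ratios must be positive")
        if not 0 <= self.contact_fraction_true <= 1:
            raise ValueError("contact_fraction_true must be in [0, 1]")
        if not all(math.isfinite(g) for g in self.per_window_dg):
            raise ValueError("per_window_dg must be finite")
        for v in self.ic50_per_condition.values():
            if v <= 0:
                raise ValueError("IC50 values must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_window_dg"] = list(self.per_window_dg)
        return d


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition parameters of the synthetic Ca2+ imaging protocol."""

    n_rois: int = 20
    frame_interval: float = 1.3   # s
    duration: float = 360.0       # s
    stimulus_time: float = 10.0   # s
    ionomycin_time: float = 190.0  # s
    noise_sd: float = 1.0         # a.u.
    oscillation_rate: float = 2.0  # events/min while oscillations are active
    gap_mask: tuple = ()          # sample indices excluded (luminescence)

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0 < self.stimulus_time < self.ionomycin_time < self.duration):
            raise ValueError(
                "need 0 < stimulus_time < ionomycin_time < duration")

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration, self.frame_interval)


@dataclass
class TraceEnsemble:
    """Grouped traces for one condition / antibody concentration."""

    traces: list
    condition: str = "wt"
    antibody_conc_molar: float = 0.0
    kind: str = "gcamp"
    background: FluorescenceTrace | None = None

    def __len__(self) -> int:
        return len(self.traces)

    def to_frame(self, series_id: str = "series") -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            rows.append(pd.DataFrame({"series_id": series_id,
                                      "roi_id": tr.roi_id,
                                      "time_s": tr.times,
                                      "value": tr.values}))
        if self.background is not None:
            rows.append(pd.DataFrame({"series_id": series_id,
                                      "roi_id": self.background.roi_id,
                                      "time_s": self.background.times,
                                      "value": self.background.values}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# evoked transient shape (unit peak amplitude)
# ---------------------------------------------------------------------------

def _shape_peak() -> float:
    t_star = RISE_TAU * math.log((RISE_TAU + DECAY_TAU) / RISE_TAU)
    return ((1 - math.exp(-t_star / RISE_TAU))
            * math.exp(-t_star / DECAY_TAU))


def transient_shape(u: np.ndarray) -> np.ndarray:
    """Unit-amplitude evoked transient at time ``u`` after the stimulus.

    A gamma-like rise/decay waveform (rise 10 s, decay 40 s), normalized to
    peak 1, with a linear taper to exactly 0 between 120 and 150 s so the
    transient has compact support.
    """
    u = np.asarray(u, dtype=float)
    p = _shape_peak()
    s = np.where(u >= 0,
                 (1 - np.exp(-np.clip(u, 0, None) / RISE_TAU))
                 * np.exp(-np.clip(u, 0, None) / DECAY_TAU) / p,
                 0.0)
    taper = np.clip((TAPER_END - u) / (TAPER_END - TAPER_START), 0.0, 1.0)
    return s * taper


def transient_area(t0: float, t1: float) -> float:
    """Closed-form integral of the unit-amplitude transient over [t0, t1].

    Valid for windows ending at or before the taper start (120 s).
    """
    if not (0 <= t0 < t1 <= TAPER_START):
        raise ValueError("closed form valid only within [0, taper start]")
    p = _shape_peak()
    tc = RISE_TAU * DECAY_TAU / (RISE_TAU + DECAY_TAU)

    def antideriv(u):
        return (DECAY_TAU * (1 - math.exp(-u / DECAY_TAU))
                - tc * (1 - math.exp(-u / tc)))

    return (antideriv(t1) - antideriv(t0)) / p


def transient_fwhm() -> float:
    """FWHM of the unit transient, found numerically on a fine grid."""
    u = np.linspace(0, TAPER_START, 200001)
    s = transient_shape(u)
    above = np.flatnonzero(s >= 0.5)
    return float(u[above[-1]] - u[above[0]])


def hill_inhibition(conc: float, ic50: float, h: float) -> float:
    """Fractional response remaining at antibody concentration ``conc``."""
    if conc <= 0:
        return 1.0
    return 1.0 / (1.0 + (conc / ic50) ** h)


def dfmax_expected(config: SynthConfig) -> float:
    """The ionomycin dF_max the pipeline will measure on noise-free data."""
    t = config.time_grid()
    t_last = t[-1]
    return IONO_LEVEL * (1 - math.exp(-(t_last - config.ionomycin_time)
                                      / IONO_RISE_TAU))


def expected_ccl(config: SynthConfig, truth: GroundTruth, condition: str,
                 antibody_conc: float = 0.0, t0: float = 0.0,
                 t1: float = 100.0) -> float:
    """Analytic CCL of a noise-free, oscillation-free, bleach-free trace."""
    amp = TRANSIENT_AMP_WT * (truth.effect_ratio_ccl
                              if condition == "mutant" else 1.0)
    amp *= hill_inhibition(antibody_conc,
                           truth.ic50_per_condition[condition], truth.hill_h)
    return amp * transient_area(t0, t1) / dfmax_expected(config)


def gen_gcamp_ensemble(config: SynthConfig, truth: GroundTruth,
                       condition: str = "wt", antibody_conc: float = 0.0,
                       stimulated: bool = True,
                       oscillations: str = "none",
                       ) -> tuple[TraceEnsemble, GroundTruth]:
    """Generate one GCaMP6s trace ensemble plus a cell-free background ROI.

    ``oscillations`` selects when spontaneous events may occur: ``"none"``
    (the default for uptake assays -- spontaneous activity is halted by the
    low-Ca recording medium well before the baseline window), ``"full"``
    (throughout the pre-ionomycin period, for characterizing spontaneous
    activity in normal Ca), or ``"pre-stimulus"``.
    """
    if condition not in truth.ic50_per_condition:
        raise ValueError(f"unknown condition {condition!r}")
    if antibody_conc < 0:
        raise ValueError("antibody concentration must be >= 0")
    rng = substream(truth.seed, f"gcamp/{condition}/{antibody_conc}"
                                f"/{stimulated}/{oscillations}")
    t = config.time_grid()
    amp = TRANSIENT_AMP_WT * (truth.effect_ratio_ccl
                              if condition == "mutant" else 1.0)
    amp *= hill_inhibition(antibody_conc,
                           truth.ic50_per_condition[condition], truth.hill_h)

    if truth.bleach_tau is None:
        bleach = np.ones_like(t)
    else:
        bleach = np.exp(-t / truth.bleach_tau)

    osc_windows = {"pre-stimulus": (0.0, config.stimulus_time),
                   "full": (0.0, config.ionomycin_time),
                   "none": None}[oscillations]
    fwhm_evoked = transient_fwhm()
    osc_sigma = fwhm_evoked / truth.transient_fold / (2 * math.sqrt(2 * math.log(2)))
    osc_amp_mean = TRANSIENT_AMP_WT / truth.transient_fold
    # log-normal with the requested *mean* amplitude
    osc_mu = math.log(osc_amp_mean) - OSC_AMP_SIGMA ** 2 / 2

    iono_sat = np.where(
        t >= config.ionomycin_time,
        IONO_LEVEL * (1 - np.exp(-(t - config.ionomycin_time) / IONO_RISE_TAU)),
        0.0)

    traces = []
    for i in range(config.n_rois):
        extra = np.zeros_like(t)
        if stimulated:
            extra += amp * transient_shape(t - config.stimulus_time)
        if osc_windows is not None and config.oscillation_rate > 0:
            lo, hi = osc_windows
            n_ev = rng.poisson(config.oscillation_rate / 60.0 * (hi - lo))
            ev_t = rng.uniform(lo, hi, n_ev)
            ev_a = rng.lognormal(osc_mu, OSC_AMP_SIGMA, n_ev)
            for et, ea in zip(ev_t, ev_a):
                extra += ea * np.exp(-0.5 * ((t - et) / osc_sigma) ** 2)
        signal = np.maximum(extra, iono_sat)
        values = (BACKGROUND_OFFSET + BASELINE_F0 * bleach + signal
                  + rng.normal(0.0, config.noise_sd, t.size)
                  if config.noise_sd > 0
                  else BACKGROUND_OFFSET + BASELINE_F0 * bleach + signal)
        traces.append(FluorescenceTrace(
            times=t, values=values, roi_id=f"roi{i:03d}",
            stimulus_time=config.stimulus_time,
            ionomycin_time=config.ionomycin_time))

    bg_values = np.full(t.size, BACKGROUND_OFFSET)
    if config.noise_sd > 0:
        bg_values = bg_values + rng.normal(0.0, config.noise_sd, t.size)
    background = FluorescenceTrace(times=t, values=bg_values,
                                   roi_id="background",
                                   stimulus_time=config.stimulus_time,
                                   ionomycin_time=config.ionomycin_time)
    ens = TraceEnsemble(traces=traces, condition=condition,
                        antibody_conc_molar=antibody_conc, kind="gcamp",
                        background=background)
    return ens, truth


def gen_dapi_traces(n: int, slope: float, dead_cell_offset: float,
                    duration: float, seed: int, frame_interval: float = 2.0,
                    noise_sd: float = 1.0, stream: str = "dapi",
                    ) -> TraceEnsemble:
    """Linear DAPI uptake traces: offset + slope*t + noise."""
    if slope < 0:
        raise ValueError("slope must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = substream(seed, stream)
    t = np.arange(0.0, duration, frame_interval)
    traces = []
    for i in range(n):
        v = dead_cell_offset + slope * t
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, t.size)
        traces.append(FluorescenceTrace(times=t, values=v,
                                        roi_id=f"nuc{i:03d}"))
    return TraceEnsemble(traces=traces, kind="dapi")


def atp_shape(u: np.ndarray, peak_time: float = 300.0) -> np.ndarray:
    """Unit-peak ATP luminescence response, peaking at ``peak_time``."""
    u = np.asarray(u, dtype=float)
    return np.where(u > 0, (u / peak_time) * np.exp(1 - u / peak_time), 0.0)


def gen_atp_traces(n_wells: int, baseline: float, fold_peak: float,
                   stimulus_time: float, gap_mask=(), seed: int = 0,
                   interval: float = 30.0, post_duration: float = 600.0,
                   noise_sd: float = 10.0, stream: str = "atp",
                   ) -> TraceEnsemble:
    """Plate-reader luminescence: baseline, then a rise to fold_peak*baseline.

    Samples are spaced ``interval`` seconds apart; ``gap_mask`` lists sample
    indices removed from every well (instrument gaps after the ionophore
    addition).
    """
    if fold_peak < 1:
        raise ValueError("fold_peak must be >= 1")
    if stimulus_time < 2 * interval:
        raise ValueError("need at least 2 pre-stimulus samples")
    rng = substream(seed, stream)
    t = np.arange(0.0, stimulus_time + post_duration + interval, interval)
    keep = np.ones(t.size, dtype=bool)
    for idx in gap_mask:
        keep[idx] = False
    t_kept = t[keep]
    traces = []
    for i in range(n_wells):
        v = baseline * (1.0 + (fold_peak - 1.0) * atp_shape(t - stimulus_time))
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, t.size)
        traces.append(FluorescenceTrace(times=t_kept, values=v[keep],
                                        roi_id=f"well{i:02d}",
                                        stimulus_time=stimulus_time))
    return TraceEnsemble(traces=traces, kind="atp")


def gen_fep_samples(per_window_dg, work_sd: float, n_samples: int,
                    temperature: float = 310.0, seed: int = 0,
                    stream: str = "fep") -> WindowWorkSamples:
    """Crooks-consistent Gaussian work samples for each lambda window.

    Forward work ~ N(dg_i + sigma^2/(2RT), sigma^2) and reverse work
    ~ N(-dg_i + sigma^2/(2RT), sigma^2), in kcal/mol, which satisfies the
    Crooks fluctuation relation at the stated temperature.
    """
    dgs = np.asarray(per_window_dg, dtype=float)
    if work_sd < 0:
        raise ValueError("work_sd must be >= 0")
    if n_samples < 2:
        raise ValueError("need at least 2 samples per direction")
    rng = substream(seed, stream)
    rt = kt(temperature)
    shift = work_sd ** 2 / (2 * rt)
    fwd, rev = [], []
    for dg in dgs:
        if work_sd == 0:
            fwd.append(np.full(n_samples, dg))
            rev.append(np.full(n_samples, -dg))
        else:
            fwd.append(rng.normal(dg + shift, work_sd, n_samples))
            rev.append(rng.normal(-dg + shift, work_sd, n_samples))
    return WindowWorkSamples(forward=fwd, reverse=rev, temperature=temperature)


# toy trajectory geometry: two residue "triads" plus one hydrogen each
_GROUP_A = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 1.2, 0.0]])
_GROUP_A_H = np.array([[0.0, 0.0, 1.0]])


def gen_toy_trajectory(contact_schedule, seed: int = 0,
                       contact_distance: float = 2.5,
                       apart_distance: float = 4.5) -> TrajectoryFrames:
    """Two residue groups with a prescribed per-frame contact schedule.

    On scheduled frames the minimum heavy-atom distance between the groups
    is exactly ``contact_distance`` (default 2.5 A, i.e. < 3 A contact);
    otherwise it is ``apart_distance`` (default 4.5 A). Each frame is given
    an independent rigid-body pose, which preserves all distances.
    """
    schedule = np.asarray(contact_schedule, dtype=bool)
    if schedule.ndim != 1 or schedule.size < 1:
        raise ValueError("contact_schedule must be a non-empty 1-D sequence")
    if contact_distance <= 0.5 or apart_distance <= 0.5:
        raise ValueError("degenerate geometry: groups would overlap")
    rng = substream(seed, "trajectory")

    atoms = pd.DataFrame({
        "chain": ["A", "A", "A", "A", "H", "H", "H", "H"],
        "res_number": [178, 178, 178, 178, 56, 56, 56, 56],
        "res_name": ["ASP"] * 4 + ["SER"] * 4,
        "atom_name": ["CB", "CG", "OD1", "HB2", "CB", "OG", "CA", "HB2"],
        "is_hydrogen": [False, False, False, True,
                        False, False, False, True],
    })

    frames = np.empty((schedule.size, 8, 3))
    for f, in_contact in enumerate(schedule):
        d = contact_distance if in_contact else apart_distance
        # closest heavy pair is A:(1.2,0,0) vs B:(1.2+d,0,0)
        group_b = _GROUP_A + np.array([d + 1.2, 0.0, 0.0])
        group_b_h = np.array([[d + 1.2, 0.0, 1.0]])
        xyz = np.vstack([_GROUP_A, _GROUP_A_H, group_b, group_b_h])
        # random rigid pose (distance-preserving)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, 2 * np.pi)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = (np.eye(3) + np.sin(angle) * k
               + (1 - np.cos(angle)) * (k @ k))
        frames[f] = xyz @ rot.T + rng.uniform(-5, 5, 3)
    # reorder atoms to interleave as listed in the table
    order = [0, 1, 2, 3, 4, 5, 6, 7]
    return TrajectoryFrames(atoms=atoms, coords=frames[:, order])
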