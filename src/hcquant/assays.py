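"""Hemichannel activity statistics.

Implements the assay read-outs used to quantify connexin hemichannel
function and its pharmacological block:

* CCL (cytosolic Ca2+ load): area under the dF/dF_max trace over a fixed
  post-stimulus window (default 0-100 s, t = 0 at the stimulus).
* DAPI uptake rate: origin-constrained linear regression slope of the
  first-frame-subtracted nuclear fluorescence.
* ATP release: area under the baseline-subtracted luminescence curve plus
  the peak fold over baseline.
* qPCR relative expression by the 2^-ddCt method.
* Antibody dose-response: Hill fit of normalized CCL vs concentration,
  exposed both as a plain function and as a Model/Results pair.

All integrals are trapezoidal: exact for piecewise-linear signals and
robust to the irregular sampling left by instrument gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .traces import FluorescenceTrace, NormalizedTrace


def _trapz_window(times: np.ndarray, values: np.ndarray,
                  t0: float, t1: float) -> float:
    """Trapezoidal integral of a sampled signal over [t0, t1].

    Window endpoints that fall off-grid are included by linear
    interpolation, so the result is exact for piecewise-linear signals.
    """
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError(
            f"integration window [{t0}, {t1}] outside trace support "
            f"[{times[0]}, {times[-1]}]")
    if t1 <= t0:
        raise ValueError("window must have t1 > t0")
    inner = (times > t0) & (times < t1)
    grid = np.concatenate(([t0], times[inner], [t1]))
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


@dataclass(frozen=True)
class CclResult:
    """Cytosolic Ca2+ load of one ROI: area under dF/dF_max."""

    roi_id: str
    area: float  # dimensionless * seconds
    window: tuple[float, float]


@dataclass(frozen=True)
class AtpResult:
    """ATP-release read-out of one well."""

    well_id: str
    baseline: float
    auc: float  # a.u. * seconds, baseline-subtracted
    peak_fold: float


@dataclass(frozen=True)
class QpcrMeasurement:
    """Threshold cycles for target and reference gene, treated vs control."""

    ct_target_treated: np.ndarray
    ct_ref_treated: np.ndarray
    ct_target_control: np.ndarray
    ct_ref_control: np.ndarray

    def __post_init__(self):
        for name in ("ct_target_treated", "ct_ref_treated",
                     "ct_target_control", "ct_ref_control"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size < 1:
                raise ValueError(f"{name} needs at least one replicate")
            if np.any((arr <= 0) | (arr >= 45)):
                raise ValueError(f"{name} has Ct values outside (0, 45)")
            object.__setattr__(self, name, arr)


def compute_ccl(norm: NormalizedTrace, t0: float = 0.0,
                t1: float = 100.0) -> CclResult:
    """Area under dF/dF_max over [t0, t1], times relative to the stimulus."""
    t_rel = norm.times - norm.stimulus_time
    area = _trapz_window(t_rel, norm.dff, t0, t1)
    return CclResult(roi_id=norm.roi_id, area=area, window=(t0, t1))


def dapi_rate(trace: FluorescenceTrace) -> float:
    """Origin-constrained uptake rate in a.u./s.

    The first sample is subtracted from the whole trace (removing the
    contribution of cells already permeable at t = 0) and time is re-zeroed,
    after which the least-squares line through the origin has the closed
    form slope = sum(t*F) / sum(t^2).
    """
    if trace.n < 3:
        raise ValueError("DAPI rate needs at least 3 samples")
    t = trace.times - trace.times[0]
    f = trace.values - trace.values[0]
    denom = float(np.sum(t * t))
    if denom == 0.0:
        raise ValueError("all times identical; cannot fit a rate")
    return float(np.sum(t * f) / denom)


def atp_release(lum: FluorescenceTrace, stimulus_time: float,
                horizon: float = 600.0) -> AtpResult:
    """Baseline-subtracted luminescence AUC and peak fold over baseline.

    The baseline is the mean of pre-stimulus readings; the AUC integrates
    L - baseline over [stimulus, stimulus + horizon] with linear
    interpolation bridging instrument gaps.
    """
    pre = lum.times < stimulus_time
    if pre.sum() < 2:
        raise ValueError("need at least 2 pre-stimulus samples")
    baseline = float(lum.values[pre].mean())
    if baseline <= 0:
        raise ValueError("baseline luminescence must be positive")
    t1 = min(stimulus_time + horizon, float(lum.times[-1]))
    if t1 <= stimulus_time:
        raise ValueError("no post-stimulus samples within the horizon")
    auc = _trapz_window(lum.times, lum.values - baseline, stimulus_time, t1)
    peak_fold = float(lum.values.max() / baseline)
    return AtpResult(well_id=lum.roi_id, baseline=baseline, auc=auc,
                     peak_fold=peak_fold)


def ddct_fold(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = mean(Ct_target) - mean(Ct_reference) per condition;
    ddCt = dCt_treated - dCt_control; fold = 2^-ddCt.
    """
    dct_treated = m.ct_target_treated.mean() - m.ct_ref_treated.mean()
    dct_control = m.ct_target_control.mean() - m.ct_ref_control.mean()
    return float(2.0 ** (-(dct_treated - dct_control)))


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResults:
    """Hill-fit results for an antibody inhibition panel.

    ``normalized_response`` is mean CCL at each concentration divided by the
    control (c = 0) mean, so the control point is 1 by construction. The fit
    is R(c) = floor + (1 - floor) / (1 + (c/ic50)^h), performed in log10
    concentration on the non-zero points only.
    """

    concentrations: np.ndarray          # molar, includes the 0 control
    mean_ccl: np.ndarray
    normalized_response: np.ndarray
    ic50: float                         # molar
    hill_h: float
    floor: float
    ic50_ci: tuple[float, float]
    hill_h_ci: tuple[float, float]
    floor_ci: tuple[float, float]
    flagged: bool
    diagnostics: dict = field(default_factory=dict)

    def predict(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.floor + (1 - self.floor) / (1 + (c / self.ic50) ** self.hill_h)

    def summary(self) -> str:
        lines = [
            "Hill inhibition fit (normalized CCL vs concentration)",
            "=" * 56,
            f"IC50            {self.ic50:.4g} M "
            f"(95% CI {self.ic50_ci[0]:.4g} - {self.ic50_ci[1]:.4g})",
            f"Hill h          {self.hill_h:.3f} "
            f"(95% CI {self.hill_h_ci[0]:.3f} - {self.hill_h_ci[1]:.3f})",
            f"floor           {self.floor:.3f} "
            f"(95% CI {self.floor_ci[0]:.3f} - {self.floor_ci[1]:.3f})",
            f"flagged         {self.flagged}",
            f"n concentrations {len(self.concentrations)}",
        ]
        return "\n".join(lines)


class DoseResponseModel:
    """Antibody dose-response model for per-ROI CCL panels.

    Parameters
    ----------
    concentrations : sequence of float
        Antibody concentrations in molar; must include 0 (the control used
        as the normalizer) and at least 4 distinct non-zero values.
    ccls : sequence of arrays
        Per-ROI CCL values for each concentration, in the same order.
    """

    _HILL_BOUNDS = ((0.3, 4.0), (0.0, 0.99))  # h, floor

    def __init__(self, concentrations, ccls):
        conc = np.asarray(concentrations, dtype=float)
        if conc.ndim != 1 or len(ccls) != conc.size:
            raise ValueError("one CCL sample per concentration required")
        if not np.any(conc == 0):
            raise ValueError("a concentration-0 control is required")
        nonzero = np.unique(conc[conc > 0])
        if nonzero.size < 4:
            raise ValueError("need at least 4 distinct non-zero concentrations")
        order = np.argsort(conc)
        self.concentrations = conc[order]
        self.ccls = [np.asarray(ccls[i], dtype=float) for i in order]

    @staticmethod
    def _hill(logc: np.ndarray, log_ic50: float, h: float,
              floor: float) -> np.ndarray:
        return floor + (1 - floor) / (1 + 10 ** (h * (logc - log_ic50)))

    def _fit_point(self, responses: np.ndarray, logc: np.ndarray):
        (h_lo, h_hi), (f_lo, f_hi) = self._HILL_BOUNDS
        lo_b = logc.min() - 3.0
        hi_b = logc.max() + 3.0
        # start near the half-response concentration
        i0 = int(np.argmin(np.abs(responses - 0.5)))
        x0 = (float(np.clip(logc[i0], lo_b, hi_b)), 1.0,
              float(np.clip(responses.min() * 0.5, f_lo, f_hi - 1e-6)))
        res = least_squares(
            lambda p: self._hill(logc, *p) - responses, x0,
            bounds=([lo_b, h_lo, f_lo], [hi_b, h_hi, f_hi]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        return res

    def fit(self, n_boot: int = 200, seed: int = 0) -> DoseResponseResults:
        """Fit the Hill curve; bootstrap ROIs within each concentration."""
        mean_ccl = np.array([c.mean() for c in self.ccls])
        control = float(mean_ccl[self.concentrations == 0][0])
        if control == 0:
            raise ValueError("control mean CCL is zero; cannot normalize")
        norm = mean_ccl / control

        mask = self.concentrations > 0
        logc = np.log10(self.concentrations[mask])
        resp = norm[mask]

        res = self._fit_point(resp, logc)
        log_ic50, h, floor = res.x
        lo_b, hi_b = logc.min() - 3.0, logc.max() + 3.0
        at_bound = (log_ic50 <= lo_b + 1e-6) or (log_ic50 >= hi_b - 1e-6)
        span = resp.max() - resp.min()
        flagged = bool((not res.success) or at_bound or span < 0.05)

        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 3))
        nz_ccls = [c for c, m in zip(self.ccls, mask) if m]
        ctrl_ccl = self.ccls[int(np.argmax(self.concentrations == 0))]
        for b in range(n_boot):
            ctrl_mean = rng.choice(ctrl_ccl, ctrl_ccl.size).mean()
            if ctrl_mean == 0:
                boots[b] = np.nan
                continue
            r_b = np.array([rng.choice(c, c.size).mean() for c in nz_ccls])
            r_b = r_b / ctrl_mean
            try:
                boots[b] = self._fit_point(r_b, logc).x
            except Exception:
                boots[b] = np.nan
        ok = ~np.isnan(boots[:, 0])
        if ok.sum() >= 10:
            lo, hi = np.nanpercentile(boots[ok], [2.5, 97.5], axis=0)
            ic50_ci = (10 ** lo[0], 10 ** hi[0])
            h_ci = (lo[1], hi[1])
            floor_ci = (lo[2], hi[2])
            # a CI touching the artificial bracket, or a response range too
            # small to define a half-maximal point, means the data carry no
            # information about the IC50
            if lo[0] <= lo_b + 0.1 or hi[0] >= hi_b - 0.1 or span < 0.05:
                flagged = True
                ic50_ci = (0.0, np.inf)
        else:
            flagged = True
            ic50_ci = (0.0, np.inf)
            h_ci = (np.nan, np.nan)
            floor_ci = (np.nan, np.nan)

        return DoseResponseResults(
            concentrations=self.concentrations, mean_ccl=mean_ccl,
            normalized_response=norm, ic50=float(10 ** log_ic50),
            hill_h=float(h), floor=float(floor), ic50_ci=ic50_ci,
            hill_h_ci=h_ci, floor_ci=floor_ci, flagged=flagged,
            diagnostics={"residual_norm": float(np.linalg.norm(res.fun)),
                         "success": bool(res.success),
                         "n_boot_ok": int(ok.sum())})


def fit_dose_response(concentrations, ccls, n_boot: int = 200,
                      seed: int = 0) -> DoseResponseResults:
    """Functional wrapper around :class:`DoseResponseModel`."""
    return DoseResponseModel(concentrations, ccls).fit(n_boot=n_boot, seed=seed)


def ccl_table(results: list[CclResult]) -> pd.DataFrame:
    """Tidy per-ROI CCL table."""
    return pd.DataFrame({"roi_id": [r.roi_id for r in results],
                         "ccl": [r.area for r in results]})
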