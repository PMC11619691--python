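# Methods

This note documents the models behind `hcquant`: what the synthetic data
emulate, how each estimator works, the defaults and why, and what passing
the test suite does and does not establish about real data.

## Synthetic GCaMP6s ensembles

Each ROI trace is built as

    F(t) = B + F0·exp(−t/τ_b) + S(t) + ε(t)

with background offset B = 10 a.u. (cell-free back-reflection and
electronic offset), baseline indicator fluorescence F0 = 100 a.u. subject
to photobleaching with τ_b = 600 s by default (mild, ~25% over the 6-min
acquisition; the time constant is a generator choice — imaging conditions
vary widely — and `bleach_tau=None` disables it), signal S(t), and
i.i.d. Gaussian noise with σ = 1 a.u. (1% of baseline; ROI averaging over
hundreds of pixels makes sub-percent noise realistic for a bright
indicator).

The signal has three components:

* **Evoked transient** — a gamma-like waveform (1−e^(−u/τ_r))·e^(−u/τ_d)
  normalized to unit peak, with rise τ_r = 10 s and decay τ_d = 40 s,
  linearly tapered to exactly zero between 120 and 150 s after the
  stimulus. The taper gives the transient compact support, so the late
  pre-ionomycin segment is genuinely quiescent; it does not affect the
  0–100 s quantification window, over which the waveform's integral has
  the closed form used by the exact-recovery tests. The amplitude is
  50 a.u. for wild type, ×1.58 for the mutant (the condition effect), and
  ×1/(1+(c/IC50)^h) under antibody at concentration c with IC50 10 nM
  (WT) / 80 nM (mutant) and h = 1.
* **Spontaneous oscillations** — Poisson-timed Gaussian bumps (rate
  2 events/min while active) with log-normal amplitudes (mean = evoked
  amplitude / 9, shape 0.3) and width set so their FWHM is 1/9 of the
  evoked FWHM. Stimulated (uptake-assay) ensembles carry no oscillations:
  the assay holds cells in low-Ca medium, which quenches spontaneous
  activity before the baseline window; spontaneous-characterization
  ensembles enable them over the whole pre-ionomycin epoch.
* **Ionomycin saturation** — from the ionomycin time the signal rises to a
  saturation level of 200 a.u. with a 3-s time constant, replacing (not
  adding to) whatever signal is smaller. Saturation mirrors the indicator
  ceiling and makes ΔF_max identical across conditions, which is what
  renders the CCL ratio exactly recoverable at zero noise.

Other generators: DAPI traces are offset + slope·t + noise at a 2-s frame
interval (the acquisition interval is not fixed by the assay; 2 s is a
configurable default); ATP luminescence rises as (u/300)·e^(1−u/300) to
`fold_peak`×baseline (peak 300 s post-stimulus) at 30-s cadence with an
index-based gap mask; FEP work samples are Gaussian with forward mean
dg + σ²/2RT and reverse mean −dg + σ²/2RT (Crooks-consistent); toy
trajectories place two residue groups at exactly 2.5 Å (contact) or 4.5 Å
(apart) minimum heavy-atom distance per scheduled frame, each frame in a
random rigid pose.

Seeding: one integer seed is expanded into independent per-stream
sub-seeds keyed by a CRC of the stream label, so adding a generator never
perturbs another's draws, and identical (config, seed) give bit-identical
output.

## Trace preprocessing

1. **Background.** The cell-free background ROI is replaced by a smooth
   model of itself (offset + slow exponential drift, time constant bounded
   below by half the trace span) before subtraction. Subtracting the raw
   background would inject one shared noise realization into every ROI of
   the ensemble — a bias that ROI-resampling bootstraps cannot see.
2. **Bleach correction.** a·e^(−t/τ)+c is fitted on the quiescent
   segments only (pre-stimulus, plus post-transient/pre-ionomycin), so
   evoked signal never biases the fit. τ is profiled: for each candidate τ
   the linear pair (a, c) is solved exactly, avoiding the a/τ ridge that
   defeats joint 3-parameter optimization when the decay is slow relative
   to the window; the grid stops at 5× the window span because slower
   trends are indistinguishable from linear (and the basis becomes
   collinear with the intercept). A 10-s baseline cannot identify a
   ~600-s decay on its own, and the illumination is shared, so the
   pipeline estimates τ once on the ensemble-mean trace (or across a
   whole dose panel) and then fits only amplitude/offset per ROI by
   linear least squares. The corrected trace is F − a·e^(−t/τ) (trend
   removed, offset retained).
3. **Normalization.** F₀ is the mean of pre-stimulus samples,
   ΔF = F − F₀, and ΔF_max the maximum of a 5-sample moving average of ΔF
   within the ionomycin window — the raw maximum of a saturated plateau
   rides the largest of ~100 noise excursions and would bias ΔF_max
   upward by ~2.5σ. ROIs with non-positive ionomycin response are
   excluded with a recorded reason.

CCL is the trapezoidal integral of ΔF/ΔF_max over 0–100 s post-stimulus
(endpoints interpolated if off-grid); per-ROI areas are averaged per
condition. Negative fluorescence is never clamped, keeping all areas
linear in the signal. The mutant/WT ratio's confidence interval comes
from a full-pipeline bootstrap: each replicate resamples ROIs and reruns
background modeling, shared bleach fitting and normalization, so the CI
reflects every estimation step.

## Event statistics (spontaneous vs evoked)

The evoked transient's amplitude is the 3-point average around the apex
of the corrected ΔF (noise-robust for a wide peak) and its FWHM comes
from linearly interpolated half-maximum crossings. Spontaneous events are
detected by matched filtering: the corrected trace is convolved with a
Gaussian template at the event timescale (self-calibrated from a
high-threshold first pass) minus an 8×-broader Gaussian (removing slow
bleach-fit residuals), and local maxima above 3.5× the propagated noise
level are kept. Each isolated event is then characterized by a local
Gaussian least-squares fit to the raw trace with the offset pinned to the
trace median (a free offset is degenerate with a near-flat Gaussian on a
short window); FWHM = √(8 ln 2)·σ̂.

Poisson timing makes event pile-up unavoidable: two bumps closer than the
filter's resolution limit w = 2√2·σ_template merge into one apex, so
detected amplitudes are cluster sums. The mean cluster size for a Poisson
process is e^(λw); λ is recovered from the observed cluster rate by
fixed-point iteration and the amplitude mean divided by e^(λw).
**Known limitation:** the cluster-rate estimate has finite detection
efficiency, so the correction is incomplete and the spontaneous amplitude
mean stays ~5–15% high — equivalently the evoked/spontaneous amplitude
fold reads ~8–8.7 when the generating truth is 9. The FWHM fold does not
suffer from pile-up (width is amplitude-independent) and is unbiased.
On real recordings, quasi-periodic (non-Poisson) oscillation timing would
reduce pile-up and this bias.

## Dose–response

Responses are mean CCL at each concentration divided by the control
(c = 0) mean, so the control is the normalizer and not a fitted point.
The Hill fit runs in log₁₀ concentration with a free floor (incomplete
inhibition at the top concentration is a real feature of weakened
binding), h bounded to [0.3, 4] and IC50 bracketed three decades beyond
the tested range. Confidence intervals bootstrap ROIs within each
concentration. A fit is flagged — rather than raised — when the response
span is under 0.05, the IC50 lands on its bracket, or the bootstrap CI
touches it; a flagged fit reports an unbounded IC50 CI.

## Free energies

`bar_estimator` solves the Bennett self-consistent equation by bracketed
Brent root finding to 10⁻⁹ kcal/mol; the logistic form is evaluated with
`expit` for stability, and the equation's monotonicity in ΔG guarantees a
unique root. Uncertainty is a seeded bootstrap over samples in both
directions. `exp_estimator` (one-sided exponential averaging with
log-sum-exp stabilization) is retained as a cross-check; on
Crooks-consistent Gaussian work BAR's error is verified to be no worse.
Windows sum into a leg with standard errors in quadrature (windows are
independent); the cycle is ΔΔG = ΔG_complex − ΔG_free with
positive = weakened binding; the six per-protomer ΔΔG values (the
mutated residues on different protomers do not interact) sum to the
total, and the affinity fold change is exp(ΔΔG/RT) with
R = 1.9872×10⁻³ kcal/(mol·K), reported also as its nearest power of ten.
The conversion temperature defaults to 310 K, matching the thermostat of
the simulations the work samples would come from.

The synthetic FEP study runs five independent replicas per protomer and
leg — 32 windows, 750 samples per direction per window (the order
produced by 1.5 ns/window sampled every 10 ps across five replicas),
per-window work s.d. 0.25 kcal/mol (sub-kT overlap typical of a 32-window
ladder) — and reports the replica mean with replica-scatter standard
errors. The six ground-truth protomer contributions default to
(1.43, 0.50, −0.37, −0.08, −0.08, −0.08) kcal/mol: three resolvable
contributions and three small ones summing to a 1.32 kcal/mol total,
read as ~10-fold affinity loss at 310 K. The component sum of the three
printed-size contributions (1.56) and the supplied total are reported
side by side without reconciliation.

## Trajectory statistics

Contacts: per frame, the minimum heavy-atom distance between two
selections (hydrogens always excluded); contact iff strictly below the
cutoff (default 3.0 Å — a pair at exactly the cutoff is a non-contact);
the fraction is the per-frame mean. RMSD uses Kabsch superposition
(SVD with reflection guard) onto a reference frame; collinear atom sets
are rejected because they leave a rotational degree of freedom.
Multi-model PDB I/O goes through biotite; coordinates survive the
3-decimal PDB format far within the 2 Å margin between the toy
geometries.

## Statistics

All groups must pass Shapiro–Wilk at α for the parametric branch
(one-way ANOVA, Bonferroni-adjusted two-sided t-tests; a plain t-test for
two groups); any failure — including a constant group, for which
normality is undefined — routes to Kruskal–Wallis with the standard tie
correction and Dunn's pairwise z-tests on the joint ranking under the
Šidák adjustment 1−(1−p)^m. Stars use nested thresholds: * p<0.05,
** p<0.005, *** p<0.0005 (the overlapping conventions in circulation are
reconciled as strictly nested intervals). Summaries are mean ± s.e.m.
with n.

## Problem sizes and determinism

The default synthetic study uses 30 ROIs per condition for the CCL
comparison, 15 ROIs × 7 concentrations per dose panel, 40 nuclei for
DAPI, 5 wells × 5 conditions for ATP, 100 frames per toy trajectory and
the FEP dimensions above; `scripts/acceptance.py` finishes in well under
a minute and the test suite in about a minute. Every random draw
descends from the single `--seed`/config seed, so reports are
byte-identical across reruns.

## What the tests do and do not show

Zero-noise recovery to ≤10⁻⁶ and noisy recovery within bootstrap CIs
demonstrate that the estimator chain is internally consistent and
unbiased under the generator's assumptions: additive Gaussian noise,
exponential bleaching shared within an ensemble, linear superposition of
events, saturating ionomycin response, Crooks-consistent work samples,
and equilibrium-sampled λ-windows. Real recordings violate several of
these (motion, focus drift, indicator nonlinearity, correlated noise,
non-Poisson oscillation timing, HREX correlation between windows), so
passing here bounds algorithmic error, not biological measurement error.
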