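# hcquant

Quantification of connexin hemichannel activity assays and of the
energetics of antibody–hemichannel binding.

Mutations in *GJB1*/Cx32 cause the X-linked Charcot–Marie–Tooth neuropathy
CMTX1; several of them, including p.D178Y, leave "leaky" hemichannels (HCs)
in the plasma membrane whose deregulated Ca²⁺ and metabolite fluxes are
thought to drive the disease. A candidate therapeutic is an anti-connexin
antibody that plugs the extracellular mouth of the channel. Assessing such
an antibody requires a quantitative chain from raw fluorescence movies and
plate-reader kinetics to channel-activity statistics and inhibition
constants, and — on the structural side — from alchemical free-energy
simulations to a binding-affinity change. `hcquant` implements that chain
as a reusable, fully tested Python library with a synthetic-data module so
every stage can be validated against known ground truth.

## What it computes

**Ca²⁺ uptake.** GCaMP6s traces F(t) per ROI are background-subtracted,
corrected for photobleaching (a·e^(−t/τ)+c fitted on quiescent segments,
with the decay shared across the ensemble), and normalized to
ΔF/ΔF_max, where ΔF_max is the maximum response evoked by ionomycin.
The cytosolic Ca²⁺ load is the area under ΔF/ΔF_max over a fixed
post-stimulus window:

    CCL = ∫₀¹⁰⁰ ΔF(t)/ΔF_max dt   (t = 0 at the stimulus)

**Antibody dose–response.** Normalized CCL versus antibody concentration
is fitted with a Hill inhibition curve

    R(c) = floor + (1 − floor) / (1 + (c/IC50)^h)

in log₁₀ concentration, with bootstrap confidence intervals
(`DoseResponseModel(...).fit()` returns a results object with
`summary()`).

**DAPI uptake and ATP release.** Dye uptake rate as the origin-constrained
regression slope ΣtF/Σt² after first-frame subtraction; ATP release as the
area under the baseline-subtracted luminescence curve with linear
interpolation across instrument gaps, plus the peak fold over baseline.
qPCR fold changes use the 2^−ΔΔCt method.

**Binding energetics.** Per-λ-window forward/reverse work samples are
combined with the Bennett acceptance ratio (solving
Σ_F f(β(W_F−ΔG)+M) = Σ_R f(β(W_R+ΔG)−M), f the logistic function), windows
sum into the complex and free legs, the thermodynamic cycle gives
ΔΔG = ΔG_complex − ΔG_free per protomer, the six protomer contributions of
the hexamer sum to a total, and the affinity fold change is exp(ΔΔG/RT).
Trajectory statistics (residue contact fractions at a 3 Å heavy-atom
cutoff, Kabsch-aligned RMSD) come from multi-model PDB input.

**Statistics.** The group-comparison tree mirrors standard practice:
Shapiro–Wilk per group; ANOVA + Bonferroni t-tests when all groups pass,
otherwise Kruskal–Wallis with Dunn–Šidák pairwise z-tests; summaries as
mean ± s.e.m. with significance stars (\*, \*\*, \*\*\* at 0.05 / 0.005 /
0.0005).

## Worked example

```python
from hcquant import (GroundTruth, SynthConfig, gen_gcamp_ensemble,
                     preprocess_ensemble, compute_ccl)
from hcquant.pipeline import ccl_ratio_with_ci

truth = GroundTruth(seed=1)          # mutant CCL = 1.58x wild type
config = SynthConfig(n_rois=30)
wt, _ = gen_gcamp_ensemble(config, truth, condition="wt")
mut, _ = gen_gcamp_ensemble(config, truth, condition="mutant")
ratio, ci = ccl_ratio_with_ci(mut, wt, seed=1)
print(f"CCL ratio mutant/WT: {ratio:.3f}  95% CI ({ci[0]:.3f}, {ci[1]:.3f})")
```

prints

```
CCL ratio mutant/WT: 1.585  95% CI (1.579, 1.592)
```

i.e. the pipeline recovers the generator's 1.58-fold mutant Ca²⁺-load
increase from noisy traces, with a bootstrap CI that covers the truth.
The same round trip exists for every stage; `hcquant run-all --seed 1
--out report/` executes the whole synthetic study (Ca²⁺ uptake, dose–
response for both conditions, DAPI, ATP, the six-protomer FEP cycle and
the contact analysis) and writes one JSON report.

## Command line

One subcommand per stage, tidy CSV in, JSON out:

```
hcquant simulate --seed 1 --n-rois 20 --out traces.csv
hcquant ccl traces.csv --out ccl.json
hcquant dose panel.csv
hcquant qpcr ct.csv --target cx32 --reference gapdh --treated dox --control ctrl
hcquant fep work.csv
hcquant contacts traj.pdb --chain-a A --res-a 178 --chain-b H --res-b 56
hcquant stats groups.csv --out comparison.json
hcquant run-all --seed 1 --out report/
```

Exit codes: 0 success, 1 validation error, 2 runtime failure.

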