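# Methods

## Signal model and relaxometry

All volumes are assumed to come from a spoiled gradient-echo (SPGR)
steady state,

    S = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1).

Precontrast T1 and M0 are estimated per voxel from the repeat-averaged
variable-flip-angle signals by the standard linearization (regress
S/sin α on S/tan α; the slope is E1).  Voxels whose slope leaves (0, 1)
are marked invalid (NaN) rather than raising — pure-noise background
voxels are expected and harmless.  The ten repeats per flip angle are
averaged before the fit; no B1 or water-exchange correction is applied.

Dynamic frames are converted to concentration by inverting the SPGR
equation for T1(t) and applying linear relaxivity,
C(t) = (R1(t) − R1(0))/r1 with R1 = 1/T1 in s⁻¹.  Before inversion, M0
is rescaled per voxel so the modeled baseline signal matches the mean
of the first `baseline_frames` dynamic frames; this absorbs scanner
scaling differences between the VFA and dynamic acquisitions and
anchors C = 0 at baseline.  Frames whose implied E1 leaves (0, 1)
(noise excursions at very high enhancement) become NaN and are skipped
by the fitters.

Defaults and their units:

| parameter | default | unit | rationale |
|---|---|---|---|
| TR / TE | 4.4 / 2.1 | ms | 1.5 T THRIVE dynamic protocol |
| flip angles | 6, 12, 18 (dyn 18) | deg | VFA triple + dynamic flip |
| frame spacing | 2.5 | s | dynamic temporal resolution |
| r1 relaxivity | 4.5 | L mmol⁻¹ s⁻¹ | mid-range gadolinium value at 1.5 T; the source study's agent naming is ambiguous, so this is deliberately a config knob |
| hematocrit | 0.42 | — | population default; config knob |
| tissue / blood T1 | 1000 / 1400 | ms | literature 1.5 T values, used by the generator |

The arterial input function is the voxelwise **median** concentration
curve over the artery ROI (robust to partial-volume edge voxels),
divided by (1 − Hct) to convert whole blood to plasma.  A peak below
1 mM raises a low-quality warning, mirroring the exclusion of
AIF-sampling failures in clinical practice.

## Kinetic models

Units throughout: Ktrans and Kep in min⁻¹; Ve and Vp in mL/100 mL; F
and PS in mL/min/100 mL; Tc (= MTT) in seconds.

**Extended Tofts.**  C(t) = (Vp/100)·Cp(t) + Ktrans ∫ Cp e^(−Kep(t−u))du,
Kep = 100·Ktrans/Ve.  The convolution with an exponential kernel is
evaluated exactly for a piecewise-linear Cp via a one-pole recursive
filter, so there is no quadrature error on the frame grid.

**Distributed parameter.**  The capillary is a plug-flow tube (transit
time Tc) exchanging with a well-mixed interstitium.  The residue is

    R(t) = 1                                   t < Tc
    R(t) = E − ∫₀^{t−Tc} g(u) du               t ≥ Tc
    g(u) = e^(−kp·Tc − ke·u) √(kp·ke·Tc/u) · I₁(2√(kp·ke·Tc·u))

with kp = PS/Vp, ke = PS/Ve, E = 1 − e^(−PS/F), and the tissue curve is
(F/100)(R ⊛ Cp).  The Bessel factor uses the exponentially scaled
`i1e` with all exponentials collected into one non-positive argument,
so it cannot overflow; the √(1/u)·I₁ product at u → 0 is replaced by
its series limit kp·ke·Tc·e^(−kp·Tc).

The forward convolution splits R into its two phases: the vascular
box-car contributes ∫_{t−Tc}^{t} Cp exactly (running integral of the
piecewise-linear AIF), and only the smooth reflux tail is convolved by
trapezoid on an internal grid (default 0.5 s), so the discontinuity of
R at Tc causes no quadrature error.  The parameterization fitted is
(F, Tc, Ve, PS) with Vp = F·Tc/60 derived — this makes MTT an estimated
primitive and the Vp identity exact by construction, consistent with
reported tumor values where Vp/F reproduces the printed MTT.

**Independent oracle.**  `dp_pde_oracle` solves the underlying
two-region convection–exchange PDE (first-order upwind in space,
explicit stepping with CFL- and exchange-limited sub-steps) and returns
the volume-weighted spatial average.  It shares no code with the
analytic path and pins it to <1% of curve peak over the tumor parameter
range; halving the spatial step shrinks the gap (first-order
convergence), which is the test that the agreement is not coincidental.

## Voxelwise fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`)
with multi-start: one physiologically typical start plus a seeded Latin
hypercube over the bounds, mapped through u² so starts concentrate near
the lower bounds where tumor values live.  The best SSR wins; ties go
to the smaller parameter-vector norm (determinism).  Bounds default to
generous supersets of reported tumor ranges (Ktrans ≤ 3 min⁻¹,
Ve ≤ 60, Vp ≤ 20 mL/100 mL, F ≤ 200 mL/min/100 mL, Tc ∈ [0.5, 60] s,
PS ≤ 100).  All-zero curves short-circuit to the zero boundary solution
with SSR = 0.  Noiseless forward-generated curves are recovered to
better than 1% relative; a run whose best SSR reaches the numerical
floor stops early, which keeps noiseless identity tests cheap without
affecting noisy fits.

**Bolus-arrival delay.**  The ET functional form has no transit time,
so when tissue curves carry a real plug-flow delay the fitted Vp
degenerates (it trades off against Ktrans and can even invert group
ordering).  The pipeline therefore runs a grid search over AIF shifts
of 0–10 s in frame steps for ET fits by default; DP fits do not need
it because Tc absorbs arrival delay natively.  Both behaviors are
config switches (`StudyConfig.fit_delay`), as is whether the AIF is
plasma or whole blood.

ROI aggregation records the per-parameter **median** over converged
voxels; failed voxels are NaN in the maps and excluded from medians,
with a warning when more than half an ROI fails.  SSR outliers are
deliberately not trimmed.

## Cohort statistics

- Risk rule: low risk iff endometrioid grade 1–2 with no deep
  myometrial invasion, cervical stroma invasion, lymphovascular space
  invasion, or nodal metastasis; anything else is high risk.
- Mann–Whitney U, two-sided; exact enumeration when the pooled sample
  is ≤ 12 and tie-free, otherwise normal approximation with tie and
  continuity corrections.
- FDR: Benjamini–Hochberg step-up **within each model family** (4 ET
  tests, 6 DP tests) with standard monotone enforcement; a published
  analysis of this design shows corrected values consistent with
  per-model families rather than one global family, and a config
  switch (`fdr_family="global"`) provides the alternative.
- Median 95% CIs by the distribution-free binomial order-statistic
  interval (the source tables do not name a method; this one is exact
  and assumption-free, and a seeded simulation at n = 25 confirms
  ≥ 93% coverage).
- Bland–Altman with 1.96·sd limits, a Wilcoxon signed-rank test on the
  paired differences, and a Spearman difference-vs-mean trend.
- ROC: empirical curve over all thresholds; orientation chosen so
  AUC ≥ 0.5 (in this application high-risk tumors have *lower*
  perfusion parameters, so the positive call is "value ≤ cutoff");
  Youden-index cutoff with ties broken toward higher specificity
  (fewer false positives in a surgical-triage context); DeLong AUC CI;
  Wilson CIs on sensitivity/specificity.
- McNemar on paired per-patient correctness, exact binomial for ≤ 25
  discordant pairs; the sensitivity comparison is computed within
  high-risk patients, specificity within low-risk, accuracy over all —
  the stratification is stated here because published per-metric
  p-value pairs do not spell it out.
- ICC(2,1), two-way random effects, absolute agreement, with the
  conventional poor/good/excellent bands at 0.40 and 0.75.

## Synthetic cohort

The generator draws per-patient kinetic truths log-normally (log-sd
0.3) around two sets of group medians taken from published endometrial
carcinoma values (e.g. Ktrans 0.10 vs 0.05 min⁻¹, F 13.01 vs 8.12
mL/min/100 mL); Ve is drawn once and shared between models, and the ET
blood volume is the DP blood volume scaled by the ratio of the
published ET/DP Vp medians (≈ 0.34).  Tissue curves are generated from
the **DP** model by default so ET fitting faces realistic model
mismatch; a switch generates from ET for pure recovery tests.  Noise is
added to the **signal** (not concentration), Gaussian with
sd = baseline/SNR (Rician optional), so the relaxometry inversion is
genuinely exercised.  Bolus arrival is 30 s into the dynamic run,
leaving the ten baseline frames clean.  Clinical tables carry pathology
flags frequency-matched to the risk groups, microvessel density
(log-normal around 55 and 90 vessels/mm²), and simulated radiologist
reads with per-finding sensitivity/specificity matching published
reader performance.  Everything is a pure function of (seed, config).

What the generator does **not** emulate: anatomy and spatial
correlation (tumors are distance-ordered blobs, noise is voxel-
independent), motion, partial-volume mixing at ROI edges, B1/B0
inhomogeneity, signal drift, and inter-voxel parameter correlation
beyond an optional log-normal jitter.  Passing end-to-end tests
therefore demonstrate the correctness of the estimation and statistics
chain under the stated physics, not robustness to acquisition
artifacts.

## Problem sizes

Desk-scale runs use 12-voxel tumor ROIs (the source study's range was
6–800, median 40), 4 fit starts and a 1.0 s internal convolution grid
for the cohort replication, and 100 voxels per model for the noisy
recovery study; these sizes are the package's own defaults for its
shipped studies and keep a full 51-patient replication in the
few-minute range on one core.  Estimator precision per patient scales
with ROI size, so small-ROI runs understate the significance a
40-voxel study would reach — the qualitative group pattern is already
stable at 12 voxels for every parameter except the mismatch-sensitive
ET Vp and ET Ve, the least robust channels in this design (see
Known limitations).

## Known limitations

- The ET Vp estimate under DP-generated curves is biased low even with
  delay fitting — the bias anti-correlates with uptake, which partially
  cancels its group difference — and ET Ve absorbs part of the same
  mismatch.  Both are reported, but the DP estimates of Vp and Ve are
  the trustworthy channels for those quantities in simulated studies.
- The exact-p branches of the rank tests enumerate only tie-free
  small samples; ties always fall back to corrected normal
  approximations.
- No spatial regularization, model selection, or ATH-type alternative
  models; one model is fitted per voxel independently.
- DICOM ingestion is out of scope; inputs are NIfTI-1 plus CSV/YAML.
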