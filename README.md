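# dcekin

Tracer-kinetic analysis of dynamic contrast-enhanced MRI (DCE-MRI) for
two-group tumor studies, built around the comparison of two kinetic
models of the capillary–tissue system:

- **Extended Tofts (ET)** — a compartmental description in which blood
  flow and vessel permeability are lumped into a single transfer
  constant:

  C_tiss(t) = (Vp/100)·Cp(t) + Ktrans·∫₀ᵗ Cp(u)·e^(−Kep·(t−u)) du,
  with Kep = 100·Ktrans/Ve.

- **Distributed parameter (DP)** — a spatially distributed model (the
  Sangren–Sheppard solution) that separates blood flow F from the
  permeability–surface-area product PS.  Its residue function is 1
  during the vascular phase t < Tc, then decays through interstitial
  reflux governed by kp = PS/Vp and ke = PS/Ve; the tissue curve is
  C_tiss = (F/100)·(R ⊛ Cp).  Derived quantities: Vp = F·Tc/60,
  MTT = Tc, extraction fraction E = 1 − e^(−PS/F), Te = Ve/PS.

The package covers the full analysis chain for a cohort of patients:

1. **Relaxometry** — variable-flip-angle T1/M0 mapping from precontrast
   spoiled gradient-echo (SPGR) scans, and frame-by-frame inversion of
   the dynamic SPGR signal into contrast-agent concentration via linear
   relaxivity.
2. **Patient-specific AIF** — median arterial concentration over an
   artery ROI, scaled to plasma by 1/(1 − hematocrit).
3. **Voxelwise fitting** — bounded multi-start nonlinear least squares
   of both models per tumor voxel, with per-patient ROI medians.
4. **Cohort statistics** — low- vs high-risk group comparison with
   Mann–Whitney U tests and Benjamini–Hochberg FDR per model family,
   Bland–Altman and Spearman agreement between models, ROC analysis
   with Youden-index cutoffs and DeLong AUC confidence intervals,
   McNemar comparison against radiologist reads, and two-reader
   ICC(2,1).
5. **Synthetic cohorts** — a generator that emulates the acquisition
   (TR 4.4 ms, flips 6°/12°/18° with 10 repeats, 115 dynamics at 2.5 s)
   and the two-group kinetic-parameter structure, so the whole pipeline
   is testable end to end with known ground truth.

It is intended for researchers evaluating perfusion parameters as
preoperative imaging biomarkers (the shipped defaults model endometrial
carcinoma risk stratification at 1.5 T), and as a tested open
re-implementation of analyses usually run in closed commercial tools.

## Worked example

```python
import dcekin as dk

cfg = dk.StudyConfig(n_starts=4, fine_dt_s=1.0)
report = dk.run_all(cfg, seed=7, work_dir="study", n_low=10, n_high=10,
                    tumor_voxels=9, noise_snr=20.0)
r = report["group_comparison"]["et_Ktrans"]
print(f"Ktrans low {r['median_low']:.3f} vs high {r['median_high']:.3f} "
      f"min^-1, adjusted p = {r['p_adjusted']:.1e}")
print(f"AUC(Ktrans) = {report['roc']['et_Ktrans']['auc']:.2f}")
```

This simulates a 20-patient cohort, fits both models voxel by voxel,
and prints:

```
Ktrans low 0.086 vs high 0.033 min^-1, adjusted p = 7.3e-04
AUC(Ktrans) = 1.00
```

i.e. the high-risk group shows the lower transfer constant it was
generated with (group medians 0.10 vs 0.05 min⁻¹), the difference
survives FDR correction, and Ktrans separates the groups almost
perfectly at this cohort size.  The same CLI chain is available as
`dcekin simulate`, `dcekin t1map`, `dcekin fit`, `dcekin compare`,
`dcekin run-all`.

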