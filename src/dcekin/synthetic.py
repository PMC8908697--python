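"""Fully synthetic DCE-MRI studies with known ground truth.

Generates everything the analysis pipeline consumes — arterial input
function, kinetic ground-truth maps, spoiled gradient-echo signal with
noise, tumor/artery masks, and the clinical table — for a two-group
(low/high risk) cohort whose kinetic-parameter distributions are
centered on values reported for endometrial carcinoma at 1.5 T.
Every output is fully determined by (seed, configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AcquisitionProtocol, save_series
from .relaxometry import ArterialInputFunction, spgr_signal
from .tracer_kinetics import DPParams, ETParams, dp_forward, et_forward

logger = logging.getLogger("dcekin")

__all__ = [
    "AIFModel",
    "GroundTruthRecord",
    "GROUP_MEDIANS",
    "MVD_MEDIANS",
    "READER_PERFORMANCE",
    "EXCLUSION_COUNTS",
    "population_aif",
    "sample_patient_params",
    "generate_patient",
    "generate_cohort",
    "generate_screening_roster",
]


@dataclass
class AIFModel:
    """Gamma-variate bolus plus recirculation/washout arterial input.

    Cp(t) = A1 ((t-t0)/b)^a exp(a - a (t-t0)/b)
          + A2 (1 - exp(-(t-t0)/c)) exp(-(t-t0)/d)      for t >= t0, else 0.

    The gamma term peaks at exactly t0 + b with height A1.  Defaults give
    a plasma peak of ~5 mM about 15 s after bolus arrival and a tail of
    ~1 mM at 4 minutes, typical of a standard-dose injection at 2 mL/s.
    Bolus arrival defaults to 30 s after the dynamic run starts, leaving
    the first ten frames as a clean pre-contrast baseline.
    """

    t0_s: float = 30.0
    A1: float = 4.3      # mM, bolus amplitude
    a: float = 2.5       # gamma shape
    b_s: float = 15.0    # gamma scale: time-to-peak after arrival
    A2: float = 1.5      # mM, recirculation amplitude
    c_s: float = 20.0    # wash-in time constant
    d_s: float = 480.0   # wash-out time constant

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b_s <= 0 or self.c_s <= 0 or self.d_s <= 0:
            raise ValueError("AIF shape/scale parameters must be positive")


@dataclass
class GroundTruthRecord:
    """Everything needed to regenerate one synthetic patient."""

    patient_id: str
    group: str                   # low | high
    et: ETParams
    dp: DPParams
    noise_snr: float
    seed: int


# Group medians of the kinetic parameters (units as elsewhere: Ktrans/Kep
# min^-1, volumes mL/100 mL, flows mL/min/100 mL, MTT s).
GROUP_MEDIANS: dict[str, dict[str, float]] = {
    "low": {"Ktrans": 0.10, "Vp_et": 1.02, "F": 13.01, "MTT": 15.15,
            "Vp_dp": 3.03, "Ve": 6.17, "PS": 8.32},
    "high": {"Ktrans": 0.05, "Vp_et": 0.58, "F": 8.12, "MTT": 12.38,
             "Vp_dp": 1.46, "Ve": 6.31, "PS": 4.01},
}
MVD_MEDIANS = {"low": 55.0, "high": 90.0}       # microvessels per mm^2

# Simulated radiologist sensitivity/specificity per finding.
READER_PERFORMANCE = {"dmi": (0.58, 0.68), "csi": (0.19, 1.00), "lnm": (0.31, 0.96)}

# Screening-roster exclusion categories and counts (112 screened -> 51).
EXCLUSION_COUNTS = {"lesion_too_small": 33, "refusal": 9, "therapy_change": 7,
                    "not_target_disease": 6, "aif_failure": 6}


def population_aif(times_s, model: AIFModel | None = None) -> ArterialInputFunction:
    """Evaluate the parametric plasma AIF on a time grid (mM)."""
    model = model or AIFModel()
    t = np.asarray(times_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    tau = t - model.t0_s
    Cp = np.zeros_like(t)
    pos = tau > 0
    tp = tau[pos]
    bolus = model.A1 * (tp / model.b_s) ** model.a * np.exp(model.a - model.a * tp / model.b_s)
    wash = model.A2 * (1.0 - np.exp(-tp / model.c_s)) * np.exp(-tp / model.d_s)
    Cp[pos] = bolus + wash
    return ArterialInputFunction(times_s=t, Cp=Cp)


def sample_patient_params(
    group: str,
    rng: np.random.Generator | int,
    log_sd: float = 0.3,
    vp_et_scale: float | None = None,
) -> tuple[ETParams, DPParams]:
    """Draw coherent ET and DP ground truths for one patient.

    All primitives are log-normal around the group medians; Ve is drawn
    once and shared between models, and the ET blood volume is the DP
    blood volume scaled by ``vp_et_scale`` (default: the ratio of the
    group's ET and DP Vp medians), reflecting the systematically smaller
    vascular signal the Tofts form attributes to Vp.
    """
    if group not in GROUP_MEDIANS:
        raise ValueError(f"group must be low|high, got {group!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    med = GROUP_MEDIANS[group]

    def draw(m: float) -> float:
        return float(m * np.exp(rng.normal(0.0, log_sd)))

    F = draw(med["F"])
    Tc = draw(med["MTT"])
    Ve = draw(med["Ve"])
    PS = draw(med["PS"])
    Ktrans = draw(med["Ktrans"])
    dp = DPParams(F=F, Tc=Tc, Ve=Ve, PS=PS)
    scale = vp_et_scale if vp_et_scale is not None else med["Vp_et"] / med["Vp_dp"]
    et = ETParams(Ktrans=Ktrans, Ve=Ve, Vp=scale * dp.Vp)
    return et, dp


def _blob_mask(shape: tuple[int, int, int], center: tuple[int, int, int],
               n_voxels: int) -> np.ndarray:
    """Connected blob of exactly n_voxels around a center (distance ordering)."""
    zz = np.indices(shape).reshape(3, -1).T
    d = ((zz - np.asarray(center)) ** 2).sum(axis=1)
    order = np.lexsort((zz[:, 2], zz[:, 1], zz[:, 0], d))
    mask = np.zeros(shape, dtype=bool)
    sel = zz[order[:n_voxels]]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


def generate_patient(
    truth: GroundTruthRecord,
    protocol: AcquisitionProtocol,
    out_dir: str | Path,
    *,
    geometry: tuple[int, int, int] = (16, 16, 9),
    tumor_voxels: int = 40,
    artery_voxels: int = 8,
    aif_model: AIFModel | None = None,
    t1_tissue_ms: float = 1000.0,
    t1_blood_ms: float = 1400.0,
    m0: float = 1000.0,
    heterogeneity_log_sd: float = 0.0,
    noise_model: str = "gaussian",
    curve_model: str = "dp",
    fine_dt_s: float = 0.25,
) -> dict:
    """Write one synthetic patient study (NIfTI files) and return its truth row.

    Tissue curves come from the distributed-parameter forward model by
    default (``curve_model='et'`` switches to pure Tofts generation for
    recovery tests); artery voxels carry the whole-blood AIF
    Cp (1 - Hct).  Concentration is pushed through the SPGR signal
    equation at the protocol settings, with additive noise of standard
    deviation baseline/SNR per voxel (``noise_model='rician'`` for
    magnitude noise).  Output: three 10-repeat variable-flip-angle
    stacks, the 115-frame dynamic series, and both ROI masks.
    """
    if truth.noise_snr <= 0:
        raise ValueError("noise SNR must be positive (use np.inf for noiseless)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    shape = geometry
    times = protocol.frame_times_s

    center = (shape[0] // 4, shape[1] // 4, shape[2] // 2)
    tumor = _blob_mask(shape, center, tumor_voxels)
    a_center = (3 * shape[0] // 4, 3 * shape[1] // 4, shape[2] // 2)
    artery = _blob_mask(shape, a_center, artery_voxels) & ~tumor

    aif = population_aif(times, aif_model)
    conc = np.zeros(shape + (len(times),))
    # tumor tissue curves (optionally heterogeneous around the patient truth)
    t_idx = np.argwhere(tumor)
    base_curve = None
    for i0, i1, i2 in t_idx:
        if heterogeneity_log_sd > 0:
            jit = np.exp(rng.normal(0.0, heterogeneity_log_sd, size=4))
            if curve_model == "dp":
                p = DPParams(truth.dp.F * jit[0], truth.dp.Tc * jit[1],
                             truth.dp.Ve * jit[2], truth.dp.PS * jit[3])
                conc[i0, i1, i2] = dp_forward(p, aif, times, fine_dt_s=fine_dt_s)
            else:
                p = ETParams(truth.et.Ktrans * jit[0], truth.et.Ve * jit[1],
                             truth.et.Vp * jit[2])
                conc[i0, i1, i2] = et_forward(p, aif, times)
        else:
            if base_curve is None:
                base_curve = (dp_forward(truth.dp, aif, times, fine_dt_s=fine_dt_s)
                              if curve_model == "dp"
                              else et_forward(truth.et, aif, times))
            conc[i0, i1, i2] = base_curve
    conc[artery] = aif.Cp * (1.0 - protocol.hematocrit)   # whole-blood concentration

    T10 = np.full(shape, t1_tissue_ms)
    T10[artery] = t1_blood_ms
    R10 = 1000.0 / T10
    R1t = R10[..., None] + protocol.r1_relaxivity * conc
    T1t = 1000.0 / R1t
    dyn = spgr_signal(m0, T1t, protocol.dyn_flip_deg, protocol.TR_ms)

    def add_noise(signal: np.ndarray, baseline: np.ndarray) -> np.ndarray:
        if not np.isfinite(truth.noise_snr):
            return signal
        sd = baseline / truth.noise_snr
        if noise_model == "rician":
            n1 = rng.normal(0.0, 1.0, signal.shape) * sd
            n2 = rng.normal(0.0, 1.0, signal.shape) * sd
            return np.sqrt((signal + n1) ** 2 + n2**2)
        return np.clip(signal + rng.normal(0.0, 1.0, signal.shape) * sd, 0.0, None)

    base_sig = dyn[..., :1]
    dyn = add_noise(dyn, base_sig)
    save_series(dyn, out_dir / "dyn.nii.gz")

    for flip in protocol.vfa_flips_deg:
        s = spgr_signal(m0, T10, flip, protocol.TR_ms)
        stack = np.repeat(s[..., None], protocol.n_baseline_per_flip, axis=-1)
        stack = add_noise(stack, s[..., None])
        save_series(stack, out_dir / f"vfa_{int(round(flip)):02d}.nii.gz")

    save_series(tumor.astype(np.float64), out_dir / "tumor_mask.nii.gz")
    save_series(artery.astype(np.float64), out_dir / "artery_mask.nii.gz")

    row = {"id": truth.patient_id, "risk": truth.group, "seed": truth.seed,
           "noise_snr": truth.noise_snr,
           "et_Ktrans_true": truth.et.Ktrans, "et_Ve_true": truth.et.Ve,
           "et_Vp_true": truth.et.Vp, "et_Kep_true": truth.et.Kep,
           "dp_F_true": truth.dp.F, "dp_Tc_true": truth.dp.Tc,
           "dp_Ve_true": truth.dp.Ve, "dp_PS_true": truth.dp.PS,
           "dp_Vp_true": truth.dp.Vp}
    return row


def _sample_clinical(group: str, rng: np.random.Generator) -> dict:
    """Pathology fields consistent with the risk group (frequency-matched)."""
    if group == "low":
        rec = {"subtype": "endometrioid", "grade": int(rng.integers(1, 3)),
               "dmi": False, "csi": False, "lvsi": False, "lnm": False}
    else:
        nonendo = rng.random() < 20.0 / 26.0
        if nonendo:
            rec = {"subtype": "nonendometrioid", "grade": np.nan}
        else:
            grade3 = rng.random() < 4.0 / 6.0
            rec = {"subtype": "endometrioid", "grade": 3 if grade3 else int(rng.integers(1, 3))}
        rec["dmi"] = bool(rng.random() < 11.0 / 26.0)
        rec["csi"] = bool(rng.random() < 4.0 / 26.0)
        rec["lvsi"] = bool(rng.random() < 8.0 / 26.0)
        rec["lnm"] = bool(rng.random() < 5.0 / 26.0)
        if rec["subtype"] == "endometrioid" and rec["grade"] != 3 and not any(
                (rec["dmi"], rec["csi"], rec["lvsi"], rec["lnm"])):
            rec["dmi"] = True      # keep the record genuinely high-risk
    return rec


def _simulate_reader(flag: bool, sens: float, spec: float,
                     rng: np.random.Generator) -> bool:
    return bool(rng.random() < sens) if flag else bool(rng.random() >= spec)


def generate_cohort(
    n_low: int,
    n_high: int,
    seed: int,
    out_dir: str | Path,
    *,
    protocol: AcquisitionProtocol | None = None,
    noise_snr: float = 20.0,
    log_sd: float = 0.3,
    mvd_log_sd: float = 0.35,
    force: bool = False,
    write_images: bool = True,
    **patient_kwargs,
) -> pd.DataFrame:
    """Generate a full synthetic cohort on disk.

    Writes ``<out_dir>/<patient>/`` image trees plus ``truth.csv`` (the
    ground-truth kinetic parameters), ``clinical.csv`` (pathology flags
    consistent with the risk groups, simulated radiologist reads, and
    microvessel density), and a YAML snapshot of the protocol.  Returns
    the truth table.  ``write_images=False`` skips the NIfTI volumes and
    emits the tables only (fast statistical-structure studies).
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("both groups need at least one patient")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    protocol = protocol or AcquisitionProtocol()

    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    truth_rows, clin_rows = [], []
    groups = ["low"] * n_low + ["high"] * n_high
    child_seeds = ss.spawn(len(groups))
    for i, (group, child) in enumerate(zip(groups, child_seeds)):
        rng = np.random.default_rng(child)
        pid = f"pt{i + 1:03d}"
        et, dp = sample_patient_params(group, rng, log_sd=log_sd)
        pseed = int(rng.integers(0, 2**31 - 1))
        truth = GroundTruthRecord(patient_id=pid, group=group, et=et, dp=dp,
                                  noise_snr=noise_snr, seed=pseed)
        if write_images:
            row = generate_patient(truth, protocol, out_dir / pid, **patient_kwargs)
        else:
            row = {"id": pid, "risk": group, "seed": pseed, "noise_snr": noise_snr,
                   "et_Ktrans_true": et.Ktrans, "et_Ve_true": et.Ve,
                   "et_Vp_true": et.Vp, "et_Kep_true": et.Kep,
                   "dp_F_true": dp.F, "dp_Tc_true": dp.Tc,
                   "dp_Ve_true": dp.Ve, "dp_PS_true": dp.PS, "dp_Vp_true": dp.Vp}
        truth_rows.append(row)

        clin = {"id": pid}
        clin.update(_sample_clinical(group, rng))
        for finding, (sens, spec) in READER_PERFORMANCE.items():
            clin[f"reader_{finding}"] = _simulate_reader(
                bool(clin.get(finding, False)), sens, spec, rng)
        clin["mvd"] = float(MVD_MEDIANS[group] * np.exp(rng.normal(0.0, mvd_log_sd)))
        clin["risk"] = group
        clin_rows.append(clin)

    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(out_dir / "truth.csv", index=False)
    pd.DataFrame(clin_rows).to_csv(out_dir / "clinical.csv", index=False)
    protocol.to_yaml(out_dir / "config.yaml")
    logger.info("generate_cohort: wrote %d patients to %s", len(groups), out_dir)
    return truth_df


def generate_screening_roster(
    seed: int,
    n_total: int = 112,
    exclusion_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Screening roster with per-record exclusion reasons (study-flow model).

    Defaults mirror a prospective recruitment of 112 with five exclusion
    categories totalling 61, leaving 51 analyzable records.
    """
    counts = dict(EXCLUSION_COUNTS if exclusion_counts is None else exclusion_counts)
    n_excl = sum(counts.values())
    if n_excl > n_total:
        raise ValueError("exclusions exceed roster size")
    reasons = [r for r, k in counts.items() for _ in range(k)]
    reasons += [""] * (n_total - n_excl)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rng.shuffle(reasons)
    return pd.DataFrame({
        "id": [f"scr{i + 1:03d}" for i in range(n_total)],
        "exclusion_reason": reasons,
    })
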