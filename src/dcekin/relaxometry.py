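"""Variable-flip-angle T1 mapping and signal-to-concentration conversion.

The steady-state spoiled gradient-echo (SPGR) signal model

    S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1)

is used in both directions: fitted against multiple precontrast flip
angles to estimate T1 and M0 per voxel, and inverted frame-by-frame on
the dynamic series to recover T1(t).  Contrast-agent concentration then
follows from linear relaxivity, C(t) = (R1(t) - R1(0)) / r1 with
R1 = 1/T1 in s^-1.  Water exchange and B1 inhomogeneity are not modeled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import AcquisitionProtocol, DynamicSeries, VoxelMask

logger = logging.getLogger("dcekin")

__all__ = [
    "T1M0Map",
    "ConcentrationSeries",
    "ArterialInputFunction",
    "LowQualityAIFWarning",
    "spgr_signal",
    "fit_vfa_t1",
    "vfa_t1_map",
    "signal_to_concentration",
    "extract_aif",
]


class LowQualityAIFWarning(UserWarning):
    """Arterial input function peak is implausibly low (sampling failure)."""


@dataclass
class T1M0Map:
    """Per-voxel precontrast T1 (ms) and equilibrium signal M0 (a.u.)."""

    T1_ms: np.ndarray
    M0: np.ndarray
    valid: np.ndarray


@dataclass
class ConcentrationSeries:
    """4D contrast-agent concentration (mmol/L) on the dynamic time grid."""

    data: np.ndarray
    frame_times_s: np.ndarray


@dataclass
class ArterialInputFunction:
    """Plasma contrast concentration Cp(t) (mmol/L) in a feeding artery."""

    times_s: np.ndarray
    Cp: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.Cp = np.asarray(self.Cp, dtype=float)
        if self.times_s.shape != self.Cp.shape:
            raise ValueError("times_s and Cp must have equal length")


def spgr_signal(M0, T1_ms, flip_deg, TR_ms):
    """Steady-state SPGR signal; broadcasts over array inputs.

    Raises on non-positive T1 or flip angle outside [0, 90] (the flip-0
    limit returns S = 0).
    """
    T1_ms = np.asarray(T1_ms, dtype=float)
    if np.any(T1_ms <= 0):
        raise ValueError("T1_ms must be positive")
    flip = np.asarray(flip_deg, dtype=float)
    if np.any((flip < 0) | (flip > 90)):
        raise ValueError("flip angle must lie in [0, 90] degrees")
    a = np.deg2rad(flip)
    E1 = np.exp(-TR_ms / T1_ms)
    return M0 * np.sin(a) * (1.0 - E1) / (1.0 - E1 * np.cos(a))


def fit_vfa_t1(mean_signals, flips_deg, TR_ms):
    """Linearized variable-flip-angle T1/M0 fit.

    Regresses y = S/sin(a) on x = S/tan(a); the slope is E1 = exp(-TR/T1)
    and the intercept M0 (1 - E1).  Voxels whose slope falls outside (0, 1)
    (non-physical, e.g. pure noise) are marked invalid with NaN rather than
    raising.

    Parameters
    ----------
    mean_signals : array, shape (..., n_flips)
        Repeat-averaged signal per flip angle.
    flips_deg : sequence of flip angles, length n_flips.
    TR_ms : repetition time (ms).

    Returns
    -------
    T1M0Map with arrays of shape ``mean_signals.shape[:-1]``.
    """
    S = np.asarray(mean_signals, dtype=float)
    flips = np.deg2rad(np.asarray(flips_deg, dtype=float))
    if flips.size < 2 or len(np.unique(flips)) < 2:
        raise ValueError("need at least two distinct flip angles")
    if S.shape[-1] != flips.size:
        raise ValueError("last axis of mean_signals must match number of flips")

    y = S / np.sin(flips)
    x = S / np.tan(flips)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=-1)
    sxy = ((x - xm) * (y - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym[..., 0] - slope * xm[..., 0]
        valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & (intercept > 0)
        T1 = np.where(valid, -TR_ms / np.log(np.where(valid, slope, 0.5)), np.nan)
        M0 = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)), np.nan)
    return T1M0Map(T1_ms=T1, M0=M0, valid=valid)


def vfa_t1_map(vfa_stacks: dict[float, np.ndarray], protocol: AcquisitionProtocol) -> T1M0Map:
    """T1/M0 map from per-flip 4D repeat stacks ``{flip_deg: (x,y,z,reps)}``.

    Repeats are averaged before the fit (noise reduction).
    """
    flips = sorted(vfa_stacks)
    means = np.stack(
        [np.asarray(vfa_stacks[f], dtype=float).mean(axis=-1) for f in flips], axis=-1
    )
    return fit_vfa_t1(means, flips, protocol.TR_ms)


def _invert_spgr_t1(S, M0, flip_deg, TR_ms):
    """Solve the SPGR equation for T1 given signal and M0.

    Returns T1 (ms) with NaN wherever the implied E1 leaves (0, 1).
    """
    a = np.deg2rad(flip_deg)
    sa, ca = np.sin(a), np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        E1 = (M0 * sa - S) / (M0 * sa - S * ca)
        ok = np.isfinite(E1) & (E1 > 0) & (E1 < 1)
        T1 = np.where(ok, -TR_ms / np.log(np.where(ok, E1, 0.5)), np.nan)
    return T1


def signal_to_concentration(
    series: DynamicSeries,
    t1m0: T1M0Map,
    protocol: AcquisitionProtocol,
    baseline_frames: int = 10,
) -> ConcentrationSeries:
    """Convert a dynamic SPGR series to contrast-agent concentration.

    Per voxel, M0 is rescaled so that the modeled baseline signal equals
    the mean of the first ``baseline_frames`` dynamic frames (absorbs
    scanner scaling drift between the VFA and dynamic acquisitions), the
    SPGR equation is inverted per frame for T1(t), and
    C(t) = (R1(t) - R1(0)) / r1 with R1 in s^-1.  Negative concentrations
    are clipped to zero on the baseline frames only; frames where the
    inversion leaves its domain become NaN (count logged).
    """
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    S = series.data
    T1_0 = t1m0.T1_ms
    valid = t1m0.valid & np.isfinite(T1_0)

    base = S[..., :baseline_frames].mean(axis=-1)
    a = np.deg2rad(protocol.dyn_flip_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        E1_0 = np.exp(-protocol.TR_ms / T1_0)
        shape_factor = np.sin(a) * (1.0 - E1_0) / (1.0 - E1_0 * np.cos(a))
        M0 = np.where(valid & (shape_factor > 0), base / shape_factor, np.nan)

    T1_t = _invert_spgr_t1(S, M0[..., None], protocol.dyn_flip_deg, protocol.TR_ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        R1_t = 1000.0 / T1_t            # s^-1
        R1_0 = 1000.0 / T1_0
        C = (R1_t - R1_0[..., None]) / protocol.r1_relaxivity
    C = np.where(valid[..., None], C, np.nan)
    C[..., :baseline_frames] = np.clip(C[..., :baseline_frames], 0.0, None)

    n_bad = int(np.sum(~np.isfinite(C) & valid[..., None]))
    if n_bad:
        logger.warning("signal_to_concentration: %d frame values outside invertible range", n_bad)
    return ConcentrationSeries(data=C, frame_times_s=series.frame_times_s.copy())


def extract_aif(
    conc: ConcentrationSeries,
    artery_mask: VoxelMask,
    hematocrit: float,
    peak_floor_mM: float = 1.0,
) -> ArterialInputFunction:
    """Patient-specific AIF from an arterial ROI.

    The whole-blood curve is the voxelwise median over the artery ROI;
    plasma concentration is Cp(t) = C_blood(t) / (1 - Hct).  A peak below
    ``peak_floor_mM`` triggers a low-quality warning (noisy images /
    failure to sample the AIF); negative excursions are clipped to zero.
    """
    if not (0.0 <= hematocrit < 1.0):
        raise ValueError("hematocrit must lie in [0, 1)")
    curves = conc.data[artery_mask.data]        # (n_voxels, n_t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        blood = np.nanmedian(curves, axis=0)
    blood = np.nan_to_num(blood, nan=0.0)
    Cp = np.clip(blood, 0.0, None) / (1.0 - hematocrit)
    if Cp.max(initial=0.0) < peak_floor_mM:
        warnings.warn(
            f"AIF peak {Cp.max(initial=0.0):.3f} mM below quality floor "
            f"{peak_floor_mM} mM",
            LowQualityAIFWarning,
            stacklevel=2,
        )
        logger.warning("low-quality AIF: peak %.3f mM", Cp.max(initial=0.0))
    return ArterialInputFunction(times_s=conc.frame_times_s.copy(), Cp=Cp)
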