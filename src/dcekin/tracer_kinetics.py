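"""Extended Tofts and distributed-parameter tracer-kinetic models.

Two two-compartment descriptions of contrast-agent transport are
implemented, together with bounded multi-start nonlinear least-squares
voxelwise fitting and per-ROI aggregation.

Extended Tofts (ET) lumps flow and vessel permeability into a single
transfer constant:

    Ctiss(t) = (Vp/100) Cp(t) + Ktrans * int_0^t Cp(u) exp(-Kep (t-u)) du

with Kep = 100 Ktrans / Ve (time in minutes inside the integral).

The distributed-parameter (DP) model treats the capillary as an axially
distributed plug-flow tube exchanging with a well-mixed interstitium
(the Sangren-Sheppard solution).  Its residue function is

    R(t) = 1                       for 0 <= t < Tc (vascular phase)
    R(t) = E - int_0^{t-Tc} g(u)du for t >= Tc     (interstitial reflux)

    g(u) = exp(-kp Tc - ke u) sqrt(kp ke Tc / u) I1(2 sqrt(kp ke Tc u))

where kp = PS/Vp, ke = PS/Ve, E = 1 - exp(-PS/F), I1 the modified
Bessel function, and the tissue curve is Ctiss = (F/100) (R * Cp).
An independent finite-difference solver of the underlying two-region
convection-exchange PDE serves as a numerical oracle.

Units: Ktrans, Kep in min^-1; Ve, Vp in mL/100 mL; F, PS in
mL/min/100 mL; Tc (= MTT) in seconds; concentrations in mmol/L; all
time grids passed to these functions are in seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.special import i1e
from scipy.stats import qmc

from .core_io import VoxelMask
from .relaxometry import ArterialInputFunction, ConcentrationSeries

logger = logging.getLogger("dcekin")

__all__ = [
    "ETParams",
    "DPParams",
    "VoxelFit",
    "ROIFitResult",
    "FitQualityWarning",
    "ET_BOUNDS",
    "DP_BOUNDS",
    "et_forward",
    "dp_residue",
    "dp_forward",
    "dp_pde_oracle",
    "fit_voxel",
    "fit_roi",
    "derived_params",
]


class FitQualityWarning(UserWarning):
    """More than half of the ROI voxels failed to fit."""


# Fit bounds: generous supersets of values reported for pelvic tumors.
ET_BOUNDS: dict[str, tuple[float, float]] = {
    "Ktrans": (0.0, 3.0),       # min^-1
    "Ve": (1e-3, 60.0),         # mL/100 mL
    "Vp": (0.0, 20.0),          # mL/100 mL
}
DP_BOUNDS: dict[str, tuple[float, float]] = {
    "F": (0.5, 200.0),          # mL/min/100 mL
    "Tc": (0.5, 60.0),          # s
    "Ve": (1e-3, 60.0),         # mL/100 mL
    "PS": (0.0, 100.0),         # mL/min/100 mL
}

_ET_NAMES = ("Ktrans", "Ve", "Vp")
_DP_NAMES = ("F", "Tc", "Ve", "PS")


@dataclass
class ETParams:
    """Extended-Tofts parameters; Kep is derived, never fitted."""

    Ktrans: float   # min^-1
    Ve: float       # mL/100 mL
    Vp: float       # mL/100 mL

    def __post_init__(self) -> None:
        if self.Ktrans < 0 or self.Ve < 0 or self.Vp < 0:
            raise ValueError("ET parameters must be non-negative")
        if self.Ktrans > 0 and self.Ve <= 0:
            raise ValueError("Ve must be positive when Ktrans > 0")

    @property
    def Kep(self) -> float:
        """Efflux rate constant (min^-1)."""
        return 100.0 * self.Ktrans / self.Ve if self.Ve > 0 else np.nan


@dataclass
class DPParams:
    """Distributed-parameter primitives; Vp, MTT, E, Te are derived."""

    F: float        # mL/min/100 mL
    Tc: float       # s
    Ve: float       # mL/100 mL
    PS: float       # mL/min/100 mL

    def __post_init__(self) -> None:
        if min(self.F, self.Tc, self.Ve, self.PS) < 0:
            raise ValueError("DP parameters must be non-negative")

    @property
    def Vp(self) -> float:
        """Capillary blood (plasma) volume, F * Tc / 60 (mL/100 mL)."""
        return self.F * self.Tc / 60.0

    @property
    def MTT(self) -> float:
        """Capillary mean transit time (s), identical to Tc."""
        return self.Tc

    @property
    def E(self) -> float:
        """Extraction fraction, 1 - exp(-PS/F), as a fraction."""
        return 1.0 - np.exp(-self.PS / self.F) if self.F > 0 else np.nan

    @property
    def Te(self) -> float:
        """Interstitial residence time Ve/PS (min); NaN when PS = 0."""
        return self.Ve / self.PS if self.PS > 0 else np.nan


@dataclass
class VoxelFit:
    """Result of fitting one voxel curve with one model."""

    model: str                       # "et" | "dp"
    params: dict[str, float]         # primitives + derived values
    SSR: float
    converged: bool
    n_starts_used: int
    at_boundary: bool = False


@dataclass
class ROIFitResult:
    """Per-parameter maps and ROI medians over converged voxels."""

    model: str
    maps: dict[str, np.ndarray]
    medians: dict[str, float]
    n_fitted: int
    n_failed: int
    fits: list = field(default_factory=list, repr=False)


# --------------------------------------------------------------------------
# Forward models
# --------------------------------------------------------------------------

def _exp_conv(Cp: np.ndarray, times_s: np.ndarray, k_per_s: float) -> np.ndarray:
    """int_0^t Cp(u) exp(-k (t-u)) du  (seconds), Cp piecewise linear.

    Exact per-interval recursion; on a uniform grid it reduces to a
    first-order IIR filter, evaluated with scipy.signal.lfilter.
    """
    t = np.asarray(times_s, dtype=float)
    Cp = np.asarray(Cp, dtype=float)
    dt = np.diff(t)
    if dt.size == 0:
        return np.zeros_like(Cp)
    if np.allclose(dt, dt[0]):
        h = dt[0]
        kh = k_per_s * h
        if kh > 1e-8:
            e = np.exp(-kh)
            A = (1.0 - e) / k_per_s
            B = (1.0 - (1.0 + kh) * e) / k_per_s**2
        else:  # series limits, k -> 0
            e = np.exp(-kh)
            A = h - k_per_s * h**2 / 2.0
            B = h**2 / 2.0 - k_per_s * h**3 / 3.0
        alpha = A - B / h
        beta = B / h
        # I_i = e I_{i-1} + alpha Cp_i + beta Cp_{i-1}, I_0 = 0.  lfilter's
        # implicit start adds alpha Cp_0 e^{-k t_i}; remove it explicitly.
        out = sp_signal.lfilter([alpha, beta], [1.0, -e], Cp)
        if Cp[0] != 0.0:
            out -= alpha * Cp[0] * e ** np.arange(len(Cp))
        out[0] = 0.0
        return out
    # non-uniform grid: explicit recursion
    out = np.zeros_like(Cp)
    for i in range(1, len(t)):
        h = dt[i - 1]
        kh = k_per_s * h
        if kh > 1e-8:
            e = np.exp(-kh)
            A = (1.0 - e) / k_per_s
            B = (1.0 - (1.0 + kh) * e) / k_per_s**2
        else:
            e = np.exp(-kh)
            A = h - k_per_s * h**2 / 2.0
            B = h**2 / 2.0 - k_per_s * h**3 / 3.0
        out[i] = e * out[i - 1] + Cp[i] * (A - B / h) + Cp[i - 1] * (B / h)
    return out


def et_forward(params: ETParams, aif: ArterialInputFunction, times_s) -> np.ndarray:
    """Extended-Tofts tissue concentration curve (mM) on ``times_s``."""
    t = np.asarray(times_s, dtype=float)
    Cp = np.interp(t, aif.times_s, aif.Cp, left=0.0)
    if params.Ktrans == 0.0:
        return (params.Vp / 100.0) * Cp
    kep_s = params.Kep / 60.0
    integral = _exp_conv(Cp, t, kep_s)              # mM * s
    return (params.Vp / 100.0) * Cp + (params.Ktrans / 60.0) * integral


def _dp_rates(params: DPParams) -> tuple[float, float, float]:
    """(kp, ke) in s^-1 and the extraction fraction E."""
    Vp = params.Vp
    kp = params.PS / (Vp * 60.0) if Vp > 0 else np.inf
    ke = params.PS / (params.Ve * 60.0) if params.Ve > 0 else np.inf
    return kp, ke, params.E


def _dp_reflux_kernel(tau: np.ndarray, params: DPParams) -> np.ndarray:
    """Interstitial outflow density g(tau) (s^-1) for tau >= 0.

    Uses the exponentially scaled Bessel function i1e to stay finite at
    large arguments; the sqrt(1/tau) * I1 product is replaced by its
    series limit a * exp(-kp Tc) at tau = 0.
    """
    kp, ke, _E = _dp_rates(params)
    Tc = params.Tc
    a = kp * ke * Tc
    tau = np.asarray(tau, dtype=float)
    g = np.empty_like(tau)
    small = tau <= 0.0
    g[small] = a * np.exp(-kp * Tc)
    u = tau[~small]
    x = 2.0 * np.sqrt(a * u)
    # I1(x) = i1e(x) e^x ; collect all exponentials into one argument <= 0
    expo = x - kp * Tc - ke * u
    g[~small] = np.sqrt(a / u) * i1e(x) * np.exp(expo)
    return g


def _dp_residue_on_grid(params: DPParams, t_fine: np.ndarray) -> np.ndarray:
    """R(t) evaluated on an increasing grid (post-jump value at t = Tc)."""
    Tc = params.Tc
    if params.F <= 0:
        raise ValueError("dp residue requires F > 0")
    R = np.ones_like(t_fine)
    if params.PS == 0.0:
        R[t_fine >= Tc] = 0.0
        return R
    _kp, ke, E = _dp_rates(params)
    if params.Vp == 0.0 or Tc == 0.0:
        # compartmental limit: no vascular delay, Tofts-type washout
        ktrans = params.F * E                       # mL/min/100 mL
        kep_s = 100.0 * ktrans / params.Ve / 60.0 if params.Ve > 0 else np.inf
        return E * np.exp(-kep_s * np.clip(t_fine, 0.0, None)) * (params.F > 0)
    late = t_fine >= Tc
    tau = t_fine[late] - Tc
    if tau.size:
        g = _dp_reflux_kernel(tau, params)
        W = np.concatenate([[0.0], cumulative_trapezoid(g, tau)]) if tau.size > 1 else np.zeros(1)
        R[late] = E - W
    return np.clip(R, 0.0, None)


def dp_residue(params: DPParams, t_s, fine_dt_s: float = 0.05) -> np.ndarray:
    """Distributed-parameter residue function R(t) at times ``t_s`` (s).

    R is 1 during the vascular phase t < Tc, drops by exp(-PS/F) as the
    unextracted bolus leaves, and decays through interstitial reflux.
    Values exactly at t = Tc take the post-jump value E.
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    out = np.ones_like(t)
    late = t >= params.Tc
    if late.any():
        tau_max = float(t[late].max() - params.Tc)
        n = max(int(np.ceil(tau_max / fine_dt_s)) + 1, 2)
        tau_fine = np.linspace(0.0, max(tau_max, fine_dt_s), n)
        Q = _dp_residue_on_grid(params, tau_fine + params.Tc)
        out[late] = np.interp(t[late] - params.Tc, tau_fine, Q)
    return out if np.ndim(t_s) else float(out[0])


def dp_forward(
    params: DPParams,
    aif: ArterialInputFunction,
    times_s,
    fine_dt_s: float = 0.5,
) -> np.ndarray:
    """Distributed-parameter tissue curve Ctiss = (F/100) (R * Cp) (mM).

    The vascular phase is integrated exactly as a running integral of the
    (piecewise-linear) AIF over the last Tc seconds; the smooth reflux
    phase is a trapezoidal convolution on an internal grid of spacing
    ``fine_dt_s``, so the discontinuity of R at Tc introduces no
    quadrature error.
    """
    t = np.asarray(times_s, dtype=float)
    if params.F <= 0:
        if params.PS == 0 and params.Ve == 0 and params.Tc == 0:
            return np.zeros_like(t)
        raise ValueError("dp_forward requires F > 0")
    t_end = float(t.max(initial=0.0))
    n = max(int(np.ceil(t_end / fine_dt_s)) + 1, 2)
    tf = np.linspace(0.0, max(t_end, fine_dt_s), n)
    h = tf[1] - tf[0]
    Cp = np.interp(tf, aif.times_s, aif.Cp, left=0.0)
    cumCp = np.concatenate([[0.0], cumulative_trapezoid(Cp, tf)])

    Tc = params.Tc
    # vascular term: int_{t-Tc}^{t} Cp  (piecewise-quadratic cumCp, interp ok)
    lower = np.clip(tf - Tc, 0.0, None)
    vasc = cumCp - np.interp(lower, tf, cumCp)

    if params.PS > 0.0 and params.Ve > 0.0:
        Q = _dp_residue_on_grid(params, tf + Tc)    # smooth reflux tail E - W
        conv = sp_signal.fftconvolve(Q, Cp)[:n] * h
        conv -= 0.5 * h * (Q[0] * Cp + Q * Cp[0])   # trapezoid end weights
        reflux = np.interp(tf - Tc, tf, conv, left=0.0)
        reflux[tf < Tc] = 0.0
    else:
        reflux = 0.0
    C_fine = (params.F / 6000.0) * (vasc + reflux)
    return np.interp(t, tf, C_fine)


def dp_pde_oracle(
    params: DPParams,
    aif: ArterialInputFunction,
    times_s,
    n_segments: int = 400,
) -> np.ndarray:
    """Independent ground truth for the DP model: explicit finite differences.

    Solves the two-region convection-exchange system on x in [0, 1]

        dcp/dt = -(1/Tc) dcp/dx - (PS/Vp)(cp - ce)
        dce/dt =  (PS/Ve)(cp - ce)

    with first-order upwind advection and inlet cp(0, t) = Cp(t), then
    returns the volume-weighted spatial average (Vp cbar_p + Ve cbar_e)/100.
    The time step honours both the CFL limit and the exchange rates via
    automatic sub-stepping.
    """
    if n_segments < 100:
        raise ValueError("n_segments must be >= 100 for a trustworthy oracle")
    t = np.asarray(times_s, dtype=float)
    Tc, Vp, Ve = params.Tc, params.Vp, params.Ve
    kp = params.PS / (Vp * 60.0) if Vp > 0 else 0.0
    ke = params.PS / (Ve * 60.0) if Ve > 0 else 0.0
    dx = 1.0 / n_segments
    v = 1.0 / Tc
    dt_cfl = 0.9 * dx / v
    dt_exch = 0.2 / max(kp, ke, 1e-12)
    dt = min(dt_cfl, dt_exch)

    t_end = float(t.max(initial=0.0))
    n_steps = int(np.ceil(t_end / dt)) + 1
    dt = t_end / max(n_steps - 1, 1)

    cp = np.zeros(n_segments)
    ce = np.zeros(n_segments)
    out = np.zeros(n_steps)
    tt = np.linspace(0.0, t_end, n_steps)
    Cin = np.interp(tt, aif.times_s, aif.Cp, left=0.0)
    for i in range(1, n_steps):
        upstream = np.concatenate([[Cin[i - 1]], cp[:-1]])
        adv = -v * (cp - upstream) / dx
        ex = cp - ce
        cp = cp + dt * (adv - kp * ex)
        ce = ce + dt * (ke * ex)
        out[i] = (Vp * cp.mean() + Ve * ce.mean()) / 100.0
    return np.interp(t, tt, out)


# --------------------------------------------------------------------------
# Voxelwise fitting
# --------------------------------------------------------------------------

def _model_curve(model: str, x: np.ndarray, aif, times_s, fine_dt_s: float) -> np.ndarray:
    if model == "et":
        return et_forward(ETParams(*x), aif, times_s)
    return dp_forward(DPParams(*x), aif, times_s, fine_dt_s=fine_dt_s)


def _start_points(model: str, bounds: dict, n_starts: int, seed: int) -> np.ndarray:
    names = _ET_NAMES if model == "et" else _DP_NAMES
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    typical = {"et": np.array([0.1, 10.0, 1.0]), "dp": np.array([15.0, 12.0, 8.0, 6.0])}[model]
    starts = [np.clip(typical, lo, hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=int(seed) & 0x7FFFFFFF)
        u = sampler.random(n_starts - 1)
        # square the unit sample: physiologic values sit near the lower bounds
        starts.append(lo + (hi - lo) * u**2)
    return np.vstack(starts)


def fit_voxel(
    curve,
    aif: ArterialInputFunction,
    times_s,
    model: str = "et",
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    fine_dt_s: float = 0.5,
    fit_delay: bool = False,
    delay_grid_s: np.ndarray | None = None,
) -> VoxelFit:
    """Bounded multi-start least-squares fit of one tissue curve.

    Starts are one physiologically typical point plus a seeded Latin
    hypercube over the bounds; the start with the smallest sum of squared
    residuals (SSR) wins, ties broken toward the smaller parameter-vector
    norm.  Derived parameters (Kep; Vp, MTT, E, Te) are computed from the
    fitted primitives, never fitted independently.  An optional
    bolus-arrival delay is handled by a grid search over shifted AIFs
    (off by default).
    """
    if model not in ("et", "dp"):
        raise ValueError(f"unknown model {model!r}")
    curve = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if not np.all(np.isfinite(curve)):
        finite = np.isfinite(curve)
        if finite.sum() < 5:
            return VoxelFit(model=model, params={}, SSR=np.nan,
                            converged=False, n_starts_used=0)
        curve = curve[finite]
        t = t[finite]
    bounds = dict((ET_BOUNDS if model == "et" else DP_BOUNDS), **(bounds or {}))
    names = _ET_NAMES if model == "et" else _DP_NAMES

    peak = float(np.abs(curve).max(initial=0.0))
    if peak == 0.0:  # flat-zero voxel: boundary solution, nothing to fit
        zero = {"et": ETParams(0, 1e-3, 0), "dp": DPParams(0, 0, 0, 0)}[model]
        return VoxelFit(model=model, params=_collect_params(model, zero),
                        SSR=0.0, converged=True, n_starts_used=0, at_boundary=True)

    delays = [0.0]
    if fit_delay:
        delays = list(delay_grid_s if delay_grid_s is not None
                      else np.arange(0.0, 10.01, float(np.median(np.diff(t)))))

    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    starts = _start_points(model, bounds, n_starts, seed)
    early_stop = 1e-12 * curve.size * max(peak, 1e-6) ** 2

    best = None
    n_used = 0
    for delay in delays:
        aif_d = aif if delay == 0.0 else ArterialInputFunction(
            times_s=aif.times_s + delay, Cp=aif.Cp)

        def resid(x, _aif=aif_d):
            return _model_curve(model, x, _aif, t, fine_dt_s) - curve

        for x0 in starts:
            n_used += 1
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                    ftol=1e-10, xtol=1e-10, gtol=1e-10,
                                    max_nfev=120 * len(names))
            except Exception:  # pragma: no cover - solver pathologies
                continue
            ssr = float(2.0 * sol.cost)
            cand = (ssr, float(np.linalg.norm(sol.x)), sol.x, delay)
            if best is None or cand[0] < best[0] * (1 - 1e-12) or (
                    abs(cand[0] - best[0]) <= 1e-12 * max(best[0], 1e-300)
                    and cand[1] < best[1]):
                best = cand
            if best[0] <= early_stop:
                break
        if best is not None and best[0] <= early_stop:
            break

    if best is None:
        return VoxelFit(model=model, params={k: np.nan for k in names},
                        SSR=np.nan, converged=False, n_starts_used=n_used)
    x = best[2]
    pobj = ETParams(*x) if model == "et" else DPParams(*x)
    params = _collect_params(model, pobj)
    if best[3] != 0.0:
        params["delay_s"] = best[3]
    at_bound = bool(np.any(np.isclose(x, lo)) or np.any(np.isclose(x, hi)))
    return VoxelFit(model=model, params=params, SSR=best[0],
                    converged=True, n_starts_used=n_used, at_boundary=at_bound)


def _collect_params(model: str, p) -> dict[str, float]:
    if model == "et":
        return {"Ktrans": p.Ktrans, "Ve": p.Ve, "Vp": p.Vp, "Kep": p.Kep}
    return {"F": p.F, "Tc": p.Tc, "Ve": p.Ve, "PS": p.PS,
            "Vp": p.Vp, "MTT": p.MTT, "E": 100.0 * p.E, "Te": p.Te}


def derived_params(fit: VoxelFit) -> dict[str, float]:
    """Derived quantities of a converged fit.

    ET: Kep = 100 Ktrans / Ve (min^-1).  DP: Vp = F Tc / 60 (mL/100 mL),
    MTT = Tc (s), E = 100 (1 - exp(-PS/F)) (%), Te = Ve/PS (min).
    Divisions by zero yield NaN.
    """
    if not fit.converged:
        raise ValueError("derived_params requires a converged fit")
    p = fit.params
    if fit.model == "et":
        kep = 100.0 * p["Ktrans"] / p["Ve"] if p["Ve"] > 0 else np.nan
        return {"Kep": kep}
    out = {
        "Vp": p["F"] * p["Tc"] / 60.0,
        "MTT": p["Tc"],
        "E": 100.0 * (1.0 - np.exp(-p["PS"] / p["F"])) if p["F"] > 0 else np.nan,
        "Te": p["Ve"] / p["PS"] if p["PS"] > 0 else np.nan,
    }
    return out


def fit_roi(
    conc: ConcentrationSeries,
    mask: VoxelMask,
    aif: ArterialInputFunction,
    model: str = "et",
    *,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    fine_dt_s: float = 0.5,
    fit_delay: bool = False,
    keep_fits: bool = False,
) -> ROIFitResult:
    """Fit every voxel inside the ROI and aggregate per-parameter medians.

    Failed voxels carry NaN in the maps and are excluded from medians.
    A warning is raised when more than half the voxels fail.
    """
    idx = mask.indices()
    shape = mask.data.shape
    if conc.data.shape[:3] != shape:
        raise ValueError("concentration series and mask shapes disagree")
    param_names = list(_collect_params(
        model, ETParams(0, 1, 0) if model == "et" else DPParams(1, 1, 1, 1)))
    maps = {k: np.full(shape, np.nan) for k in param_names}
    rows: dict[str, list[float]] = {k: [] for k in param_names}
    fits = []
    n_fitted = n_failed = 0
    for j, (i0, i1, i2) in enumerate(idx):
        vseed = (int(seed) * 1_000_003 + j) & 0x7FFFFFFF
        fit = fit_voxel(conc.data[i0, i1, i2], aif, conc.frame_times_s,
                        model=model, bounds=bounds, n_starts=n_starts,
                        seed=vseed, fine_dt_s=fine_dt_s, fit_delay=fit_delay)
        if keep_fits:
            fits.append(fit)
        if fit.converged:
            n_fitted += 1
            for k in param_names:
                maps[k][i0, i1, i2] = fit.params[k]
                rows[k].append(fit.params[k])
        else:
            n_failed += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = {k: float(np.nanmedian(v)) if v else np.nan for k, v in rows.items()}
    logger.info("fit_roi(%s): %d fitted, %d failed", model, n_fitted, n_failed)
    if n_failed > n_fitted:
        warnings.warn(
            f"{n_failed}/{n_failed + n_fitted} voxels failed to fit",
            FitQualityWarning, stacklevel=2,
        )
    return ROIFitResult(model=model, maps=maps, medians=medians,
                        n_fitted=n_fitted, n_failed=n_failed, fits=fits)
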