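"""File formats and validated containers for the DCE-MRI pipeline.

All image volumes are NIfTI-1 (via nibabel); cohort tables are CSV with a
header row; acquisition settings live in a YAML file mirroring
:class:`AcquisitionProtocol`.  Loaders never reorder axes or resample:
voxel (i, j, k) in a mask indexes voxel (i, j, k) in the series it was
drawn on, and masks must already be on the acquisition grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dcekin")

__all__ = [
    "AcquisitionProtocol",
    "DynamicSeries",
    "VoxelMask",
    "FormatError",
    "GeometryError",
    "EmptyROIError",
    "ValidationError",
    "ProtocolMismatchWarning",
    "load_dynamic_series",
    "load_mask",
    "read_cohort_table",
    "write_parameter_map",
    "read_parameter_map",
    "save_series",
]


class FormatError(ValueError):
    """Input file is not in the expected format (wrong dimensionality etc.)."""


class GeometryError(ValueError):
    """Spatial shapes of two volumes that must share a grid disagree."""


class EmptyROIError(ValueError):
    """A region-of-interest mask selects no voxels."""


class ValidationError(ValueError):
    """A cohort table violates its schema."""


class ProtocolMismatchWarning(UserWarning):
    """Loaded data is inconsistent with the declared acquisition protocol."""


@dataclass
class AcquisitionProtocol:
    """Acquisition settings of a spoiled gradient-echo DCE protocol.

    Defaults follow a 1.5 T THRIVE protocol: TR 4.4 ms, TE 2.1 ms,
    variable-flip-angle precontrast scans at 6/12/18 degrees (10 repeats
    each), then 115 dynamic frames at 18 degrees every 2.5 s.

    ``r1_relaxivity`` is the longitudinal relaxivity of the contrast agent
    in L mmol^-1 s^-1; ``hematocrit`` converts whole-blood to plasma
    concentration.
    """

    TR_ms: float = 4.4
    TE_ms: float = 2.1
    vfa_flips_deg: list[float] = field(default_factory=lambda: [6.0, 12.0, 18.0])
    dyn_flip_deg: float = 18.0
    n_baseline_per_flip: int = 10
    n_dynamic: int = 115
    dt_s: float = 2.5
    r1_relaxivity: float = 4.5
    hematocrit: float = 0.42

    def __post_init__(self) -> None:
        if self.TR_ms <= 0:
            raise ValueError(f"TR_ms must be positive, got {self.TR_ms}")
        if self.dt_s <= 0:
            raise ValueError(f"dt_s must be positive, got {self.dt_s}")
        flips = list(self.vfa_flips_deg) + [self.dyn_flip_deg]
        if any(not (0.0 < f <= 90.0) for f in flips):
            raise ValueError(f"flip angles must lie in (0, 90] deg, got {flips}")
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError(f"hematocrit must lie in [0, 1), got {self.hematocrit}")

    @property
    def frame_times_s(self) -> np.ndarray:
        """Uniform dynamic time grid, t = 0 at the first dynamic frame."""
        return np.arange(self.n_dynamic) * self.dt_s

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionProtocol":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class DynamicSeries:
    """4D (x, y, z, t) signal-intensity series with its time grid."""

    data: np.ndarray
    frame_times_s: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"dynamic series must be 4D, got {self.data.ndim}D")
        if len(self.frame_times_s) != self.data.shape[3]:
            raise FormatError(
                f"{len(self.frame_times_s)} frame times for {self.data.shape[3]} frames"
            )
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("signal data must be finite and non-negative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class VoxelMask:
    """Boolean 3D region of interest (tumor or artery)."""

    data: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"mask must be 3D, got {self.data.ndim}D")
        if not self.data.any():
            raise EmptyROIError(f"{self.label} mask selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        return np.argwhere(self.data)


def load_dynamic_series(
    path: str | Path,
    protocol: AcquisitionProtocol,
    frame_times_s: np.ndarray | None = None,
) -> DynamicSeries:
    """Load a 4D dynamic NIfTI series.

    Frame times default to a uniform grid ``n * protocol.dt_s``; an explicit
    per-frame table overrides.  A frame count differing from
    ``protocol.n_dynamic`` is a warning, not an error, so partial
    acquisitions remain loadable.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D dynamic series, got {data.ndim}D")
    n_t = data.shape[3]
    if n_t != protocol.n_dynamic:
        warnings.warn(
            f"{path}: {n_t} frames but protocol declares {protocol.n_dynamic}",
            ProtocolMismatchWarning,
            stacklevel=2,
        )
        logger.warning("frame-count mismatch for %s: %d != %d", path, n_t, protocol.n_dynamic)
    if frame_times_s is None:
        frame_times_s = np.arange(n_t) * protocol.dt_s
    zooms = img.header.get_zooms()[:3]
    return DynamicSeries(
        data=data,
        frame_times_s=np.asarray(frame_times_s, dtype=float),
        voxel_dims_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )


def load_mask(
    path: str | Path,
    series: DynamicSeries | None = None,
    label: str = "tumor",
) -> VoxelMask:
    """Load a 3D ROI mask; nonzero voxels select.

    When ``series`` is given, the mask's spatial shape must match the
    series' grid exactly (no resampling is ever performed).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    if series is not None and data.shape != series.spatial_shape:
        raise GeometryError(
            f"{path}: mask shape {data.shape} != series spatial shape {series.spatial_shape}"
        )
    return VoxelMask(data=data != 0, label=label)


# Cohort-table schema ------------------------------------------------------

SUBTYPES = ("endometrioid", "nonendometrioid")
GRADES = (1, 2, 3)
_FLAG_COLUMNS = ("dmi", "csi", "lvsi", "lnm")
_READER_COLUMNS = ("reader_dmi", "reader_csi", "reader_lnm")


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    mapping = {
        True: True, False: False, 1: True, 0: False,
        "1": True, "0": False, "true": True, "false": False,
        "yes": True, "no": False,
    }

    def conv(v):
        if pd.isna(v):
            return pd.NA
        key = v.strip().lower() if isinstance(v, str) else v
        if key not in mapping:
            raise ValidationError(f"column {column!r}: cannot interpret {v!r} as boolean")
        return mapping[key]

    return series.map(conv).astype("boolean")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-patient clinical CSV.

    Required columns: ``id`` and ``subtype``; ``grade`` is required for
    endometrioid rows (allowed values 1-3) and ignored otherwise.
    Pathology flags (dmi/csi/lvsi/lnm), reader calls and ``mvd`` are
    optional; absent columns stay absent rather than silently zero.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'id'")
    dupes = df["id"][df["id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate patient ids: {dupes}")
    if "subtype" in df.columns:
        bad = set(df["subtype"].dropna()) - set(SUBTYPES)
        if bad:
            raise ValidationError(f"{path}: unknown subtype tokens: {sorted(bad)}")
        if "grade" in df.columns:
            endo = df["subtype"] == "endometrioid"
            grades = pd.to_numeric(df.loc[endo, "grade"], errors="coerce")
            bad_grades = sorted(set(grades.dropna()) - set(GRADES))
            if bad_grades:
                raise ValidationError(
                    f"{path}: endometrioid grade must be one of {GRADES}, got {bad_grades}"
                )
    for col in (*_FLAG_COLUMNS, *_READER_COLUMNS):
        if col in df.columns:
            df[col] = _coerce_bool(df[col], col)
    if "risk" in df.columns:
        bad = set(df["risk"].dropna()) - {"low", "high"}
        if bad:
            raise ValidationError(f"{path}: risk labels must be low/high, got {sorted(bad)}")
    return df


def write_parameter_map(
    data: np.ndarray,
    name: str,
    units: str,
    path: str | Path,
    affine: np.ndarray | None = None,
) -> Path:
    """Write a 3D parameter map as NIfTI-1, units recorded in the header.

    NaN marks voxels where the fit failed and is preserved verbatim.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"parameter map must be 3D, got {data.ndim}D")
    img = nib.Nifti1Image(data, np.eye(4) if affine is None else affine)
    img.header["descrip"] = f"{name} [{units}]".encode()[:79]
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_parameter_map(path: str | Path) -> tuple[np.ndarray, str]:
    """Read a parameter map; returns (data, header description string)."""
    img = nib.load(str(path))
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    return np.asanyarray(img.dataobj).astype(np.float64), descrip


def save_series(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None,
                voxel_dims_mm: tuple[float, float, float] | None = None) -> Path:
    """Write a 3D/4D volume as NIfTI-1 (float64, bit-exact round trip)."""
    if affine is None:
        affine = np.eye(4)
        if voxel_dims_mm is not None:
            for i, d in enumerate(voxel_dims_mm):
                affine[i, i] = d
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    path = Path(path)
    nib.save(img, str(path))
    return path
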