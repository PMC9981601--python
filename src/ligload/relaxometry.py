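"""Voxel-wise T2* relaxometry from multi-echo gradient-echo volumes.

The signal model is a mono-exponential decay,

    S(TE) = S0 * exp(-TE / T2*),

fitted per voxel either by ordinary least squares on ``ln S`` vs ``TE``
(``log_linear``) or by nonlinear least squares on the exponential itself
(``nonlinear``, the default), initialized from the log-linear solution.

Voxels whose fit is non-physical (non-positive intensities on the log path,
or a non-positive fitted decay rate) are removed from the output mask rather
than imputed, so downstream region statistics stay well defined.  Fitted
T2* values are clamped to a configurable ceiling (default 100 ms, twice the
top sub-volume bin edge) so runaway fits cannot dominate region means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import nibabel as nib
import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MultiEchoVolume",
    "T2StarMap",
    "VoxelFit",
    "fit_t2star_voxel",
    "fit_t2star_map",
    "DEFAULT_T2_CEILING",
]

DEFAULT_T2_CEILING = 100.0  # ms


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_echo_times(echo_times: Sequence[float]) -> np.ndarray:
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or te.size < 2:
        raise ValidationError("need at least 2 echo times")
    if np.any(te < 0):
        raise ValidationError("echo times must be non-negative")
    if np.any(np.diff(te) <= 0):
        raise ValidationError("echo times must be strictly increasing")
    return te


@dataclass
class MultiEchoVolume:
    """A 4-D multi-echo acquisition: spatial axes x, y, z plus echo axis.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, n_echoes)
        Signal intensities in arbitrary units.
    echo_times : sequence of float
        Echo times in milliseconds, strictly increasing, one per echo.
    voxel_size : triple of float
        Voxel edge lengths in millimetres.
    """

    signal: np.ndarray
    echo_times: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError("signal must be 4-D (x, y, z, echo)")
        self.echo_times = _check_echo_times(self.echo_times)
        if self.signal.shape[-1] != self.echo_times.size:
            raise ValidationError(
                f"{self.signal.shape[-1]} echo volumes but "
                f"{self.echo_times.size} echo times"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    # --- NIfTI round trip ------------------------------------------------
    def to_nifti(self, path: str | Path) -> Path:
        """Write the 4-D volume plus a JSON echo-time sidecar (ms)."""
        path = Path(path)
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.signal.astype(np.float32), affine), path)
        sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
        sidecar.write_text(
            json.dumps({"EchoTimes": list(map(float, self.echo_times)), "Units": "ms"})
        )
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, echo_times: Sequence[float] | None = None) -> "MultiEchoVolume":
        """Load a 4-D volume; echo times come from the sidecar unless given."""
        path = Path(path)
        img = nib.load(path)
        if echo_times is None:
            sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
            if not sidecar.exists():
                raise ValidationError(f"no echo-time sidecar at {sidecar}")
            echo_times = json.loads(sidecar.read_text())["EchoTimes"]
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), np.asarray(echo_times, float), voxel_size)


@dataclass
class T2StarMap:
    """Per-voxel T2* map with fit diagnostics, restricted to a mask.

    ``t2star`` is in ms and positive wherever ``mask`` is true;
    ``fit_quality`` is the coefficient of determination of the voxel fit.
    """

    t2star: np.ndarray
    s0: np.ndarray
    fit_quality: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("t2star", "s0", "fit_quality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.mask.shape:
                raise ValidationError(f"{name} shape {arr.shape} != mask shape {self.mask.shape}")
            setattr(self, name, arr)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def values(self) -> np.ndarray:
        """In-mask T2* values, 1-D."""
        return self.t2star[self.mask]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.t2star.astype(np.float32), affine), path)
        return path

    def mask_to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), path)
        return path


class VoxelFit(NamedTuple):
    t2star: float
    s0: float
    fit_quality: float
    valid: bool


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ssr = float(np.sum((observed - fitted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if ssr == 0.0 else 0.0
    return 1.0 - ssr / sst


def _log_linear(intensities: np.ndarray, te: np.ndarray, ceiling: float) -> VoxelFit:
    if np.any(intensities <= 0):
        return VoxelFit(ceiling, float(np.max(intensities, initial=0.0)), 0.0, False)
    slope, intercept = np.polyfit(te, np.log(intensities), 1)
    s0 = float(np.exp(intercept))
    rate = -slope  # 1/T2*
    if rate <= 1.0 / ceiling:  # non-decaying (or too slow to resolve)
        return VoxelFit(ceiling, s0, 0.0, False)
    t2 = 1.0 / rate
    fitted = s0 * np.exp(-te / t2)
    return VoxelFit(float(t2), s0, _r_squared(intensities, fitted), True)


def _nonlinear(intensities: np.ndarray, te: np.ndarray, ceiling: float) -> VoxelFit:
    init = _log_linear(intensities, te, ceiling)
    p0 = [init.s0 if init.s0 > 0 else max(float(intensities.max()), 1e-3),
          init.t2star if init.valid else ceiling / 2.0]

    def model(x, s0, t2):
        return s0 * np.exp(-x / t2)

    try:
        popt, _ = curve_fit(
            model, te, intensities, p0=p0,
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=200, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except RuntimeError:
        return VoxelFit(ceiling, p0[0], 0.0, False)
    s0, t2 = float(popt[0]), float(popt[1])
    if t2 <= 0 or not np.isfinite(t2) or t2 >= ceiling:
        return VoxelFit(ceiling, s0, 0.0, False)
    return VoxelFit(t2, s0, _r_squared(intensities, model(te, s0, t2)), True)


def fit_t2star_voxel(
    intensities: Sequence[float],
    echo_times: Sequence[float],
    method: str = "nonlinear",
    ceiling: float = DEFAULT_T2_CEILING,
) -> VoxelFit:
    """Fit S(TE) = S0·exp(−TE/T2*) to one voxel's echo intensities.

    Returns a :class:`VoxelFit`; ``valid`` is False for non-physical fits
    (non-positive intensities on the log path, non-positive decay rate),
    in which case ``t2star`` is clamped to ``ceiling``.
    """
    te = _check_echo_times(echo_times)
    y = np.asarray(intensities, dtype=float)
    if y.shape != te.shape:
        raise ValidationError("intensities and echo_times must have equal length")
    if method == "log_linear":
        return _log_linear(y, te, ceiling)
    if method == "nonlinear":
        return _nonlinear(y, te, ceiling)
    raise ValidationError(f"unknown method {method!r}; use 'log_linear' or 'nonlinear'")


def fit_t2star_map(
    volume: MultiEchoVolume,
    mask: np.ndarray,
    method: str = "nonlinear",
    ceiling: float = DEFAULT_T2_CEILING,
) -> T2StarMap:
    """Fit every in-mask voxel of a multi-echo volume.

    Invalid voxels are dropped from the output mask; the count of removed
    voxels is reported on the returned map (``n_excluded``).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.spatial_shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume {volume.spatial_shape}"
        )
    if not mask.any():
        raise ValidationError("mask is empty")
    if method not in ("log_linear", "nonlinear"):
        raise ValidationError(f"unknown method {method!r}")

    te = volume.echo_times
    sig = volume.signal[mask]  # (n_vox, k)
    n_vox = sig.shape[0]
    t2 = np.zeros(n_vox)
    s0 = np.zeros(n_vox)
    r2 = np.zeros(n_vox)
    valid = np.zeros(n_vox, dtype=bool)

    # vectorized log-linear pass (exact on noiseless data, seeds nonlinear)
    pos = np.all(sig > 0, axis=1)
    if pos.any():
        logs = np.log(sig[pos])
        A = np.vstack([te, np.ones_like(te)]).T
        coef, *_ = np.linalg.lstsq(A, logs.T, rcond=None)
        slope, intercept = coef
        rate = -slope
        ok = rate > 1.0 / ceiling
        idx = np.flatnonzero(pos)
        t2[idx[ok]] = 1.0 / rate[ok]
        s0[idx[ok]] = np.exp(intercept[ok])
        valid[idx[ok]] = True
        fitted = s0[idx[ok], None] * np.exp(-te[None, :] / t2[idx[ok], None])
        obs = sig[idx[ok]]
        ssr = np.sum((obs - fitted) ** 2, axis=1)
        sst = np.sum((obs - obs.mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2v = np.where(sst > 0, 1.0 - ssr / sst, np.where(ssr == 0, 1.0, 0.0))
        r2[idx[ok]] = r2v

    if method == "nonlinear":
        for i in range(n_vox):
            fit = _nonlinear(sig[i], te, ceiling)
            t2[i], s0[i], r2[i], valid[i] = fit

    out_mask = np.zeros_like(mask)
    out_mask[mask] = valid
    t2_map = np.zeros(mask.shape)
    s0_map = np.zeros(mask.shape)
    r2_map = np.zeros(mask.shape)
    t2_map[mask] = t2
    s0_map[mask] = s0
    r2_map[mask] = r2

    return T2StarMap(
        t2star=t2_map,
        s0=s0_map,
        fit_quality=np.clip(r2_map, 0.0, 1.0),
        mask=out_mask,
        voxel_size=volume.voxel_size,
        n_excluded=int(mask.sum() - out_mask.sum()),
    )
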