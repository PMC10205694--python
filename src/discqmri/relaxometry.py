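"""Voxel-wise relaxation-time mapping from multi-spin-lock image series.

The decay of the MR signal with spin-lock time (TSL) in a T1rho-prepared
acquisition — or with echo time in a T2 mapping sequence — follows, to a
good approximation in the intervertebral disc, the mono-exponential model

    SI(TSL) = S0 * exp(-TSL / T)

where ``T`` is the tissue relaxation time in milliseconds (T1rho or T2
depending on the preparation).  This module fits that model per voxel by
nonlinear least squares (Levenberg-Marquardt) initialised from the
log-linear regression of ln(SI) on TSL; the log-linear estimate is the
fallback when the nonlinear solver fails.  Fitted times are clamped to a
physiological window and voxels whose signal is indistinguishable from
background noise are flagged invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DEFAULT_TSL_MS",
    "FitConfig",
    "SpinLockSeries",
    "RelaxationMap",
    "VoxelFit",
    "fit_monoexponential",
    "fit_map",
]

#: Default spin-lock time grid (ms).  Overridable per run.
DEFAULT_TSL_MS = (2.0, 10.0, 20.0, 40.0, 60.0)


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the per-voxel decay fit.

    Attributes
    ----------
    t_min, t_max:
        Clamp for the fitted relaxation time (ms).  Estimates at either
        bound are flagged invalid: disc tissue relaxation times observed
        in vivo lie well inside [1, 500] ms.
    noise_sigma:
        Estimate of the background noise standard deviation in signal
        units.  Voxels whose mean signal falls below
        ``noise_k * noise_sigma`` are treated as background.
    noise_k:
        Multiplier on ``noise_sigma`` for the background threshold.
    """

    t_min: float = 1.0
    t_max: float = 500.0
    noise_sigma: float = 1.0
    noise_k: float = 3.0
    max_nfev: int = 400

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise ValueError(f"clamp bounds must satisfy 0 < t_min < t_max, got ({self.t_min}, {self.t_max})")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


class VoxelFit(NamedTuple):
    """Result of a single-voxel decay fit."""

    s0: float
    t_ms: float
    fit_r2: float
    valid: bool


@dataclass
class SpinLockSeries:
    """A stack of co-registered images acquired at increasing spin-lock times.

    ``signals`` has shape (slice, row, column, acquisition); the last axis
    is ordered like ``tsl_ms``.
    """

    signals: np.ndarray
    tsl_ms: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality_tag: str = "T1rho"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.tsl_ms = np.asarray(self.tsl_ms, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4-D (slice, row, column, acquisition)")
        _check_tsl(self.tsl_ms, n_min=3)
        if self.signals.shape[-1] != self.tsl_ms.size:
            raise ValueError(
                f"acquisition axis has length {self.signals.shape[-1]} but {self.tsl_ms.size} TSLs were given"
            )
        if np.any(self.signals < 0):
            raise ValueError("signal intensities must be non-negative")
        if self.modality_tag not in ("T1rho", "T2"):
            raise ValueError(f"modality_tag must be 'T1rho' or 'T2', got {self.modality_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signals.shape[:3]


@dataclass
class RelaxationMap:
    """Per-voxel amplitude, relaxation time (ms), fit quality and validity.

    Invalid voxels carry NaN in ``t_ms``/``s0``/``fit_r2`` unless the fit
    ran but was rejected (clamp hit, sub-threshold signal), in which case
    the rejected estimate is kept for inspection with ``valid`` False.
    """

    s0: np.ndarray
    t_ms: np.ndarray
    fit_r2: np.ndarray
    valid: np.ndarray
    modality_tag: str = "T1rho"
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t_ms.shape


def _check_tsl(tsl_ms: np.ndarray, n_min: int) -> None:
    if tsl_ms.ndim != 1 or tsl_ms.size < n_min:
        raise ValueError(f"need at least {n_min} spin-lock times, got {tsl_ms.size}")
    if np.any(tsl_ms < 0):
        raise ValueError("spin-lock times must be non-negative")
    if np.any(np.diff(tsl_ms) <= 0):
        raise ValueError("spin-lock times must be strictly increasing")


def _model(tsl: np.ndarray, s0: float, t: float) -> np.ndarray:
    return s0 * np.exp(-tsl / t)


def _loglinear(signals: np.ndarray, tsl_ms: np.ndarray, cfg: FitConfig) -> tuple[float, float]:
    """Log-linear initialisation: regress ln(SI) on TSL, positive signals only."""
    pos = signals > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(tsl_ms[pos], np.log(signals[pos]), 1)
        t0 = -1.0 / slope if slope < 0 else cfg.t_max
        s00 = float(np.exp(intercept))
    else:
        t0, s00 = cfg.t_max, float(max(signals.max(), 1e-12))
    t0 = float(np.clip(t0, cfg.t_min, cfg.t_max))
    return s00, t0


def fit_monoexponential(
    signals: np.ndarray,
    tsl_ms: np.ndarray,
    config: FitConfig | None = None,
) -> VoxelFit:
    """Fit S0*exp(-TSL/T) to one voxel's signal-intensity decay.

    Parameters
    ----------
    signals:
        Signal intensities, one per spin-lock time, finite and non-negative.
    tsl_ms:
        Strictly increasing spin-lock times (ms), same length as ``signals``.
        Two points are accepted (closed-form log-ratio solution); the
        normal path requires at least three.
    config:
        Clamp, noise threshold and solver settings; defaults to
        :class:`FitConfig`.

    Returns
    -------
    VoxelFit
        ``(s0, t_ms, fit_r2, valid)``.  ``valid`` is False when the mean
        signal is below the noise threshold, the series shows no
        measurable decay (T at the upper clamp), T hits either clamp
        bound, or the fit diverged.
    """
    cfg = config or FitConfig()
    signals = np.asarray(signals, dtype=float).ravel()
    tsl_ms = np.asarray(tsl_ms, dtype=float).ravel()
    if signals.size != tsl_ms.size:
        raise ValueError(f"signals ({signals.size}) and tsl_ms ({tsl_ms.size}) lengths differ")
    _check_tsl(tsl_ms, n_min=2)
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")

    below_noise = signals.mean() < cfg.noise_k * cfg.noise_sigma

    # Two-point closed form: T = dTSL / ln(S1/S2).
    if signals.size == 2:
        s1, s2 = signals
        if s1 > s2 > 0:
            t = (tsl_ms[1] - tsl_ms[0]) / np.log(s1 / s2)
        else:
            t = cfg.t_max
        t_cl = float(np.clip(t, cfg.t_min, cfg.t_max))
        s0 = float(s1 * np.exp(tsl_ms[0] / t_cl)) if t_cl > 0 else s1
        at_clamp = t_cl != t or t_cl in (cfg.t_min, cfg.t_max)
        return VoxelFit(s0, t_cl, 1.0, not (below_noise or at_clamp))

    sst = float(np.sum((signals - signals.mean()) ** 2))
    if sst == 0.0:
        # Flat series: no measurable decay, T -> infinity.
        return VoxelFit(float(signals.mean()), cfg.t_max, np.nan, False)

    s00, t0 = _loglinear(signals, tsl_ms, cfg)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _model, tsl_ms, signals, p0=[s00, t0], method="lm", maxfev=cfg.max_nfev
            )
        s0, t = float(popt[0]), float(popt[1])
        diverged = not (np.isfinite(s0) and np.isfinite(t)) or t <= 0
    except RuntimeError:
        diverged = True
    if diverged:
        s0, t = s00, t0  # log-linear fallback

    t_cl = float(np.clip(t, cfg.t_min, cfg.t_max))
    at_clamp = not (cfg.t_min < t < cfg.t_max)
    resid = signals - _model(tsl_ms, s0, t_cl)
    fit_r2 = 1.0 - float(np.sum(resid**2)) / sst
    valid = not (below_noise or at_clamp or diverged)
    return VoxelFit(float(s0), t_cl, fit_r2, valid)


def fit_map(
    series: SpinLockSeries,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> RelaxationMap:
    """Fit the mono-exponential decay in every foreground voxel of a series.

    Voxels outside ``mask`` (when given) or whose first-acquisition signal
    does not exceed the noise threshold are left invalid with NaN
    estimates.  Deterministic for fixed input.
    """
    cfg = config or FitConfig()
    shape = series.shape
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} incompatible with series shape {shape}")
        if not mask.any():
            raise ValueError("mask is empty")
    else:
        mask = np.ones(shape, dtype=bool)

    s0 = np.full(shape, np.nan)
    t_ms = np.full(shape, np.nan)
    fit_r2 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    threshold = cfg.noise_k * cfg.noise_sigma
    candidates = mask & (series.signals[..., 0] > threshold)
    for idx in zip(*np.nonzero(candidates)):
        res = fit_monoexponential(series.signals[idx], series.tsl_ms, cfg)
        s0[idx], t_ms[idx], fit_r2[idx], valid[idx] = res

    if not valid.any():
        warnings.warn("relaxation map contains no valid voxels", stacklevel=2)
    return RelaxationMap(
        s0=s0,
        t_ms=t_ms,
        fit_r2=fit_r2,
        valid=valid,
        modality_tag=series.modality_tag,
        spacing_mm=series.spacing_mm,
        config=cfg,
    )
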