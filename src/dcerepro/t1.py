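"""Variable-flip-angle (VFA) T1 mapping for spoiled gradient-echo data.

Forward model (steady-state SPGR):

    S(theta) = m0 * sin(theta) * (1 - E) / (1 - E * cos(theta)),
    E = exp(-TR / T1).

``fit_vfa_t1`` estimates per-pixel (m0, T1) from signals at several flip
angles by a two-stage procedure: the classical linearisation (regress
S/sin(theta) on S/tan(theta); the slope is E) provides the initial value,
then bounded nonlinear least squares refines it.  The linear stage alone is
biased at low SNR, which is why the refinement stage exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionMeta

__all__ = ["T1Map", "spgr_signal", "fit_vfa_t1"]

T1_BOUNDS = (0.05, 10.0)  # seconds; generous envelope for tissue at 3 T


@dataclass
class T1Map:
    """Per-pixel longitudinal relaxation estimates.

    ``t1`` (s) and ``m0`` (signal units) are NaN where the fit failed;
    ``success`` flags usable pixels, ``fit_residual`` holds the per-pixel
    sum of squared residuals over the flip angles.
    """

    t1: np.ndarray
    m0: np.ndarray
    fit_residual: np.ndarray
    success: np.ndarray

    @property
    def n_failed(self) -> int:
        return int(np.size(self.success) - np.count_nonzero(self.success))


def spgr_signal(m0, t1, theta_deg, tr):
    """Steady-state SPGR signal.

    Parameters
    ----------
    m0 : array_like
        Equilibrium signal intensity (arbitrary units).
    t1 : array_like
        Longitudinal relaxation time in seconds (> 0).
    theta_deg : array_like
        Flip angle in degrees, strictly inside (0, 90).
    tr : float
        Repetition time in seconds (> 0).
    """
    theta = np.asarray(theta_deg, float)
    if np.any(theta <= 0) or np.any(theta >= 90):
        raise ValueError("flip angle must lie strictly between 0 and 90 degrees")
    if tr <= 0:
        raise ValueError("tr must be positive")
    t1 = np.asarray(t1, float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    th = np.deg2rad(theta)
    e1 = np.exp(-tr / t1)
    out = np.asarray(m0, float) * np.sin(th) * (1.0 - e1) / (1.0 - e1 * np.cos(th))
    if out.ndim == 0:
        return float(out)
    return out


def _linear_vfa(signals, angles_rad, tr):
    """Closed-form linearised VFA estimate; vectorised over leading axes.

    Returns (m0, t1, ok) where ok marks pixels with a usable slope.
    """
    s = np.asarray(signals, float)
    y = s / np.sin(angles_rad)          # S/sin(theta)
    x = s / np.tan(angles_rad)          # S/tan(theta)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=-1)
    sxy = ((x - xm) * (y - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym[..., 0] - slope * xm[..., 0]
    ok = np.isfinite(slope) & (slope > 0) & (slope < 1) & (sxx > 0)
    slope_safe = np.clip(np.where(ok, slope, 0.5), 1e-12, 1 - 1e-12)
    t1 = -tr / np.log(slope_safe)
    m0 = intercept / (1.0 - slope_safe)
    ok &= np.isfinite(t1) & (t1 > 0) & np.isfinite(m0) & (m0 > 0)
    return m0, t1, ok


def fit_vfa_t1(vfa_signals, meta: AcquisitionMeta, refine: bool = True) -> T1Map:
    """Estimate per-pixel m0 and T1 from multi-flip-angle SPGR signals.

    Parameters
    ----------
    vfa_signals : ndarray, shape (..., n_angles)
        Signal at each flip angle in ``meta.flip_angles_deg`` (last axis).
    meta : AcquisitionMeta
        Supplies the flip angles and TR.
    refine : bool
        Run the bounded nonlinear refinement after linear initialisation.

    Notes
    -----
    Degenerate pixels (all-zero signal, or signal constant across angles so
    the linear system has no unique solution) are flagged as failures, never
    silently zeroed.
    """
    s = np.asarray(vfa_signals, float)
    angles = np.asarray(meta.flip_angles_deg, float)
    if s.shape[-1] != angles.size:
        raise ValueError("last axis of vfa_signals must match the flip-angle list")
    if angles.size < 2 or np.unique(angles).size < 2:
        raise ValueError("at least two distinct flip angles are required")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")

    shape = s.shape[:-1]
    flat = s.reshape(-1, angles.size)
    ang_rad = np.deg2rad(angles)

    with np.errstate(divide="ignore", invalid="ignore"):
        m0_lin, t1_lin, ok = _linear_vfa(flat, ang_rad, meta.tr)
    # pixels with no signal or no variation across angles cannot be fit
    degenerate = (flat.max(axis=-1) <= 0) | (np.ptp(flat, axis=-1) == 0)
    ok &= ~degenerate
    t1_lin = np.clip(t1_lin, *T1_BOUNDS)

    m0 = np.where(ok, m0_lin, np.nan)
    t1 = np.where(ok, t1_lin, np.nan)
    rss = np.full(flat.shape[0], np.nan)
    success = ok.copy()

    sin_a, cos_a = np.sin(ang_rad), np.cos(ang_rad)

    def model(p):
        e1 = np.exp(-meta.tr / p[1])
        return p[0] * sin_a * (1.0 - e1) / (1.0 - e1 * cos_a)

    for i in np.flatnonzero(ok):
        sig = flat[i]
        if refine:
            m0_hi = max(10.0 * m0_lin[i], 10.0 * sig.max(), 1.0)
            res = least_squares(
                lambda p: model(p) - sig,
                x0=[m0_lin[i], t1_lin[i]],
                bounds=([0.0, T1_BOUNDS[0]], [m0_hi, T1_BOUNDS[1]]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            m0[i], t1[i] = res.x
            rss[i] = float(np.sum(res.fun ** 2))
            success[i] = res.success and np.isfinite(res.x).all()
        else:
            rss[i] = float(np.sum((model([m0[i], t1[i]]) - sig) ** 2))

    return T1Map(
        t1=t1.reshape(shape),
        m0=m0.reshape(shape),
        fit_residual=rss.reshape(shape),
        success=success.reshape(shape),
    )
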