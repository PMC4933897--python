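"""Extended Tofts two-compartment model: forward evaluation and fitting.

Tissue concentration under the extended Tofts model is

    C_t(t) = v_p C_p(t) + Ktrans * int_0^t C_p(u) exp(-kep (t-u)) du,

with Ktrans the plasma-to-EES transfer constant (min^-1), v_e the EES
volume fraction, v_p the plasma volume fraction and kep = Ktrans / v_e the
efflux rate (min^-1).  For the bi-exponential population input function the
convolution has the closed form, per exponential term (s = minutes since
bolus onset):

    Ktrans * D * a_i * (exp(-kep s) - exp(-m_i s)) / (m_i - kep),

with the L'Hopital limit  Ktrans * D * a_i * s * exp(-kep s)  when
m_i ~= kep.  All times are converted to minutes inside the model so that
Ktrans and kep come out in min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import AIFModel, population_aif

__all__ = ["ParameterMap", "tofts_forward", "fit_voxel", "fit_map", "FitConfig"]

_DEGENERACY_EPS = 1e-8  # |m_i - kep| below this switches to the limit formula


@dataclass(frozen=True)
class FitConfig:
    """Bounds and initialisation for the voxelwise nonlinear fit.

    Bounds are a physiologic envelope deliberately wider than any post-hoc
    pixel-exclusion threshold, so exclusion stays a distinct downstream step.
    """

    ktrans_bounds: tuple = (0.0, 5.0)      # min^-1
    ve_bounds: tuple = (1e-3, 1.0)
    vp_bounds: tuple = (0.0, 0.5)
    init: tuple = (0.1, 0.3, 0.02)         # (ktrans, ve, vp)
    restart: tuple = (0.5, 0.6, 0.05)      # fallback start on non-convergence


@dataclass
class ParameterMap:
    """Per-pixel extended-Tofts parameter estimates.

    ``ktrans`` and ``kep`` in min^-1, ``ve``/``vp`` dimensionless fractions;
    ``rss`` the residual sum of squares of the fit and ``converged`` the
    per-pixel success flag.  Unfitted pixels (outside the mask, or failed)
    are NaN.  kep is reported as ktrans/ve by definition.
    """

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    kep: np.ndarray
    rss: np.ndarray
    converged: np.ndarray

    @property
    def n_converged(self) -> int:
        return int(np.count_nonzero(self.converged))


def tofts_forward(ktrans, ve, vp, aif: AIFModel, times):
    """Closed-form extended-Tofts tissue concentration on a time grid.

    Parameters
    ----------
    ktrans : float
        Transfer constant in min^-1 (>= 0).
    ve : float
        EES fraction; must be > 0 whenever ktrans > 0 (kep undefined else).
    vp : float
        Plasma fraction.
    aif : AIFModel
        Bi-exponential input function (amplitudes kg/l, rates min^-1).
    times : array_like
        Frame times in seconds since acquisition start.

    Returns
    -------
    ndarray
        C_t at each time, in mM; zero before bolus onset.
    """
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be positive when ktrans > 0 (kep = ktrans/ve)")
    t = np.asarray(times, float)
    s = (t - aif.onset_time) / 60.0       # minutes since onset
    post = s >= 0
    sp = np.where(post, s, 0.0)

    ct = vp * population_aif(t, aif)
    if ktrans > 0:
        kep = ktrans / ve
        for a, m in zip(aif.amplitudes, aif.rates):
            if abs(m - kep) < _DEGENERACY_EPS:
                term = ktrans * aif.dose_D * a * sp * np.exp(-kep * sp)
            else:
                term = (
                    ktrans * aif.dose_D * a
                    * (np.exp(-kep * sp) - np.exp(-m * sp)) / (m - kep)
                )
            ct = ct + np.where(post, term, 0.0)
    return ct


def fit_voxel(conc, times, aif: AIFModel, config: FitConfig = FitConfig()):
    """Bounded nonlinear least-squares fit of one voxel's concentration curve.

    Returns ``(ktrans, ve, vp, kep, rss, converged)``.  A flat or non-finite
    series yields ``converged=False`` with NaN parameters rather than an
    exception; an all-zero series is a legitimate non-enhancing voxel and
    fits to ktrans ~ 0, vp ~ 0.
    """
    c = np.asarray(conc, float)
    t = np.asarray(times, float)
    n_post = int(np.sum(t >= aif.onset_time))
    if n_post < 8:
        raise ValueError("need at least 8 post-bolus frames to fit three parameters")
    if not np.isfinite(c).all():
        return (np.nan,) * 5 + (False,)

    lo = [config.ktrans_bounds[0], config.ve_bounds[0], config.vp_bounds[0]]
    hi = [config.ktrans_bounds[1], config.ve_bounds[1], config.vp_bounds[1]]

    def residual(p):
        return tofts_forward(p[0], p[1], p[2], aif, t) - c

    best = None
    for x0 in (config.init, config.restart):
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residual, x0=x0, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost <= 1e-12 * max(1.0, float(np.sum(c ** 2))):
            break  # essentially exact fit; no restart needed
    if best is None or not np.isfinite(best.x).all():
        return (np.nan,) * 5 + (False,)

    ktrans, ve, vp = best.x
    kep = ktrans / ve if ve > 0 else np.nan
    rss = float(np.sum(best.fun ** 2))
    return float(ktrans), float(ve), float(vp), float(kep), rss, bool(best.success)


def fit_map(conc_series, mask, aif: AIFModel, config: FitConfig = FitConfig()) -> ParameterMap:
    """Fit every pixel inside ``mask`` of a ConcentrationSeries.

    Raises on an empty mask; individual pixel failures are flagged in
    ``converged`` and counted, never silently dropped.
    """
    mask = np.asarray(mask, bool)
    conc = np.asarray(conc_series.conc, float)
    if conc.shape[:-1] != mask.shape:
        raise ValueError("mask and concentration grids differ")
    if not mask.any():
        raise ValueError("mask is empty")

    shape = mask.shape
    out = {k: np.full(shape, np.nan) for k in ("ktrans", "ve", "vp", "kep", "rss")}
    converged = np.zeros(shape, bool)
    times = conc_series.times

    for idx in np.argwhere(mask):
        idx = tuple(idx)
        kt, ve, vp, kep, rss, ok = fit_voxel(conc[idx], times, aif, config)
        out["ktrans"][idx], out["ve"][idx], out["vp"][idx] = kt, ve, vp
        out["kep"][idx], out["rss"][idx] = kep, rss
        converged[idx] = ok

    return ParameterMap(converged=converged, **out)
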