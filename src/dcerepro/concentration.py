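"""Signal-to-concentration conversion for dynamic SPGR series.

Each dynamic frame's signal is inverted through the SPGR equation (with the
pre-contrast equilibrium signal m0 from the VFA fit) to an instantaneous T1,
and the tissue contrast-agent concentration follows from the linear
relaxivity model

    C_t(t) = (1/T1(t) - 1/T10) / r,

with r the longitudinal relaxivity in s^-1 mM^-1.  The pre-contrast
reference rate 1/T10 is taken from the averaged pre-bolus frames, so the
baseline concentration is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionMeta
from .t1 import T1Map

__all__ = ["ConcentrationSeries", "signal_to_t1", "to_concentration"]


@dataclass
class ConcentrationSeries:
    """Per-pixel tissue concentration (mM) over the dynamic frames.

    ``conc`` has shape grid + (n_frames,); NaN marks pixels/frames where the
    signal inversion failed.  ``baseline_frames`` lists the pre-contrast
    frame indices averaged into the reference.
    """

    conc: np.ndarray
    baseline_frames: tuple
    meta: AcquisitionMeta
    n_failed: int = 0
    failed_mask: np.ndarray = field(default=None, repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.meta.frame_times, float)


def signal_to_t1(signal, m0, theta_deg, tr):
    """Invert the SPGR equation for T1 given the signal and m0.

    Solving S = m0 sin(theta)(1-E)/(1-E cos(theta)) for E = exp(-TR/T1):

        E = (m0 sin(theta) - S) / (m0 sin(theta) - S cos(theta)),
        T1 = -TR / ln(E).

    Valid for 0 < S < m0 sin(theta) (below saturation).  Outside that range
    the return is NaN — the caller flags the pixel rather than raising, so a
    single bad pixel never aborts a map.
    """
    s = np.asarray(signal, float)
    m0 = np.asarray(m0, float)
    th = np.deg2rad(theta_deg)
    smax = m0 * np.sin(th)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (smax - s) / (smax - s * np.cos(th))
        valid = (s > 0) & (s < smax) & (e1 > 0) & (e1 < 1)
        t1 = np.where(valid, -tr / np.log(np.where(valid, e1, 0.5)), np.nan)
    if t1.ndim == 0:
        return float(t1)
    return t1


def to_concentration(series, t1map: T1Map, relaxivity: float = None) -> ConcentrationSeries:
    """Convert a dynamic signal series into tissue concentration.

    Parameters
    ----------
    series : DynamicSeries
        Dynamic frames plus acquisition metadata (see ``dcerepro.synthetic``).
    t1map : T1Map
        Pre-contrast VFA fit supplying per-pixel m0 (m0 is contrast-agent
        independent, so it is not re-estimated per frame).
    relaxivity : float, optional
        r in s^-1 mM^-1; defaults to ``series.meta.relaxivity``.

    Notes
    -----
    The reference relaxation rate is obtained by inverting the average of
    the pre-bolus frames; pixels whose baseline or frame inversion fails
    propagate as NaN and are counted in ``n_failed``.
    """
    meta = series.meta
    if relaxivity is None:
        relaxivity = meta.relaxivity
    if relaxivity <= 0:
        raise ValueError("relaxivity must be positive")
    frames = np.asarray(series.frames, float)
    if frames.shape[:-1] != t1map.t1.shape:
        raise ValueError("dynamic series and T1 map grids differ")

    baseline_idx = tuple(range(meta.bolus_frame_index))
    if not baseline_idx:
        raise ValueError("no pre-bolus frames: bolus_frame_index must be >= 1")
    theta, tr = meta.dynamic_flip_deg, meta.tr
    m0 = t1map.m0

    baseline = frames[..., list(baseline_idx)].mean(axis=-1)
    t1_base = signal_to_t1(baseline, m0, theta, tr)
    t1_t = signal_to_t1(frames, m0[..., None], theta, tr)

    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (1.0 / t1_t - 1.0 / t1_base[..., None]) / relaxivity
    conc = np.where(np.isfinite(conc), conc, np.nan)
    bad_pixel = ~np.isfinite(t1_base) | ~np.asarray(t1map.success, bool)
    conc[bad_pixel] = np.nan

    failed = ~np.isfinite(conc)
    return ConcentrationSeries(
        conc=conc,
        baseline_frames=baseline_idx,
        meta=meta,
        n_failed=int(failed.any(axis=-1).sum()),
        failed_mask=failed.any(axis=-1),
    )
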