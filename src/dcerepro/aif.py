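"""Population-averaged arterial input function (AIF).

The plasma concentration is the classic bi-exponential Weinmann/Tofts form

    C_p(t) = D * (a1 * exp(-m1 * tau) + a2 * exp(-m2 * tau)),   tau >= 0,

with tau the time since bolus arrival expressed in minutes, D the dose in
mmol/kg, amplitudes a_i in kg/l (so C_p comes out in mmol/l = mM) and decay
rates m_i in min^-1.  Before bolus arrival C_p is identically zero.

Default constants: D = 1.0 mmol/kg, a1 = 2.4 kg/l, a2 = 0.62 kg/l,
m1 = 3.0 min^-1, m2 = 0.016 min^-1.  Note D = 1.0 is the literature curve's
normalisation constant; the clinically administered dose (0.1 mmol/kg) is a
separate quantity and deliberately not substituted here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["AIFModel", "population_aif"]


@dataclass(frozen=True)
class AIFModel:
    """Bi-exponential population plasma input function.

    ``onset_time`` is the bolus arrival time in seconds on the acquisition
    clock; amplitudes in kg/l, rates in min^-1, dose in mmol/kg.
    """

    dose_D: float = 1.0
    amplitudes: tuple = (2.4, 0.62)
    rates: tuple = (3.0, 0.016)
    onset_time: float = 0.0

    def __post_init__(self):
        if len(self.amplitudes) != len(self.rates):
            raise ValueError("amplitudes and rates must pair up")
        if np.any(np.asarray(self.amplitudes) <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(np.asarray(self.rates) <= 0):
            raise ValueError("rates must be positive")
        if self.dose_D <= 0:
            raise ValueError("dose must be positive")

    def __call__(self, t):
        return population_aif(t, self)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["amplitudes"] = list(d["amplitudes"])
        d["rates"] = list(d["rates"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "AIFModel":
        d = json.loads(Path(path).read_text())
        d["amplitudes"] = tuple(d["amplitudes"])
        d["rates"] = tuple(d["rates"])
        return cls(**d)


def population_aif(t, model: AIFModel = None):
    """Evaluate the plasma concentration C_p(t) in mM.

    Parameters
    ----------
    t : array_like
        Times in seconds since acquisition start.
    model : AIFModel, optional
        Defaults to the standard population constants with onset at t = 0.

    Returns
    -------
    ndarray or float
        C_p(t); zero for t < ``model.onset_time``.
    """
    if model is None:
        model = AIFModel()
    t = np.asarray(t, float)
    tau_min = (t - model.onset_time) / 60.0
    cp = np.zeros_like(tau_min)
    post = tau_min >= 0
    for a, m in zip(model.amplitudes, model.rates):
        cp = np.where(post, cp + model.dose_D * a * np.exp(-m * np.where(post, tau_min, 0.0)), cp)
    if cp.ndim == 0:
        return float(cp)
    return cp
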