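"""Sample size for an ICC reliability study (Walter-Eliasziw-Donner).

For testing H0: rho = rho0 against H1: rho = rho1 (> rho0) with k raters,
one-sided significance alpha and power 1 - beta, the approximate minimum
number of subjects is

    n = 1 + 2 k (z_{1-alpha} + z_{1-beta})^2 / [(k - 1) (ln C0)^2],

    C0 = (1 + k rho0 / (1 - rho0)) / (1 + k rho1 / (1 - rho1)),

rounded up to the next integer.  With rho0 = 0.75, rho1 = 0.9, k = 3,
alpha = 0.05, beta = 0.20 this gives n = 19.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["IccDesign", "icc_sample_size"]


@dataclass(frozen=True)
class IccDesign:
    """Design of an ICC reliability study.

    rho0: lowest acceptable ICC (null); rho1: expected ICC (alternative);
    k_raters: observers per subject; alpha: significance (one-sided by
    default, matching the standard reliability-study formulation);
    beta: type-II error (power = 1 - beta).
    """

    rho0: float = 0.75
    rho1: float = 0.9
    k_raters: int = 3
    alpha: float = 0.05
    beta: float = 0.20
    two_sided: bool = False

    def __post_init__(self):
        if not (0 <= self.rho0 < self.rho1 < 1):
            raise ValueError("require 0 <= rho0 < rho1 < 1")
        if self.k_raters < 2:
            raise ValueError("need at least 2 raters")
        if not (0 < self.alpha < 0.5 and 0 < self.beta < 0.5):
            raise ValueError("alpha and beta must lie in (0, 0.5)")


def icc_sample_size(design: IccDesign = IccDesign()) -> int:
    """Minimum subject count for the ICC reliability design (rounded up)."""
    k = design.k_raters
    alpha = design.alpha / 2 if design.two_sided else design.alpha
    za = norm.ppf(1 - alpha)
    zb = norm.ppf(1 - design.beta)
    c0 = (1 + k * design.rho0 / (1 - design.rho0)) / \
         (1 + k * design.rho1 / (1 - design.rho1))
    n = 1 + 2 * k * (za + zb) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return max(2, math.ceil(n - 1e-12))
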