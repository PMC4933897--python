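"""Fit T1 and m0 from variable-flip-angle SPGR signals.

Signals are simulated at the protocol's five angles (3-15 degrees,
TR = 2.8 ms) for a tissue with T1 = 1.4 s, with and without noise.
"""

import numpy as np

from dcerepro import fit_vfa_t1, spgr_signal
from dcerepro.acquisition import study_protocol

meta = study_protocol()
angles = np.array(meta.flip_angles_deg)
clean = spgr_signal(1000.0, 1.4, angles, meta.tr)
print("signals at", angles, "deg:", np.round(clean, 2))

fit = fit_vfa_t1(clean[None, :], meta)
print(f"noiseless fit: T1 = {fit.t1[0]:.6f} s, m0 = {fit.m0[0]:.2f}")

rng = np.random.default_rng(1)
noisy = np.clip(clean[None, :] + rng.normal(0, clean.max() / 50, (500, 5)), 0, None)
fit_n = fit_vfa_t1(noisy, meta)
print(f"noisy (SNR 50, 500 px): median T1 = {np.median(fit_n.t1[fit_n.success]):.3f} s, "
      f"{fit_n.n_failed} failed pixels")
# The noiseless fit recovers the generating T1 exactly; at SNR 50 the
# median over pixels stays within a few percent of 1.4 s.
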