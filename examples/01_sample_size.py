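"""Plan an ICC reliability study: how many subjects do three observers need?

Tests H0: ICC = 0.75 (lowest acceptable agreement) against the expected
ICC = 0.9, at one-sided alpha 0.05 with 80% power, using the
Walter-Eliasziw-Donner approximation.
"""

from dcerepro import IccDesign, icc_sample_size

design = IccDesign(rho0=0.75, rho1=0.9, k_raters=3, alpha=0.05, beta=0.20)
n = icc_sample_size(design)
print(f"minimum subjects: {n}")
# The printed count is the smallest cohort for which the study can
# distinguish "good" agreement (0.9) from the acceptance floor (0.75).
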