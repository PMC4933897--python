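"""Reproducibility statistics on a simulated multi-rater cohort.

A two-way random-effects cohort is drawn with known variance components
(population ICC 0.9), then summarised with ICC(A,1) + 95% CI, the
agreement band, the coefficient of variation, and ANOVA across raters.
"""

from dcerepro import cov, icc, make_cohort, one_way_anova, design_matrix

# variance components on the scale of a Ktrans ROI mean (units min^-2)
table = make_cohort(n_subjects=21, design={"n_raters": 3},
                    variance_components={"between": 9e-3, "rater": 2e-4,
                                         "residual": 1e-3},
                    mu=0.335, seed=19)
print(f"population ICC = {table.attrs['population_icc']:.3f}")

r = icc(table, "inter")
print(f"estimated ICC(A,1) = {r.estimate:.3f} "
      f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), {r.category} agreement, "
      f"p = {r.p_value:.2e}")

c = cov(table, "inter")
print(f"inter-observer CoV = {c.estimate:.2f}%")

x = design_matrix(table, "inter")
a = one_way_anova([x[:, j] for j in range(x.shape[1])])
print(f"ANOVA across raters: F = {a.estimate:.3f}, p = {a.p_value:.3f}")
# With 21 subjects the ICC estimate scatters around 0.9 ("good", > 0.75);
# a non-significant ANOVA means no systematic rater offset.
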