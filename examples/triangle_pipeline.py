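"""End-to-end dense-survey pipeline: counts to detection-corrected totals.

Simulates 25 years of a densely sampled (~36% coverage) triangular study
area holding a cyclic population with a north-coast density gradient, then
runs the full chain: inclusion rules -> 1-km segmentation -> NB-GAM (M1:
spatial smooth + year smooth) -> 500-draw coefficient posterior -> grid
prediction of annual index totals -> Beta detection correction -> trend
and dominant cycle period.
"""

import numpy as np

import surveygam as sg

cfg = sg.preset("triangle_like", seed=1)
obs, transects, area, truth = sg.simulate(cfg)
obs = sg.indicated_units(sg.apply_inclusion_rules(obs))
segments = sg.assign_counts(sg.segment_transects(transects, 1.0, 0.4), obs)
print(f"{len(segments)} segments, {segments['count'].sum()} indicated pairs observed")

fit = sg.fit_gam(sg.standard_models(which=["M1"], k_year=12)["M1"], segments)
print(f"M1 fit: edf={fit.edf_total:.1f}, theta={fit.theta:.2f}, AIC={fit.aic:.1f}")

years = sorted(segments["year"].unique())
grid = sg.make_grid(area, 1.0, years)
draws = sg.sample_coefficients_mvn(fit, 500, seed=11)
post = sg.detection_correct(
    sg.totals_from_draws(draws, fit, grid), sg.canonical_prior(), seed=12
)
summ = sg.summarize(post, corrected=True)

print("\nindicated breeding birds (detection-corrected), first 5 years:")
print(summ.head().round(1).to_string(index=False))

t25 = sg.trend(post, years[0], 24)
print(f"\n24-year log growth rate: {t25['mean']:.4f} "
      f"(95% CI {t25['q025']:.4f} to {t25['q975']:.4f})")

pp = sg.posterior_period(post.corrected_totals)
print(f"dominant cycle period: {pp.mean:.2f} years "
      f"(95% CI {pp.q025:.2f} to {pp.q975:.2f}); truth = {cfg.period}")
# The posterior band is wide (the detection prior alone spans a 2-6x
# correction) but the cycle period is pinned tightly: trends depend on
# where in the cycle the endpoints sit, the period does not.
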