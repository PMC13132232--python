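"""Wavelet detection of a population cycle in a short annual series.

Builds a 25-year log-cyclic abundance series (period 6.5 years) with
observation noise, computes its Morlet wavelet power spectrum, tests the
time-averaged power against a white-noise null, and reports the dominant
period with a bootstrap interval.  Also shows the null calibration: white
noise should trigger at roughly the nominal rate.
"""

import numpy as np

from surveygam import cwt_morlet, dominant_period, ridge, white_noise_test

rng = np.random.default_rng(7)
years = np.arange(1999, 2024)
series = np.exp(1.0 * np.sin(2 * np.pi * years / 6.5) + 0.2 * rng.standard_normal(25))

spec = cwt_morlet(series, times=years)
white_noise_test(spec, n_sim=200, seed=0)
dp = dominant_period(spec)
print(f"dominant period: {dp['period']:.2f} years "
      f"(bootstrap 95% CI {dp['ci_low']:.2f} to {dp['ci_high']:.2f})")
print(f"white-noise bootstrap p-value at that period: {dp['pvalue']:.3f}")
print(f"boundary hit (unresolved cycle?): {dp['boundary_hit']}")

r = ridge(spec)
print(f"ridge points traced: {len(r)}; median ridge period "
      f"{r['period'].median():.2f} years")

fp = np.mean(white_noise_test(cwt_morlet(rng.standard_normal(25)),
                              n_sim=200, seed=1) <= 0.05)
print(f"fraction of periods flagged at alpha=0.05 for pure noise: {fp:.2f}")
# A 25-point series is short for spectral work: the cone of influence
# covers much of the spectrogram, but a strong stationary cycle still
# stands far above the white-noise band at its true period.
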