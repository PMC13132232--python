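# surveygam

Population size, spatial density, trend and cycle estimation for rare
birds counted on **aerial strip-transect surveys** — built around the kind
of data an arctic-breeding sea duck survey produces: a handful of single
males and pairs per year scattered along transects, many empty segments,
detection far below one, and boom–bust dynamics that make naive trend
estimates meaningless.

The package implements the full inference chain:

1. **Survey data model** — observations (single male / pair / lone female /
   open group), transects and study-area polygons, with the standard
   inclusion rules (drop lone females and off-transect sightings, recode
   size-1 open groups to single males) reducing sightings to *indicated
   pairs*.
2. **Design-based estimation** — the strip-adapted Fewster R3 estimator
   per stratum and year: N̂ = A·Σnᵢ/Σaᵢ with its between-strip variance,
   95% CIs truncated at zero.
3. **Model-based estimation** — spatio-temporal negative-binomial GAMs
   (log link, log segment-area offset) over the model menu
   M0: `s(X,Y)` … M2: `s(X,Y)+s(Year)+ti(X,Y,Year)` … M4:
   `s(X,Y)+s(fYear)`, fit by penalized IRLS with Laplace-REML smoothing
   and dispersion selection, compared by edf-based AIC.
4. **Posterior simulation** — MVN or Metropolis-Hastings coefficient
   draws pushed through a 1 km² prediction grid: index totals
   Ŷᵢⱼ = Σₖ aₖ exp(x′ⱼₖbᵢ), detection-corrected totals N̂ᵢⱼ = 2Ŷᵢⱼ/dᵢ with
   dᵢ ~ Beta(7.41, 16.73) (moment-matched to detection 0.307 ± 0.092),
   and per-draw geometric-mean growth rates
   T = (log N_{j+t} − log N_j)/t.
5. **Wavelet cycle analysis** — Morlet power spectra of annual totals,
   white-noise bootstrap significance, and the posterior distribution of
   the dominant cycle period across GAM draws.
6. **Synthetic surveys** — a generator with known truth (coastal
   gradient × log-scale cycle × optional drift, NB counts, binomial
   detection thinning) and presets mimicking a dense small-area survey
   (~36% coverage) and a sparse stratified one (~2–6%).

See `docs/methods.md` for the statistical details and design choices.

## Worked example

`examples/triangle_pipeline.py` simulates 25 years of a densely surveyed
216 km² triangular area holding a cyclic population (period 6.5 years,
detection 0.307) and runs the whole chain:

```
$ python examples/triangle_pipeline.py
5100 segments, 383 indicated pairs observed
M1 fit: edf=13.7, theta=3.89, AIC=2632.3

indicated breeding birds (detection-corrected), first 5 years:
 year  mean  median  q025  q975
 1999 258.4   227.4 108.1 586.3
 2000 116.5   105.7  51.2 248.2
 2001 135.4   122.1  64.3 279.5
 2002 254.3   235.5 123.4 511.5
 2003 486.4   452.6 253.4 940.0

24-year log growth rate: 0.0449 (95% CI 0.0211 to 0.0688)
dominant cycle period: 6.45 years (95% CI 6.26 to 6.48); truth = 6.5
```

The posterior bands are wide — the detection prior alone spans a 2–6-fold
correction — yet the cycle period is recovered within a ladder step of
the simulated truth.  The other examples show the detection-prior
construction (`detection_prior.py`), the shrinkage of model-based annual
estimates relative to design-based ones on a sparse survey
(`design_vs_model.py`), and wavelet cycle detection on short series
(`wavelet_demo.py`).

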