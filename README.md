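# paleorange

Geographic range evolution and diversification of extinct clades from
fossil occurrence records.

Most animal clades wax and then wane: they start small, spread and
diversify, and then decline to extinction along a surprisingly regular
path. One candidate explanation is progressive specialisation — over a
clade's history its species tend to become smaller-ranged and more
sympatric (their ranges overlap more), which depresses speciation and
promotes extinction. `paleorange` implements the full analytical pipeline
needed to test that idea on occurrence data in Paleobiology Database
download format, and a synthetic-data generator that produces occurrence
records with the statistical structure the analysis assumes, so the whole
pipeline runs and is tested without any download.

## What it computes

Given one clade's occurrences (species, paleo-longitude/latitude, age
interval), the pipeline:

1. **filters and bins** the records (open nomenclature, optional
   rare-species filter, stratigraphic continuity; equal-length clade-
   specific time bins chosen so every bin keeps ≥ 3 species with ≥ 3
   occurrences);
2. **estimates range sizes** per species and bin as minimum convex
   polygon (MCP) areas on equal-area projections (Lambert azimuthal /
   Mollweide / Albers by extent), and the clade's per-bin range as the
   union of species polygons;
3. **builds the range curves**: total (Σ species areas), clade (union),
   and average range per bin, their cumulative versions, and the
   **degree of sympatry** s_t = total/clade (1 = disjoint ranges, higher
   = more overlap);
4. **fits growth models** (linear vs logistic vs Richards) to the
   cumulative total range by maximum likelihood and compares them by
   AICc;
5. **infers origination/extinction times** (ts, te) per species under a
   Poisson preservation model by MCMC, and per-Myr speciation, extinction
   and net diversification rates from the posterior;
6. **locates shift points** on the net-rate, cumulative-range, and
   sympatry curves by BIC changepoint search, matches them into triples,
   and tests their temporal coincidence by randomization (p_dist);
7. **runs the directionality tests** around each shift: the area test
   (gap between cumulative total and clade curves per unit time,
   after/before, as a %), the slope test (OLS of average range size on
   time after the shift), the one-sided Mann-Whitney test for a net-rate
   decrease, and exact binomial summaries across shifts and clades;
8. **fits the covariate birth-death model** λ(t) = λ₀·exp(γ_λ·s_t),
   μ(t) = μ₀·exp(γ_μ·s_t) by MCMC, flagging correlations whose 95%
   credible interval excludes zero.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Simulate a clade that undergoes a late-phase regime shift (extinction
rises while new species pack a shrinking residual range), then run the
full analysis:

```python
from paleorange import occurrences as occ, pipeline_cli as pc, synthetic_data as sd

occ_df, truth = sd.end_to_end_case("late-phase-specialisation", seed=3)
ds = occ.dataset_from_frame(occ_df, planar=True)   # synthetic km coordinates
config = pc.RunConfig(planar=True, seed=3, n_rand=499, candidate_bin_lengths=[2.5],
                      mcmc_iterations=6000, mcmc_burnin=1500, mcmc_thin=45,
                      covariate_iterations=20000, covariate_thin=20,
                      covariate_burnin_samples=100)
result = pc.analyze_clade(ds, config)
```

On this dataset (1,433 sampled species, 16,368 occurrences, 27 bins of
2.5 Myr) the run prints:

```
best trend model: generalized_logistic
 shift_mean_age  shift_pct_of_duration  p_dist  area_test  sympatry_increased  net_p     slope  slope_p
         36.384                 49.526   0.092    587.634                True    0.0 -2848.995      0.0
gamma_lambda -0.03 (-0.10, 0.03) sig False
gamma_mu     0.30 (0.23, 0.36) sig True
```

Reading it: range accumulation saturates (a Richards curve beats the
linear model); one matched shift triple sits at 36.4 Ma, halfway through
the clade's life; the per-bin degree of sympatry is higher after the
shift than before (`sympatry_increased`), and the area between the
cumulative total and clade curves per unit time is ~5.9× larger after the
shift (`area_test` 588); the net diversification rate is significantly
lower after the shift (`net_p` ≈ 0); the average species range shrinks
toward the present (slope −2,849 km²/Myr, p ≈ 0); and the covariate model
finds extinction positively and significantly linked to sympatry
(γ_μ = 0.30, 95% CI 0.23–0.36) — the generating process for this scenario
couples extinction to the geography exactly this way.

The same pipeline runs from the shell:

```bash
paleorange simulate --scenario late-phase-specialisation --seed 3 --out sim/
paleorange run --config run.yaml          # stages, seeds, paths in YAML
paleorange report --rows out/table2_style.csv
```

Outputs are plain CSV (per-shift rows, covariate posterior summaries,
binomial rollups) plus a JSON manifest with checksums, config echo and
seeds; reruns with the same seeds reproduce the artifacts byte for byte.

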