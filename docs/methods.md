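# Methods

`paleorange` reconstructs the geographic history of an extinct clade from
fossil occurrence records and asks whether its path to extinction shows the
signature of progressive specialisation: shrinking, increasingly
overlapping species ranges coinciding with a collapse in net
diversification, and speciation/extinction rates that respond to the
degree of sympatry. This note describes each model, the parameters that
matter, the synthetic data the test suite runs on, and the design choices
made where more than one reasonable option existed.

## Occurrence processing

Input tables follow the Paleobiology Database download convention: one row
per fossil find with species name, clade, paleocoordinates (degrees), and
a minimum/maximum locality age (Ma). Filters:

* **Open nomenclature** — species whose epithet carries a marker of
  uncertain assignment (`sp.`, `spp.`, `cf.`, `aff.`, `?`, `indet.`;
  configurable) are removed wholesale.
* **Rare species** — an optional minimum total occurrence count
  (`k_min_occurrences`; 1 = no filter, 10 = the robustness variant that
  drops rarely sampled species).
* **Stratigraphic continuity** — after binning, species (and genera)
  whose occupied-bin sequence has a gap longer than `max_gap_bins`
  (default 0, i.e. strictly continuous) are removed. "Continuity" has no
  unique definition for binned data; the gap rule makes the choice
  explicit and loggable.

Time bins are equal-length, clade-specific, half-open toward the present
(an age on an interior edge belongs to the younger bin; the oldest bin is
closed). The bin length is the shortest candidate (default candidates
1, 2, 2.5, 5, 10 Myr) for which every bin spanned by the record keeps at
least three species with at least three occurrences each — three distinct
points being the minimum for a convex-hull range estimate. If no candidate
satisfies the rule the least-violating one is used and flagged in the
provenance log. Occurrences map to bins by their age-interval midpoint by
default; a seeded uniform random draw from [min_ma, max_ma] is available
for sensitivity analysis.

## Range geometry

A species' per-bin range size is the area of the minimum convex polygon
(MCP, the extent of occurrence) of its occurrences in that bin, in km².
Coordinates are first projected to an equal-area plane chosen from the
point set's extent: Lambert azimuthal equal-area (longitudinal extent
< 180°, centred on the centroid), Mollweide (≥ 180° within ±60° latitude),
or Albers equal-area conic (≥ 180° reaching beyond ±60°). The projections
use spherical formulas on the authalic Earth radius (6371.0072 km), so
equal-area holds exactly on the sphere; tests verify < 0.5% distortion of
a 1° cell against the spherical-excess area. Point sets straddling the
antimeridian of their centroid are split there, projected separately, and
their part areas summed. Collinear point sets score area 0 and are flagged
degenerate; degenerate species-bins are excluded from totals and averages.

The clade-level range of a bin is the area of the geometric union of the
species MCPs, computed on a single clade-wide projection per bin so the
polygons are co-registered. Per-species areas use per-species projections;
the sub-percent discrepancy between the two planes is accepted, and the
union is capped at the sum of parts so the total ≥ clade invariant can
never be violated by projection round-off. Synthetic planar data (already
in km) bypass cartography entirely.

No land-mask clipping is applied: removing land from marine MCPs requires
digitized paleogeographic maps, an external resource. MCPs of marine taxa
are therefore somewhat inflated; this is a known, documented deviation.

## Range curves and the degree of sympatry

Per bin: *total* range = Σ species MCP areas; *clade* range = union area;
*average* range = total / richness. Accumulating total and clade ranges
over consecutive bins (oldest → youngest) gives the total and clade range
curves. The per-bin ratio total/clade is the **degree of sympatry**: 1
when ranges are pairwise disjoint, equal to richness when they coincide.
The average range curve uses per-bin totals, not the cumulative curve
(the cumulative variant conflates standing diversity with history; it is
available behind a flag).

## Trend models for the cumulative total range

Three Gaussian maximum-likelihood models are compared by AICc on the
cumulative total range versus time since clade origin: linear
(`a + b·t`), a 3-parameter logistic, and the 4-parameter Richards
(generalized logistic, nesting the logistic at shape ν = 1). Curves are
normalized to [0, 1] by their maximum before fitting so likelihoods are
comparable across clades of wildly different areal scales; raw-scale
fitting is a flag. Nonlinear fits use ten seeded multi-starts of
Levenberg–Marquardt. Saturating winners (logistic/Richards) indicate that
range accumulation slows toward the present. Residuals are treated as
iid; autocorrelation along the cumulative curve is a known limitation.

## Shift points and coincidence

A shift point is a statistically supported change in a curve's behaviour,
found by exhaustive breakpoint placement (series up to 80 points; seeded
cross-entropy search above: population 200, elite fraction 0.1, 50
iterations) and selected by a modified BIC. Two segment families are
used:

* **continuous piecewise-linear** (hinge regression) for the cumulative
  total range and sympatry curves — these are trending curves, so trend
  changes are the signal;
* **piecewise-constant means** for the net diversification rate — rate
  series shift in level, the same family birth-death shift models use.
  (A continuous hinge model systematically misses level shifts between
  two flat regimes; this was verified on synthetic regime-shift clades.)

Each breakpoint is charged 3·log n in the BIC: its location is optimized
over ~n candidate positions, which behaves like more than one ordinary
parameter under model search. With the ordinary 2·log n charge the
false-positive rate on pure-trend noise was ~15%; the 3·log n charge
brings it to ≤ 10% (calibrated over 200 seeded replicates at σ = 10% of
signal) while leaving localization of genuine breaks intact (≥ 90/100
within two grid steps). Segments need at least 3 points.

Shifts from the three curves (net rate, cumulative total range, sympatry;
the clade-range curve can be substituted for sympatry by config) are
matched into triples by greedy nearest-age assembly followed by a
single-swap hill-climb, so the matching is locally optimal in total
within-triple age distance. Temporal coincidence of a triple is tested by
randomization: two ages drawn from the curve bin midpoints and one from
the 1-Myr rate grid, 9,999 times by default, with the add-one correction
p = (1 + #{random mean pairwise distance ≤ observed}) / (n_rand + 1).

## Preservation and lineage times

Fossil preservation is a homogeneous Poisson process with rate `q`
(occurrences per lineage per Myr) — a deliberate simplification of
non-homogeneous ("hump-shaped") preservation models; downstream statistics
consume only the origination/extinction times, so the simplification is
localized. True origination (ts) and extinction (te) ages of each species
are sampled by Metropolis-within-Gibbs: elementwise sliding-window
proposals on every ts (bounded below by the oldest find) and te (bounded
by 0 and the youngest find), a multiplier proposal on `q` (exponential
prior, mean 1), a weak exponential prior on lineage duration (rate
0.05/Myr) standing in for a constant-rate birth-death duration prior, and
conditioning on each lineage being sampled at least once. The posterior
gap between ts and the oldest find shrinks as 1/q, as it must.

## Rates through time

For each posterior (ts, te) draw and each 1-Myr cell, speciation rate =
originations in the cell / lineage-Myr of exposure in the cell (extinction
likewise); net = difference; summaries are means and 2.5/97.5 percentiles
across draws. Cells with under 2 lineage-Myr of exposure are masked: a
per-lineage rate estimated from less data is noise, and such cells occur
only at the clade's origin and terminal collapse, where they would
otherwise attract spurious shift points. This per-cell ratio estimator
replaces reversible-jump rate-shift machinery; shift detection happens
downstream on the net curve, preserving the analysis logic at desk scale.

## The sympatry covariate birth-death model

Speciation and extinction rates respond exponentially to the degree of
sympatry s_t (stepwise constant over bins, standardized to zero mean and
unit variance, so the baselines are the rates at mean sympatry):

    lambda(t) = lambda0 · exp(gamma_lambda · s_t)
    mu(t)     = mu0     · exp(gamma_mu     · s_t)

The log-likelihood is Σ log λ at birth times (all originations except the
clade's oldest) + Σ log μ at death times − Σ over 1-Myr cells of
exposure·(λ+μ), with exposure the exact lineage-Myr in the cell — so at
γ = 0 the expression reduces to the constant-rate closed form to machine
precision (asserted at 1e-10 in the tests). Lineage times entering the
model are posterior means by default. The sampler is Metropolis-Hastings:
multiplier proposals on the baselines (exponential priors, mean 1),
Gaussian random walks (sd 0.3) on the gammas (normal priors, sd 10),
one parameter per iteration. A correlation is significant when 0 lies
outside the 95% credible interval of its gamma. Default chain length is
50,000 iterations thinned by 50 with 200 samples of burn-in — a 1/20
scale-down of a 10⁶-iteration protocol at fixed thinning fraction; tests
use shorter chains still (20,000/20/100), which posterior-width checks
showed to be converged for the problem sizes involved. Whether the
covariate should be interpolated between bins rather than held stepwise
is unknowable from first principles; stepwise is implemented. A smoothed
(moving-average) covariate was evaluated and rejected: it flattens
exactly the excursions that carry the signal.

## Synthetic data

The generator grows a clade by continuous-time birth-death from one
ancestor. Each species carries a disc range on a planar km coordinate
system (MCPs of uniform samples from a disc converge to the disc, so the
geometric estimators are exercised honestly): children bud at an isotropic
Gaussian step from the parent, scaled down for small-ranged species
(specialists disperse less), with lognormally perturbed radii. Optional
mechanisms: a per-Myr specialisation rate shrinking descendant radii; a
contraction rate pulling new species toward the clade core (the shrinking
residual range of a decaying clade); an extinction-rate trend; an explicit
early/late regime shift (`phase_shift_time`) after which extinction is
multiplied by `late_mu_factor` and the specialisation/contraction clocks
start; and sympatry feedback (γ ≠ 0), where the rates respond to the
realized log sympatry ratio of the standing species, recomputed on a 1-Myr
lattice. Preservation is Poisson(q) per lineage with locations uniform in
the species' disc and symmetric age uncertainty; unsampled species are
dropped. Default conditioning accepts only clades that reach at least
`min_species` and go entirely extinct before `t_max` (rejection sampling,
capped); an unconditioned mode exists for process-level checks (pure-birth
growth against the Yule mean).

Baseline parameters describe a mid-sized extinct marine invertebrate
clade: λ0 = 0.4, μ0 = 0.35 per lineage-Myr (slightly supercritical, so
richness waxes before waning; conditioned acceptance ~3%), t_max = 60 Myr,
q = 3/Myr, lognormal radii (median 200 km, log-sd 0.7; right-skewed range
sizes), dispersal 300 km, age uncertainty ±0.5 Myr, ≥ 40 species.

Three canned scenarios drive the end-to-end calibrations:

* **null** — baseline constant-rate dynamics; coincident shift triples
  are false positives and their rate is checked against a 15% allowance.
* **late-phase-specialisation** — an explicit regime shift at 25 Myr:
  extinction triples (μ0 = 0.15 before), new species pack an exponentially
  shrinking residual range (contraction 0.12/Myr) with slowly shrinking
  radii (0.01... 0.02/Myr), q = 4, ≥ 60 species, t_max = 70. Smooth
  specialisation trends were tried first and rejected: the degree of
  sympatry is bounded by richness, so under smooth trends it peaks with
  richness and *declines* over the detected late phase — an explicit
  onset is what makes "sympatry rises after the shift" true of the
  generating process itself.
* **covariate-extinction** — extinction responds to realized sympatry
  with γ_μ = +2 while geographic contraction (0.035/Myr from origin)
  drives the sympatry trend; λ0 = 0.35, μ0 = 0.06, q = 4, ≥ 100 species.
  A pure feedback loop without the exogenous geographic driver was tried
  first and abandoned: self-regulation pins the per-lineage death rate at
  λ0 and leaves γ unidentifiable from a single clade. The low baseline μ0
  lets the covariate term dominate the demise, and the denser sampling
  gives the estimated per-bin sympatry series enough fidelity (its
  correlation with the true series is ~0.65–0.7) for the link test to
  have power.

What the generator does **not** emulate: plate tectonics and
paleogeography, facies- and substrate-dependent preservation,
non-homogeneous sampling through time, taxonomy (genera are synthetic
labels), and real range shapes. Passing calibrations therefore show the
pipeline recovers the *statistical* structure it assumes — not that real
occurrence data satisfy those assumptions.

## Test and calibration problem sizes

Module tests run at small n (tens of species, thousands of MCMC
iterations). Calibration suites use: 200 replicates for changepoint false
positives, 100 for localization, 50 per direction for covariate recovery
(150+ lineages each), 50 per scenario for end-to-end checks, and
20 replicates per group inside `scripts/acceptance.py` (which also
recomputes every printed-table summary count and the worked geometry
example). These sizes were chosen so the whole suite completes on a single
CPU in well under half an hour while leaving the binomial noise on each
calibrated proportion at a few percent.

## Known limitations

* Homogeneous preservation can bias ts/te where true sampling is strongly
  time-varying.
* The per-cell rate estimator has high variance in low-exposure cells
  (masked below 2 lineage-Myr) and no pooling across cells.
* Gaussian iid residuals on cumulative curves ignore autocorrelation;
  AICc comparisons remain interpretable as relative fit but the absolute
  likelihoods are optimistic.
* The area test's ratio is undefined when the pre-shift gap area is zero
  (reported as missing, never infinity).
* Sympatry is undefined in one-species bins (the ratio is pinned to 1);
  such bins are excluded from the post-shift sympatry classification.
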