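# Methods

## Scope and design

`eldersim` simulates the daily interaction between a fixed population of
older adults and a fixed stock of health facilities in discrete daily time
steps, tracking one state variable per agent — the health value
`H ∈ [0, 1]` — plus a visit log. There is no mortality, aging, migration,
capacity constraint, or agent-to-agent interaction: the model isolates the
feedback between *spatial accessibility* (who can reach which facility) and
*health maintenance* (what a visit does to `H`), which is the question the
intervention scenarios probe.

## The synthetic city

The generator replaces real GIS inputs with a seeded synthetic equivalent:

- **Region.** A 15.5 × 11.25 km rectangle (174.375 km², matching the ~174 km²
  footprint of a dense urban core) in a local planar km frame; no geodesy,
  because all behavioral radii are stated in km.
- **Density surface.** A mixture of 3 isotropic Gaussian kernels with seeded
  centres (inside the central 80% of the rectangle), spreads of 1.2–2.5 km,
  and normalized weights. Three kernels with km-scale spreads give the
  multi-centre clustering typical of an urban core without encoding any real
  coordinates.
- **Facilities and homes** are both sampled from the same surface
  (rejection sampling truncated to the rectangle), so facilities concentrate
  where people live — the qualitative core-clustering of real POI data. How
  the original 200 homes were placed beyond "randomly within the study area"
  is unknown; both density-weighted (default) and uniform placement are
  supported.
- **Distances.** Euclidean by default. The optional network mode snaps
  points to a perturbed grid graph (0.5 km spacing, Gaussian jitter, edges
  weighted by their euclidean length) and adds access/egress legs, which
  guarantees network ≥ euclidean for every pair. All decision rules depend
  only on the distance function, so the modes are interchangeable; euclidean
  is the test default because it is exact and fast.

What the generator does **not** emulate: real road topology and congestion,
land-use barriers (rivers, rail), the true joint distribution of where poor
or disabled residents live relative to facilities, and facility quality
heterogeneity. Passing tests therefore demonstrate the internal consistency
and calibration of the mechanism, not forecasts for any real city.

## Population initialization

Attribute shares (health 0.80/0.16/0.04, living 0.70/0.29/0.01, economic
0.69/0.26/0.05) are allocated *exactly* by largest-remainder rounding rather
than independent Bernoulli draws, so an `n = 200` population always contains
160/32/8, 140/58/2, and 138/52/10 agents per dimension. This makes
initialization reproducible and testable; only the seeded assignment of
attribute combinations to individuals varies. The three dimensions are
assigned independently — only marginal shares are known, and the plausible
real-world correlation between poor health, living alone, and low income is
deliberately not invented. Initial `H` is uniform within the agent's state
band (the within-band distribution is otherwise unspecified).

With `n = 200` the "alone" subgroup has 2 members and the "disabled"
subgroup 8, so their equity series are noisy; the experiment runner
averages Gini day-by-day across replicates for that reason, and any
configuration whose shares leave a subgroup empty fails fast with an error
naming the subgroup.

## Behavioral rules and their ambiguities

The daily decision is two-stage: first a demanded *type* from the
state-specific preference weights, then a facility of that type uniformly at
random within the activity radius. The alternative single-stage reading
(weight each facility by its type's weight) is rejected because it would
make the preference weights depend on the facility stock; the two-stage
form keeps them interpretable as demand shares. For the same reason the
50%-fallback searches only the demanded type — the agent keeps its need
rather than re-drawing.

Other resolved ambiguities, all keyed to determinism:

- Band boundaries are half-open (`0.3` and `0.7` belong to the upper band)
  so classification is a function.
- Outing probability, radius, and preference weights all key on the
  *current* state, re-derived from `H` at the start of each day.
- `liveAdjust` is a multiplicative within-pool weight `1 + liveAdjust` on
  education-host facilities (by default all prevention facilities and all
  comprehensive hubs host education). With a single-type candidate pool this
  redistributes choices among hosts but cannot change the type mix — which
  is why the education scenario's health effect flows almost entirely
  through its outing-probability increase.
- Fallback ties (equidistant nearest facilities) break by lowest facility
  id; coverage-gap siting ties break by lowest agent index.
- Travel time is not modeled; every visit completes the same day.

## Health dynamics

The daily update is multiplicative:
`H' = clip(H (1 − α_s − β − γ)(1 + δ), 0, 1)`. An additive-gain variant
`H(1 − α_s − β − γ) + Hδ` sits behind `HealthParams.gain_mode="additive"`;
the two differ only at second order (`~δ·(α+β+γ)·H ≈ 10⁻⁵`). The gain
applies only on the day of a visit. Decay uses the current state's rate, so
decline accelerates across downward band crossings; `H = 0` is absorbing,
and a trajectory with no visits follows the piecewise geometric closed form
`H₀(1 − r)^t` segment-by-segment (used as an exact oracle in tests, at
tolerance 1e-12).

With the baseline coefficients every net factor is below 1
(`(1 − 0.006)(1 + 0.003) < 1`), so the whole population declines and mean
health approaches the floor by day 500. Only a comprehensive-hub visit
(`δ = 0.05`) gives non-disabled agents a net factor above 1.

## The equity statistic

`G = Σ_{i<j} w_i w_j |x_i − x_j| / (2 Σ w_i x_i)` over three subgroup mean
health values, computed daily after burn-in, with subgroup membership fixed
by *initial* attributes and weights fixed to the census shares. Note the
normalization: summing *unordered* pairs makes `G` exactly half the
conventional ordered-pair population Gini. The statistic is implemented as
stated; the tests verify it against a brute-force pseudo-population oracle
(replicate group *i* in proportion `w_i`, evaluate the unordered-pair form
over individuals), to which it is identical by a grouping identity, and
verify scale invariance and the `[0, 1]` bound.

## Scenarios

S1's hubs are sited by greedy max-min: repeatedly place the next hub at the
agent home whose distance to the nearest existing-or-new facility is
largest. Agent homes are the candidate set — finite, demand-relevant, and
deterministic. Hubs match every demanded type, host education, and their
gain *replaces* (not adds to) the type gain. S4 combines scenarios by
taking the maximum of every shared scalar parameter and accumulating
facility additions; combination is associative and never mutates its
inputs.

**Sensitivity of the intervention ranking to the hub gain.** The hub
per-visit gain (0.05) is 17× the largest baseline gain and the only
coefficient that can outweigh natural decay. Under the defaults roughly one
visit in five in an S1 run lands on a hub, hub users recover toward
`H = 1`, and S1's day-500 mean-health gain (~0.4) dwarfs the transport
scenario's (~0.0007), giving the ranking S4 > S1 > S2 > S3 in every
replicate. If the hub gain is instead set on the same scale as the other
gains (0.005), the ranking becomes S4 > S2 > S1 > S3 — spatial access
dominates — and the test suite demonstrates exactly this contrast
(`test_efficacy_hierarchy_with_moderate_hub_gain` vs the default-parameter
hierarchy check). Conclusions about the relative worth of building hubs
versus improving transport therefore hinge on one poorly-constrained
coefficient, and should be read with that caveat.

## Experiment design and problem sizes

Replicate `r` of an experiment builds one world from seed `(base_seed, r)`
and runs every scenario on it with scenario-specific behavioral streams, so
scenario contrasts are within-replicate, paired comparisons (`delta_h` =
scenario minus baseline, same day, same replicate — identically 0 for S0).
Identity of the shared world is asserted by hashing the initial population.
All randomness flows through `numpy.random.SeedSequence`, so every output
is bit-reproducible from `(config, seed)`.

Defaults: 30 replicates per experiment and 100 trials per sensitivity grid
point, with 200 agents × 500 days per run (~0.25 s each). The test suite
exercises the same code paths at reduced sizes (e.g. 100 agents × 100 days,
8–30 replicates, 20 sensitivity trials per grid point) chosen so the full
suite completes in well under a minute while keeping Monte-Carlo error far
below the asserted effects.

## Known limitations

- No mortality or state-dependent dropout: long baseline runs converge to
  the `H = 0` floor, compressing late-run equity contrasts.
- Unlimited facility capacity: interventions can only help, never congest.
- Independent attribute dimensions understate real clustering of
  disadvantage, likely biasing equity effects toward zero.
- The education intervention is reduced to its two measurable behavioral
  channels (outing probability, host up-weighting); knowledge-conversion
  heterogeneity is out of scope.
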