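# Methods

## The analysis pipeline

### Diversity indices

All indices operate on one 50 µL well's worth of counts. Proportions are
counts over total counts; *H′* and *BH′* are in nats (natural log). *BH′*
replaces count proportions with biomass proportions, count × per-individual
biovolume (µm³), using the pool's nominal biovolumes (bacterium 1, ciliate
10⁴, filamentous cyanobacterium 10³, unicellular cyanobacterium 10, green
algae 10² each). Hill numbers use the closed-form limit exp(*H′*) inside a
1e-9 window of q = 1 rather than a numerical limit; ^qD is computed on
positive proportions only, so ^0D counts detected species. The default q grid
is 0–3 in steps of 0.1; its granularity matches the resolution at which the
predictability maximum is reported. The detection limit (default 1 individual
per 50 µL, configurable per species) is applied *before* any index, so
"richness" always means detected richness.

### Competitive stability Θ

Abundances are log₁₀; a species below its detection limit contributes x = 0
(the same value as a count of one — the floor of the measurable scale).
For source *i*, every outcome whose pair contains *i* contributes, for every
species, the squared displacement between the outcome's log abundance and the
source's initial log abundance; Θᵢ is the reciprocal of the total. The
self-pair is included: it is one of the n(n+1)/2 dispensed outcomes and
measures self-persistence under the same handling. Replicate wells of a pair
are collapsed first by the mean of their log vectors (the logarithmic mean,
the same convention used to summarise replicate wells in the tables);
`stability_table(..., replicate_aggregation="none")` instead lets every
replicate contribute its own term. D = 0 maps to Θ = +∞ as an explicit
sentinel; correlation and regression drop non-finite rows with a warning, and
D itself (always finite) is reported alongside so the inverse relationship
can be examined without the sentinel.

The log base only rescales every D by a common factor, so Θ *rankings* and
all correlations are base-invariant; base 10 is used because populations
span decades.

### Correlations and predictability scans

Pearson R with a two-sided p from the t distribution on n − 2 degrees of
freedom (the parametric small-n convention), via `scipy.stats`. Min–max
normalization to [0, 1] is provided for presentation; it is affine, so it
cannot change R — a property the tests assert numerically. All R² values
come from one-predictor OLS fits; the q-scan's explanatory variable is the
^qD of the *merged* (equal-volume pooled) pre-coalescence pair, which equals
the coalesced well's initial state, and its dependent variable is the
outcome's ^qD. Replicates are averaged on the dependent side by default
(`pool_replicates=True` pools them as separate points instead). Argmax ties
break toward the smaller q for determinism.

### Dominant-mode analysis

Features are log₁₀(channel biomass + 1), where the three default channels sum
count × biovolume over cyanobacteria, green algae, and the labeled bacterium
— a proxy for a plate reader's fluorescence, which scales with pigmented
biomass rather than cell count. PCA is column-centered and unscaled so that
loadings stay in comparable log units and explained fractions read as
contribution fractions. The fluctuation direction is the leading principal
axis of a replicate ensemble at the reference condition, sign-fixed so its
largest-magnitude entry is positive. Temperature responses are *mean
displacements* (perturbed-ensemble mean minus same-duration control mean).
The long-term change direction is the leading principal axis of the
endpoint ensemble, not its mean displacement: replicates drift both ways
along the constrained mode, so a mean would cancel exactly the signal of
interest, while the axis captures it regardless of sign. All alignments are
absolute cosines, since principal axes carry no orientation.

## The synthetic microcosm

### Model

Generalized Lotka–Volterra dynamics for counts n per 50 µL, integrated with
fixed-step RK4 (dt = 0.01 d, counts clamped at 0 after each step — small
enough for the rate scales here, fixed for cross-platform reproducibility):

- **Producers** grow logistically against a *shared biomass capacity*
  K = 4×10⁷ µm³ per well: the crowding term for producer *i* is
  Σⱼ c·vⱼnⱼ / K with vⱼ the per-individual biovolume, c = 1 within a guild
  (cyanobacteria: both cyanos; algae: both greens) and c = β = 1.03 across
  guilds. Competition through biomass — not counts — reflects what the
  producers actually contend for (light, CO₂) and makes species of very
  different cell size reach comparable equilibrium biomass at very different
  counts (~10⁴ filamentous cyanobacteria vs ~10⁶ unicellular ones). β > 1
  makes the guild *balance* a soft unstable axis while the guild *sum* stays
  pinned near K: the one-dimensional mode that the constraint analysis
  recovers, and the mechanism behind ensemble scatter toward
  cyanobacteria-only and algae-only endpoints in long closed runs.
- **The decomposer** grows at r_E × (producer biomass / K) × (1 − n_E/K_D):
  producer-supported (mutualistic) growth with its own saturation at
  K_D = 10⁷ cells.
- **The consumer** has no intrinsic growth; it gains
  Σ_prey a·y·n_prey × (1 − n_C/K_C) per capita from type-I (linear) predation
  on the bacterium (attack 10⁻³ d⁻¹ per predator, yield 5×10⁻⁴) and the
  unicellular cyanobacterium (10⁻⁴, 10⁻³). The factor (1 − n_C/K_C), with
  K_C = 2000, is interference competition among the large motile predators;
  without it, type-I predation on prey held far below their own capacity has
  no damping and serial dilution drives unbounded boom–bust cycles that
  extinguish the prey. Attack terms remain strictly linear in prey density.
- **Mortality**: 0.1 d⁻¹ for decomposer and consumer; producers lose
  individuals only through dilution.
- **Growth rates** (d⁻¹, at 23 °C): bacterium 1.2; cyanobacteria 0.70 and
  0.70; green algae 0.62 and 0.70. The 0.62 species persistently loses
  ~0.26 nat per transfer cycle and falls below detection over many months —
  the kind of slow single-species decline long-run serial cultures show.
- **Temperature** multiplies growth rates by max(0, 1 + s·(T − 23)) with
  s = +0.02/°C for cyanobacteria and −0.02/°C for green algae: warming tilts
  the producer balance along the shared-capacity axis. 23 °C is exactly
  neutral; the culturable range is bounded at [15, 40] °C.

All rates are synthetic constants. They were calibrated **once** — so that
all six species coexist through biweekly transfers on the experimental
timescale, predator and prey persist at realistic count scales, and the
guild axis is soft but not explosive — and then frozen; nothing is fitted to
any measured dataset, and no parameter moves between scenarios.

### Transfers, observation, sources

Serial transfer keeps a fraction 0.1 every 14 days. With demographic
sampling on (default), each species' surviving count is binomial(round(n),
0.1) — the exact distribution of individuals captured in the transferred
volume — so a species at count 3 goes extinct with probability 0.9³ = 0.729,
and the consumer (~10³ per well) feels real extinction risk while the
bacterium (~10⁶–10⁷) does not. Observation multiplies counts by lognormal
noise (σ = 0.2 natural-log units, median-unbiased) and zeroes anything below
the detection limit.

Source ecosystems draw 2–5 species from the pool with sizes stratified
across that range (a panel of 8 sources spans the richness gradient rather
than clustering), always include a producer, and include the bacterium
whenever the ciliate is drawn (a consumer without its main prey is dead on
arrival). Sources are equilibrated by three deterministic growth/dilution
cycles and used as end-of-cycle states.

The RNG is a single root `SeedSequence` per experiment with spawned
substreams per replicate and per stage, so replicate counts do not perturb
each other's draws and every run is bit-reproducible from one seed.

### The constraint-assay scenario

The dominant-mode assay runs a guild-balanced, consumer-free community
(bacterium + both cyanobacteria + one alga). With the ciliate present, its
predator–prey fluctuations dominate the bacterial channel and mask the
producer mode; the assay's object is the producer constraint, to which only
the cyanobacteria and algae channels contribute. The inoculum splits the
producer capacity equally between guilds (then within guilds), starting the
ensemble on the balanced ridge. Scenario sizes: 32 replicates; fluctuation
ensemble measured after 8 biweekly transfers; temperature shifts measured
7 days after a transfer at 23/25/28/33 °C with 8 replicate wells each;
long-term runs 39 transfers (~18 months), either closed (independent wells)
or fully merged (all wells pooled and redistributed at every transfer).
Endpoint dispersion is the RMS distance of ensemble endpoints from their
centroid in feature space.

## What the generator does and does not emulate

It emulates: the dispensing design and transfer protocol; functional-group
interaction structure (producer guild competition on a shared capacity,
producer-supported decomposer, keystone predation); realistic per-well count
scales spanning decades; demographic extinction at transfer;
detection-limited, multiplicative measurement noise; temperature-dependent
producer balance.

It does not emulate: evolution or physiological adaptation within runs;
spatial structure; resource dynamics beyond the implicit shared capacity;
instrument-specific measurement detail (channel cross-talk, counting error
models); or any particular measured community. Passing tests therefore show
that the *analysis* recovers known structure from data with these
properties — not that any real community has them.

## Numerical choices and degenerate inputs

Θ = +∞ on zero divergence is an explicit sentinel, excluded (with a warning)
from correlations. Min–max normalization refuses constant vectors.
Regressions on constant vectors return R² = 0 rather than NaN. Hill numbers
of an empty community are 0 by convention (and an error where an index
presupposes a non-empty well, as in *BH′*). `hill_prediction_scan` and
`richness_predictors` require ≥ 3 pairs; `fit_dominant_mode` requires ≥ 3
samples, ≥ 2 features and non-zero rank. The q = 1 window (1e-9) makes the
profile continuous to ~1e-4 across the switch, asserted by tests. Problem
sizes in the acceptance checks (20 campaigns of 8 sources × 4 replicates × 8
transfers; 32-replicate constraint ensembles) are the package's chosen study
sizes, matching the emulated design.

## Known limitations

- Pearson R at n = 8 sources is a noisy statistic; single campaigns vary
  widely (the acceptance check therefore reports a 20-campaign median).
- Θ depends on the detection-limit convention (x = 0); communities dominated
  by near-limit species compress toward the floor.
- The guild-competition asymmetry β is a minimal stand-in for whatever
  nonlinearity produces alternative producer states in real microcosms; its
  value sets the timescale of symmetry breaking and was chosen, not
  measured.
- The consumer's interference term caps predator density phenomenologically;
  a mechanistic treatment would model handling time or spatial refuges.
- `merge_counts` with very uneven mix fractions can push a parent's rare
  species below detection in the merged state; gamma richness is computed on
  the detected merged community, as a measurement would be.
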