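# ecocoalesce

Analysis pipeline for **microbial community coalescence** experiments — and a
synthetic serial-dilution microcosm generator to drive it — aimed at
researchers studying how ecosystem-level diversity relates to stability when
whole communities are mixed.

The experimental template is a small aquatic microcosm: six species spanning
three functional groups (four phototrophic producers — two cyanobacteria and
two green algae — one bacterial decomposer, one ciliate consumer) cultured in
50 µL wells and passaged every two weeks with a 1/10 dilution. Source
communities of 2–5 species are mixed pairwise in every combination (for 8
sources: 28 cross pairs + 8 self-pairs = 36 outcomes, 4 replicate wells
each), cultured for months, and asked: *which ecosystems keep their
composition, and what did we need to know beforehand to predict the outcome?*

## What it computes

**Diversity indices.** Species richness, the Shannon–Wiener index
*H′ = −Σᵢ pᵢ ln pᵢ*, its biomass-corrected variant *BH′* (proportions
replaced by relative biomass, count × per-individual biovolume), and Hill
numbers

> ^qD = (Σᵢ pᵢ^q)^{1/(1−q)},  with ^1D = exp(*H′*) as the q → 1 limit,

whose order q tunes sensitivity from presence/absence (q = 0, richness) to
dominance (large q; ^2D is the inverse Simpson concentration).

**Competitive stability.** For source *i* with pre-coalescence log-abundance
vector *x*_init and post-coalescence outcomes *j* (every pair containing *i*),

> Θᵢ = 1 / Σⱼ Σₖ (x_after,k,j − x_init,k,i)²,

with log₁₀ abundances and *x* = 0 for species below the detection limit. A
large Θ means the ecosystem's composition survived every mixture it entered.

**Predictability scans.** Simple-OLS R² of post-coalescence richness on the
smaller / larger / mean / merged (gamma) richness of each pair, and the
q-profile of R² when the merged pair's ^qD predicts the outcome's ^qD — the
location of its maximum tells whether species composition or species
abundance is the quantity that persists through coalescence.

**Constrained dynamics.** PCA of log fluorescence-like channel signals
(cyanobacteria / green algae / labeled bacterium) across replicate ensembles,
with |cos| alignment between the fluctuation axis, 7-day temperature-shift
responses (23→25/28/33 °C), and the long-term (18-month) drift axis — a
quantitative test of whether all three kinds of change share one
low-dimensional mode.

**Synthetic microcosm.** A generalized Lotka–Volterra model with a shared
producer biomass capacity (guild-structured competition), producer-supported
decomposer growth, type-I predation by the ciliate, biweekly binomial-thinning
transfers (demographic stochasticity, low-abundance extinction), and
detection-limited lognormal observation noise. See `docs/methods.md` for the
model, parameter meanings and calibration rationale.

## Worked example

The `analysis/` scripts run the full campaign as a narrative; each writes its
tables under `results/analysis/`:

```bash
python analysis/01_simulate_coalescence.py
python analysis/02_stability_correlations.py
python analysis/03_richness_predictors.py
python analysis/04_hill_qscan.py
python analysis/05_constraint_modes.py
```

Step 02 prints, for one seeded campaign (seed 42):

```
 richness vs theta: R = +0.85 (p = 0.008); vs 1/theta: R = -0.83 (p = 0.011)
  shannon vs theta: R = +0.37 (p = 0.374); vs 1/theta: R = -0.12 (p = 0.780)
 bshannon vs theta: R = +0.56 (p = 0.151); vs 1/theta: R = -0.43 (p = 0.290)
```

— ecosystems with more (and more biomass-even) species resist being
overwritten, while count-based *H′* is the weakest correlate, because it
discounts the large-bodied, low-count keystone predator. Step 03 finds the
merged (gamma) richness the best outcome predictor (R² = 1.00 here, vs 0.55
for the larger and 0.10 for the smaller parent), step 04 places the
predictability maximum at low q (composition is conserved; abundances are
flexible), and step 05 reports

```
  alignment T25: |cos| = 0.999
  alignment T28: |cos| = 0.995
  alignment T33: |cos| = 0.983
  alignment long_term: |cos| = 0.990
```

with a one-dimensional producer mode (leading PCA fraction 1.00) and a
merged-to-closed endpoint dispersion ratio of 0.01: steady-state fluctuation,
rapid temperature response and 18-month drift all move along the same
cyanobacteria-vs-algae axis, and only ensembles that are neither fully closed
nor fully merged retain between-replicate variety.

The same stages are available as subcommands of one CLI
(`ecocoalesce simulate | coalesce-experiment | diversity | stability | qscan |
dmh | run-all`); `ecocoalesce run-all --seed 42 --out results/full_study`
reproduces everything above plus a digest manifest in one call.

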