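"""Statistics of the pairwise coalescence experiment.

The experiment mixes ``n`` source ecosystems all-vs-all (including self-pairs,
``n(n+1)/2`` outcomes) and asks two questions after the mixed wells have been
serially transferred for months:

* how stable is each source ecosystem? — the competitive stability index
  ``Θ_i = 1 / D_i`` where ``D_i`` sums squared log10-abundance displacement of
  source *i*'s initial state across every post-coalescence outcome whose pair
  contains *i*;
* which pre-coalescence summary best predicts the outcome? — simple OLS R² of
  post-coalescence richness on the smaller / larger / mean / merged (gamma)
  richness of the pair, and the q-profile of R² when the Hill number ``^qD``
  of the merged pre-coalescence community predicts the outcome's ``^qD``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community import (
    CommunityState,
    LogAbundanceVector,
    SpeciesTable,
    log_transform,
    to_relative,
)
from .diversity import hill_number, merge_counts, species_richness

__all__ = [
    "CoalescenceDesign",
    "StabilityResult",
    "PredictionScan",
    "enumerate_pairs",
    "divergence",
    "stability_index",
    "aggregate_log_mean",
    "stability_table",
    "normalize_minmax",
    "correlate",
    "richness_predictors",
    "hill_prediction_scan",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class CoalescenceDesign:
    """All unordered source pairs, self-pairs included."""

    source_ids: tuple[str, ...]
    pairs: tuple[Pair, ...]
    replicates: int

    @property
    def n_sources(self) -> int:
        return len(self.source_ids)

    def pairs_containing(self, source_id: str) -> tuple[Pair, ...]:
        return tuple(p for p in self.pairs if source_id in p)


@dataclass(frozen=True)
class StabilityResult:
    ecosystem_id: str
    divergence: float  # squared log10 units
    theta: float  # 1/divergence; +inf for perfect persistence


@dataclass(frozen=True)
class PredictionScan:
    """Predictor label (or Hill order q) → coefficient of determination."""

    keys: tuple
    r_squared: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r_squared, dtype=float)
        object.__setattr__(self, "r_squared", r2)
        if len(self.keys) != r2.size:
            raise ValueError("keys and r_squared must have the same length")

    @property
    def argmax_key(self):
        # first occurrence wins -> ties break toward the smaller q / first label
        return self.keys[int(np.argmax(self.r_squared))]


def enumerate_pairs(n_sources: int, replicates: int = 4, ids: tuple[str, ...] | None = None) -> CoalescenceDesign:
    """All-vs-all unordered pairs of ``n`` sources, self-pairs included.

    For 8 sources this yields the 36 distinct outcomes (28 cross pairs plus
    the 8 self-mixes of the dispensing diagonal).
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if ids is None:
        ids = tuple(f"E{i}" for i in range(n_sources))
    elif len(ids) != n_sources:
        raise ValueError("ids must have n_sources entries")
    pairs = tuple((ids[i], ids[j]) for i in range(n_sources) for j in range(i, n_sources))
    return CoalescenceDesign(ids, pairs, replicates)


def divergence(init: LogAbundanceVector, after: list[LogAbundanceVector]) -> float:
    """D = Σ_j Σ_k (x_after,k,j − x_init,k)² over outcome vectors j, species k."""
    if not after:
        raise ValueError("need at least one post-coalescence vector")
    total = 0.0
    for vec in after:
        if vec.species_ids != init.species_ids:
            raise ValueError("log-abundance vectors are on different species axes")
        total += float(((vec.x - init.x) ** 2).sum())
    return total


def stability_index(d: float) -> float:
    """Θ = 1/D; +inf when D = 0 (the composition persisted exactly)."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    return math.inf if d == 0 else 1.0 / d


def aggregate_log_mean(states: list[CommunityState], species: SpeciesTable) -> LogAbundanceVector:
    """Replicate aggregation by the mean of log10 abundances (x = 0 when undetected)."""
    if not states:
        raise ValueError("no states to aggregate")
    xs = np.stack([log_transform(s, species).x for s in states])
    return LogAbundanceVector(xs.mean(axis=0), species.ids)


def stability_table(
    initial: dict[str, CommunityState],
    outcomes: dict[Pair, list[CommunityState]],
    species: SpeciesTable,
    replicate_aggregation: str = "log_mean",
) -> list[StabilityResult]:
    """Per-source divergence D_i and competitive stability Θ_i = 1/D_i.

    For each source *i*, every outcome whose pair contains *i* (the self-pair
    included) contributes one squared-displacement term per species.  With the
    default ``replicate_aggregation="log_mean"`` the replicate outcomes of a
    pair are collapsed to their logarithmic mean first, matching how replicate
    wells are summarised experimentally; ``"none"`` instead lets every
    replicate contribute its own term.
    """
    if replicate_aggregation not in ("log_mean", "none"):
        raise ValueError(f"unknown replicate_aggregation {replicate_aggregation!r}")
    results = []
    for eco_id, init_state in initial.items():
        init_x = log_transform(init_state, species)
        after: list[LogAbundanceVector] = []
        for pair, reps in outcomes.items():
            if eco_id not in pair:
                continue
            if replicate_aggregation == "log_mean":
                after.append(aggregate_log_mean(reps, species))
            else:
                after.extend(log_transform(r, species) for r in reps)
        if not after:
            raise ValueError(f"source {eco_id!r} appears in no outcome pair")
        d = divergence(init_x, after)
        results.append(StabilityResult(eco_id, d, stability_index(d)))
    return results


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Linear rescale to [0, 1]; infinities are dropped from the range with a warning."""
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < v.size:
        warnings.warn("non-finite values excluded from min-max range", stacklevel=2)
    if finite.size < 2 or finite.max() == finite.min():
        raise ValueError("need >= 2 distinct finite values to normalize")
    return (v - finite.min()) / (finite.max() - finite.min())


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson R with two-sided p from the t distribution on n − 2 df.

    Rows where either value is non-finite (e.g. Θ = +inf for a perfectly
    persistent source) are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < x.size:
        warnings.warn(f"dropping {x.size - keep.sum()} non-finite pairs", stacklevel=2)
    if keep.sum() < 3:
        raise ValueError("need at least 3 finite pairs to correlate")
    r, p = stats.pearsonr(x[keep], y[keep])
    return float(r), float(p)


def _simple_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R² of a one-predictor OLS fit; 0 when either variable is constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def _pair_outcome_value(reps, func, pool: bool):
    if pool:
        return [func(r) for r in reps]
    return [float(np.mean([func(r) for r in reps]))]


def richness_predictors(
    design: CoalescenceDesign,
    pre: dict[str, CommunityState],
    post: dict[Pair, list[CommunityState]],
    species: SpeciesTable,
    pool_replicates: bool = False,
) -> PredictionScan:
    """R² of post-coalescence richness on four pre-coalescence predictors.

    Predictors per pair (i, j): the smaller, larger and mean of the two
    source richnesses, and the merged (gamma) richness of the pooled pair.
    By default the replicate outcomes of a pair are averaged before the fit.
    """
    if len(design.pairs) < 3:
        raise ValueError("need at least 3 pairs to fit")
    rich = {e: species_richness(s, species) for e, s in pre.items()}
    xs: dict[str, list[float]] = {k: [] for k in ("smaller", "larger", "mean", "merged")}
    ys: list[float] = []
    for pair in design.pairs:
        i, j = pair
        reps = post[pair]
        y_vals = _pair_outcome_value(reps, lambda s: species_richness(s, species), pool_replicates)
        merged = merge_counts(pre[i], pre[j])
        for y in y_vals:
            xs["smaller"].append(min(rich[i], rich[j]))
            xs["larger"].append(max(rich[i], rich[j]))
            xs["mean"].append(0.5 * (rich[i] + rich[j]))
            xs["merged"].append(species_richness(merged, species))
            ys.append(y)
    y_arr = np.array(ys)
    keys = tuple(xs)
    r2 = np.array([_simple_r2(np.array(xs[k], dtype=float), y_arr) for k in keys])
    return PredictionScan(keys, r2)


def hill_prediction_scan(
    design: CoalescenceDesign,
    pre: dict[str, CommunityState],
    post: dict[Pair, list[CommunityState]],
    species: SpeciesTable,
    q_grid: np.ndarray,
    pool_replicates: bool = False,
) -> PredictionScan:
    """q-profile of R²: ``^qD`` of the merged pre-coalescence pair predicting
    the outcome's ``^qD``.

    A maximum at small q means species composition (presence/absence) is the
    conserved quantity through coalescence while abundances reshuffle; a
    maximum at large q would instead indicate dominance is what persists.
    Ties in the argmax break toward the smaller q.
    """
    if len(design.pairs) < 3:
        raise ValueError("need at least 3 pairs to fit")
    q = np.asarray(q_grid, dtype=float)
    if q.size and (np.any(q < 0) or np.any(np.diff(q) < 0)):
        raise ValueError("q_grid must be sorted ascending and non-negative")

    merged_profiles = {}
    for pair in design.pairs:
        i, j = pair
        merged_profiles[pair] = to_relative(merge_counts(pre[i], pre[j]))

    r2 = np.empty(q.size)
    for qi_idx, qi in enumerate(q):
        xs, ys = [], []
        for pair in design.pairs:
            x_val = hill_number(merged_profiles[pair], qi)
            y_vals = _pair_outcome_value(
                post[pair], lambda s: hill_number(to_relative(s), qi), pool_replicates
            )
            for y in y_vals:
                xs.append(x_val)
                ys.append(y)
        r2[qi_idx] = _simple_r2(np.array(xs), np.array(ys))
    return PredictionScan(tuple(q), r2)
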