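"""Diversity indices: richness, Shannon–Wiener H′, biomass-corrected BH′,
and Hill-number profiles.

Hill numbers ``^qD = (Σ p_i^q)^(1/(1-q))`` interpolate between
presence/absence sensitivity (q = 0, species richness) and dominance
sensitivity (large q); ``^1D`` is defined by the limit ``exp(H′)`` and
``^2D`` is the inverse Simpson concentration.  H′ and BH′ are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import AbundanceProfile, CommunityState, SpeciesTable, to_relative

__all__ = [
    "DiversityProfile",
    "species_richness",
    "shannon_index",
    "biomass_shannon",
    "hill_number",
    "hill_profile",
    "merge_counts",
    "default_q_grid",
]

#: window around q = 1 inside which the closed-form limit exp(H') is used
_Q1_WINDOW = 1e-9


@dataclass(frozen=True)
class DiversityProfile:
    """Hill numbers evaluated on a grid of orders q."""

    q_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "values", v)
        if q.shape != v.shape:
            raise ValueError("q_grid and values must have the same length")


def default_q_grid(start: float = 0.0, stop: float = 3.0, step: float = 0.1) -> np.ndarray:
    """q grid 0–3 in steps of 0.1 unless overridden."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def species_richness(state: CommunityState, species: SpeciesTable) -> int:
    """Number of species at or above their detection limit (^0D)."""
    counts = state.count_vector(species)
    return int(np.sum(counts >= species.detection_limits))


def shannon_index(profile: AbundanceProfile) -> float:
    """H' = -sum p_i ln p_i with 0 ln 0 := 0, in nats."""
    p = profile.p[profile.p > 0]
    return float(-(p * np.log(p)).sum())


def biomass_shannon(state: CommunityState, species: SpeciesTable) -> float:
    """Shannon index on relative biomass shares (count × biovolume).

    Weighting by per-individual biovolume counteracts H′'s underrepresentation
    of large-bodied, low-count species (e.g. a ciliate predator whose few
    individuals dominate the community's biomass).
    """
    counts = state.count_vector(species)
    detected = counts >= species.detection_limits
    biomass = np.where(detected, counts, 0.0) * species.biovolumes
    total = biomass.sum()
    if total <= 0:
        raise ValueError(f"empty ecosystem {state.ecosystem_id!r}: no detected species")
    return shannon_index(AbundanceProfile(biomass / total))


def hill_number(profile: AbundanceProfile, q: float) -> float:
    """Effective species number of order q.

    ``(Σ p_i^q)^(1/(1-q))`` away from q = 1; ``exp(H′)`` inside a 1e-9 window
    around q = 1 (the mathematical limit).  Zero-abundance entries are
    excluded, so q = 0 counts species with p_i > 0.
    """
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    p = profile.p[profile.p > 0]
    if p.size == 0:
        return 0.0
    if abs(q - 1.0) < _Q1_WINDOW:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def hill_profile(profile: AbundanceProfile, q_grid: np.ndarray) -> DiversityProfile:
    """Element-wise Hill numbers over an ascending q grid."""
    q = np.asarray(q_grid, dtype=float)
    if q.size and np.any(np.diff(q) < 0):
        raise ValueError("q_grid must be sorted ascending")
    return DiversityProfile(q, np.array([hill_number(profile, qi) for qi in q]))


def merge_counts(a: CommunityState, b: CommunityState, mix_fraction: float = 0.5) -> CommunityState:
    """Volume-weighted pooled community (gamma community of the pair).

    With the default equal-volume mix the result equals the initial state of
    the coalesced ecosystem; its richness is the gamma richness of the pair.
    """
    if not 0.0 <= mix_fraction <= 1.0:
        raise ValueError("mix_fraction must be in [0, 1]")
    if set(a.counts) != set(b.counts):
        raise ValueError("states must share one species axis")
    merged = {
        sid: mix_fraction * a.counts[sid] + (1.0 - mix_fraction) * b.counts[sid]
        for sid in a.counts
    }
    return CommunityState(
        counts=merged,
        ecosystem_id=f"{a.ecosystem_id}+{b.ecosystem_id}",
        replicate=a.replicate,
        transfer_index=a.transfer_index,
        day=a.day,
        temperature=a.temperature,
    )
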