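"""Synthetic serial-dilution microcosm generator.

Emulates a 6-species aquatic microcosm (four phototrophic producers, one
bacterial decomposer, one ciliate consumer) cultured in 50 µL wells and
passaged every two weeks with a 1/10 dilution.  Population dynamics are
generalized Lotka–Volterra:

* producers grow logistically against one shared carrying capacity ``K``
  (competition for a common resource such as CO₂), with cross-group
  competition between the cyanobacterial and green-algal guilds slightly
  stronger than within-guild competition, so the guild balance is a soft,
  slowly-deciding axis — the low-dimensional mode the constraint analysis
  recovers;
* the decomposer's growth is proportional to total producer abundance
  (mutualistic support) with its own saturation;
* the consumer feeds by linear (type-I) predation on the bacterium and the
  small unicellular cyanobacterium, damped by interference among predators;
* the decomposer and consumer carry a baseline mortality; producers lose
  individuals only through dilution.

Serial transfers optionally apply binomial thinning (an exact model of
pipetting a 1/10 volume of discrete individuals), which supplies demographic
stochasticity and low-abundance extinctions.  Observation applies lognormal
multiplicative noise and a hard detection threshold.

All default rates are documented synthetic constants — chosen once so that
all six species coexist through biweekly transfers at 23 °C — not fits to
any measured system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coalescence import CoalescenceDesign, enumerate_pairs
from .community import (
    CommunityState,
    FunctionalGroup,
    SpeciesTable,
    default_species_table,
)
from .diversity import merge_counts

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CoalescenceRun",
    "default_config",
    "default_initial_state",
    "grow",
    "serial_transfer",
    "run_experiment",
    "coalesce",
    "merge_all_replicates",
    "apply_temperature",
    "observe",
    "make_source_ecosystems",
    "run_coalescence_experiment",
    "run_branched_experiment",
    "run_temperature_response",
    "composition_robust_outcomes",
]

REFERENCE_TEMPERATURE = 23.0  # °C

# Producer guilds whose cross-competition exceeds within-guild competition.
_GUILDS = {"Cyano": ("CyanoA", "CyanoS"), "Alga": ("AlgaR", "AlgaC")}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic microcosm.

    Rates are day⁻¹, abundances individuals per 50 µL.  ``producer_capacity``
    is a shared biomass capacity (µm³ per 50 µL): producers crowd each other
    through count × biovolume, so species of very different cell size reach
    very different equilibrium counts but comparable biomass — the regime a
    fluorometer sees as a constant summed signal.  ``growth_rates`` are
    the intrinsic rates at the 23 °C reference; ``temperature_sensitivity``
    scales them linearly per °C away from the reference.  ``predation`` maps
    (predator, prey) to an (attack, yield) pair: per-capita prey loss is
    ``attack × n_predator`` and per-capita predator gain is
    ``attack × yield × n_prey``.
    """

    species: SpeciesTable = field(default_factory=default_species_table)
    growth_rates: dict[str, float] = field(default_factory=dict)
    mortality: dict[str, float] = field(default_factory=dict)
    producer_capacity: float = 4e7
    decomposer_capacity: float = 1e7
    consumer_capacity: float = 2e3
    cross_guild_competition: float = 1.1
    predation: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    temperature_sensitivity: dict[str, float] = field(default_factory=dict)
    transfer_period: float = 14.0
    dilution: float = 0.1
    n_transfers: int = 7
    n_replicates: int = 1
    temperature: float = 23.0
    observation_noise_sd: float = 0.2
    demographic_sampling: bool = True
    seed: int = 0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution < 1.0:
            raise ValueError("dilution must be in (0, 1)")
        if self.producer_capacity <= 0 or self.transfer_period <= 0 or self.dt <= 0:
            raise ValueError("capacities, transfer_period and dt must be positive")
        for sid, r in self.growth_rates.items():
            if not np.isfinite(r):
                raise ValueError(f"non-finite growth rate for {sid!r}")


def default_config(**overrides) -> SimulationConfig:
    """The frozen default parameterization of the 6-species microcosm.

    The two cyanobacteria and one green alga are competitively neutral
    (equal intrinsic rates); the crescent-shaped alga carries a rate deficit
    and declines over months, mirroring the gradual loss of one alga in
    long-run serial cultures.  The ciliate persists at around a thousand
    individuals per well, limited by its prey supply and by interference
    among predators.
    """
    base = dict(
        growth_rates={
            "Ecoli": 1.2,
            "Tetra": 0.0,  # the consumer grows only through predation
            "CyanoA": 0.70,
            "CyanoS": 0.70,
            "AlgaR": 0.62,
            "AlgaC": 0.70,
        },
        mortality={
            "Ecoli": 0.10,
            "Tetra": 0.10,
            "CyanoA": 0.0,
            "CyanoS": 0.0,
            "AlgaR": 0.0,
            "AlgaC": 0.0,
        },
        producer_capacity=4e7,
        decomposer_capacity=1e7,
        consumer_capacity=2e3,
        cross_guild_competition=1.03,
        predation={
            ("Tetra", "Ecoli"): (1e-3, 5e-4),
            ("Tetra", "CyanoS"): (1e-4, 1e-3),
        },
        temperature_sensitivity={
            "Ecoli": 0.0,
            "Tetra": 0.0,
            "CyanoA": 0.02,
            "CyanoS": 0.02,
            "AlgaR": -0.02,
            "AlgaC": -0.02,
        },
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class Trajectory:
    """Time-ordered states across transfers and replicates."""

    states: list[CommunityState]
    config: SimulationConfig

    def endpoints(self) -> list[CommunityState]:
        last = max(s.transfer_index for s in self.states)
        return [s for s in self.states if s.transfer_index == last]

    def at_transfer(self, transfer_index: int) -> list[CommunityState]:
        return [s for s in self.states if s.transfer_index == transfer_index]


# ---------------------------------------------------------------------------
# compiled parameter arrays and the gLV right-hand side


@dataclass(frozen=True)
class _Params:
    r: np.ndarray
    m: np.ndarray
    biovol: np.ndarray
    producer_mask: np.ndarray
    decomposer_mask: np.ndarray
    consumer_mask: np.ndarray
    comp: np.ndarray  # (S, S) producer competition weights
    attack: np.ndarray  # (S, S): attack[pred, prey]
    gain: np.ndarray  # (S, S): per-capita predator gain coefficient
    K_P: float
    K_D: float
    K_C: float


def _temperature_factor(config: SimulationConfig) -> np.ndarray:
    sens = np.array(
        [config.temperature_sensitivity.get(s, 0.0) for s in config.species.ids]
    )
    return np.maximum(0.0, 1.0 + sens * (config.temperature - REFERENCE_TEMPERATURE))


def _compile(config: SimulationConfig) -> _Params:
    sp = config.species
    ids = sp.ids
    S = len(ids)
    r = np.array([config.growth_rates.get(s, 0.0) for s in ids]) * _temperature_factor(config)
    m = np.array([config.mortality.get(s, 0.0) for s in ids])
    prod = sp.group_mask(FunctionalGroup.PRODUCER)
    dec = sp.group_mask(FunctionalGroup.DECOMPOSER)
    cons = sp.group_mask(FunctionalGroup.CONSUMER)

    guild_of = {}
    for guild, members in _GUILDS.items():
        for s in members:
            guild_of[s] = guild
    comp = np.zeros((S, S))
    for i, si in enumerate(ids):
        if not prod[i]:
            continue
        for j, sj in enumerate(ids):
            if not prod[j]:
                continue
            same = guild_of.get(si) == guild_of.get(sj)
            comp[i, j] = 1.0 if same else config.cross_guild_competition

    attack = np.zeros((S, S))
    gain = np.zeros((S, S))
    index = {s: k for k, s in enumerate(ids)}
    for (pred, prey), (a, y) in config.predation.items():
        if pred in index and prey in index:
            attack[index[pred], index[prey]] = a
            gain[index[pred], index[prey]] = a * y
    return _Params(r, m, sp.biovolumes, prod, dec, cons, comp, attack, gain,
                   config.producer_capacity, config.decomposer_capacity,
                   config.consumer_capacity)


def _rhs(N: np.ndarray, p: _Params) -> np.ndarray:
    """dN/dt for a batch of wells, N of shape (batch, S)."""
    growth = np.zeros_like(N)
    B = N * p.biovol  # biomass per species, µm³ per 50 µL
    # producers: logistic in biomass against the shared light/CO2 capacity,
    # with guild-weighted crowding
    crowding = B @ p.comp.T  # (batch, S); nonzero only in producer columns
    growth += p.producer_mask * p.r * (1.0 - crowding / p.K_P)
    # decomposer: supported proportionally to total producer biomass
    sumP = B @ p.producer_mask.astype(float)
    growth += (
        p.decomposer_mask
        * p.r
        * (sumP / p.K_P)[:, None]
        * (1.0 - N / p.K_D)
    )
    # consumer: type-I gains from its prey, damped by interference
    # competition among the large motile predators
    growth += p.consumer_mask * (N @ p.gain.T) * (1.0 - N / p.K_C)
    # predation losses on prey, baseline mortality on everyone
    loss = N @ p.attack
    return N * (growth - p.m - loss)


def _integrate(N: np.ndarray, params: _Params, duration: float, dt: float) -> np.ndarray:
    """Fixed-step RK4; counts clamped at zero after every step."""
    N = np.array(N, dtype=float)
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        k1 = _rhs(N, params)
        k2 = _rhs(np.maximum(N + 0.5 * dt * k1, 0.0), params)
        k3 = _rhs(np.maximum(N + 0.5 * dt * k2, 0.0), params)
        k4 = _rhs(np.maximum(N + dt * k3, 0.0), params)
        N = np.maximum(N + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    rem = duration - n_steps * dt
    if rem > 1e-12:
        k1 = _rhs(N, params)
        N = np.maximum(N + rem * k1, 0.0)
    return N


def _state_from_vector(template: CommunityState, vec: np.ndarray, species: SpeciesTable, **meta) -> CommunityState:
    counts = {sid: float(c) for sid, c in zip(species.ids, vec)}
    return template.with_counts(counts, **meta)


# ---------------------------------------------------------------------------
# public operations


def grow(state: CommunityState, config: SimulationConfig, duration: float) -> CommunityState:
    """Deterministic gLV integration of one well for ``duration`` days."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    vec = state.count_vector(config.species)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite state")
    out = _integrate(vec[None, :], _compile(config), duration, config.dt)[0]
    return _state_from_vector(state, out, config.species, day=state.day + duration)


def serial_transfer(
    state: CommunityState, config: SimulationConfig, rng: np.random.Generator | None = None
) -> CommunityState:
    """Dilute a well 1/10 (or ``config.dilution``) into fresh medium.

    With demographic sampling each species' surviving count is binomial with
    retention probability equal to the dilution — the exact distribution of
    individuals captured in the transferred volume — so low-count species can
    go extinct at transfer.
    """
    vec = state.count_vector(config.species)
    if config.demographic_sampling:
        if rng is None:
            raise ValueError("demographic sampling requires an rng")
        out = rng.binomial(np.round(vec).astype(np.int64), config.dilution).astype(float)
    else:
        out = vec * config.dilution
    return _state_from_vector(
        state, out, config.species, transfer_index=state.transfer_index + 1
    )


def _batch_transfer(N: np.ndarray, config: SimulationConfig, rng: np.random.Generator | None) -> np.ndarray:
    if config.demographic_sampling:
        return rng.binomial(np.round(N).astype(np.int64), config.dilution).astype(float)
    return N * config.dilution


def coalesce(a: CommunityState, b: CommunityState) -> CommunityState:
    """Equal-volume mixture: per-species mean of the two wells' concentrations."""
    return merge_counts(a, b, mix_fraction=0.5)


def merge_all_replicates(states: list[CommunityState]) -> CommunityState:
    """Complete mixing of replicate wells into one pooled concentration."""
    if not states:
        raise ValueError("no states to merge")
    axis = set(states[0].counts)
    if any(set(s.counts) != axis for s in states):
        raise ValueError("states must share one species axis")
    merged = {sid: float(np.mean([s.counts[sid] for s in states])) for sid in axis}
    return states[0].with_counts(merged, replicate=0)


def apply_temperature(config: SimulationConfig, temperature: float) -> SimulationConfig:
    """Config with growth rates rescaled for a new incubation temperature.

    Each species' rate is multiplied by ``max(0, 1 + s·(T − 23))`` at
    integration time; 23 °C is the identity.  Temperatures outside the
    culturable range [15, 40] °C are rejected.
    """
    if not 15.0 <= temperature <= 40.0:
        raise ValueError(f"temperature {temperature} °C outside [15, 40]")
    return replace(config, temperature=temperature)


def observe(
    state: CommunityState, config: SimulationConfig, rng: np.random.Generator | None = None
) -> CommunityState:
    """Detection-limited noisy measurement of a well.

    Counts are multiplied by lognormal(0, sd) noise (so the median observation
    equals the true count) and then thresholded at each species' detection
    limit; below-limit observations are recorded as 0.
    """
    if config.observation_noise_sd < 0:
        raise ValueError("observation_noise_sd must be >= 0")
    vec = state.count_vector(config.species)
    if config.observation_noise_sd > 0:
        if rng is None:
            raise ValueError("noisy observation requires an rng")
        vec = vec * rng.lognormal(0.0, config.observation_noise_sd, size=vec.shape)
    limits = config.species.detection_limits
    vec = np.where(vec >= limits, vec, 0.0)
    return _state_from_vector(state, vec, config.species)


def default_initial_state(config: SimulationConfig, include: tuple[str, ...] | None = None) -> CommunityState:
    """A plausible inoculum: producers share the capacity, the decomposer and
    consumer start near their typical persistent levels."""
    sp = config.species
    if include is None:
        include = sp.ids
    producers = [s for s in include if sp[s].functional_group is FunctionalGroup.PRODUCER]
    counts = {sid: 0.0 for sid in sp.ids}
    # split producer capacity equally between guilds, then within each guild,
    # so the inoculum starts on the guild-balanced ridge
    guilds: dict[str, list[str]] = {}
    for s in producers:
        g = next((name for name, members in _GUILDS.items() if s in members), s)
        guilds.setdefault(g, []).append(s)
    for members in guilds.values():
        for s in members:
            biomass = 0.9 * config.producer_capacity / (len(guilds) * len(members))
            counts[s] = biomass / sp[s].biovolume
    for s in include:
        if sp[s].functional_group is FunctionalGroup.DECOMPOSER:
            counts[s] = 0.6 * config.decomposer_capacity
        elif sp[s].functional_group is FunctionalGroup.CONSUMER:
            counts[s] = 500.0
    return CommunityState(counts=counts, ecosystem_id="inoculum", temperature=config.temperature)


def run_experiment(
    config: SimulationConfig, initial: CommunityState | None = None
) -> Trajectory:
    """Replicated serial-transfer chains: grow for a transfer period, dilute, repeat.

    Emits the initial state plus the end-of-growth (pre-dilution) state of
    every transfer for every replicate.  Each replicate draws from its own
    RNG substream derived from ``config.seed``, so trajectories are
    bit-reproducible and independent of the replicate count.
    """
    if initial is None:
        initial = default_initial_state(config)
    params = _compile(config)
    sp = config.species
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    states: list[CommunityState] = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(streams[rep])
        vec = initial.count_vector(sp)
        states.append(
            _state_from_vector(initial, vec, sp, replicate=rep, transfer_index=0, day=0.0,
                               temperature=config.temperature)
        )
        day = 0.0
        for t in range(1, config.n_transfers + 1):
            vec = _integrate(vec[None, :], params, config.transfer_period, config.dt)[0]
            day += config.transfer_period
            states.append(
                _state_from_vector(initial, vec, sp, replicate=rep, transfer_index=t,
                                   day=day, temperature=config.temperature)
            )
            if config.demographic_sampling:
                vec = rng.binomial(np.round(vec).astype(np.int64), config.dilution).astype(float)
            else:
                vec = vec * config.dilution
    return Trajectory(states, config)


# ---------------------------------------------------------------------------
# experiment-level drivers


def make_source_ecosystems(
    config: SimulationConfig,
    n_sources: int,
    rng: np.random.Generator,
    equilibration_transfers: int = 3,
) -> dict[str, CommunityState]:
    """Random source ecosystems of 2–5 species drawn from the 6-species pool.

    Every source contains at least one producer, and a source containing the
    consumer also contains at least one of its prey (otherwise the consumer
    would be a dead member by construction).  Sources are equilibrated by a
    few deterministic growth/dilution cycles and returned as end-of-cycle
    (pre-dilution) states.
    """
    if n_sources < 2:
        raise ValueError("need at least 2 source ecosystems")
    sp = config.species
    producers = set(sp.group_ids(FunctionalGroup.PRODUCER))
    prey_of_consumer = {prey for (pred, prey) in config.predation}

    # stratify sizes over the 2-5 range so every panel spans the richness
    # gradient, as the study's source ecosystems did
    sizes = [2 + (k % 4) for k in range(n_sources)]
    rng.shuffle(sizes)
    subsets: list[tuple[str, ...]] = []
    for size in sizes:
        while True:
            subset = tuple(sorted(rng.choice(sp.ids, size=size, replace=False)))
            if not producers & set(subset):
                continue
            if "Tetra" in subset and "Ecoli" not in subset:
                continue
            subsets.append(subset)
            break

    params = _compile(config)
    vecs = np.stack(
        [default_initial_state(config, include=s).count_vector(sp) for s in subsets]
    )
    for _ in range(equilibration_transfers):
        vecs = _integrate(vecs, params, config.transfer_period, config.dt)
        vecs = vecs * config.dilution
    vecs = _integrate(vecs, params, config.transfer_period, config.dt)

    return {
        f"E{i}": CommunityState(
            counts={sid: float(c) for sid, c in zip(sp.ids, vecs[i])},
            ecosystem_id=f"E{i}",
            temperature=config.temperature,
        )
        for i in range(n_sources)
    }


@dataclass
class CoalescenceRun:
    """Everything the coalescence analyses consume."""

    design: CoalescenceDesign
    sources: dict[str, CommunityState]  # true (noise-free) source states
    pre: dict[str, CommunityState]  # observed initial states
    post: dict[tuple[str, str], list[CommunityState]]  # observed outcomes per pair
    config: SimulationConfig


def run_coalescence_experiment(
    config: SimulationConfig,
    n_sources: int = 8,
    replicates: int = 4,
    n_transfers: int = 8,
    seed: int | None = None,
) -> CoalescenceRun:
    """All-vs-all pairwise coalescence followed by months of serial transfers.

    Sources are mixed equal-volume in every unordered combination (self-pairs
    included), dispensed into replicate wells, passaged ``n_transfers`` times
    and observed (noisily, detection-limited) at the end.  The observed
    initial source states are returned alongside so stability and prediction
    analyses see the same measurement channel for both time points.
    """
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    s_sources, s_obs_pre, s_dispense, s_run, s_obs_post = root.spawn(5)

    sources = make_source_ecosystems(config, n_sources, np.random.default_rng(s_sources))
    design = enumerate_pairs(n_sources, replicates, ids=tuple(sources))

    obs_rng = np.random.default_rng(s_obs_pre)
    pre = {e: observe(s, config, obs_rng) for e, s in sources.items()}

    sp = config.species
    # one well per (pair, replicate); dispensing applies demographic thinning
    wells = []
    for pair in design.pairs:
        mixed = coalesce(sources[pair[0]], sources[pair[1]]).count_vector(sp)
        for _ in range(replicates):
            wells.append(mixed)
    N = np.stack(wells)
    dispense_rng = np.random.default_rng(s_dispense)
    N = _batch_transfer(N, config, dispense_rng)

    params = _compile(config)
    run_rng = np.random.default_rng(s_run)
    for t in range(n_transfers):
        N = _integrate(N, params, config.transfer_period, config.dt)
        if t < n_transfers - 1:
            N = _batch_transfer(N, config, run_rng)

    post: dict[tuple[str, str], list[CommunityState]] = {}
    post_rng = np.random.default_rng(s_obs_post)
    k = 0
    for pair in design.pairs:
        outs = []
        for rep in range(replicates):
            st = CommunityState(
                counts={sid: float(c) for sid, c in zip(sp.ids, N[k])},
                ecosystem_id=f"{pair[0]}x{pair[1]}",
                replicate=rep,
                transfer_index=n_transfers,
                day=n_transfers * config.transfer_period,
                temperature=config.temperature,
            )
            outs.append(observe(st, config, post_rng))
            k += 1
        post[pair] = outs
    return CoalescenceRun(design, sources, pre, post, config)


def run_branched_experiment(
    config: SimulationConfig,
    initial: CommunityState,
    n_replicates: int,
    n_transfers: int,
    seed: int,
    merge_each_transfer: bool = False,
) -> Trajectory:
    """Branch one ecosystem into replicate wells and passage them for months.

    ``merge_each_transfer=False`` is the closed scenario: replicates evolve
    independently and drift apart.  ``True`` is the fully-open scenario: all
    wells are pooled at every transfer and redistributed, so between-replicate
    differences reset to redistribution noise each cycle.
    """
    sp = config.species
    params = _compile(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    N = np.tile(initial.count_vector(sp), (n_replicates, 1))
    N = _batch_transfer(N, config, rng)

    states: list[CommunityState] = []

    def emit(N, t):
        for rep in range(n_replicates):
            states.append(
                CommunityState(
                    counts={sid: float(c) for sid, c in zip(sp.ids, N[rep])},
                    ecosystem_id=initial.ecosystem_id,
                    replicate=rep,
                    transfer_index=t,
                    day=t * config.transfer_period,
                    temperature=config.temperature,
                )
            )

    for t in range(1, n_transfers + 1):
        N = _integrate(N, params, config.transfer_period, config.dt)
        emit(N, t)
        if merge_each_transfer:
            N = np.tile(N.mean(axis=0), (n_replicates, 1))
        N = _batch_transfer(N, config, rng)
    return Trajectory(states, config)


def run_temperature_response(
    config: SimulationConfig,
    initial: CommunityState,
    temperatures: tuple[float, ...] = (23.0, 25.0, 28.0, 33.0),
    days: float = 7.0,
    n_replicates: int = 8,
    seed: int = 0,
) -> dict[float, list[CommunityState]]:
    """Short-term temperature-shift assay.

    From a common end-of-cycle state, replicate wells are dispensed (with
    demographic thinning), incubated ``days`` days at each temperature, and
    returned per temperature.  The reference condition is the same-duration
    incubation at 23 °C, so displacements isolate the temperature effect.
    """
    sp = config.species
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: dict[float, list[CommunityState]] = {}
    for T in temperatures:
        cfg_T = apply_temperature(config, T)
        params = _compile(cfg_T)
        N = np.tile(initial.count_vector(sp), (n_replicates, 1))
        N = _batch_transfer(N, config, rng)
        N = _integrate(N, params, days, config.dt)
        out[T] = [
            CommunityState(
                counts={sid: float(c) for sid, c in zip(sp.ids, N[rep])},
                ecosystem_id=initial.ecosystem_id,
                replicate=rep,
                day=days,
                temperature=T,
            )
            for rep in range(n_replicates)
        ]
    return out


def composition_robust_outcomes(
    design: CoalescenceDesign,
    pre: dict[str, CommunityState],
    species: SpeciesTable,
    rng: np.random.Generator,
    sigma_log10: float = 0.6,
    replicates: int | None = None,
) -> dict[tuple[str, str], list[CommunityState]]:
    """Synthetic outcome regime: composition robust, abundances flexible.

    Each pair's outcome keeps exactly the merged pair's species set but
    rescales every species' abundance by an independent lognormal factor
    (``sigma_log10`` decades of spread).  This is the regime in which
    presence/absence information survives coalescence while population sizes
    do not — the low-q-predictability end of the spectrum.
    """
    if replicates is None:
        replicates = design.replicates
    post: dict[tuple[str, str], list[CommunityState]] = {}
    for pair in design.pairs:
        merged = merge_counts(pre[pair[0]], pre[pair[1]])
        vec = merged.count_vector(species)
        outs = []
        for rep in range(replicates):
            noisy = vec * 10.0 ** rng.normal(0.0, sigma_log10, size=vec.shape)
            # keep the species set intact: surviving species stay detectable
            noisy = np.where(vec >= species.detection_limits,
                             np.maximum(noisy, species.detection_limits), 0.0)
            outs.append(
                CommunityState(
                    counts={sid: float(c) for sid, c in zip(species.ids, noisy)},
                    ecosystem_id=f"{pair[0]}x{pair[1]}",
                    replicate=rep,
                )
            )
        post[pair] = outs
    return post
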