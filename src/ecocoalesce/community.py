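"""Core data types and I/O for microcosm community tables.

The experimental unit throughout the package is a 50 µL well of a synthetic
aquatic microcosm.  A :class:`CommunityState` records absolute abundances
(individuals per 50 µL) of each species in one well at one time point, and a
:class:`SpeciesTable` carries the per-species metadata (functional group,
biovolume, detection limit) that the diversity and stability analyses need.

Two transforms are used everywhere downstream:

* :func:`to_relative` — proportions ``p_i`` for the diversity indices;
* :func:`log_transform` — decadic log abundances with the convention that an
  undetected species has ``x = 0``, which is the scale on which community
  displacement (and hence the competitive stability index) is measured.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "Species",
    "SpeciesTable",
    "CommunityState",
    "AbundanceProfile",
    "LogAbundanceVector",
    "default_species_table",
    "read_community_table",
    "write_community_table",
    "states_to_frame",
    "to_relative",
    "log_transform",
]

TABLE_COLUMNS = [
    "ecosystem",
    "replicate",
    "transfer",
    "day",
    "temperature",
    "species",
    "count",
]


class FunctionalGroup(str, enum.Enum):
    PRODUCER = "producer"
    DECOMPOSER = "decomposer"
    CONSUMER = "consumer"


@dataclass(frozen=True)
class Species:
    """One species of the pool.

    ``biovolume`` (µm³ per individual) doubles as the per-individual biomass
    in the biomass-corrected Shannon index; ``detection_limit`` is the count
    per 50 µL below which the species is recorded as absent.
    """

    species_id: str
    name: str
    functional_group: FunctionalGroup
    biovolume: float
    detection_limit: float = 1.0

    def __post_init__(self) -> None:
        if self.biovolume <= 0:
            raise ValueError(f"biovolume must be positive, got {self.biovolume}")
        if self.detection_limit < 1:
            raise ValueError(
                f"detection_limit must be >= 1 individual, got {self.detection_limit}"
            )


@dataclass(frozen=True)
class SpeciesTable:
    """Ordered, immutable collection of the species pool."""

    species: tuple[Species, ...]

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate species_id in {ids}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.species_id for s in self.species)

    def __len__(self) -> int:
        return len(self.species)

    def __getitem__(self, species_id: str) -> Species:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.ids

    @property
    def biovolumes(self) -> np.ndarray:
        return np.array([s.biovolume for s in self.species], dtype=float)

    @property
    def detection_limits(self) -> np.ndarray:
        return np.array([s.detection_limit for s in self.species], dtype=float)

    def group_ids(self, group: FunctionalGroup) -> tuple[str, ...]:
        return tuple(s.species_id for s in self.species if s.functional_group is group)

    def group_mask(self, group: FunctionalGroup) -> np.ndarray:
        return np.array([s.functional_group is group for s in self.species])

    @classmethod
    def from_tsv(cls, path) -> "SpeciesTable":
        df = pd.read_csv(path, sep="\t")
        required = {"species_id", "name", "functional_group", "biovolume_um3"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"species table missing columns: {sorted(missing)}")
        rows = []
        for _, r in df.iterrows():
            rows.append(
                Species(
                    species_id=str(r["species_id"]),
                    name=str(r["name"]),
                    functional_group=FunctionalGroup(r["functional_group"]),
                    biovolume=float(r["biovolume_um3"]),
                    detection_limit=float(r.get("detection_limit", 1.0)),
                )
            )
        return cls(tuple(rows))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "species_id": [s.species_id for s in self.species],
                "name": [s.name for s in self.species],
                "functional_group": [s.functional_group.value for s in self.species],
                "biovolume_um3": [s.biovolume for s in self.species],
                "detection_limit": [s.detection_limit for s in self.species],
            }
        ).to_csv(path, sep="\t", index=False)


def default_species_table() -> SpeciesTable:
    """The six-species producer/decomposer/consumer pool of the study system.

    Approximate per-individual biovolumes (µm³): a rod-shaped enteric
    bacterium (1), a large swimming ciliate predator (10⁴), a filamentous and
    a unicellular cyanobacterium (10³ and 10), and two green algae (10² each).
    """
    P, D, C = FunctionalGroup.PRODUCER, FunctionalGroup.DECOMPOSER, FunctionalGroup.CONSUMER
    return SpeciesTable(
        (
            Species("Ecoli", "Escherichia coli", D, 1.0),
            Species("Tetra", "Tetrahymena thermophila", C, 1e4),
            Species("CyanoA", "Anabaenopsis circularis", P, 1e3),
            Species("CyanoS", "Synechocystis sp.", P, 10.0),
            Species("AlgaR", "Raphidocelis subcapitata", P, 1e2),
            Species("AlgaC", "Chlorella vulgaris", P, 1e2),
        )
    )


@dataclass
class CommunityState:
    """Absolute abundances in one 50 µL well at one observation.

    ``counts`` maps species_id to individuals per 50 µL; counts are reals
    because observation applies multiplicative noise (demographic sampling in
    the simulator yields integers).
    """

    counts: dict[str, float]
    ecosystem_id: str = ""
    replicate: int = 0
    transfer_index: int = 0
    day: float = 0.0
    temperature: float = 23.0

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if not math.isfinite(c) or c < 0:
                raise ValueError(f"count for {sp!r} must be finite and >= 0, got {c}")
        if self.replicate < 0 or self.transfer_index < 0:
            raise ValueError("replicate and transfer_index must be >= 0")

    def count_vector(self, species: SpeciesTable) -> np.ndarray:
        """Counts aligned to the species-table axis; absent species are 0."""
        unknown = set(self.counts) - set(species.ids)
        if unknown:
            raise KeyError(f"species not in pool: {sorted(unknown)}")
        return np.array([self.counts.get(sid, 0.0) for sid in species.ids], dtype=float)

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def with_counts(self, counts: dict[str, float], **meta) -> "CommunityState":
        return replace(self, counts=counts, **meta)


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundances p_i; sums to one."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.size and (np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12):
            raise ValueError("relative abundances must be >= 0 and sum to 1")


@dataclass(frozen=True)
class LogAbundanceVector:
    """Decadic log abundances on a fixed species axis.

    ``x_k = log10(count_k)`` for detected species and 0 otherwise, so a count
    of one individual and an undetected species both map to 0 — the boundary
    convention under which stability displacements are computed.
    """

    x: np.ndarray
    species_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.shape != (len(self.species_ids),):
            raise ValueError("x must have one entry per species")
        if np.any(x < 0):
            raise ValueError("log abundances below the detection convention (x >= 0)")


def to_relative(state: CommunityState) -> AbundanceProfile:
    """Proportion of individuals belonging to each species present in the state."""
    values = np.array(list(state.counts.values()), dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError(
            f"empty ecosystem {state.ecosystem_id!r}: all counts are zero"
        )
    return AbundanceProfile(values / total)


def log_transform(state: CommunityState, species: SpeciesTable) -> LogAbundanceVector:
    """log10 counts with x = 0 for species below their detection limit."""
    counts = state.count_vector(species)
    detected = counts >= species.detection_limits
    x = np.zeros(len(species))
    x[detected] = np.log10(counts[detected])
    # counts in [limit, 1) cannot occur because limits are >= 1
    return LogAbundanceVector(x, species.ids)


def states_to_frame(states: list[CommunityState], species: SpeciesTable) -> pd.DataFrame:
    """Long/tidy frame with one row per (state, species), zero-filled."""
    rows = []
    for st in states:
        vec = st.count_vector(species)
        for sid, c in zip(species.ids, vec):
            rows.append(
                (st.ecosystem_id, st.replicate, st.transfer_index, st.day, st.temperature, sid, c)
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_community_table(states: list[CommunityState], species: SpeciesTable, path, sep: str = "\t") -> None:
    states_to_frame(states, species).to_csv(path, sep=sep, index=False)


def read_community_table(path, species: SpeciesTable, sep: str | None = None) -> list[CommunityState]:
    """Read a tidy community table into one state per (ecosystem, replicate, transfer).

    Species of the pool absent from a group are imputed as count 0 so that all
    states share one species axis.  Unknown species or negative counts are
    hard errors naming the offending row.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"community table missing columns: {sorted(missing)}")

    known = set(species.ids)
    for idx, row in df.iterrows():
        sid = str(row["species"])
        if sid not in known:
            raise ValueError(f"row {idx}: unknown species {sid!r} not in species table")
        c = float(row["count"])
        if not math.isfinite(c) or c < 0:
            raise ValueError(f"row {idx}: invalid count {row['count']!r} for {sid!r}")

    states: list[CommunityState] = []
    for (eco, rep, tr), grp in df.groupby(["ecosystem", "replicate", "transfer"], sort=True):
        counts = {sid: 0.0 for sid in species.ids}
        for _, row in grp.iterrows():
            counts[str(row["species"])] = float(row["count"])
        states.append(
            CommunityState(
                counts=counts,
                ecosystem_id=str(eco),
                replicate=int(rep),
                transfer_index=int(tr),
                day=float(grp["day"].iloc[0]),
                temperature=float(grp["temperature"].iloc[0]),
            )
        )
    return states
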