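"""Dominant-mode analysis of community trajectories.

The dominant-mode hypothesis (DMH) holds that a living system's state changes
are confined to a low-dimensional subspace, and that three kinds of change —
steady-state fluctuation, rapid response to an environmental shift, and slow
long-term drift — share that subspace.  Here the state is a vector of log10
measurement channels (fluorescence-like sums over species groups), the
subspace is estimated by PCA, and alignment between change directions is
quantified by the absolute cosine of their angle (PCA axes carry no sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .community import CommunityState, SpeciesTable

__all__ = [
    "DominantModeReport",
    "default_channels",
    "feature_matrix",
    "fit_dominant_mode",
    "fluctuation_direction",
    "response_alignment",
    "effective_dimension",
]


def default_channels(species: SpeciesTable) -> dict[str, tuple[str, ...]]:
    """Three measurement channels: cyanobacteria, green algae, and the
    red-labeled bacterium — the groups a plate-reader fluorescence assay
    resolves.  Species absent from the pool are dropped from their channel."""
    channels = {
        "Cyano": ("CyanoA", "CyanoS"),
        "Alga": ("AlgaR", "AlgaC"),
        "Red": ("Ecoli",),
    }
    return {
        name: tuple(s for s in members if s in species)
        for name, members in channels.items()
    }


def feature_matrix(
    states: list[CommunityState],
    species: SpeciesTable,
    channels: dict[str, tuple[str, ...]] | None = None,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Samples × features matrix of log10(channel biomass + pseudocount).

    Each channel sums count × biovolume over its member species, emulating a
    fluorescence signal proportional to pigment-bearing biomass.  The
    pseudocount keeps extinct channels finite.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    if channels is None:
        channels = default_channels(species)
    for name, members in channels.items():
        if not members:
            raise ValueError(f"channel {name!r} maps to no species")
    rows = []
    for st in states:
        row = [
            np.log10(
                sum(st.counts.get(s, 0.0) * species[s].biovolume for s in members)
                + pseudocount
            )
            for members in channels.values()
        ]
        rows.append(row)
    return np.asarray(rows, dtype=float)


@dataclass
class DominantModeReport:
    """PCA decomposition plus the DMH alignment summaries."""

    loadings: np.ndarray  # components × features
    explained_fractions: np.ndarray  # descending, sums to 1
    scores: np.ndarray  # samples × components
    mean: np.ndarray  # feature-space column means
    fluctuation_direction: np.ndarray | None = None
    response_displacements: dict[str, np.ndarray] = field(default_factory=dict)
    alignment: dict[str, float] = field(default_factory=dict)

    def effective_dimension(self, threshold: float = 0.9) -> int:
        return effective_dimension(self.explained_fractions, threshold)


def fit_dominant_mode(matrix: np.ndarray) -> DominantModeReport:
    """Column-centered, unscaled PCA of a samples × features matrix.

    Unscaled so that loadings stay in comparable log10-abundance units and
    the explained fractions read as contribution fractions of real variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a matrix of >= 3 samples and >= 2 features")
    if np.allclose(X - X.mean(axis=0), 0.0):
        raise ValueError("matrix has rank 0 after centering")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    scores = pca.fit_transform(X)
    fractions = pca.explained_variance_ / pca.explained_variance_.sum()
    return DominantModeReport(
        loadings=pca.components_,
        explained_fractions=fractions,
        scores=scores,
        mean=pca.mean_,
    )


def fluctuation_direction(matrix: np.ndarray) -> np.ndarray:
    """Leading principal axis of a control (unperturbed replicate) cloud.

    Returned as a unit vector with the sign fixed so its largest-magnitude
    entry is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 control replicates")
    report = fit_dominant_mode(X)
    axis = report.loadings[0]
    axis = axis / np.linalg.norm(axis)
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def response_alignment(
    fluct_dir: np.ndarray, control_mean: np.ndarray, perturbed_mean: np.ndarray
) -> float:
    """|cos angle| between the fluctuation axis and a mean displacement.

    1 means the environmental response moves along the axis the system
    already fluctuates on; 0 means it leaves that subspace entirely.
    """
    d = np.asarray(perturbed_mean, dtype=float) - np.asarray(control_mean, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("zero displacement: no response to align")
    f = np.asarray(fluct_dir, dtype=float)
    return float(abs(f @ d) / (np.linalg.norm(f) * norm))


def effective_dimension(fractions: np.ndarray, threshold: float = 0.9) -> int:
    """Smallest number of components whose cumulative fraction reaches the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    f = np.asarray(fractions, dtype=float)
    cum = np.cumsum(f)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)
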