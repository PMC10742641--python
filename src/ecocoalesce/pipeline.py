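"""End-to-end studies: coalescence screen and constraint (dominant-mode) assay.

``run_full_study`` reproduces a complete synthetic campaign from one seed:

1. generate source ecosystems and run the all-vs-all coalescence experiment;
2. compute per-source divergence/Θ, the three diversity indices and their
   correlations with Θ;
3. the richness-predictor comparison and the Hill-number q-scan;
4. the constraint assay: replicate fluctuation cloud, 7-day temperature
   responses, 18-month closed and fully-merged branched runs, and the
   alignment summary between their change directions.

Every tabular output is a tidy CSV/TSV that round-trips through
:func:`ecocoalesce.community.read_community_table`; the manifest records the
config, seed and a digest of every file so a rerun can be verified
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coalescence import (
    correlate,
    hill_prediction_scan,
    normalize_minmax,
    richness_predictors,
    stability_table,
)
from .community import (
    CommunityState,
    SpeciesTable,
    states_to_frame,
    to_relative,
    write_community_table,
)
from .constraints import (
    effective_dimension,
    feature_matrix,
    fit_dominant_mode,
    fluctuation_direction,
    response_alignment,
)
from .diversity import biomass_shannon, default_q_grid, shannon_index, species_richness
from .simulate import (
    SimulationConfig,
    default_config,
    default_initial_state,
    run_branched_experiment,
    run_coalescence_experiment,
    run_experiment,
    run_temperature_response,
)

__all__ = [
    "CONSTRAINT_SCENARIO_SPECIES",
    "run_coalescence_study",
    "run_constraint_study",
    "run_full_study",
]

#: Composition of the constraint-assay community: producer-rich with both
#: guilds balanced and no ciliate, so the slow guild-exchange mode is the
#: only low-dimensional axis the channels see.
CONSTRAINT_SCENARIO_SPECIES = ("Ecoli", "CyanoA", "CyanoS", "AlgaC")

TEMPERATURE_SHIFTS = (23.0, 25.0, 28.0, 33.0)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["species"] = [s.species_id for s in config.species.species]
    d["predation"] = {f"{pred}->{prey}": v for (pred, prey), v in config.predation.items()}
    return d


def run_coalescence_study(
    config: SimulationConfig,
    seed: int,
    n_sources: int = 8,
    replicates: int = 4,
    n_transfers: int = 8,
    q_grid: np.ndarray | None = None,
    outdir: Path | None = None,
) -> dict:
    """Coalescence screen: stability, diversity correlations, predictor scans.

    Returns a result dict; when ``outdir`` is given, also writes sources.tsv,
    initial.tsv, final.tsv, stability.csv, correlations.csv and qscan.csv.
    """
    species = config.species
    if q_grid is None:
        q_grid = default_q_grid()
    run = run_coalescence_experiment(config, n_sources, replicates, n_transfers, seed=seed)

    stab = stability_table(run.pre, run.post, species)
    rows = []
    for res in stab:
        pre_state = run.pre[res.ecosystem_id]
        rows.append(
            {
                "ecosystem": res.ecosystem_id,
                "divergence": res.divergence,
                "theta": res.theta,
                "richness": species_richness(pre_state, species),
                "shannon": shannon_index(to_relative(pre_state)),
                "bshannon": biomass_shannon(pre_state, species),
            }
        )
    stability = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in ("theta", "richness", "shannon", "bshannon"):
            try:
                stability[f"{col}_norm"] = normalize_minmax(stability[col].to_numpy())
            except ValueError:
                stability[f"{col}_norm"] = np.nan

    correlations = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for index in ("richness", "shannon", "bshannon"):
            r_theta, p_theta = correlate(stability[index], stability["theta"])
            r_inv, p_inv = correlate(stability[index], stability["divergence"])
            correlations.append(
                {
                    "index": index,
                    "r_theta": r_theta,
                    "p_theta": p_theta,
                    "r_inverse_theta": r_inv,
                    "p_inverse_theta": p_inv,
                }
            )
    correlations = pd.DataFrame(correlations)

    predictors = richness_predictors(run.design, run.pre, run.post, species)
    qscan = hill_prediction_scan(run.design, run.pre, run.post, species, q_grid)

    result = {
        "run": run,
        "stability": stability,
        "correlations": correlations,
        "predictors": predictors,
        "qscan": qscan,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_community_table(list(run.sources.values()), species, outdir / "sources.tsv")
        write_community_table(list(run.pre.values()), species, outdir / "initial.tsv")
        final_states = [s for reps in run.post.values() for s in reps]
        write_community_table(final_states, species, outdir / "final.tsv")
        stability.to_csv(outdir / "stability.csv", index=False)
        correlations.to_csv(outdir / "correlations.csv", index=False)
        pd.DataFrame(
            {"predictor": list(predictors.keys), "r_squared": predictors.r_squared}
        ).to_csv(outdir / "predictors.csv", index=False)
        pd.DataFrame({"q": list(qscan.keys), "r_squared": qscan.r_squared}).to_csv(
            outdir / "qscan.csv", index=False
        )
    return result


def run_constraint_study(
    config: SimulationConfig,
    seed: int,
    n_replicates: int = 32,
    fluctuation_transfers: int = 8,
    long_term_transfers: int = 39,
    response_replicates: int = 8,
    outdir: Path | None = None,
) -> dict:
    """Constraint assay: do fluctuation, response and drift share one mode?

    Runs the producer-rich scenario community through (i) a branched
    fluctuation run, (ii) 7-day temperature shifts, (iii) long closed and
    fully-merged branched runs, then reports PCA fractions, the fluctuation
    axis, per-temperature response alignments, the long-term drift axis
    alignment, and the merged/closed endpoint dispersion ratio.
    """
    species = config.species
    root = np.random.SeedSequence(seed)
    s_fluct, s_closed, s_merged, s_resp = [int(s.generate_state(1)[0]) % 2**31 for s in root.spawn(4)]

    inoculum = default_initial_state(config, include=CONSTRAINT_SCENARIO_SPECIES)
    settle = dataclasses.replace(config, demographic_sampling=False, n_transfers=3, n_replicates=1)
    start = run_experiment(settle, inoculum).endpoints()[0]

    fluct = run_branched_experiment(config, start, n_replicates, fluctuation_transfers, seed=s_fluct)
    closed = run_branched_experiment(config, start, n_replicates, long_term_transfers, seed=s_closed)
    merged = run_branched_experiment(
        config, start, n_replicates, long_term_transfers, seed=s_merged, merge_each_transfer=True
    )
    response = run_temperature_response(
        config, start, TEMPERATURE_SHIFTS, days=7.0, n_replicates=response_replicates, seed=s_resp
    )

    F = feature_matrix(fluct.endpoints(), species)
    fluct_dir = fluctuation_direction(F)
    report = fit_dominant_mode(F)
    producer_report = fit_dominant_mode(F[:, :2])  # Cyano and Alga channels

    control_mean = feature_matrix(response[TEMPERATURE_SHIFTS[0]], species).mean(axis=0)
    alignments: dict[str, float] = {}
    displacements: dict[str, list[float]] = {}
    for T in TEMPERATURE_SHIFTS[1:]:
        perturbed_mean = feature_matrix(response[T], species).mean(axis=0)
        alignments[f"T{T:g}"] = response_alignment(fluct_dir, control_mean, perturbed_mean)
        displacements[f"T{T:g}"] = (perturbed_mean - control_mean).tolist()

    closed_F = feature_matrix(closed.endpoints(), species)
    drift_axis = fluctuation_direction(closed_F)
    alignments["long_term"] = float(abs(fluct_dir @ drift_axis))

    def dispersion(X: np.ndarray) -> float:
        return float(np.sqrt(((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()))

    merged_F = feature_matrix(merged.endpoints(), species)
    result = {
        "fluctuation_direction": fluct_dir.tolist(),
        "explained_fractions": report.explained_fractions.tolist(),
        "effective_dimension": report.effective_dimension(0.9),
        "producer_explained_fractions": producer_report.explained_fractions.tolist(),
        "producer_effective_dimension": producer_report.effective_dimension(0.9),
        "loadings": report.loadings.tolist(),
        "response_displacements": displacements,
        "alignment": alignments,
        "drift_axis": drift_axis.tolist(),
        "closed_dispersion": dispersion(closed_F),
        "merged_dispersion": dispersion(merged_F),
        "dispersion_ratio": dispersion(merged_F) / dispersion(closed_F),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "dmh_report.json", "w") as fh:
            json.dump({"schema_version": 1, **result}, fh, indent=2)
        frames = []
        for label, traj in (("fluctuation", fluct), ("closed", closed), ("merged", merged)):
            df = states_to_frame(traj.endpoints(), species)
            df.insert(0, "scenario", label)
            frames.append(df)
        for T, states in response.items():
            df = states_to_frame(states, species)
            df.insert(0, "scenario", f"response_T{T:g}")
            frames.append(df)
        pd.concat(frames).to_csv(outdir / "constraint_states.csv", index=False)
    return result


def run_full_study(
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: Path | str = "results/full_study",
    n_sources: int = 8,
    replicates: int = 4,
    n_transfers: int = 8,
    constraint_kwargs: dict | None = None,
) -> dict:
    """One command, one seed, the whole synthetic campaign, with a manifest."""
    if config is None:
        config = default_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(seed).spawn(2)
    coal_seed = int(child[0].generate_state(1)[0]) % 2**31
    cons_seed = int(child[1].generate_state(1)[0]) % 2**31

    coal = run_coalescence_study(
        config, coal_seed, n_sources, replicates, n_transfers, outdir=outdir
    )
    cons = run_constraint_study(
        config, cons_seed, outdir=outdir, **(constraint_kwargs or {})
    )

    files = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "tool": "ecocoalesce",
        "version": __version__,
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(),
        "config": _config_dict(config),
        "n_sources": n_sources,
        "replicates": replicates,
        "n_transfers": n_transfers,
        "outputs": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"coalescence": coal, "constraints": cons, "manifest": manifest}
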