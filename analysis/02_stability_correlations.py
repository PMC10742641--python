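"""Competitive stability Θ per source and its correlation with diversity.

Reads the observed initial/final tables from step 01, computes each source's
divergence D (summed squared log10 displacement across all outcomes involving
it) and Θ = 1/D, then correlates Θ — and its inverse — with three α-diversity
indices: species richness, the Shannon-Wiener index H′, and the
biomass-corrected BH′.

Outputs: results/analysis/{stability,correlations}.csv
"""

import warnings
from pathlib import Path

import pandas as pd

from ecocoalesce.coalescence import correlate, stability_table
from ecocoalesce.community import default_species_table, read_community_table, to_relative
from ecocoalesce.diversity import biomass_shannon, shannon_index, species_richness

OUT = Path("results/analysis")


def load_campaign(species):
    initial = {s.ecosystem_id: s for s in read_community_table(OUT / "initial.tsv", species)}
    post = {}
    for st in read_community_table(OUT / "final.tsv", species):
        i, _, j = st.ecosystem_id.partition("x")
        post.setdefault((i, j or i), []).append(st)
    return initial, post


def main() -> None:
    species = default_species_table()
    initial, post = load_campaign(species)

    rows = []
    for res in stability_table(initial, post, species):
        pre = initial[res.ecosystem_id]
        rows.append(
            {
                "ecosystem": res.ecosystem_id,
                "divergence": res.divergence,
                "theta": res.theta,
                "richness": species_richness(pre, species),
                "shannon": shannon_index(to_relative(pre)),
                "bshannon": biomass_shannon(pre, species),
            }
        )
    stability = pd.DataFrame(rows)
    stability.to_csv(OUT / "stability.csv", index=False)

    corr_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for index in ("richness", "shannon", "bshannon"):
            r, p = correlate(stability[index], stability["theta"])
            r_inv, p_inv = correlate(stability[index], stability["divergence"])
            corr_rows.append(
                {"index": index, "r_theta": r, "p_theta": p,
                 "r_inverse_theta": r_inv, "p_inverse_theta": p_inv}
            )
            print(f"{index:>9} vs theta: R = {r:+.2f} (p = {p:.3f}); "
                  f"vs 1/theta: R = {r_inv:+.2f} (p = {p_inv:.3f})")
    pd.DataFrame(corr_rows).to_csv(OUT / "correlations.csv", index=False)

    best = max(corr_rows, key=lambda row: row["r_theta"])
    print(f"strongest positive association with stability: {best['index']}")


if __name__ == "__main__":
    main()
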