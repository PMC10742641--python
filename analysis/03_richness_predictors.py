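"""Which pre-coalescence richness summary predicts the outcome's richness?

For every pair, the candidate predictors are the smaller, larger and mean
richness of the two parents and the merged (gamma) richness of the pooled
pair; each is regressed against the post-coalescence richness (simple OLS)
and compared by R².

Output: results/analysis/predictors.csv
"""

from pathlib import Path

import pandas as pd

from ecocoalesce.coalescence import enumerate_pairs, richness_predictors
from ecocoalesce.community import default_species_table

import importlib

step02 = importlib.import_module("02_stability_correlations")

OUT = Path("results/analysis")


def main() -> None:
    species = default_species_table()
    initial, post = step02.load_campaign(species)
    n_reps = max(len(v) for v in post.values())
    design = enumerate_pairs(len(initial), n_reps, ids=tuple(initial))

    scan = richness_predictors(design, initial, post, species)
    table = pd.DataFrame({"predictor": list(scan.keys), "r_squared": scan.r_squared})
    table.to_csv(OUT / "predictors.csv", index=False)

    for _, row in table.iterrows():
        print(f"  {row.predictor:>7}: R^2 = {row.r_squared:.3f}")
    print(f"best predictor of post-coalescence richness: {scan.argmax_key}")


if __name__ == "__main__":
    main()
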