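"""Community composition, alpha/beta diversity, and environmental ANOVA.

Reads the niche-filtered survey written by 01_simulate.py, summarizes
phylum-level composition by site and season, computes Shannon and Margalef
indices, embeds the Bray-Curtis matrix with NMDS, and tests site/season
structure with PERMANOVA and the environmental variables with one-way ANOVA.
"""

import argparse
from pathlib import Path

import pandas as pd

from planktonscape import data_io, diversity


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data/deterministic"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--permutations", type=int, default=999)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = data_io.read_otu_table(args.data / "otu.tsv")
    table.taxonomy = data_io.read_taxonomy(args.data / "taxonomy.tsv")
    meta = data_io.read_metadata(args.data / "metadata.csv", table).loc[table.sample_ids]
    env = data_io.read_env(args.data / "env.csv", table).loc[table.sample_ids]

    for by in ("site", "season"):
        comp = data_io.aggregate_composition(table, meta, rank="phylum", top_k=10,
                                             grouping=by)
        comp.to_csv(args.out / f"composition_by_{by}.tsv", sep="\t")
        lead = comp.drop(columns="Others").mean().idxmax()
        print(f"composition by {by}: leading phylum overall = {lead}")

    alpha = diversity.alpha_diversity(table)
    alpha.to_csv(args.out / "alpha_diversity.tsv", sep="\t", index=False)
    print(f"alpha diversity: mean H = {alpha['H'].mean():.3f}, "
          f"mean M = {alpha['M'].mean():.3f}")

    bc = diversity.bray_curtis_matrix(table)
    ordn = diversity.nmds(bc, k=2, seed=args.seed)
    coords = pd.DataFrame(ordn.coordinates, index=bc.labels, columns=["NMDS1", "NMDS2"])
    coords.to_csv(args.out / "nmds_coordinates.tsv", sep="\t")
    print(f"NMDS: stress-1 = {ordn.stress:.4f}")

    for by in ("site", "season"):
        res = diversity.permanova(bc, meta[by], n_perm=args.permutations, seed=args.seed)
        print(f"PERMANOVA by {by}: pseudo-F = {res.statistic:.2f}, p = {res.p_value:.4f}")
        for index in ("H", "M"):
            a = diversity.one_way_anova(alpha[index].to_numpy(), meta[by].to_numpy())
            print(f"  ANOVA of {index} by {by}: F = {a.statistic:.2f}, p = {a.p_value:.4f}")

    rows = []
    for var in data_io.ENV_VARIABLES:
        for by in ("site", "season"):
            a = diversity.one_way_anova(env[var].to_numpy(), meta[by].to_numpy())
            rows.append({"variable": var, "grouping": by, "F": a.statistic,
                         "p_value": a.p_value})
    anova = pd.DataFrame(rows)
    anova.to_csv(args.out / "env_anova.tsv", sep="\t", index=False)
    sig = anova[anova.p_value < 0.05]
    print(f"environmental ANOVA: {len(sig)}/{len(anova)} variable x grouping "
          f"combinations significant at 0.05")


if __name__ == "__main__":
    main()
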