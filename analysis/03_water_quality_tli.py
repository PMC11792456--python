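"""Trophic level index scoring and its regressions on environment and diversity.

Scores every sample and site with the five-parameter TLI (Chl a, TP, TN,
SD, COD_Mn weighted by squared correlation with Chl a), grades nutrient
status, and regresses TLI on each environmental variable and on the
diversity indices.
"""

import argparse
from pathlib import Path

from planktonscape import data_io, diversity, tli


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data/deterministic"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = data_io.read_otu_table(args.data / "otu.tsv")
    meta = data_io.read_metadata(args.data / "metadata.csv", table).loc[table.sample_ids]
    env = data_io.read_env(args.data / "env.csv", table).loc[table.sample_ids]

    weights = tli.compute_weights()
    print("TLI weights:", dict(zip(weights.parameters, weights.W.round(4))))

    per_sample = tli.tli_per_sample(env, weights)
    per_sample.to_csv(args.out / "tli_per_sample.tsv", sep="\t", index=False)
    per_site = tli.tli_per_site(env, meta, weights)
    per_site.to_csv(args.out / "tli_per_site.tsv", sep="\t")
    for site, row in per_site.iterrows():
        print(f"  {site}: TLI = {row['TLI']:.2f} ({row['status']})")

    reg_env = tli.tli_linear_regressions(per_sample["TLI"], env[data_io.ENV_VARIABLES])
    reg_env.to_csv(args.out / "tli_vs_environment.tsv", sep="\t")
    signs = reg_env["slope"].apply(lambda s: "+" if s > 0 else "-")
    print("TLI-environment slope signs:", signs.to_dict())

    alpha = diversity.alpha_diversity(table)
    reg_div = tli.tli_linear_regressions(per_sample["TLI"], alpha[["H", "M"]])
    reg_div.to_csv(args.out / "tli_vs_diversity.tsv", sep="\t")
    for idx, row in reg_div.iterrows():
        print(f"TLI vs {idx}: slope = {row['slope']:.3f}, r2 = {row['r2']:.3f}, "
              f"p = {row['p_value']:.3g}")


if __name__ == "__main__":
    main()
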