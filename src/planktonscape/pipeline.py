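"""End-to-end orchestration: run every analysis stage from one config.

Stage order mirrors the analysis narrative: composition -> diversity ->
environmental ANOVA -> distance decay -> Mantel -> DCA/RDA -> network ->
TLI -> assembly. A stage failure is recorded in the report and later,
independent stages still run. All numeric outputs are deterministic under
the config's seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assembly, data_io, diversity, network, ordination, spatial, tli
from .synthetic_data import SimulationParams, simulate_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_all", "load_config"]

ALL_STAGES = [
    "composition", "diversity", "env_anova", "decay", "mantel",
    "ordination", "network", "tli", "assembly",
]


@dataclass
class PipelineConfig:
    output_dir: str = "planktonscape_out"
    otu_path: str | None = None
    metadata_path: str | None = None
    env_path: str | None = None
    simulate: dict | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    n_permutations: int = 999
    top_k: int = 10
    rank: str = "phylum"
    network_min_abs_r: float = 0.6
    network_alpha: float = 0.05
    network_min_prevalence: float = 1 / 3
    network_min_mean_abund: float = 1e-4
    network_per: str = "site"
    null_iterations: int = 100
    rda_variables: list[str] = field(default_factory=lambda: ["TP", "SD", "TN", "NH4_N", "pH"])

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulate is None and self.otu_path is None:
            raise ValueError("config needs either input paths or a simulate block")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineReport:
    config: dict
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "config": self.config,
                "stages": self.stages,
                "failures": self.failures,
                "warnings": self.warnings,
            },
            indent=2,
            default=_jsonify,
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PipelineConfig(**doc)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        params = SimulationParams(**config.simulate)
        ds = simulate_dataset(params)
        return ds.table, ds.metadata, ds.env
    table = data_io.read_otu_table(config.otu_path)
    metadata = data_io.read_metadata(config.metadata_path, table)
    env = data_io.read_env(config.env_path, table) if config.env_path else None
    return table, metadata, env


def run_all(config: PipelineConfig, output_dir: str | Path | None = None) -> PipelineReport:
    """Execute every enabled stage; write tables under the output directory."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    report = PipelineReport(config=cfg, config_hash=cfg_hash, version=__version__)

    table, metadata, env = _load_inputs(config)
    metadata = metadata.loc[table.sample_ids]
    if env is not None:
        env = env.loc[table.sample_ids]

    bc = None  # shared across stages

    def stage(name):
        def deco(fn):
            if name in config.stages:
                try:
                    report.stages[name] = fn()
                except Exception as exc:  # keep independent stages running
                    report.failures[name] = {
                        "error": str(exc),
                        "traceback": traceback.format_exc(limit=3),
                    }
            return fn
        return deco

    @stage("composition")
    def _composition():
        summary = data_io.aggregate_composition(
            table, metadata, rank=config.rank, top_k=config.top_k, grouping="site"
        )
        summary.to_csv(out / "composition_by_site.tsv", sep="\t")
        by_season = data_io.aggregate_composition(
            table, metadata, rank=config.rank, top_k=config.top_k, grouping="season"
        )
        by_season.to_csv(out / "composition_by_season.tsv", sep="\t")
        return {"files": ["composition_by_site.tsv", "composition_by_season.tsv"],
                "top_taxa": list(summary.columns)}

    @stage("diversity")
    def _diversity():
        nonlocal bc
        alpha = diversity.alpha_diversity(table)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        bc = diversity.bray_curtis_matrix(table)
        ord_res = diversity.nmds(bc, k=2, seed=config.seed)
        coords = pd.DataFrame(ord_res.coordinates, index=bc.labels, columns=["NMDS1", "NMDS2"])
        coords.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        tests = {}
        for by in ("site", "season"):
            res = diversity.permanova(bc, metadata[by], n_perm=config.n_permutations,
                                      seed=config.seed)
            tests[by] = {"pseudo_F": res.statistic, "p_value": res.p_value}
        return {"nmds_stress": ord_res.stress, "permanova": tests,
                "mean_shannon": float(alpha["H"].mean()),
                "mean_margalef": float(alpha["M"].mean())}

    @stage("env_anova")
    def _env_anova():
        if env is None:
            raise ValueError("env table required for the ANOVA stage")
        rows = []
        for var in data_io.ENV_VARIABLES:
            for by in ("site", "season"):
                res = diversity.one_way_anova(env[var].to_numpy(), metadata[by].to_numpy())
                rows.append({"variable": var, "grouping": by, "F": res.statistic,
                             "p_value": res.p_value})
        df = pd.DataFrame(rows)
        df.to_csv(out / "env_anova.tsv", sep="\t", index=False)
        return {"n_tests": len(df),
                "significant": df.loc[df.p_value < 0.05, ["variable", "grouping"]]
                                 .to_dict("records")}

    @stage("decay")
    def _decay():
        nonlocal bc
        if bc is None:
            bc = diversity.bray_curtis_matrix(table)
        geo = spatial.haversine_matrix(metadata)
        fit_geo = spatial.distance_decay_fit(bc, geo, n_perm=config.n_permutations,
                                             seed=config.seed, predictor="geographic_km")
        result = {"geographic": dataclasses.asdict(fit_geo)}
        if env is not None:
            envd = spatial.env_distance_matrix(env, data_io.ENV_VARIABLES)
            fit_env = spatial.distance_decay_fit(bc, envd, n_perm=config.n_permutations,
                                                 seed=config.seed, predictor="environmental")
            result["environmental"] = dataclasses.asdict(fit_env)
        return result

    @stage("mantel")
    def _mantel():
        nonlocal bc
        if env is None:
            raise ValueError("env table required for the Mantel stage")
        if bc is None:
            bc = diversity.bray_curtis_matrix(table)
        rows = []
        for var in data_io.ENV_VARIABLES:
            envd = spatial.env_distance_matrix(env, [var])
            res = spatial.mantel_test(bc, envd, method="spearman",
                                      n_perm=config.n_permutations, seed=config.seed)
            rows.append({"variable": var, "r": res.r, "p_value": res.p_value})
        df = pd.DataFrame(rows)
        df.to_csv(out / "mantel_by_variable.tsv", sep="\t", index=False)
        return df.to_dict("records")

    @stage("ordination")
    def _ordination():
        if env is None:
            raise ValueError("env table required for the ordination stage")
        y = table.drop_empty_otus().counts.T
        dca = ordination.dca_gradient_length(y)
        result = {"dca_axis1_length": dca.axis1_length, "model_choice": dca.model_choice}
        if dca.model_choice != "linear":
            result["note"] = ("gradient length >= 3 SD; a unimodal method (CCA) is "
                              "recommended and RDA was not run")
            return result
        x = env[config.rda_variables]
        res = ordination.rda(y, x, sample_ids=table.sample_ids, otu_ids=table.otu_ids)
        overall = ordination.rda_permutation_test(y, x, scope="overall",
                                                  n_perm=config.n_permutations,
                                                  seed=config.seed)
        marginal = ordination.rda_permutation_test(y, x, scope="marginal",
                                                   n_perm=config.n_permutations,
                                                   seed=config.seed)
        scores = pd.DataFrame(res.site_scores[:, :2], index=table.sample_ids,
                              columns=["RDA1", "RDA2"])
        scores.to_csv(out / "rda_site_scores.tsv", sep="\t")
        res.biplot_scores.to_csv(out / "rda_biplot_scores.tsv", sep="\t")
        result.update({
            "axis_percent": res.axis_percent.tolist(),
            "constrained_proportion": res.constrained_proportion,
            "overall": {"F": overall.statistic, "p_value": overall.p_value},
            "marginal": [{"scope": m.scope, "F": m.statistic, "p_value": m.p_value}
                         for m in marginal],
        })
        return result

    @stage("network")
    def _network():
        groups = (metadata.groupby(config.network_per).groups
                  if config.network_per != "none" else {"all": metadata.index})
        topo_rows = []
        key_counts = {}
        for gname, sample_ids in groups.items():
            sub = table.select_samples(list(sample_ids))
            filtered = network.filter_otus_for_network(
                sub, config.network_min_prevalence, config.network_min_mean_abund
            )
            edges = network.correlation_edges(
                filtered, min_abs_r=config.network_min_abs_r, alpha=config.network_alpha
            )
            g = network.build_network(filtered, edges)
            if g.number_of_nodes() == 0:
                topo_rows.append({"group": gname, "n_nodes": 0, "n_edges": 0})
                key_counts[str(gname)] = 0
                continue
            partition = network.detect_modules(g, seed=config.seed)
            topo = network.topology_metrics(g, partition)
            roles = network.zi_pi(g, partition)
            for r in roles:
                g.nodes[r.otu_id].update(module=r.module_id, zi=r.zi, pi=r.pi, role=r.role)
            data_io.write_network(g, out / f"network_{gname}.graphml")
            keys = network.key_species(roles, filtered)
            keys.to_csv(out / f"key_species_{gname}.tsv", sep="\t", index=False)
            topo_rows.append({"group": gname, **dataclasses.asdict(topo)})
            key_counts[str(gname)] = len(keys)
        pd.DataFrame(topo_rows).to_csv(out / "network_topology.tsv", sep="\t", index=False)
        return {"topology": topo_rows, "key_species_counts": key_counts}

    @stage("tli")
    def _tli():
        if env is None:
            raise ValueError("env table required for the TLI stage")
        weights = tli.compute_weights()
        per_sample = tli.tli_per_sample(env, weights)
        per_sample.to_csv(out / "tli_per_sample.tsv", sep="\t", index=False)
        per_site = tli.tli_per_site(env, metadata, weights)
        per_site.to_csv(out / "tli_per_site.tsv", sep="\t")
        predictors = env[data_io.ENV_VARIABLES]
        reg_env = tli.tli_linear_regressions(per_sample["TLI"], predictors)
        reg_env.to_csv(out / "tli_vs_environment.tsv", sep="\t")
        alpha = diversity.alpha_diversity(table)
        reg_div = tli.tli_linear_regressions(per_sample["TLI"], alpha[["H", "M"]])
        reg_div.to_csv(out / "tli_vs_diversity.tsv", sep="\t")
        return {
            "per_site": per_site["TLI"].round(2).to_dict(),
            "status": per_site["status"].to_dict(),
            "env_slopes": reg_env["slope"].to_dict(),
            "diversity_slopes": reg_div["slope"].to_dict(),
        }

    @stage("assembly")
    def _assembly():
        stats_all = assembly.occurrence_stats(table)
        fit = assembly.fit_ncm(stats_all)
        fit.per_otu.to_csv(out / "ncm_per_otu.tsv", sep="\t")
        nulls = assembly.null_communities(table, n_iter=config.null_iterations,
                                          seed=config.seed)
        mst_res = assembly.mst(table, nulls, seed=config.seed)
        per_site = {}
        for site, sample_ids in metadata.groupby("site").groups.items():
            sub = table.select_samples(list(sample_ids))
            try:
                site_fit = assembly.fit_ncm(assembly.occurrence_stats(sub))
                per_site[str(site)] = {"m": site_fit.m, "r2": site_fit.r2}
            except Exception as exc:
                per_site[str(site)] = {"error": str(exc)}
        return {
            "ncm": {"m": fit.m, "r2": fit.r2, "fraction_within": fit.fraction_within,
                    "formula": "f_hat = 1 - BetaCDF(d; NT*m*p, NT*m*(1-p))"},
            "ncm_per_site": per_site,
            "mst": {"mean": mst_res.mean, "classification": mst_res.classification,
                    "null": mst_res.null_algorithm, "n_iter": mst_res.n_iter,
                    "formula": "MST = D/E if D<=E else (1-D)/(1-E)"},
        }

    (out / "report.json").write_text(report.to_json())
    return report
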