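"""Readers, writers, and composition summaries for the tabular formats the pipeline touches.

The canonical on-disk OTU-table dialect is TSV (first column OTU id, remaining
columns samples, integer counts); the BIOM JSON flavor is supported read-only.
Metadata and environment tables are CSV/TSV with a header. Networks round-trip
through GraphML or GEXF via networkx.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_env",
    "aggregate_composition",
    "write_network",
    "read_network",
    "ENV_VARIABLES",
]

#: Environmental variables measured per sample, in canonical column order.
#: Units: WT degC; pH unitless; DO mg/L; SD m (Secchi depth); Chl_a mg/m3;
#: TN, TP, NH4_N, COD_Cr, COD_Mn mg/L.
ENV_VARIABLES = ["WT", "pH", "DO", "SD", "Chl_a", "TN", "TP", "NH4_N", "COD_Cr", "COD_Mn"]

METADATA_COLUMNS = ["sample_id", "site", "season", "replicate", "latitude", "longitude"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class OTUTable:
    """Integer count matrix (OTU x sample) with optional ranked taxonomy.

    Parameters
    ----------
    otu_ids : list of str
        Row identifiers; must be unique.
    sample_ids : list of str
        Column identifiers; must be unique. Case-sensitive, file order preserved.
    counts : ndarray of int, shape (n_otus, n_samples)
        Nonnegative read counts.
    taxonomy : dict, optional
        Map OTU id -> ranked lineage, e.g. {"OTU_1": {"phylum": "Ciliophora", ...}}.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, dict[str, str]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (OTU x sample)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        for name, ids in (("otu", self.otu_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} ids: {sorted(dupes)}")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise ValidationError(f"taxonomy keys not in otu_ids: {sorted(unknown)[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.library_sizes()
        if np.any(totals == 0):
            empty = [self.sample_ids[i] for i in np.where(totals == 0)[0]]
            raise ValidationError(f"samples with zero total reads: {empty}")
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def drop_empty_otus(self) -> "OTUTable":
        """Drop OTUs with zero counts in every sample."""
        keep = self.counts.sum(axis=1) > 0
        otu_ids = [o for o, k in zip(self.otu_ids, keep) if k]
        taxonomy = (
            {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        return OTUTable(
            otu_ids=otu_ids,
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep],
            taxonomy=taxonomy,
        )

    def select_samples(self, sample_ids: list[str]) -> "OTUTable":
        """Subset to the given samples (order as given), dropping all-zero OTUs' taxonomy is kept."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OTUTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            taxonomy=self.taxonomy,
        )


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        (dupes if x in seen else seen).add(x)
    return dupes


def read_otu_table(path: str | Path, format: str = "tsv") -> OTUTable:
    """Read an OTU count table from TSV or BIOM (JSON flavor).

    TSV layout: first column OTU id, remaining columns sample counts.
    Non-integer or negative cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom-json'")


def _read_otu_tsv(path: Path) -> OTUTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = _duplicates(header[1:])  # pandas would silently mangle these
    if dupes:
        raise ValidationError(f"duplicate sample columns in {path.name}: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    sample_ids = header[1:]
    otu_ids = df.iloc[:, 0].tolist()
    try:
        counts = df.iloc[:, 1:].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"non-integer count cell in {path.name}: {exc}") from exc
    return OTUTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts)


def _read_biom_json(path: Path) -> OTUTable:
    # BIOM 1.0 (JSON) layout: rows = observations (OTUs), columns = samples;
    # data either dense (list of row lists) or sparse [[row, col, value], ...].
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n, m = len(otu_ids), len(sample_ids)
    if doc.get("matrix_type") == "sparse":
        counts = np.zeros((n, m), dtype=np.int64)
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = int(v)
    else:
        counts = np.asarray(doc["data"], dtype=np.int64)
    taxonomy = None
    if doc["rows"] and doc["rows"][0].get("metadata") and "taxonomy" in (doc["rows"][0]["metadata"] or {}):
        ranks = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
        taxonomy = {}
        for r in doc["rows"]:
            lineage = (r.get("metadata") or {}).get("taxonomy", [])
            taxonomy[r["id"]] = dict(zip(ranks, lineage))
    return OTUTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts, taxonomy=taxonomy)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    """Write an OTU table as TSV (first column ``#OTU_ID``)."""
    df = table.to_dataframe()
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")


def write_taxonomy(table: OTUTable, path: str | Path) -> None:
    """Write the taxonomy map as a TSV (otu_id, rank columns)."""
    if table.taxonomy is None:
        raise ValidationError("table has no taxonomy")
    df = pd.DataFrame.from_dict(table.taxonomy, orient="index")
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", index_col="otu_id", dtype=str)
    return {otu: row.dropna().to_dict() for otu, row in df.iterrows()}


def _read_table_auto(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_metadata(path: str | Path, otu_table: OTUTable | None = None) -> pd.DataFrame:
    """Read sample metadata (sample_id, site, season, replicate, latitude, longitude).

    When ``otu_table`` is given the sample ids are cross-validated against it.
    """
    path = Path(path)
    df = _read_table_auto(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    dupes = _duplicates(df["sample_id"].tolist())
    if dupes:
        raise ValidationError(f"duplicate sample_ids in metadata: {sorted(dupes)}")
    if not df["latitude"].between(-90, 90).all():
        raise ValidationError("latitude out of range [-90, 90]")
    if not df["longitude"].between(-180, 180).all():
        raise ValidationError("longitude out of range [-180, 180]")
    df = df.set_index("sample_id", drop=False)
    if otu_table is not None:
        validate_sample_ids(df, otu_table, what="metadata")
    return df


def read_env(path: str | Path, otu_table: OTUTable | None = None) -> pd.DataFrame:
    """Read the per-sample environmental table (sample_id + measured variables)."""
    path = Path(path)
    df = _read_table_auto(path)
    if "sample_id" not in df.columns:
        raise ValidationError("env table missing required column: ['sample_id']")
    missing = [c for c in ENV_VARIABLES if c not in df.columns]
    if missing:
        raise ValidationError(f"env table missing required columns: {missing}")
    df = df.set_index("sample_id", drop=False)
    if otu_table is not None:
        validate_sample_ids(df, otu_table, what="env table")
    return df


def validate_sample_ids(df: pd.DataFrame, table: OTUTable, what: str = "table") -> None:
    """Require that ``df`` covers every OTU-table sample id."""
    have = set(df["sample_id"])
    need = set(table.sample_ids)
    if not need <= have:
        raise ValidationError(f"{what} is missing sample_ids: {sorted(need - have)}")


def aggregate_composition(
    table: OTUTable,
    metadata: pd.DataFrame,
    rank: str = "phylum",
    top_k: int = 10,
    grouping: str = "site",
) -> pd.DataFrame:
    """Per-group relative abundance of the globally top-k taxa at a rank, plus "Others".

    Taxa are ranked by overall mean relative abundance across all samples and the
    same top-k set is used for every group (one shared legend). Rows are groups,
    columns the top-k taxa then "Others"; each row sums to 1.
    """
    if table.taxonomy is None:
        raise ValidationError("OTU table has no taxonomy")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranks_present = set().union(*(set(v) for v in table.taxonomy.values()))
    if rank not in ranks_present:
        raise ValidationError(f"rank {rank!r} absent from taxonomy (have {sorted(ranks_present)})")
    if grouping not in metadata.columns:
        raise ValidationError(f"grouping column {grouping!r} absent from metadata")

    rel = table.relative_abundance()  # read-count proportions (documented choice)
    taxa = np.array([
        (table.taxonomy.get(o) or {}).get(rank, "Unclassified") for o in table.otu_ids
    ])
    rel_df = pd.DataFrame(rel, index=table.otu_ids, columns=table.sample_ids)
    by_taxon = rel_df.groupby(taxa).sum()  # taxon x sample, columns sum to 1

    overall = by_taxon.mean(axis=1).sort_values(ascending=False)
    top = list(overall.index[:top_k])

    groups = metadata.loc[table.sample_ids, grouping]
    out = {}
    for g, sample_ids in groups.groupby(groups).groups.items():
        mean_ra = by_taxon[list(sample_ids)].mean(axis=1)
        row = {t: float(mean_ra.get(t, 0.0)) for t in top}
        row["Others"] = float(1.0 - sum(row.values()))
        out[g] = row
    result = pd.DataFrame.from_dict(out, orient="index")
    result.index.name = grouping
    return result


def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or GEXF.

    Edge attributes carry the correlation and its sign; node attributes carry
    module id and Zi/Pi role annotations when present. An empty network is
    written as a valid empty graph with a warning.
    """
    if graph.number_of_nodes() == 0:
        warnings.warn("writing an empty network", stacklevel=2)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "gexf":
        nx.write_gexf(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}; expected 'graphml' or 'gexf'")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gexf":
        return nx.read_gexf(path)
    raise ValueError(f"unknown network format {format!r}")
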