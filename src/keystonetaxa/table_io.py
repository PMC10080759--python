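"""Tabular and graph I/O for the pipeline.

TSV (tab-separated) is the canonical dialect; comma-delimited files are
rejected rather than guessed, because silent delimiter sniffing corrupts
taxon names that contain commas.  Taxon IDs are opaque strings; any
genus/family roll-up goes through the taxonomy sidecar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "TraitTable",
    "TableFormatError",
    "read_count_table",
    "read_trait_table",
    "align_tables",
    "write_network",
]


class TableFormatError(ValueError):
    """A table violated the format contract (parse error, duplicate IDs...)."""


@dataclass
class CountTable:
    """Non-negative integer taxa-by-sample matrix with optional taxonomy.

    ``counts``: DataFrame, index = taxon IDs, columns = sample IDs.
    ``taxonomy``: optional DataFrame indexed by taxon with 'family'/'genus'.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate taxon IDs: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample IDs: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(c)
            raise TableFormatError(f"non-numeric count at {bad}")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise TableFormatError(
                f"non-integer count at taxon {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        self.counts = c.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class TraitTable:
    """Per-sample group label plus named continuous traits.

    ``data``: DataFrame indexed by sample ID with a 'group' column and one
    numeric column per trait.  Missing trait cells stay NaN (never zero).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample IDs: {dups}")
        if "group" not in self.data.columns:
            raise TableFormatError("trait table must carry a 'group' column")
        if self.data["group"].isna().any():
            missing = self.data.index[self.data["group"].isna()].tolist()
            raise TableFormatError(f"samples without a group label: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    @property
    def traits(self) -> pd.DataFrame:
        return self.data.drop(columns=["group"]).apply(pd.to_numeric)

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]


def _first_non_numeric(frame: pd.DataFrame) -> str:
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame.notna()
    if bad.any().any():
        j = bad.any(axis=0).idxmax()
        i = bad[j].idxmax()
        return f"taxon {i!r}, sample {j!r}"
    return "unknown cell"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        raise TableFormatError(
            f"{path}: looks comma-delimited; this reader accepts TSV only"
        )
    columns = header.rstrip("\n").split("\t")[1:]
    dups = {c for c in columns if columns.count(c) > 1}
    if dups:
        raise TableFormatError(f"{path}: duplicate sample columns: {sorted(dups)}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = None  # axis labels are layout, not data
    return frame


def read_count_table(
    path: str | Path, taxonomy_path: str | Path | None = None
) -> CountTable:
    """Read a TSV count table (taxon rows, sample columns), validating that
    every cell is a non-negative integer and that IDs are unique."""
    frame = _read_tsv(path)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().any().any():
        raise TableFormatError(f"{path}: non-numeric count at {_first_non_numeric(frame)}")
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = _read_tsv(taxonomy_path)
        taxonomy.index = taxonomy.index.astype(str)
    return CountTable(counts=coerced, taxonomy=taxonomy)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a TSV trait table (sample rows; 'group' column plus traits)."""
    frame = _read_tsv(path)
    frame.index = frame.index.astype(str)
    return TraitTable(data=frame)


def align_tables(
    counts: CountTable, traits: TraitTable
) -> tuple[CountTable, TraitTable, dict[str, list[str]]]:
    """Match samples between a count table and a trait table by ID.

    Row/column order is irrelevant; the intersection (in count-table order)
    is returned.  Samples present on one side only are warned about and
    listed in the mismatch report.
    """
    count_samples = counts.sample_ids
    trait_samples = set(traits.sample_ids)
    shared = [s for s in count_samples if s in trait_samples]
    report = {
        "counts_only": [s for s in count_samples if s not in trait_samples],
        "traits_only": [s for s in traits.sample_ids if s not in set(count_samples)],
    }
    if report["counts_only"] or report["traits_only"]:
        warnings.warn(
            f"sample mismatch between counts and traits: {report}", stacklevel=2
        )
    if not shared:
        raise TableFormatError("no samples shared between counts and traits")
    aligned_counts = CountTable(counts=counts.counts[shared], taxonomy=counts.taxonomy)
    aligned_traits = TraitTable(data=traits.data.loc[shared])
    return aligned_counts, aligned_traits, report


def write_network(
    network, directory: str | Path, fmt: str = "graphml", stem: str = "network"
) -> dict[str, Path]:
    """Export a network for external viewers (e.g. Cytoscape).

    Writes ``<stem>.graphml`` plus a TSV edge list (source, target,
    correlation, sign) and a TSV node table (taxon, module, k, Zi, Pi, role
    where available).  ``fmt`` currently supports only 'graphml'.
    """
    if fmt != "graphml":
        raise ValueError(f"unknown network format {fmt!r}; supported: 'graphml'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    graph: nx.Graph = network.graph if hasattr(network, "graph") else network
    export = nx.Graph()
    export.add_nodes_from(graph.nodes)

    edge_rows = []
    for u, v, attrs in graph.edges(data=True):
        r = float(attrs.get("r", np.nan))
        sign = "positive" if r >= 0 else "negative"
        export.add_edge(u, v, r=r, sign=sign)
        edge_rows.append({"source": u, "target": v, "correlation": r, "sign": sign})

    node_rows = []
    module_of = getattr(network, "module_of", None) or {}
    topology = getattr(network, "topology", None)
    for node in graph.nodes:
        row = {"taxon": node, "module": module_of.get(node, "")}
        if topology is not None and node in topology.index:
            for col in ("k", "Zi", "Pi", "role"):
                if col in topology.columns:
                    row[col] = topology.loc[node, col]
        node_rows.append(row)
        export.nodes[node]["module"] = str(row.get("module", ""))

    paths = {
        "graphml": directory / f"{stem}.graphml",
        "edges": directory / f"{stem}.edges.tsv",
        "nodes": directory / f"{stem}.nodes.tsv",
    }
    nx.write_graphml(export, paths["graphml"])
    pd.DataFrame(edge_rows, columns=["source", "target", "correlation", "sign"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    pd.DataFrame(node_rows).to_csv(paths["nodes"], sep="\t", index=False)
    return paths
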