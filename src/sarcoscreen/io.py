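"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .simulate import PlateSet
from .splicing import TranscriptModel

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_count_matrix",
    "write_count_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_junction_counts",
    "write_junction_counts",
    "write_gtf",
]

PLATE_COLUMNS = ["well", "row", "col", "role", "drug_id", "dose_uM", "signal"]


def read_plate_csv(path) -> PlateSet:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    df = df[PLATE_COLUMNS].copy()
    # control wells carry no drug: represent as None, not NaN
    df["drug_id"] = df["drug_id"].astype(object).where(df["drug_id"].notna(), None)
    return PlateSet(wells=df)


def write_plate_csv(plate: PlateSet, path) -> None:
    plate.wells.to_csv(path, index=False)


def read_count_matrix(path) -> pd.DataFrame:
    """Gene x sample TSV with gene IDs in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_edge_list(path) -> nx.Graph:
    """Undirected simple graph from a two-column TSV (node_a, node_b)."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    pd.DataFrame(sorted(graph.edges), columns=["node_a", "node_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_junction_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "sample_id", "inc_count", "exc_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction TSV missing columns: {sorted(missing)}")
    return df


def write_junction_counts(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Emit exon features, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene}"; transcript_id "{t.transcript}";'
            for start0, end0 in t.exons:
                fh.write(
                    f"{t.chrom}\tsarcoscreen\texon\t{start0 + 1}\t{end0}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
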