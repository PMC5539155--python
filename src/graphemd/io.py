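"""Readers and writers for the plain-text formats the pipeline exchanges.

Networks travel as two-column edge-list TSV (``gene_a<TAB>gene_b``; lines
starting with ``#`` are comments). Three-column files are treated as SIF
(``gene_a<TAB>relation<TAB>gene_b``), detected per line by column count;
``.graphml`` files are also accepted. Expression tables are TSV/CSV with
gene ids in the first column and sample ids in the header. Distance
matrices are CSV with sample ids as both header row and first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DistanceMatrix
from .markov import InvariantMeasure
from .network import GeneNetwork

__all__ = [
    "read_network",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "write_measures",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_labels",
    "write_labels",
    "write_clusters",
]


def read_network(path: str | Path) -> GeneNetwork:
    """Read an interaction network from edge-list TSV, SIF, or GraphML."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        import networkx as nx

        return GeneNetwork(nx.read_graphml(path))
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 2:
                a, b = cols
            elif len(cols) == 3:  # SIF: source relation target
                a, _, b = cols
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 (edge list) or 3 (SIF) "
                    f"tab-separated columns, found {len(cols)}"
                )
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            edges.append((a, b))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return GeneNetwork.from_edges(edges)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Edge-list TSV in the canonical (sorted) edge order."""
    pairs = network.edge_index_pairs()
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for i, j in pairs:
            fh.write(f"{network.node_ids[i]}\t{network.node_ids[j]}\n")


def _delim(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a gene x sample expression table.

    Returns ``(gene_ids, sample_ids, values)`` with ``values`` of shape
    (n_genes, n_samples). Parse failures are re-raised with the file named
    (pandas reports the offending line).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delim(path), index_col=0, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse expression table: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: expression table has no sample columns")
    values = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return [str(g) for g in df.index], [str(s) for s in df.columns], values


def write_expression(
    gene_ids: list[str], sample_ids: list[str], values: np.ndarray, path: str | Path
) -> None:
    path = Path(path)
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    df.to_csv(path, sep=_delim(path))


def write_measures(
    network: GeneNetwork, measures: list[InvariantMeasure], out_dir: str | Path
) -> list[Path]:
    """One two-column TSV (gene, pi) per sample."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for m in measures:
        p = out_dir / f"pi_{m.sample_id}.tsv"
        pd.Series(m.pi, index=pd.Index(network.node_ids, name="gene"), name="pi").to_csv(
            p, sep="\t"
        )
        written.append(p)
    return written


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.d, index=list(d.sample_ids), columns=list(d.sample_ids)).to_csv(
        path
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column sample ids disagree")
    return DistanceMatrix(sample_ids=tuple(str(s) for s in df.index), d=df.to_numpy())


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample_id, group label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], comment="#")
    return {str(r.sample): str(r.label) for r in df.itertuples()}


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def write_clusters(clusters: dict[str, int], path: str | Path) -> None:
    """Two-column TSV: sample_id, cluster number."""
    with open(path, "w") as fh:
        for sid, c in clusters.items():
            fh.write(f"{sid}\t{c}\n")
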