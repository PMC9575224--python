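"""On-disk formats.

Everything is tab-separated text with '.' decimals; lines starting with '#'
are comments.  Node identity across files is the pair (layer, molecule_id),
serialized as ``layer:molecule_id`` where a single column is needed.
Writers and readers round-trip numeric cells to better than 1e-12 (floats
are written with 17 significant digits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .multilayer import MultilayerNetwork, Node, NodeRegistry

logger = logging.getLogger(__name__)

MOLECULE_TYPES = ("gene", "tf", "metabolite", "other")
SAMPLE_COLUMNS = ("condition", "timepoint", "replicate")

_FLOAT_FMT = "%.17g"


@dataclass
class OmicsDataset:
    """Expression/abundance tables for one or more omics layers.

    ``layers`` maps layer name to a molecule × sample abundance table.
    ``sample_sheet`` is indexed by sample_id with columns condition
    (control|test), timepoint and replicate; ``molecule_sheet`` is indexed
    by molecule_id with a ``molecule_type`` column.
    """

    layers: dict[str, pd.DataFrame]
    sample_sheet: pd.DataFrame
    molecule_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in SAMPLE_COLUMNS:
            if col not in self.sample_sheet.columns:
                raise ValueError(f"sample sheet is missing column {col!r}")
        if "molecule_type" not in self.molecule_sheet.columns:
            raise ValueError("molecule sheet is missing column 'molecule_type'")
        bad_types = set(self.molecule_sheet["molecule_type"]) - set(MOLECULE_TYPES)
        if bad_types:
            raise ValueError(f"unknown molecule types: {sorted(bad_types)}")
        bad_cond = set(self.sample_sheet["condition"]) - {"control", "test"}
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")

        for layer, table in self.layers.items():
            if table.index.duplicated().any():
                dup = table.index[table.index.duplicated()][0]
                raise ValueError(
                    f"duplicate molecule_id {dup!r} in layer {layer!r}"
                )
            unknown = set(table.columns) - set(self.sample_sheet.index)
            if unknown:
                raise ValueError(
                    f"layer {layer!r} has samples missing from the sample sheet: "
                    f"{sorted(unknown)}"
                )
            missing_mol = set(table.index) - set(self.molecule_sheet.index)
            if missing_mol:
                raise ValueError(
                    f"layer {layer!r} has molecules missing from the molecule "
                    f"sheet: {sorted(missing_mol)[:5]}"
                )
            cond = self.sample_sheet.loc[list(table.columns), "condition"]
            if not (cond == "control").any():
                raise ValueError(f"layer {layer!r} has no control sample")
            if (table.to_numpy(dtype=float) < 0).any():
                logger.warning(
                    "layer %r contains negative abundances; kept as-is "
                    "(log2FC handles them via the pseudocount policy)", layer,
                )

    def control_samples(self, layer: str) -> list[str]:
        cols = self.layers[layer].columns
        cond = self.sample_sheet.loc[list(cols), "condition"]
        return [c for c in cols if cond[c] == "control"]

    def test_samples(self, layer: str) -> list[str]:
        cols = self.layers[layer].columns
        cond = self.sample_sheet.loc[list(cols), "condition"]
        return [c for c in cols if cond[c] == "test"]

    def molecule_types(self, layer: str) -> pd.Series:
        return self.molecule_sheet.loc[
            list(self.layers[layer].index), "molecule_type"
        ]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_omics_dataset(
    expression_paths: Mapping[str, str | Path],
    sample_sheet_path: str | Path,
    molecule_sheet_path: str | Path,
) -> OmicsDataset:
    """Load and validate a multi-layer dataset from TSV files.

    ``expression_paths`` maps layer name to a table whose first column is
    molecule_id and whose remaining columns are samples.
    """
    sample_sheet = _read_tsv(sample_sheet_path, index_col=0)
    molecule_sheet = _read_tsv(molecule_sheet_path, index_col=0)
    layers = {
        layer: _read_tsv(path, index_col=0)
        for layer, path in expression_paths.items()
    }
    return OmicsDataset(layers, sample_sheet, molecule_sheet)


def write_omics_dataset(dataset: OmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard expression/sample/molecule TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for layer, table in dataset.layers.items():
        p = out / f"expression_{layer}.tsv"
        table.to_csv(p, sep="\t", index_label="molecule_id",
                     float_format=_FLOAT_FMT)
        paths[f"expression_{layer}"] = p
    p = out / "samples.tsv"
    dataset.sample_sheet.to_csv(p, sep="\t", index_label="sample_id")
    paths["samples"] = p
    p = out / "molecules.tsv"
    dataset.molecule_sheet.to_csv(p, sep="\t", index_label="molecule_id")
    paths["molecules"] = p
    return paths


# ---------------------------------------------------------------------------
# edge lists

EDGE_COLUMNS = ["source_id", "target_id", "weight", "source_layer", "target_layer"]


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a weighted edge list with layer annotations.

    Expected columns: source_id, target_id, weight, source_layer,
    target_layer (header optional for exactly these five columns).
    """
    df = _read_tsv(path, dtype={0: str, 1: str})
    if list(df.columns[:2]) != EDGE_COLUMNS[:2]:
        # headerless file: re-read assigning canonical names
        df = _read_tsv(path, header=None, names=EDGE_COLUMNS,
                       dtype={0: str, 1: str})
    df["weight"] = df["weight"].astype(float)
    if not np.isfinite(df["weight"]).all():
        raise ValueError(f"non-finite edge weight in {path}")
    self_pairs = (df["source_layer"] == df["target_layer"]) & (
        df["source_id"] == df["target_id"]
    )
    if self_pairs.any():
        raise ValueError(f"self-pair edge in {path}")
    return df[EDGE_COLUMNS]


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False,
                               float_format=_FLOAT_FMT)


def network_to_frames(network: MultilayerNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export a multilayer network as (edge table, node table)."""
    reg = network.registry
    coo = network.supra_adjacency.tocoo()
    rows = []
    for i, j, w in zip(coo.row, coo.col, coo.data):
        if i < j:
            a, b = reg[i], reg[j]
            rows.append((a.molecule_id, b.molecule_id, w, a.layer, b.layer))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    nodes = pd.DataFrame(
        [(n.molecule_id, n.layer, n.molecule_type) for n in reg],
        columns=["molecule_id", "layer", "molecule_type"],
    )
    return edges, nodes


def network_from_frames(
    edges: pd.DataFrame, nodes: pd.DataFrame | None = None
) -> MultilayerNetwork:
    """Rebuild a multilayer network from an edge table (+ optional node table).

    Without a node table the registry holds only nodes incident to an edge,
    typed "other", in order of first appearance grouped by layer.
    """
    import scipy.sparse as sp

    if nodes is not None:
        node_list = [
            Node(r.layer, str(r.molecule_id), r.molecule_type)
            for r in nodes.itertuples()
        ]
    else:
        seen: dict[tuple[str, str], None] = {}
        for r in edges.itertuples():
            seen.setdefault((r.source_layer, str(r.source_id)), None)
            seen.setdefault((r.target_layer, str(r.target_id)), None)
        by_layer: dict[str, list[tuple[str, str]]] = {}
        for layer, mol in seen:
            by_layer.setdefault(layer, []).append((layer, mol))
        node_list = [Node(layer, mol) for layer in by_layer
                     for layer, mol in by_layer[layer]]
    registry = NodeRegistry(node_list)
    n = len(registry)
    mat = sp.lil_matrix((n, n))
    for r in edges.itertuples():
        i = registry.index(r.source_layer, str(r.source_id))
        j = registry.index(r.target_layer, str(r.target_id))
        w = float(r.weight)
        mat[i, j] = max(mat[i, j], w)
        mat[j, i] = max(mat[j, i], w)
    return MultilayerNetwork(registry, sp.csr_matrix(mat))


# ---------------------------------------------------------------------------
# embeddings

def write_embeddings(embedding, path: str | Path) -> None:
    """Write an embedding as TSV: node_id, layer, type, dim_1 ... dim_d."""
    from .embedding import EmbeddingMatrix  # local import to avoid a cycle

    assert isinstance(embedding, EmbeddingMatrix)
    vec = embedding.vectors
    if not np.isfinite(vec).all():
        raise ValueError("embedding contains non-finite values")
    d = vec.shape[1]
    header = ["node_id", "layer", "type"] + [f"dim_{k + 1}" for k in range(d)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, node in enumerate(embedding.registry):
            cells = [node.molecule_id, node.layer, node.molecule_type]
            cells += [_FLOAT_FMT % v for v in vec[i]]
            fh.write("\t".join(cells) + "\n")


def read_embeddings(path: str | Path):
    """Read an embedding TSV written by :func:`write_embeddings`."""
    from .embedding import EmbeddingMatrix

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[:3] != ["node_id", "layer", "type"]:
        raise ValueError(f"{path}: not an embedding file (bad header)")
    d = len(header) - 3
    nodes: list[Node] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != 3 + d:
            raise ValueError(
                f"{path}:{lineno}: expected {3 + d} columns, got {len(cells)}"
            )
        nodes.append(Node(cells[1], cells[0], cells[2]))
        try:
            rows.append([float(c) for c in cells[3:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric embedding cell "
                             f"({exc})") from None
    vectors = np.asarray(rows, dtype=float).reshape(len(rows), d)
    return EmbeddingMatrix(
        vectors=vectors,
        singular_values=np.full(d, np.nan),
        registry=NodeRegistry(nodes),
    )


# ---------------------------------------------------------------------------
# DE tables and modules

def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    cols = ["molecule_id", "layer", "molecule_type", "direction", "max_abs_log2fc"]
    de[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_de_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, dtype={"molecule_id": str})


def write_modules(partition, path: str | Path) -> None:
    """Write node→module assignments as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("node_id\tmodule_id\n")
        for node_id, module_id in sorted(partition.assignments.items()):
            fh.write(f"{node_id}\t{module_id}\n")


def write_log2fc(log2fc: pd.DataFrame, path: str | Path) -> None:
    log2fc.to_csv(path, sep="\t", index_label="molecule_id",
                  float_format=_FLOAT_FMT)


def read_log2fc(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)
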