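"""Multilayer network assembly.

A multilayer omics network places each bio-molecule (gene, TF, metabolite,
...) in exactly one layer and couples layers through inter-omics edges.
The whole structure is held as a single supra-adjacency matrix: intra-omics
adjacencies form the diagonal blocks, inter-omics couplings the off-diagonal
blocks.  All edges are undirected and non-negatively weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "NodeRegistry",
    "IntraOmicsNetwork",
    "InterOmicsNetwork",
    "MultilayerNetwork",
    "build_supra_adjacency",
    "drop_isolated_nodes",
    "largest_connected_component",
]


@dataclass(frozen=True)
class Node:
    """A bio-molecule placed in one layer of the multilayer network."""

    layer: str
    molecule_id: str
    molecule_type: str = "other"

    @property
    def key(self) -> str:
        return f"{self.layer}:{self.molecule_id}"


class NodeRegistry:
    """Ordered global node index.

    Node identity is the pair ``(layer, molecule_id)``; the same molecule
    symbol may legitimately appear in two layers (e.g. a gene and the TF it
    codes for).  Indices are contiguous, and nodes of one layer occupy a
    contiguous block in insertion order.
    """

    def __init__(self, nodes: Iterable[Node | tuple]) -> None:
        self._nodes: list[Node] = [
            n if isinstance(n, Node) else Node(*n) for n in nodes
        ]
        self._index: dict[tuple[str, str], int] = {}
        for i, n in enumerate(self._nodes):
            ident = (n.layer, n.molecule_id)
            if ident in self._index:
                raise ValueError(f"duplicate node {n.key!r} in registry")
            self._index[ident] = i

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes)

    def __getitem__(self, i: int) -> Node:
        return self._nodes[i]

    def __contains__(self, ident: tuple[str, str]) -> bool:
        return tuple(ident) in self._index

    def index(self, layer: str, molecule_id: str) -> int:
        try:
            return self._index[(layer, molecule_id)]
        except KeyError:
            raise KeyError(f"node {layer}:{molecule_id} not in registry") from None

    def index_of_key(self, key: str) -> int:
        layer, _, mol = key.partition(":")
        return self.index(layer, mol)

    def key(self, i: int) -> str:
        return self._nodes[i].key

    @property
    def layers(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self._nodes:
            seen.setdefault(n.layer, None)
        return list(seen)

    def layer_indices(self, layer: str) -> np.ndarray:
        return np.array([i for i, n in enumerate(self._nodes) if n.layer == layer])

    def subset(self, indices: Sequence[int]) -> "NodeRegistry":
        return NodeRegistry(self._nodes[i] for i in indices)

    def keys(self) -> list[str]:
        return [n.key for n in self._nodes]


@dataclass
class IntraOmicsNetwork:
    """Weighted undirected network among molecules of a single omics layer."""

    layer_name: str
    nodes: list[str]
    molecule_types: dict[str, str] = field(default_factory=dict)
    adjacency: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.adjacency is None:
            self.adjacency = sp.csr_matrix((n, n))
        self.adjacency = sp.csr_matrix(self.adjacency)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node list")
        asym = abs(self.adjacency - self.adjacency.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("intra-omics adjacency must be symmetric")
        if abs(self.adjacency.diagonal()).max(initial=0.0) > 0:
            raise ValueError("intra-omics adjacency must have zero diagonal")

    @classmethod
    def from_edges(
        cls,
        layer_name: str,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
        molecule_types: dict[str, str] | None = None,
    ) -> "IntraOmicsNetwork":
        pos = {m: i for i, m in enumerate(nodes)}
        rows, cols, vals = [], [], []
        for a, b, w in edges:
            i, j = pos[a], pos[b]
            if i == j:
                raise ValueError(f"self-edge on {a!r} in layer {layer_name!r}")
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        adj = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
        return cls(layer_name, list(nodes), molecule_types or {}, adj)

    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


@dataclass
class InterOmicsNetwork:
    """Bipartite a-priori couplings between two distinct omics layers."""

    layer_a: str
    layer_b: str
    edges: list[tuple[str, str, float]]  # (molecule in layer_a, in layer_b, weight)

    def __post_init__(self) -> None:
        if self.layer_a == self.layer_b:
            raise ValueError("inter-omics network requires two distinct layers")


@dataclass
class MultilayerNetwork:
    """Global node registry plus the supra-adjacency matrix.

    ``supra_adjacency`` is symmetric, non-negative and has a zero diagonal;
    its block structure follows the registry's layer blocks.
    """

    registry: NodeRegistry
    supra_adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.registry)
        self.supra_adjacency = sp.csr_matrix(self.supra_adjacency)
        if self.supra_adjacency.shape != (n, n):
            raise ValueError("supra-adjacency shape does not match registry size")

    @property
    def n_nodes(self) -> int:
        return len(self.registry)

    @property
    def n_edges(self) -> int:
        """Undirected edge count."""
        return self.supra_adjacency.nnz // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.supra_adjacency.sum(axis=1)).ravel()

    @property
    def volume(self) -> float:
        """vol(G): the sum of weighted node degrees."""
        return float(self.degrees.sum())

    def subnetwork(self, indices: Sequence[int]) -> "MultilayerNetwork":
        idx = np.asarray(indices, dtype=int)
        sub = self.supra_adjacency[idx][:, idx]
        return MultilayerNetwork(self.registry.subset(idx), sub)


def build_supra_adjacency(
    intra: Sequence[IntraOmicsNetwork],
    inter: Sequence[InterOmicsNetwork] = (),
) -> MultilayerNetwork:
    """Assemble the supra-adjacency matrix from per-layer networks.

    The result is the direct sum of the intra-omics adjacency blocks plus a
    symmetrized inter-omics coupling matrix: every inter-omics edge
    ``(a, b, w)`` contributes ``w`` at both ``[a, b]`` and ``[b, a]``.
    Duplicate inter-omics edges collapse to their maximum weight.
    """
    layer_names = [net.layer_name for net in intra]
    if len(set(layer_names)) != len(layer_names):
        raise ValueError("layer names must be unique across intra-omics networks")

    nodes: list[Node] = []
    for net in intra:
        for m in net.nodes:
            nodes.append(Node(net.layer_name, m, net.molecule_types.get(m, "other")))
    registry = NodeRegistry(nodes)

    blocks = sp.block_diag([net.adjacency for net in intra], format="lil")

    coupling: dict[tuple[int, int], float] = {}
    for net in inter:
        for a, b, w in net.edges:
            try:
                i = registry.index(net.layer_a, a)
            except KeyError:
                raise KeyError(
                    f"inter-omics endpoint {net.layer_a}:{a} not in registry"
                ) from None
            try:
                j = registry.index(net.layer_b, b)
            except KeyError:
                raise KeyError(
                    f"inter-omics endpoint {net.layer_b}:{b} not in registry"
                ) from None
            pair = (min(i, j), max(i, j))
            coupling[pair] = max(coupling.get(pair, 0.0), float(w))

    for (i, j), w in coupling.items():
        blocks[i, j] = w
        blocks[j, i] = w

    network = MultilayerNetwork(registry, sp.csr_matrix(blocks))
    logger.info(
        "built supra-adjacency: %d nodes, %d edges, %d layers",
        network.n_nodes, network.n_edges, len(layer_names),
    )
    return network


def drop_isolated_nodes(network: MultilayerNetwork) -> MultilayerNetwork:
    """Remove degree-zero nodes so the degree matrix is invertible."""
    deg = network.degrees
    keep = np.flatnonzero(deg > 0)
    if keep.size == 0:
        raise ValueError("all nodes are isolated; nothing to embed")
    dropped = np.flatnonzero(deg == 0)
    if dropped.size:
        logger.info(
            "dropping %d isolated node(s): %s", dropped.size,
            ", ".join(network.registry.key(i) for i in dropped[:20]),
        )
    return network.subnetwork(keep)


def largest_connected_component(network: MultilayerNetwork) -> MultilayerNetwork:
    """Induced subnetwork on the largest connected component.

    Ties between equally sized components are broken in favour of the
    component containing the smallest global node index.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    n_comp, labels = connected_components(network.supra_adjacency, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = int(np.flatnonzero(sizes == sizes.max())[0])  # smallest min-index wins
    keep = np.flatnonzero(labels == best)
    return network.subnetwork(keep)
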