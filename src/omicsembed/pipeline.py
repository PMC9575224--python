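"""End-to-end convenience wrappers: dataset -> multilayer network -> embedding."""

from __future__ import annotations

import logging

import pandas as pd

from .embedding import EmbeddingMatrix, compute_ppmi, embed
from .io import OmicsDataset
from .multilayer import (MultilayerNetwork, build_supra_adjacency,
                         drop_isolated_nodes)
from .preprocess import (DEThresholds, assemble_inter_omics, compute_log2fc,
                         correlation_network, select_differentially_expressed)

logger = logging.getLogger(__name__)

__all__ = ["build_multilayer_from_dataset", "embed_network"]


def build_multilayer_from_dataset(
    dataset: OmicsDataset,
    apriori: pd.DataFrame | None = None,
    thresholds: DEThresholds | None = None,
    rho_cut: float = 0.8,
    binary: bool = False,
    pseudocount: float = 0.0,
    drop_isolated: bool = True,
) -> tuple[MultilayerNetwork, dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """DE filtering, per-layer co-expression networks, a-priori assembly.

    Returns (network, de_tables per layer, log2FC tables per layer).  The
    co-expression step runs on the DE molecules of each layer only, so the
    multilayer network contains differentially expressed molecules.
    """
    thresholds = thresholds or DEThresholds()
    intra = []
    de_tables: dict[str, pd.DataFrame] = {}
    log2fc_tables: dict[str, pd.DataFrame] = {}
    de_sets: dict[str, set[str]] = {}
    for layer in dataset.layers:
        fc = compute_log2fc(dataset, layer, pseudocount=pseudocount)
        log2fc_tables[layer] = fc
        types = dataset.molecule_types(layer)
        de = select_differentially_expressed(fc, types, thresholds)
        de.insert(1, "layer", layer)
        de_tables[layer] = de
        de_ids = list(de["molecule_id"])
        de_sets[layer] = set(de_ids)
        fc_de = fc.loc[de_ids]
        net = correlation_network(
            fc_de, layer, rho_cut=rho_cut, binary=binary,
            molecule_types={m: types[m] for m in de_ids},
        )
        intra.append(net)
        logger.info("layer %s: %d DE molecules, %d co-expression edges",
                    layer, len(de_ids), net.n_edges())

    inter = []
    if apriori is not None and len(apriori):
        inter = assemble_inter_omics(apriori, de_sets)
    network = build_supra_adjacency(intra, inter)
    if drop_isolated:
        network = drop_isolated_nodes(network)
    return network, de_tables, log2fc_tables


def embed_network(
    network: MultilayerNetwork, T: int = 3, b: float = 1.0, d: int = 128,
    clamp_d: bool = True,
) -> EmbeddingMatrix:
    """PPMI + SVD in one call; optionally clamp d to the node count."""
    if clamp_d and d > network.n_nodes:
        logger.info("clamping d=%d to node count %d", d, network.n_nodes)
        d = network.n_nodes
    ppmi = compute_ppmi(network, T=T, b=b)
    return embed(ppmi, d)
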