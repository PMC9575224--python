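import numpy as np
import pandas as pd
import pytest

import omicsembed as oe


def toy_dataset(n_ctrl=4, n_test=8):
    """Tiny 2-layer dataset: 4 genes + 3 metabolites over 12 samples."""
    samples = [f"t0_r{i}" for i in range(1, n_ctrl + 1)]
    samples += [f"t1_r{i}" for i in range(1, n_test // 2 + 1)]
    samples += [f"t2_r{i}" for i in range(1, n_test - n_test // 2 + 1)]
    sheet = pd.DataFrame(
        {
            "condition": ["control"] * n_ctrl + ["test"] * n_test,
            "timepoint": [s.split("_")[0] for s in samples],
            "replicate": [int(s.split("_r")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    rng = np.random.default_rng(0)
    genes = pd.DataFrame(
        np.exp2(rng.normal(6, 1, size=(4, len(samples)))),
        index=pd.Index([f"G{i}" for i in range(4)], name="molecule_id"),
        columns=samples,
    )
    mets = pd.DataFrame(
        np.exp2(rng.normal(4, 1, size=(3, len(samples)))),
        index=pd.Index([f"M{i}" for i in range(3)], name="molecule_id"),
        columns=samples,
    )
    molecules = pd.DataFrame(
        {"molecule_type": ["gene"] * 4 + ["metabolite"] * 3},
        index=pd.Index([f"G{i}" for i in range(4)] + [f"M{i}" for i in range(3)],
                       name="molecule_id"),
    )
    return oe.OmicsDataset({"gene": genes, "metabolite": mets}, sheet, molecules)


@pytest.fixture
def small_dataset():
    return toy_dataset()


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study (seed 7) shared across tests."""
    config = oe.SimulationConfig()
    dataset, apriori, truth = oe.simulate(config)
    return config, dataset, apriori, truth


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Full pipeline products on the default synthetic study."""
    _, dataset, apriori, truth = default_sim
    network, de_tables, log2fc = oe.build_multilayer_from_dataset(dataset, apriori)
    embedding = oe.embed_network(network, T=3, b=1.0, d=128)
    return {
        "dataset": dataset,
        "apriori": apriori,
        "truth": truth,
        "network": network,
        "de_tables": de_tables,
        "log2fc": log2fc,
        "embedding": embedding,
    }


def random_connected_network(n, p, seed):
    """Random connected single-layer graph (a spanning path plus noise)."""
    rng = np.random.default_rng(seed)
    import scipy.sparse as sp

    adj = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # spanning path => connected
        adj[a, b] = adj[b, a] = 1.0
    mask = rng.random((n, n)) < p
    mask = np.triu(mask, k=1)
    adj[mask] = 1.0
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    registry = oe.NodeRegistry(oe.Node("graph", f"n{i:03d}") for i in range(n))
    return oe.MultilayerNetwork(registry, sp.csr_matrix(adj))
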