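"""Synthetic multi-omics data with known ground truth.

The generator emulates a stress time-course design: three molecule layers
(genes, TFs, metabolites), one control timepoint plus two stress
timepoints, four biological replicates.  A configurable fraction of each
layer is differentially expressed (DE); DE molecules belong to planted
co-response modules that share a latent stress trajectory on the log2
scale, so within-module log2FC profiles correlate strongly — this is what
the |rho| > 0.8 co-expression step is meant to recover.  A-priori TF-target
and gene/TF-metabolite edges are drawn module-aware: dense within modules,
sparse across.

Everything is driven by one integer seed and is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsDataset
from .multilayer import (IntraOmicsNetwork, MultilayerNetwork, Node,
                         NodeRegistry)

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "make_graph_fixture"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic stress-response experiment.

    Effect sizes are mean planted |log2FC| at the stress peak; TF and
    metabolite effects are smaller than gene effects (their DE cutoff is
    ±1 against ±2 for genes).  ``noise_sd`` is replicate noise on the log2
    scale.
    """

    n_genes: int = 200
    n_tfs: int = 30
    n_metabolites: int = 20
    n_test_timepoints: int = 2
    n_replicates: int = 4
    de_fraction: dict[str, float] = field(
        default_factory=lambda: {"gene": 0.4, "tf": 0.5, "metabolite": 0.6}
    )
    n_modules: int = 3
    effect_size_log2: float = 3.0
    tf_effect_size_log2: float = 1.5
    metabolite_effect_size_log2: float = 1.5
    noise_sd: float = 0.3
    tf_target_density_in: float = 0.3
    tf_target_density_out: float = 0.01
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tfs", "n_metabolites",
                     "n_test_timepoints", "n_replicates", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for t, f in self.de_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"de_fraction[{t!r}] must be in [0, 1]")
        if self.tf_target_density_in <= self.tf_target_density_out:
            raise ValueError("within-module density must exceed across-module")

    @property
    def layer_sizes(self) -> dict[str, int]:
        return {"gene": self.n_genes, "tf": self.n_tfs,
                "metabolite": self.n_metabolites}

    def effect_size(self, layer: str) -> float:
        return {"gene": self.effect_size_log2,
                "tf": self.tf_effect_size_log2,
                "metabolite": self.metabolite_effect_size_log2}[layer]


@dataclass
class GroundTruth:
    """Planted labels and edges of a simulated dataset.

    Keys are (layer, molecule_id) pairs; ``de_labels`` covers every
    molecule (over | under | null), ``module_labels`` only DE molecules.
    """

    de_labels: dict[tuple[str, str], str]
    module_labels: dict[tuple[str, str], int]
    tf_target_edges: set[tuple[str, str]]  # (tf molecule, gene molecule)
    molecule_metabolite_edges: set[tuple[tuple[str, str], tuple[str, str]]]

    def de_set(self, layer: str) -> set[str]:
        return {m for (ly, m), lab in self.de_labels.items()
                if ly == layer and lab != "null"}

    def module_vector(self) -> dict[str, int]:
        """node key -> planted module id, DE molecules only."""
        return {f"{ly}:{m}": mod for (ly, m), mod in self.module_labels.items()}


def _molecule_ids(layer: str, n: int) -> list[str]:
    prefix = {"gene": "G", "tf": "TF", "metabolite": "MET"}[layer]
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate(config: SimulationConfig) -> tuple[OmicsDataset, pd.DataFrame, GroundTruth]:
    """Generate (dataset, a-priori edge table, ground truth).

    Control abundances are log-normal.  Each DE molecule i in module m gets
    test-sample log2 offsets ``sign_m * e_i * traj_m[s]`` where traj_m is a
    module-shared latent trajectory (per-timepoint level plus module-level
    per-sample jitter) and e_i a molecule effect size; replicate noise of
    sd ``noise_sd`` is added on the log2 scale everywhere.  With zero noise
    the within-module log2FC profiles are exactly collinear.
    """
    rng = np.random.default_rng(config.seed)
    timepoints = ["t0"] + [f"t{i + 1}" for i in range(config.n_test_timepoints)]
    samples: list[tuple[str, str, str, int]] = []
    for tp in timepoints:
        for rep in range(1, config.n_replicates + 1):
            cond = "control" if tp == "t0" else "test"
            samples.append((f"{tp}_r{rep}", cond, tp, rep))
    sample_sheet = pd.DataFrame(
        samples, columns=["sample_id", "condition", "timepoint", "replicate"]
    ).set_index("sample_id")
    test_samples = [s for s, c, _, _ in samples if c == "test"]
    n_test = len(test_samples)

    # --- assign DE molecules and modules -----------------------------------
    de_members: dict[str, np.ndarray] = {}
    for layer, n in config.layer_sizes.items():
        n_de = int(round(config.de_fraction.get(layer, 0.0) * n))
        de_members[layer] = np.sort(rng.choice(n, size=n_de, replace=False))

    any_de = any(len(v) for v in de_members.values())
    module_of: dict[tuple[str, str], int] = {}
    if any_de:
        # round-robin over modules, per layer, so each module mixes types
        counts = np.zeros(config.n_modules, dtype=int)
        for layer in config.layer_sizes:
            ids = _molecule_ids(layer, config.layer_sizes[layer])
            for k, idx in enumerate(de_members[layer]):
                m = k % config.n_modules
                module_of[(layer, ids[idx])] = m
                counts[m] += 1
        if (counts == 0).any():
            raise ValueError(
                "de_fraction too low: a planted module would be empty "
                f"(module sizes {counts.tolist()})"
            )

    # module-shared latent trajectories over the test samples
    module_sign = rng.choice([1.0, -1.0], size=config.n_modules, p=[0.8, 0.2])
    traj = np.empty((config.n_modules, n_test))
    for m in range(config.n_modules):
        levels = rng.uniform(0.7, 1.0, size=config.n_test_timepoints)
        jitter = rng.normal(0.0, 0.1, size=n_test)
        per_sample = np.repeat(levels, config.n_replicates)
        traj[m] = per_sample + jitter

    # --- expression tables --------------------------------------------------
    layers: dict[str, pd.DataFrame] = {}
    molecule_rows: list[tuple[str, str]] = []
    de_labels: dict[tuple[str, str], str] = {}
    for layer, n in config.layer_sizes.items():
        ids = _molecule_ids(layer, n)
        molecule_rows += [(mid, layer) for mid in ids]
        base_log2 = rng.normal(6.0, 1.5, size=n)
        de_mask = np.zeros(n, dtype=bool)
        de_mask[de_members[layer]] = True
        effect = np.zeros(n)
        sign = np.ones(n)
        traj_idx = np.zeros(n, dtype=int)
        e0 = config.effect_size(layer)
        for idx in de_members[layer]:
            mid = ids[idx]
            m = module_of[(layer, mid)]
            traj_idx[idx] = m
            sign[idx] = module_sign[m]
            effect[idx] = max(0.25 * e0, rng.normal(e0, 0.15 * e0))
            de_labels[(layer, mid)] = "over" if sign[idx] > 0 else "under"
        for idx in range(n):
            if not de_mask[idx]:
                de_labels[(layer, ids[idx])] = "null"

        n_ctrl = config.n_replicates
        log2_ctrl = base_log2[:, None] + rng.normal(
            0.0, config.noise_sd, size=(n, n_ctrl))
        delta = sign[:, None] * effect[:, None] * traj[traj_idx]
        delta[~de_mask] = 0.0
        log2_test = base_log2[:, None] + delta + rng.normal(
            0.0, config.noise_sd, size=(n, n_test))
        table = pd.DataFrame(
            np.exp2(np.hstack([log2_ctrl, log2_test])),
            index=pd.Index(ids, name="molecule_id"),
            columns=[s for s, c, _, _ in samples if c == "control"] + test_samples,
        )
        layers[layer] = table

    molecule_sheet = pd.DataFrame(
        [(mid, "tf" if layer == "tf" else
          ("metabolite" if layer == "metabolite" else "gene"))
         for mid, layer in molecule_rows],
        columns=["molecule_id", "molecule_type"],
    ).set_index("molecule_id")
    dataset = OmicsDataset(layers, sample_sheet, molecule_sheet)

    # --- a-priori inter-omics edges (planted, module-aware) -----------------
    gene_ids = _molecule_ids("gene", config.n_genes)
    tf_ids = _molecule_ids("tf", config.n_tfs)
    met_ids = _molecule_ids("metabolite", config.n_metabolites)
    de_genes = [gene_ids[i] for i in de_members["gene"]]
    de_tfs = [tf_ids[i] for i in de_members["tf"]]
    de_mets = [met_ids[i] for i in de_members["metabolite"]]

    def draw(pairs_a, layer_a, pairs_b, layer_b):
        out = set()
        for a in pairs_a:
            for b in pairs_b:
                same = module_of.get((layer_a, a)) == module_of.get((layer_b, b))
                p = (config.tf_target_density_in if same
                     else config.tf_target_density_out)
                if rng.random() < p:
                    out.add((a, b))
        return out

    tf_target = draw(de_tfs, "tf", de_genes, "gene")
    tf_met = draw(de_tfs, "tf", de_mets, "metabolite")
    gene_met = draw(de_genes, "gene", de_mets, "metabolite")

    rows = []
    for tf, g in sorted(tf_target):
        rows.append((tf, g, 1.0, "tf", "gene"))
    for tf, met in sorted(tf_met):
        rows.append((tf, met, 1.0, "tf", "metabolite"))
    for g, met in sorted(gene_met):
        rows.append((g, met, 1.0, "gene", "metabolite"))
    apriori = pd.DataFrame(
        rows, columns=["source_id", "target_id", "weight",
                       "source_layer", "target_layer"],
    )

    truth = GroundTruth(
        de_labels=de_labels,
        module_labels=module_of,
        tf_target_edges=tf_target,
        molecule_metabolite_edges=(
            {(("tf", a), ("metabolite", b)) for a, b in tf_met}
            | {(("gene", a), ("metabolite", b)) for a, b in gene_met}
        ),
    )
    logger.info(
        "simulated dataset: %d genes (%d DE), %d TFs (%d DE), %d metabolites "
        "(%d DE), %d a-priori edges",
        config.n_genes, len(de_genes), config.n_tfs, len(de_tfs),
        config.n_metabolites, len(de_mets), len(apriori),
    )
    return dataset, apriori, truth


# ---------------------------------------------------------------------------
# small deterministic graph fixtures

def make_graph_fixture(kind: str, sizes, seed: int = 0, **kw) -> MultilayerNetwork:
    """Small deterministic graphs for embedding/downstream tests.

    kinds: ``path`` (n), ``clique`` (n), ``two_cliques`` ((n1, n2), joined
    by ``bridge`` edges), ``planted_partition`` ((n_blocks, block_size)
    with p_in/p_out; block membership is encoded in the molecule id prefix
    ``b<block>_``), ``bipartite`` ((n1, n2) across two layers with edge
    probability ``p``).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)

    def from_nx(g, ids=None, layer="graph"):
        nodes = sorted(g.nodes())
        ids = ids or {v: f"n{v:03d}" for v in nodes}
        registry = NodeRegistry(Node(layer, ids[v]) for v in nodes)
        import scipy.sparse as sp
        pos = {v: i for i, v in enumerate(nodes)}
        mat = sp.lil_matrix((len(nodes), len(nodes)))
        for a, b in g.edges():
            mat[pos[a], pos[b]] = 1.0
            mat[pos[b], pos[a]] = 1.0
        return MultilayerNetwork(registry, sp.csr_matrix(mat))

    if kind == "path":
        return from_nx(nx.path_graph(int(sizes)))
    if kind == "clique":
        return from_nx(nx.complete_graph(int(sizes)))
    if kind == "two_cliques":
        n1, n2 = sizes
        bridge = int(kw.get("bridge", 1))
        g = nx.disjoint_union(nx.complete_graph(n1), nx.complete_graph(n2))
        for k in range(bridge):
            g.add_edge(k % n1, n1 + (k % n2))
        return from_nx(g)
    if kind == "planted_partition":
        n_blocks, block_size = sizes
        p_in = float(kw.get("p_in", 0.3))
        p_out = float(kw.get("p_out", 0.02))
        n = n_blocks * block_size
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for a in range(n):
            for b in range(a + 1, n):
                p = p_in if a // block_size == b // block_size else p_out
                if rng.random() < p:
                    g.add_edge(a, b)
        ids = {v: f"b{v // block_size}_n{v:03d}" for v in range(n)}
        return from_nx(g, ids=ids)
    if kind == "bipartite":
        n1, n2 = sizes
        p = float(kw.get("p", 1.0))
        left = [Node("left", f"l{v:03d}") for v in range(n1)]
        right = [Node("right", f"r{v:03d}") for v in range(n2)]
        registry = NodeRegistry(left + right)
        import scipy.sparse as sp
        mat = sp.lil_matrix((n1 + n2, n1 + n2))
        for a in range(n1):
            for b in range(n2):
                if rng.random() < p:
                    mat[a, n1 + b] = 1.0
                    mat[n1 + b, a] = 1.0
        return MultilayerNetwork(registry, sp.csr_matrix(mat))
    raise ValueError(f"unknown fixture kind {kind!r}")
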