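"""Downstream evaluation and inference on learned embeddings.

Three tasks:

* **TF-target link prediction** — per TF, half of its known targets are
  held out; edge features built from node embeddings (``average`` or
  ``weighted_l2`` operators) train an L2-regularized logistic regression,
  scored by the area under the precision-recall curve (AUPR).
* **Integrated omics network (ION) inference** — pairwise embedding dot
  products, min-max normalized to [0, 1], thresholded at theta; evaluated
  against a reference edge list by Precision@k and the Matthews
  correlation coefficient (MCC) over a theta grid.
* **Module detection** — Clauset-Newman-Moore greedy modularity
  maximization on the thresholded ION, keeping modules larger than a
  minimum size.

A grid harness sweeps window size T and dimension d for sensitivity
analysis.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .embedding import EmbeddingMatrix, PPMIMatrix, compute_ppmi, embed, similarity_matrix
from .multilayer import MultilayerNetwork

logger = logging.getLogger(__name__)

OPERATORS = ("average", "weighted_l2")
DEFAULT_KS = (1, 10, 50, 100, 200, 300, 400, 500)
DEFAULT_THETAS = tuple(round(0.1 * i, 1) for i in range(1, 10))

Pair = tuple[str, str]


# ---------------------------------------------------------------------------
# link prediction

@dataclass
class LinkPredictionSplit:
    """Train/test positives and sampled negatives for TF-target prediction."""

    positive_train: list[Pair]
    positive_test: list[Pair]
    negative_train: list[Pair]
    negative_test: list[Pair]
    seed: int

    def __post_init__(self) -> None:
        pos = set(self.positive_train) | set(self.positive_test)
        neg = set(self.negative_train) | set(self.negative_test)
        if pos & neg:
            raise ValueError("positives and negatives overlap")
        if len(self.negative_train) != len(self.positive_train):
            raise ValueError("negative_train size must equal positive_train")
        if len(self.negative_test) != len(self.positive_test):
            raise ValueError("negative_test size must equal positive_test")


def restrict_to_largest_component(edges: Iterable[Pair]) -> list[Pair]:
    """Edges of the largest connected component of the TF-target graph."""
    g = nx.Graph()
    g.add_edges_from(edges)
    if g.number_of_edges() == 0:
        raise ValueError("TF-target network has no edges")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    keep = set(comps[0])
    return sorted((a, b) for a, b in g.edges() if a in keep and b in keep)


def make_split(
    tf_target_edges: Iterable[Pair],
    all_tfs: Iterable[str] | None = None,
    all_targets: Iterable[str] | None = None,
    seed: int = 0,
    restrict_lcc: bool = True,
) -> LinkPredictionSplit:
    """Per-TF 50/50 split of targets plus matched negative sampling.

    For each TF, floor(n/2) of its targets (chosen at random) become test
    positives and the remainder train positives; a TF with a single target
    keeps it in train.  Negatives are (tf, target) pairs absent from the
    network, sampled uniformly without replacement, disjoint between train
    and test, matching the positive counts.
    """
    edges = sorted(set(map(tuple, tf_target_edges)))
    if restrict_lcc:
        edges = restrict_to_largest_component(edges)
    rng = np.random.default_rng(seed)

    by_tf: dict[str, list[str]] = {}
    for tf, tgt in edges:
        by_tf.setdefault(tf, []).append(tgt)

    pos_train: list[Pair] = []
    pos_test: list[Pair] = []
    for tf in sorted(by_tf):
        targets = sorted(by_tf[tf])
        if len(targets) == 1:
            logger.debug("TF %s has a single target; kept in train", tf)
            pos_train.append((tf, targets[0]))
            continue
        perm = rng.permutation(len(targets))
        n_test = len(targets) // 2
        for k, idx in enumerate(perm):
            (pos_test if k < n_test else pos_train).append((tf, targets[idx]))

    tfs = sorted(set(all_tfs) if all_tfs is not None else set(by_tf))
    targets_all = sorted(
        set(all_targets) if all_targets is not None
        else {t for ts in by_tf.values() for t in ts}
    )
    edge_set = set(edges)
    pool = [
        (tf, tgt)
        for tf, tgt in itertools.product(tfs, targets_all)
        if (tf, tgt) not in edge_set and tf != tgt
    ]
    need = len(pos_train) + len(pos_test)
    if len(pool) < need:
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than required ({need}); "
            "provide more candidate targets"
        )
    pick = rng.permutation(len(pool))[:need]
    neg = [pool[i] for i in pick]
    neg_train = neg[: len(pos_train)]
    neg_test = neg[len(pos_train):]
    return LinkPredictionSplit(
        sorted(pos_train), sorted(pos_test), sorted(neg_train), sorted(neg_test),
        seed=seed,
    )


def edge_features(
    embedding: EmbeddingMatrix, pairs: Sequence[Pair], operator: str
) -> np.ndarray:
    """Element-wise edge features from two node embeddings.

    ``average``: (x_i + x_j) / 2; ``weighted_l2``: (x_i - x_j)^2.  Both are
    symmetric in (i, j).
    """
    if operator not in OPERATORS:
        raise ValueError(f"unknown operator {operator!r}; use one of {OPERATORS}")
    if embedding.registry is None:
        raise ValueError("embedding has no registry; cannot resolve node keys")
    idx_a = [embedding.registry.index_of_key(a) for a, _ in pairs]
    idx_b = [embedding.registry.index_of_key(b) for _, b in pairs]
    xa = embedding.vectors[idx_a]
    xb = embedding.vectors[idx_b]
    if operator == "average":
        return (xa + xb) / 2.0
    return (xa - xb) ** 2


def predict_links(
    split: LinkPredictionSplit,
    embedding: EmbeddingMatrix,
    operator: str = "weighted_l2",
) -> float:
    """Train a logistic regression on edge features; return test AUPR."""
    x_train = np.vstack([
        edge_features(embedding, split.positive_train, operator),
        edge_features(embedding, split.negative_train, operator),
    ])
    y_train = np.r_[np.ones(len(split.positive_train)),
                    np.zeros(len(split.negative_train))]
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate single-class training set")
    x_test = np.vstack([
        edge_features(embedding, split.positive_test, operator),
        edge_features(embedding, split.negative_test, operator),
    ])
    y_test = np.r_[np.ones(len(split.positive_test)),
                   np.zeros(len(split.negative_test))]
    clf = LogisticRegression(C=1.0, max_iter=1000)  # L2 penalty is the default
    clf.fit(x_train, y_train)
    scores = clf.predict_proba(x_test)[:, 1]
    return float(average_precision_score(y_test, scores))


def repeat_prediction(
    tf_target_edges: Iterable[Pair],
    embedding: EmbeddingMatrix,
    operators: Sequence[str] = OPERATORS,
    seed: int = 0,
    n_runs: int = 10,
    all_tfs: Iterable[str] | None = None,
    all_targets: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Mean and standard deviation of AUPR over independent 50% splits.

    Run ``i`` uses seed ``seed + i``; returns one row per operator with
    columns operator, mean_aupr, sd_aupr, n_runs.
    """
    edges = sorted(set(map(tuple, tf_target_edges)))
    scores: dict[str, list[float]] = {op: [] for op in operators}
    for i in range(n_runs):
        split = make_split(edges, all_tfs, all_targets, seed=seed + i)
        for op in operators:
            scores[op].append(predict_links(split, embedding, op))
    rows = [
        (op, float(np.mean(v)), float(np.std(v)), n_runs)
        for op, v in scores.items()
    ]
    return pd.DataFrame(rows, columns=["operator", "mean_aupr", "sd_aupr", "n_runs"])


# ---------------------------------------------------------------------------
# ION inference

@dataclass
class InferredNetwork:
    """delta-scored candidate edges above a similarity threshold.

    ``edges`` has columns node_i, node_j, delta, delta_norm, sorted by
    descending delta_norm (ties broken by ascending node pair); node_i <
    node_j as registry indices serialized to keys.
    """

    edges: pd.DataFrame
    theta: float
    node_keys: list[str]

    def n_edges(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[Pair]:
        return list(zip(self.edges["node_i"], self.edges["node_j"]))


def _normalized_similarity(embedding: EmbeddingMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle (i, j, delta, delta_norm) arrays for all node pairs."""
    delta = similarity_matrix(embedding)
    n = delta.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = delta[iu, ju]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("all pairwise similarities equal; min-max "
                         "normalization undefined")
    norm = (vals - lo) / (hi - lo)
    return iu, ju, np.stack([vals, norm])


def infer_ion(embedding: EmbeddingMatrix, theta: float = 0.7) -> InferredNetwork:
    """Integrated omics network from thresholded normalized similarities.

    delta is the embedding dot product for every unordered node pair;
    delta_norm its min-max normalization over all pairs.  Pairs with
    delta_norm > theta are retained, sorted by descending delta_norm.
    """
    if embedding.registry is None:
        raise ValueError("embedding has no registry attached")
    iu, ju, (vals, norm) = _normalized_similarity(embedding)
    keep = norm > theta
    keys = embedding.registry.keys()
    df = pd.DataFrame({
        "node_i": [keys[i] for i in iu[keep]],
        "node_j": [keys[j] for j in ju[keep]],
        "delta": vals[keep],
        "delta_norm": norm[keep],
        "_i": iu[keep],
        "_j": ju[keep],
    })
    df = df.sort_values(["delta_norm", "_i", "_j"],
                        ascending=[False, True, True]).reset_index(drop=True)
    df = df.drop(columns=["_i", "_j"])
    return InferredNetwork(df, theta=theta, node_keys=keys)


def _as_unordered(edges: Iterable[Pair]) -> set[frozenset]:
    return {frozenset(e) for e in edges}


def precision_at_k(
    inferred: InferredNetwork,
    reference_edges: Iterable[Pair],
    ks: Sequence[int] = DEFAULT_KS,
) -> list[tuple[int, float]]:
    """Fraction of reference edges among the top-k inferred edges.

    Membership is tested on unordered pairs; if fewer than k edges were
    inferred, precision is computed over the available ones.
    """
    ref = _as_unordered(reference_edges)
    ranked = inferred.pairs()
    out = []
    for k in ks:
        if k < 1:
            raise ValueError("k must be >= 1")
        top = ranked[:k]
        if not top:
            out.append((k, 0.0))
            continue
        tp = sum(1 for e in top if frozenset(e) in ref)
        out.append((k, tp / len(top)))
    return out


@dataclass
class ConfusionCounts:
    """2x2 confusion counts over evaluated node pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def mcc_at_threshold(
    embedding: EmbeddingMatrix,
    reference_edges: Iterable[Pair],
    thetas: Sequence[float] = DEFAULT_THETAS,
) -> list[tuple[float, float]]:
    """MCC of pair classification (delta_norm > theta) against a reference.

    Every unordered node pair is classified; reference edges are the
    positive class.
    """
    if embedding.registry is None:
        raise ValueError("embedding has no registry attached")
    keys = embedding.registry.keys()
    key_set = set(keys)
    ref = _as_unordered(reference_edges)
    for e in ref:
        for node in e:
            if node not in key_set:
                raise KeyError(f"reference edge endpoint {node!r} not embedded")
    iu, ju, (_, norm) = _normalized_similarity(embedding)
    truth = np.array(
        [frozenset((keys[i], keys[j])) in ref for i, j in zip(iu, ju)]
    )
    out = []
    for theta in thetas:
        pred = norm > theta
        counts = ConfusionCounts(
            tp=int((pred & truth).sum()),
            fp=int((pred & ~truth).sum()),
            tn=int((~pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
        )
        out.append((float(theta), mcc(counts)))
    return out


# ---------------------------------------------------------------------------
# module detection

@dataclass
class ModulePartition:
    """Disjoint modules of the thresholded ION, labeled by decreasing size."""

    assignments: dict[str, str] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)
    modularity: float = 0.0


def _module_labels(count: int) -> list[str]:
    letters = string.ascii_uppercase
    labels = list(letters)
    while len(labels) < count:
        labels += [a + b for a in letters for b in letters]
    return labels[:count]


def detect_modules(
    inferred: InferredNetwork, min_size: int = 10
) -> ModulePartition:
    """Greedy modularity (Clauset-Newman-Moore) communities of the ION.

    The thresholded network is treated as unweighted (thresholding already
    consumed the weights).  Only modules with more than ``min_size`` nodes
    are reported, labeled A, B, ... by decreasing size.
    """
    if inferred.n_edges() == 0:
        raise ValueError("inferred network is empty")
    g = nx.Graph()
    g.add_edges_from(inferred.pairs())
    communities = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, communities)
    big = [sorted(c) for c in communities if len(c) > min_size]
    big.sort(key=lambda c: (-len(c), c[0]))
    if not big:
        logger.warning("no module exceeds min_size=%d", min_size)
    labels = _module_labels(len(big))
    partition = ModulePartition(modularity=float(q))
    for label, members in zip(labels, big):
        partition.sizes[label] = len(members)
        for node in members:
            partition.assignments[node] = label
    return partition


def rank_hubs(
    inferred: InferredNetwork,
    top_n: int = 21,
    directions: Mapping[str, str] | None = None,
) -> list[tuple[str, str, int]]:
    """Highest-degree nodes of the thresholded ION.

    Returns (node_id, direction, degree) sorted by descending degree, ties
    by ascending node id.  Direction labels (over/under) come from the DE
    table when provided.
    """
    deg: dict[str, int] = {}
    for a, b in inferred.pairs():
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    directions = directions or {}
    return [(n, directions.get(n, ""), d) for n, d in ranked]


# ---------------------------------------------------------------------------
# sensitivity grid

def grid_search(
    network: MultilayerNetwork,
    tf_target_edges: Iterable[Pair] | None = None,
    reference_edges: Iterable[Pair] | None = None,
    Ts: Sequence[int] = (1, 2, 3, 4, 5),
    ds: Sequence[int] = (32, 64, 128, 256),
    task: str = "link_prediction",
    b: float = 1.0,
    thetas: Sequence[float] = DEFAULT_THETAS,
    seed: int = 0,
    n_runs: int = 10,
    all_tfs: Iterable[str] | None = None,
    all_targets: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Sweep window size T and dimension d over a downstream task.

    ``task`` is "link_prediction" (rows: T, d, operator, mean_aupr,
    sd_aupr) or "ion" (rows: T, d, theta, mcc).  Dimensions larger than the
    node count are clamped, with a log note.
    """
    if task not in ("link_prediction", "ion"):
        raise ValueError(f"unknown task {task!r}")
    if task == "link_prediction" and tf_target_edges is None:
        raise ValueError("link_prediction task requires tf_target_edges")
    if task == "ion" and reference_edges is None:
        raise ValueError("ion task requires reference_edges")

    rows = []
    n = network.n_nodes
    for T in Ts:
        ppmi = compute_ppmi(network, T=T, b=b)
        for d in ds:
            d_eff = min(d, n)
            if d_eff < d:
                logger.info("clamping d=%d to node count %d", d, n)
            emb = embed(ppmi, d_eff)
            if task == "link_prediction":
                rep = repeat_prediction(
                    tf_target_edges, emb, seed=seed, n_runs=n_runs,
                    all_tfs=all_tfs, all_targets=all_targets,
                )
                for r in rep.itertuples():
                    rows.append((T, d, r.operator, r.mean_aupr, r.sd_aupr))
            else:
                for theta, value in mcc_at_threshold(emb, reference_edges, thetas):
                    rows.append((T, d, theta, value))
    if task == "link_prediction":
        cols = ["T", "d", "operator", "mean_aupr", "sd_aupr"]
    else:
        cols = ["T", "d", "theta", "mcc"]
    return pd.DataFrame(rows, columns=cols)
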