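"""Differential expression and network construction.

The pipeline contrasts stressed (test) samples against unstressed (control)
replicates.  For every molecule the log2 fold change (log2FC) of each test
sample is taken against the *mean* of the control replicates.  Molecules
whose log2FC clears a type-specific cutoff in at least one test sample are
called differentially expressed (DE); genes use a cutoff of ±2 while TFs,
metabolites and other molecule types use ±1, reflecting that TF transcript
levels vary less than those of their targets.

Intra-omics networks connect DE molecules of one layer whose log2FC
profiles have |Pearson correlation| above a cutoff (0.8 by default).
Inter-omics networks are filtered from a-priori knowledge edge lists
(TF-target relations, gene/TF-metabolite reaction membership), keeping only
edges between DE molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import OmicsDataset
from .multilayer import InterOmicsNetwork, IntraOmicsNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DEThresholds",
    "compute_log2fc",
    "select_differentially_expressed",
    "correlation_network",
    "assemble_inter_omics",
]

#: default over-expression cutoffs per molecule type (under = negation)
DEFAULT_OVER = {"gene": 2.0, "tf": 1.0, "metabolite": 1.0, "other": 1.0}


@dataclass
class DEThresholds:
    """Per-molecule-type log2FC cutoffs for DE selection.

    ``over`` maps molecule type to the over-expression cutoff (>0); the
    under-expression cutoff defaults to its negation.  ``min_samples`` is
    the number of test samples in which a cutoff must be cleared.
    """

    over: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OVER))
    under: dict[str, float] = field(default_factory=dict)
    min_samples: int = 1

    def __post_init__(self) -> None:
        for t, v in self.over.items():
            if v <= 0:
                raise ValueError(f"over_threshold for {t!r} must be > 0")
            self.under.setdefault(t, -v)
        for t, v in self.under.items():
            if v >= 0:
                raise ValueError(f"under_threshold for {t!r} must be < 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")

    def bounds(self, molecule_type: str) -> tuple[float, float]:
        if molecule_type not in self.over:
            raise KeyError(f"no thresholds for molecule type {molecule_type!r}")
        return self.over[molecule_type], self.under[molecule_type]


def compute_log2fc(
    dataset: OmicsDataset, layer_name: str, pseudocount: float = 0.0
) -> pd.DataFrame:
    """log2 fold change of every test sample against the mean of controls.

    Returns a molecule × test-sample table:
    ``log2((test + eps) / (mean_control + eps))`` with pseudocount ``eps``.
    With the default ``eps = 0`` a zero control mean (or zero test value) is
    a hard error, pointing at the pseudocount option, rather than silently
    shifting scales.
    """
    table = dataset.layers[layer_name]
    controls = dataset.control_samples(layer_name)
    tests = dataset.test_samples(layer_name)
    if not controls:
        raise ValueError(f"layer {layer_name!r} has no control samples")
    if not tests:
        raise ValueError(f"layer {layer_name!r} has no test samples")

    ctrl_mean = table[controls].to_numpy(dtype=float).mean(axis=1) + pseudocount
    test_vals = table[tests].to_numpy(dtype=float) + pseudocount
    if (ctrl_mean <= 0).any() or (test_vals <= 0).any():
        raise ValueError(
            f"layer {layer_name!r}: zero or negative abundance with "
            f"pseudocount {pseudocount}; pass a positive pseudocount"
        )
    fc = np.log2(test_vals / ctrl_mean[:, None])
    return pd.DataFrame(fc, index=table.index.copy(), columns=tests)


def select_differentially_expressed(
    log2fc: pd.DataFrame,
    molecule_types: Mapping[str, str] | pd.Series,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Select molecules whose log2FC clears the type cutoff in enough samples.

    A molecule is DE when its log2FC exceeds the over cutoff or falls below
    the under cutoff in at least ``min_samples`` test samples.  The reported
    direction is the side on which the cutoff was cleared; if both sides
    occur, the side of the largest \\|log2FC\\| wins.

    Returns a DataFrame (molecule_id, molecule_type, direction,
    max_abs_log2fc) sorted by descending max_abs_log2fc.
    """
    thresholds = thresholds or DEThresholds()
    if log2fc.empty:
        raise ValueError("empty log2FC table")
    rows = []
    vals = log2fc.to_numpy(dtype=float)
    for i, mol in enumerate(log2fc.index):
        mtype = molecule_types[mol]
        over, under = thresholds.bounds(mtype)
        v = vals[i]
        over_hits = v > over
        under_hits = v < under
        if over_hits.sum() + under_hits.sum() < thresholds.min_samples:
            continue
        if over_hits.any() and under_hits.any():
            direction = "over" if v[np.abs(v).argmax()] > 0 else "under"
        elif over_hits.any():
            direction = "over"
        else:
            direction = "under"
        rows.append((mol, mtype, direction, float(np.abs(v).max())))
    if not rows:
        logger.warning("no differentially expressed molecules selected")
    de = pd.DataFrame(
        rows, columns=["molecule_id", "molecule_type", "direction", "max_abs_log2fc"]
    )
    return de.sort_values(
        ["max_abs_log2fc", "molecule_id"], ascending=[False, True]
    ).reset_index(drop=True)


def correlation_network(
    log2fc: pd.DataFrame,
    layer_name: str,
    rho_cut: float = 0.8,
    binary: bool = False,
    molecule_types: Mapping[str, str] | None = None,
) -> IntraOmicsNetwork:
    """Co-expression network from pairwise Pearson correlation of profiles.

    An edge joins two molecules when the absolute Pearson correlation of
    their log2FC profiles is strictly greater than ``rho_cut``; the edge
    weight is |rho| (or 1 with ``binary=True``).  Zero-variance profiles
    cannot be correlated and are left as isolated nodes.
    """
    mols = list(log2fc.index)
    if len(mols) < 2:
        logger.warning("layer %r: fewer than 2 molecules; empty network", layer_name)
        return IntraOmicsNetwork(layer_name, mols, dict(molecule_types or {}))
    vals = log2fc.to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError("profiles must have length >= 3 for correlation")
    sd = vals.std(axis=1)
    usable = np.flatnonzero(sd > 0)
    if usable.size == 0:
        logger.warning("layer %r: all profiles zero-variance; empty network",
                       layer_name)
        return IntraOmicsNetwork(layer_name, mols, dict(molecule_types or {}))
    if usable.size < len(mols):
        logger.info("layer %r: excluding %d zero-variance profile(s) from pairing",
                    layer_name, len(mols) - usable.size)
    rho = np.corrcoef(vals[usable])
    rho = np.atleast_2d(rho)
    edges = []
    for a in range(usable.size):
        for b in range(a + 1, usable.size):
            r = rho[a, b]
            if np.isfinite(r) and abs(r) > rho_cut:
                w = 1.0 if binary else min(abs(r), 1.0)
                edges.append((mols[usable[a]], mols[usable[b]], w))
    types = dict(molecule_types or {})
    return IntraOmicsNetwork.from_edges(layer_name, mols, edges, types)


def assemble_inter_omics(
    apriori: pd.DataFrame,
    de_sets: Mapping[str, Iterable[str]],
) -> list[InterOmicsNetwork]:
    """Filter a-priori cross-layer edges down to DE endpoints.

    ``apriori`` has columns source_id, target_id, weight, source_layer,
    target_layer; ``de_sets`` maps layer name to its DE molecule ids.  Edges
    are kept only when both endpoints are DE, grouped by unordered layer
    pair, with duplicates dropped.
    """
    de = {layer: set(ids) for layer, ids in de_sets.items()}
    grouped: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    kept = 0
    for r in apriori.itertuples():
        sl, tl = r.source_layer, r.target_layer
        for layer in (sl, tl):
            if layer not in de:
                raise KeyError(f"a-priori edge names unknown layer {layer!r}")
        if sl == tl:
            raise ValueError("a-priori edges must couple two distinct layers")
        if str(r.source_id) not in de[sl] or str(r.target_id) not in de[tl]:
            continue
        # canonical orientation: lexicographically smaller layer first
        if sl <= tl:
            pair, edge = (sl, tl), (str(r.source_id), str(r.target_id))
        else:
            pair, edge = (tl, sl), (str(r.target_id), str(r.source_id))
        w = float(r.weight)
        bucket = grouped.setdefault(pair, {})
        bucket[edge] = max(bucket.get(edge, 0.0), w)
        kept += 1
    if not grouped:
        logger.warning("no a-priori edges survive the DE filter")
    logger.info("a-priori edges kept after DE filter: %d of %d", kept, len(apriori))
    return [
        InterOmicsNetwork(pair[0], pair[1],
                          [(a, b, w) for (a, b), w in sorted(bucket.items())])
        for pair, bucket in sorted(grouped.items())
    ]
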