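# Methods

## Scope and model

`omicsembed` integrates measurements from several omics layers into one
embedding space by factorizing an exact random-walk PPMI matrix of a
multilayer network. The pipeline has four stages — differential
expression, network construction, embedding, downstream inference — each
usable on its own.

### Differential expression

For each molecule the log2 fold change of every test (stress) sample is
taken against the arithmetic mean of the control replicates:
`log2FC = log2((test + ε)/(mean_control + ε))`. The pseudocount ε defaults
to 0 and a zero denominator is a hard error directing the user to set a
positive ε; silently shifting abundances would distort fold changes
differently on each omics scale, so the shift must be explicit.

A molecule is DE when its log2FC clears a type-specific cutoff in at least
`min_samples` (default 1) test samples: ±2 for genes, ±1 for TFs,
metabolites and other molecule types. TF transcript levels vary less than
those of their targets, hence the lower TF cutoff. When a molecule clears
the cutoff on both sides across samples, the side of the largest |log2FC|
wins — an arbitrary but deterministic rule.

### Network construction

Within each layer, DE molecules are joined when the absolute Pearson
correlation of their full log2FC profiles (all test samples pooled) is
strictly greater than `rho_cut = 0.8`; the edge weight is |ρ| (a `binary`
flag sets weights to 1). Zero-variance profiles cannot be correlated and
are left isolated. Across layers, a-priori knowledge edges (TF–target,
gene/TF–metabolite) are kept only when both endpoints are DE; duplicates
collapse to their maximum weight.

The supra-adjacency matrix is the direct sum of the intra-layer blocks
plus the symmetrized coupling matrix. Each molecule lives in exactly one
layer (TF-coding genes in a `tf` layer separate from `gene`), all edges
are undirected, and isolated nodes are dropped before embedding so the
degree matrix is invertible.

### Embedding

With `P = D⁻¹Ā`, the matrix
`M = vol(G)/(bT) · (Σ_{r=1..T} Pʳ) · D⁻¹` is the expected windowed walk
co-occurrence ratio, and `S = max(log M, 0)` elementwise, with `log 0`
treated as −∞ before clamping, i.e. pairs never co-visited within `T`
steps stay exactly 0. The clamp at zero is the standard positive-PMI
convention; it keeps `S` finite and non-negative without an arbitrary
floor constant. Powers of `P` are accumulated explicitly (dense below 10⁴
nodes, sparse matmuls above), so the computation is exact — the package
deliberately avoids sampled walks and stochastic Skip-Gram training.

`S` is factorized by SVD (full below 500 nodes, truncated `svds` above)
and the embedding is `Ω_d = U_d √Σ_d`. Each singular vector's sign is
fixed so its largest-magnitude component is positive; this makes results
reproducible across linear-algebra backends and gives nested embeddings a
prefix property (the top-d′ columns of a d-dimensional embedding equal the
d′-dimensional embedding when singular values are distinct). Individual
embeddings remain rotation-ambiguous in degenerate subspaces; the
invariant surface is the similarity matrix `δ = Ω Ωᵀ`, which is
permutation-equivariant and is what downstream tasks consume.

Defaults `T = 3`, `b = 1`, `d = 128` are the recommended operating point;
the `grid-search` harness sweeps `T ∈ {1..5}`, `d ∈ {32, 64, 128, 256}`
for sensitivity analysis. The library errors when `d` exceeds the node
count; the CLI clamps it with a log note, since desk-scale networks are
often smaller than 128 nodes.

### Downstream tasks

**TF-target prediction.** The TF-target graph is restricted to its largest
connected component; per TF, half of its targets (floor, remainder to
train) are held out as test positives, and an equal number of non-edge
(TF, target) pairs is sampled uniformly without replacement, disjointly
for train and test. Negatives are restricted to TF×target pairs — the task
is typed, so arbitrary node pairs would be trivially separable. Edge
features are `average` `(Ωᵢ+Ωⱼ)/2` or `weighted_l2` `(Ωᵢ−Ωⱼ)²`; an
L2-regularized logistic regression (inverse strength 1.0, max 1000
iterations) is scored by average precision (AUPR). Splits are repeated
(default 10, seeds `seed..seed+9`) and mean ± sd reported. By default the
embedding is computed on the full graph and edges are split afterwards;
this mirrors the reproduce-first protocol but lets test edges influence
the embedding, so the split helper also accepts pre-restricted edge sets
for leakage-free evaluation.

**ION inference.** Raw dot products δ are unbounded, but thresholds are
conventionally quoted on [0.1, 0.9]; δ is therefore min–max normalized
over all unordered pairs before thresholding (`δ_norm > θ`, all-equal δ is
an error). Retained edges are sorted by descending `δ_norm`, ties broken
by ascending node-index pair for determinism. Precision@k counts reference
membership among the top k (unordered pairs); MCC classifies every pair at
each θ and uses the closed confusion-matrix formula with a zero
denominator mapping to 0.

**Module detection.** Clauset–Newman–Moore greedy modularity on the
thresholded ION treated as unweighted (thresholding already consumed the
weights); only modules with more than `min_size = 10` nodes are reported,
labeled A, B, … by decreasing size, together with the modularity value.

## Synthetic data generator

The generator emulates a stress time-course: one control and two stress
timepoints, four biological replicates, three layers (genes, TFs,
metabolites). Defaults — 200 genes, 30 TFs, 20 metabolites with DE
fractions 0.4/0.5/0.6 and 3 planted modules — are a roughly quarter-scale
version of a yeast heat-shock design with ~420 DE molecules in 6 modules,
keeping module sizes (~35 molecules) proportional.

Control abundances are log-normal (log2 base ~ N(6, 1.5)). Each DE
molecule in module *m* receives test-sample log2 offsets
`sign_m · eᵢ · traj_m[s]`, where `traj_m` is a module-shared latent
trajectory (per-timepoint level ~ U(0.7, 1), plus module-level per-sample
jitter sd 0.1) and `eᵢ` a molecule effect size (genes: mean 3, TFs and
metabolites: mean 1.5, sd 15%, floored at a quarter of the mean). TF
effects are deliberately smaller, mirroring the weaker variation of TF
transcripts, which is also why the DE cutoffs differ. Replicate noise of
sd 0.3 is added on the log2 scale everywhere. With zero noise,
within-module log2FC profiles are exactly collinear; module direction is
shared (80% up), so the |ρ| filter sees correlation 1.

A-priori TF–target and gene/TF–metabolite edges are drawn module-aware
with density 0.3 within and 0.01 across modules, only among DE molecules.
All draws derive from a single integer seed.

What the generator does **not** emulate: count-distribution realism
(negative binomial overdispersion), hub-dominated scale-free degree
structure of real regulatory networks, correlated replicate effects, or
partially observed a-priori knowledge (planted edges are complete and
noise-free). Passing tests therefore demonstrate algorithmic correctness
and recovery of idealized planted structure, not performance on real
omics data.

## Numerical choices and degenerate inputs

- PPMI symmetrized as `(S + Sᵀ)/2` after the matmul chain to remove float
  asymmetry (≤1e-12).
- `embed` uses a dense full SVD up to 500 nodes so that test-scale results
  are backend-independent; the truncated path re-sorts `svds` output into
  non-increasing order.
- Zero-degree nodes are a hard error in `compute_ppmi` (the fix —
  `drop_isolated_nodes` — is named in the message).
- Min–max normalization of δ is undefined when all pairwise similarities
  are equal; this raises rather than returning NaNs.
- Edge-sort and module-label ties always break lexicographically, and all
  sampling flows through `numpy.random.default_rng(seed)`, so every CLI
  run is bit-reproducible under a fixed `--seed`.

## Problem sizes

Tests and the acceptance script run the full pipeline on the default
generator scale (250 molecules, ~100-node networks), PPMI oracle checks on
random graphs up to 50 nodes, and walk-consistency checks with 10⁵
simulated walks on a 10-node fixture — sizes chosen so the whole suite
completes in seconds while still exercising every code path at full
fidelity.

## Known limitations

- The ION threshold θ is quoted after min–max normalization, whose scale
  depends on the extreme similarity pair; on small networks the useful θ
  range sits lower than on large ones (the acceptance run reports module
  statistics both at the default θ = 0.7 and at the MCC-optimal θ for this
  reason).
- The `average` edge-feature operator carries less information than
  `weighted_l2` on module-structured graphs: within-module non-edges are
  nearly indistinguishable from within-module edges by averaged
  coordinates alone, which caps its AUPR well below the `weighted_l2`
  score on the synthetic study (0.72 vs 0.90).
- Default split mode embeds before splitting (see above); use
  pre-restricted edge sets when leakage-free protocol matters.
- No multiple-testing-corrected DE statistics: selection is a pure fold
  change filter by design.
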