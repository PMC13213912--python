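# Methods

## Representation

Molecules are parsed from SMILES with RDKit; the canonical SMILES is the
identity used everywhere downstream, so descriptor computation is a pure
function of structure and never of input order. Unparseable lines are
counted and skipped, never fatal — a billion-line library will contain a few
bad rows and a streaming pipeline must survive them.

Three representations are computed:

- **MQN** (molecular quantum numbers): 42 non-negative integer counts of
  atom types, bond types, polar groups and topological features, taken
  directly from RDKit's implementation with no scaling or centering. MQN is
  the embedding that gets compressed and clustered; its low dimensionality
  and integer structure are what make product quantization effective.
- **ECFP4**: radius-2 circular substructure fingerprints folded to 2048 bits
  by default (configurable power of two), compared by Tanimoto similarity.
  Used only for the secondary (within-cluster) maps, where substructural
  resolution matters and the cluster is small enough for exact search.
- **Descriptor panel**: MW (g/mol), heavy-atom count, ring count, rotatable
  bonds, H-bond donors/acceptors, TPSA (Å²), fraction of sp³ carbons, and
  aromatic-atom count — used for dispersion diagnostics and node colouring.

## Product quantization

Each 42-dimensional vector is split into m = 6 contiguous subvectors of
dimension 7 (m must divide 42; 6 balances code length against quantization
error for this descriptor). Per subspace, a codebook of L = 256 codewords is
trained by k-means (k-means++ initialization, Euclidean distance, 20
iterations; delegated to scikit-learn's KMeans). L = 256 lets each index fit
one unsigned byte, so a molecule compresses to 6 bytes — 7-fold versus the
42 counts.

Encoding assigns each subvector to its nearest codeword by squared Euclidean
distance computed directly (not via the BLAS inner-product expansion, whose
rounding can flip exact ties); ties resolve to the lowest codeword index, so
encoding is fully deterministic. Encoding is batched (default 100,000 rows)
so peak memory is set by the batch, not the library.

Count data routinely has fewer distinct subvectors than L, in which case
k-means converges with duplicate codewords; this is a benign fixed point and
is left as-is.

**Symmetric distance.** SD between codes a and b is
√(Σⱼ Tⱼ[aⱼ, bⱼ]) where Tⱼ is the precomputed L×L matrix of squared
codeword distances in subspace j. The square root makes SD unit-compatible
with the Euclidean distance on the original vectors; for codeword-exact
vectors the two coincide exactly. Whether to report the root or the squared
form was an open choice; the root convention was adopted so SD and Euclidean
distance can share an axis in fidelity plots.

## PQk-Means

Clustering operates entirely on codes. One Lloyd iteration is:

- **Assignment**: each code to the centroid code with minimal SD, computed
  by accumulating per-subspace table lookups; ties to the lowest centroid
  index.
- **Update**: for each cluster and subspace independently, the new centroid
  index is argmin over all L codewords of the summed squared table distance
  to the members' indices — evaluated as (member-index histogram) × (L×L
  table). Because the squared-SD objective is separable over subspaces this
  is the exact minimizer, so the objective (sum of squared SD to assigned
  centroid) is non-increasing; the iteration log asserts it.

Initialization is greedy k-means++ in code space under SD: each new seed is
chosen among 2 + ⌊ln k⌋ candidates drawn from the d² distribution, keeping
the candidate with the lowest resulting potential. The greedy variant (the
same one standard k-means++ implementations use) markedly reduces the chance
of seeding two centroids inside one natural cluster, which matters when the
requested k matches the data's true cluster count.

The iteration cap defaults to 20 with early stop on stable labels; the cap,
like k itself, is a configuration choice. Empty clusters are left in place
during fitting and dropped afterwards by `compact`, which densely re-indexes
labels — at scale a sizeable fraction of requested centroids typically ends
up unpopulated, and the atlas is built over the populated ones only.

Streaming `predict` processes codes in bounded-size batches and is
bit-identical for any batch partition. The per-cluster **representative** is
the member with minimal SD to the centroid, ties to the lowest molecule id.

## Order invariance

Input files for large libraries often arrive sorted (e.g. by heavy-atom
count), and seeded k-means++ is order sensitive. Both estimators therefore
sort their training rows lexicographically before fitting, making every
trained model a pure function of the training *multiset*: shuffled and
sorted inputs of the same library produce identical codebooks, centroids and
final cluster contents (when training uses the full data, as the desk-scale
defaults do; a seeded subsample reintroduces order sensitivity through index
selection and is off by default). The pipeline still shuffles and re-shards
input first — shard-level streaming statistics and logs are more informative
on permuted data — but correctness no longer depends on it.

## Tree-maps

A map is built as kNN graph → minimum spanning tree → 2D layout:

- **kNN graph** (default k = 10): exact mode is the reference contract — a
  chunked all-pairs scan with stable lowest-index tie-breaking, symmetrized
  (an edge is kept if either endpoint lists the other). An approximate mode
  (a seeded random-projection forest with exact re-ranking) is available for
  large maps and is validated by neighbor recall ≥ 0.9 against exact search
  on test sizes.
- **MST** via scipy's sparse solver. Stored weights are shifted by a
  constant inside the solver so genuine zero-weight edges (duplicate
  molecules) are not dropped as absent entries; the shift cancels because
  every spanning tree has n − 1 edges. If the kNN graph is disconnected,
  components are joined beforehand by the minimum-distance inter-component
  pairs (exact search over members, component-level MST selects the
  bridges), so two far components gain exactly one bridging edge.
- **Layout**: deterministic radial embedding — root at node 0, angular
  wedges proportional to subtree leaf counts, radius equal to depth, small
  seeded angular jitter. Only topology and determinism are contractual;
  coordinates are presentation.

The primary map uses Euclidean distance on the representatives' MQN vectors
and carries the descriptor panel as colour channels; secondary maps use
Tanimoto distance on members' ECFP4 fingerprints. Single-member clusters
yield one-node maps. `assemble_atlas` validates the linkage (every primary
node resolves to exactly one secondary map, no dangling maps) and
conservation (secondary node counts sum to the dataset size). The atlas
persists as a JSON bundle; interactive hosting is out of scope.

## Quality diagnostics

- **SD vs Euclidean**: paired distances from every sample vector to a fixed
  reference, with Pearson r and through-origin slope.
- **Within/between distances**: a fixed sample design (default 100 clusters
  × 10 molecules at scale; any feasible design on fixtures) with exhaustive
  pairs inside and across the sampled clusters, for Euclidean-MQN,
  Manhattan-MQN and SD-PQ metrics. Between-cluster pairs are exhaustive
  cross-cluster pairs over the sample (the design choice where resampling
  would also have been defensible).
- **Heatmap**: the block-ordered pairwise-distance matrix over such a
  sample, exported as CSV; plotting is a thin optional layer.
- **Dispersion**: per cluster and per panel descriptor, the coefficient of
  variation (population σ/μ), IQR and range (max − min, untrimmed), reported
  as 5th/median/95th percentiles across clusters with linear interpolation
  between order statistics. Clusters with zero mean are excluded from that
  descriptor's CV and counted in a flag column — small-mean count
  descriptors (HBD-like) otherwise show huge CV tails that reflect the
  division, not real spread; IQR and range are the reliable statistics
  there.

## Synthetic data

Two generators make every stage testable offline:

- **SMILES library**: seeded enumeration of ~23 scaffold templates (0–4
  rings) × ~27 substituents, validated with RDKit and filtered to
  MW ≤ 500 — emulating a drug-like combinatorial library. Duplicates are
  allowed, as in real enumeration. The library spans at least five ring
  counts so MQN space is non-degenerate, but it is *not* chemically
  representative of any vendor catalogue: passing tests show the machinery
  is correct, not that cluster contents would look like a specific
  commercial library's.
- **MQN blobs**: k integer centers drawn uniformly in a configurable box,
  rejection-sampled to enforce a minimum pairwise distance of
  `separation × spread × √42`; members add per-coordinate rounded Gaussian
  noise (σ = spread) truncated at zero, so every vector remains a valid
  count vector. Ground-truth labels are returned for recovery tests. The
  default separation of 5× spread is the regime in which exact label
  recovery (ARI = 1) is the correct expectation; real libraries are not
  separated like this, so recovery results on blobs bound the best case,
  not the typical one.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script:
oracle-equivalence checks on n ≤ 2,000; blob recovery at n = 10,000, k = 10;
quantization fidelity on a 20,000-molecule synthetic library; the end-to-end
pipeline on 2,000 molecules with k = 20 and L = 64 (L is lowered where the
input has far fewer distinct subvectors than 256). These sizes exercise
every code path, including sharding and batched streaming, while keeping a
full run in minutes on one CPU; the algorithms themselves are written so
memory scales with batch/shard size, not library size.

All tie-breaks (nearest codeword, nearest centroid, codeword vote,
representative) resolve to the lowest index. All randomness flows through
explicit integer seeds. Distances are computed directly rather than via
inner-product expansions wherever ties are semantically meaningful.

## Known limitations

- No GPU path; CPU is the reference execution contract.
- Approximate kNN is a simple projection forest, not a tuned LSH forest;
  it is validated only by recall against exact search.
- No salt stripping or standardization beyond RDKit parsing; inputs are
  taken as given.
- The atlas is a static JSON bundle; no interactive web front end.
- Asymmetric distance computation (ADC), OPQ rotations and inverted-file
  indexes are out of scope.
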