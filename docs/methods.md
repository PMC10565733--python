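# Methods

## Distances and clustering

Isomorphism between two chunks is quantified by the Pearson correlation
coefficient (CC) of intensities over their common unique reflections. Common
reflections are found by reducing indices to a canonical representative
(lexicographically greatest image under the point-group rotations and Friedel
inversion; the default operator set is the identity because integrated chunk
files normally arrive already reduced, with built-in sets for point groups 2
and 222) and intersecting the two filtered index sets. Each chunk is filtered
with its own unit cell when a high-resolution cutoff `d_min` is given, and a
pair must share at least `min_common` reflections (default 3) for its CC to
be usable. A pair whose paired intensity vector is constant is flagged
degenerate rather than given a CC.

Three distance transforms are provided — 1 − CC, (1 − CC)^½ and
d_CC = (1 − CC²)^½ — with d_CC the default used throughout; it maps
CC ∈ [−1, 1] onto [0, 1] and at CC = 0.97 evaluates to 0.243.

When assembling a full matrix, chunks that cannot be compared with the others
are removed greedily: while any invalid pair remains, drop the chunk with the
most invalid pairs (ties broken by lexicographically smallest chunk id) and
record it with a reason. This deterministic rule retains as much data as a
simple strategy can; fewer than three mutually comparable survivors is a hard
error.

Agglomeration uses `scipy.cluster.hierarchy.linkage` on the condensed
distance vector. Ward linkage is the default, treating d_CC as a
Euclidean-like dissimilarity even though Ward's Euclidean assumption is not
formally met — this mirrors how the established multi-crystal merging
pipelines apply it, and keeps heights directly comparable with theirs. All
seven standard Lance–Williams methods are exposed; centroid and median can
invert (the `Dendrogram.has_inversions` flag reports this). Tie-breaking on
equal merge distances follows scipy's deterministic ordering.

## The isomorphic threshold

With W₀ the dendrogram root height and W₁ the larger height of the root's two
children, the isomorphic threshold is R·W₀ with R a dimensionless ratio in
(0, 1). Candidate polymorph clusters are the *maximal* nodes whose height is
at or below the threshold — maximal-node semantics rather than a flat cut, so
a candidate is reported at the node where it diverges. Nodes smaller than
`min_cluster_fraction` of the leaves (default 0.05) are reported as outliers
instead of candidates: small, internally spread clusters are typically
low-quality chunks (e.g. from crystal tips), not polymorphs. An empty
candidate list is a legal outcome meaning "no polymorphs detected". The
default reporting interval is R ∈ [0.6, 0.7].

## Monte-Carlo calibration

The calibration engine models the observed pairwise CC values of a
two-structure chunk mixture with three Gaussian components — within-A,
within-B and between — each summarised by a median and standard deviation
fitted after restricting to the prominent peak d_CC < 0.4 (CC > 0.9165);
observed CC distributions have a long low tail from poor chunks which would
otherwise corrupt the fit. The packaged `TRYPSIN_MODEL` carries the medians
0.978 / 0.970 / 0.962 and SDs 0.020 / 0.019 / 0.017 measured on an
apo/inhibitor-bound trypsin chunk mixture.

`sample_cc_matrix` draws one CC per unordered pair, independently, from the
Gaussian of the pair's class, clips to ±(1 − 10⁻⁶) (the clip keeps Gaussian
tail draws off |CC| = 1, whose distance would be exactly zero), transforms to
d_CC, and symmetrises. `run_simulation` repeats sample → Ward → (W₀, W₁,
R = W₁/W₀, score) with per-replicate child seeds spawned deterministically
from the master seed. The classification score cuts the tree at its k−1
highest merges (k = 2 by default) and reports the best-assignment accuracy
(Hungarian matching of flat clusters to true labels); this is the natural
operationalisation of "were the two structures recovered as labelled", since
the exact score formula used alongside the published threshold is not
specified in the available text. The default validation run uses two groups
of 42 and 41 (83 data sets; the group split in the motivating data is not
printed, so it is a parameter).

`approach_sweep` degrades the model stepwise: step *s* of *S* moves the
between-structure median linearly toward the within-B median by s/(S−1), so
the last step has coincident locations and classification fails by
construction. Linear interpolation of the location, with spreads held fixed,
is the simplest one-parameter path between "fitted model" and
"indistinguishable structures"; the per-step schedule of the original
calibration is not specified in the available text. For each (step, n) the
sweep records the mean observed R and mean score over replicates, and
`recommend_ratio` returns the interval of observed R over sweep points with
n ≤ 500 ("several hundred data sets") whose mean score clears the 0.9
success threshold.

### What the pair-independent sampler does and does not reproduce

Under this sampler the 100-replicate mean of W₁ for the packaged model is
≈ 0.55 (SD ≈ 0.022) and the mean two-cut score is ≈ 0.94: the information for
a perfect split is present in every sampled matrix (assigning each data set
to the group with the smaller mean distance is error-free), but greedy Ward
agglomeration occasionally locks a minority of leaves into the wrong branch
because the *pair-level* noise implied by the fitted SDs is large
(SD ≈ 0.09 in d_CC against a between−within gap of 0.03–0.06). Real d_CC
matrices are not pair-independent — their fluctuations are dominated by
chunk-level quality, which cancels in comparisons — so the sampler is a
conservative stress test: scores it reports are a lower bound on what the
same model parameters yield for consistently structured matrices. For the
same reason W₀ grows like √n with the data-set count while W₁ grows slowly,
so the observed ratio R = W₁/W₀ at fixed overlap decreases with n in this
simulation.

## Synthetic reflection data

The generator emulates the chunked helical study conditions: two latent
structures over `n_unique` reflections (default 50 000), per-chunk
completeness 0.4, 48 chunks per structure (four crystals × twelve 30°
chunks), within-structure CC 0.97 and between-structure CC 0.96.

Latent intensities are exponential (Wilson acentric) with mean Σ; the second
structure is the mixture I_B = (a·I_A + I′)/(a + 1) with I′ independent
exponential, so corr(I_A, I_B) = a/√(a² + 1) exactly. Each chunk observes a
uniform-random index subset of size `completeness·n_unique` with additive
Gaussian noise of variance Var(I)(1 − ρ_w)/ρ_w, which makes the expected CC
between two chunks of one structure equal ρ_w, and the expected
between-structure chunk CC equal ρ_latent·ρ_w; the latent correlation
therefore has the closed form ρ_latent = ρ_b/ρ_w. Unit-cell lengths are
jittered by 0.05% per chunk. The Miller index set is the `n_unique`
lowest-resolution half-sphere indices of the (trypsin-like, orthorhombic
54.7 × 58.5 × 67.4 Å) cell, generated deterministically. An optional
noise multiplier on the last chunk of each crystal can emulate degraded
crystal-tip chunks; it defaults to off and is an extrapolation, not a claim
about real tip behaviour.

What the generator does *not* model: diffraction geometry (chunk completeness
is a random subset, not a wedge), radiation damage, scaling errors,
non-isomorphism of unit cells beyond isotropic jitter, and the low-CC outlier
tail of real data. Passing tests therefore demonstrate the statistical
machinery (CC estimation, exclusion, clustering, thresholding) at realistic
correlation levels, not robustness to every real-data pathology. With ~2 000
observed reflections per chunk, two chunks share ≈ 800 common reflections and
the CC estimation error (≈ 0.002) is far below the 0.01 within/between
separation, so ground-truth recovery is expected and observed in ≥ 95% of
seeds; the null (single-structure) configuration yields no spurious
candidates provided the common-reflection count keeps the CC noise below the
threshold gap, which holds at the study's overlap scale (thousands of common
reflections) but not for drastically down-scaled chunks.

## Unit-cell clustering

Cells are screened per parameter with Tukey's rule (reject outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]); with fewer than four cells the filter passes
everything through with a warning. Cells are then represented by their three
face diagonals — the *longer* parallelogram diagonal of each face,
max over sign of √(a² + b² ± 2ab cos γ) and cyclic permutations — a fixed
convention adopted because the linear-cell-variation (LCV) literature does
not pin down the choice. LCV is the maximum over pairs and faces of
100·|dᵢ − dⱼ|/min(dᵢ, dⱼ); the cell distance feeding the dendrogram is the
Euclidean distance between face-diagonal triples in Å.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| chunk width | 30° | angular chunk size for splitting helical sweeps |
| `min_common` | 3 | minimum common reflections per CC pair |
| metric | (1 − CC²)^½ | distance transform |
| linkage | ward | agglomeration method |
| R interval | [0.6, 0.7] | isomorphic-threshold ratio |
| `min_cluster_fraction` | 0.05 | below this, a candidate is an outlier |
| d_CC fit cutoff | 0.4 | peak restriction for CC-model fitting |
| score threshold | 0.9 | classification success level |
| CC clip | 1 − 10⁻⁶ | sampling bound at the |CC| = 1 boundary |

Trailing partial chunks shorter than half a chunk width are discarded (and
flagged in provenance) so chunk CC sample sizes stay comparable. Duplicate
observations merge by inverse-variance weighting, falling back to the plain
mean when a σ = 0 observation is present. The d_CC < 0.4 fit filter, the
greedy exclusion rule, and maximal-node candidate semantics are the package's
resolutions of genuinely open design points; each is documented at the
implementation site.

Test and acceptance problem sizes are chosen for desk-scale runs: synthetic
data sets use 2 000–20 000 unique reflections instead of 50 000 (CC sampling
error scales as the inverse square root of the common-reflection count, so
conclusions transfer), and sweep replicates default to 10 per grid point.
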