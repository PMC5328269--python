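# Methods

This note documents the models, numerical conventions, and design choices
behind `annealboost`, and what the synthetic-data generators do and do not
emulate.

## Feature extraction

Scenes are four co-registered reflectance channels in [0, 1] (8- or 16-bit
integer rasters are divided by their full-scale value on read; NaN pixels
are rejected). RGB is converted to hue/saturation/intensity with the
classic HSI model — I = (R+G+B)/3, S = 1 − 3·min(R,G,B)/(R+G+B), hue from
the arccos chromaticity formula scaled to [0, 1) — with achromatic pixels
assigned hue 0 and saturation 0 so every statistic downstream is defined.
Scenes are tiled into non-overlapping 8×8 blocks; partial blocks at the
right/bottom margins are dropped; a block's label is the majority vote of
its pixel labels, ties breaking positive.

The default catalog has 112 features. Per channel in {hue, saturation,
intensity, NIR}: six order statistics (mean, population std, skewness,
excess kurtosis, min, max — skewness/kurtosis of a constant block defined
as 0), nine co-occurrence statistics, and twelve mid-frequency DCT
coefficients; plus the four vegetation indices. Composition choices:

- **Co-occurrence matrices**: each block's value *range* is quantized
  uniformly into 8 levels (64-pixel blocks cannot support finer bins), and
  pairs are accumulated symmetrically over the four distance-1 directions,
  normalized to sum 1. A constant block puts all mass on one diagonal cell.
  The statistics (1-based level weights, entropies in bits, 0·log 0 := 0)
  are entropy, angular second moment, energy = √ASM (kept as a separate
  feature: the square root is monotone, so the two train identical stumps
  but remain distinct catalog entries), autocorrelation, sum-of-squares
  variance, sum entropy, homogeneity, contrast, and correlation (0 when a
  marginal has zero variance). Matrices come from
  `skimage.feature.graycomatrix`; the statistics are computed here.
- **DCT**: orthonormal type-II 2-D transform; the default mid-frequency
  band is the twelve (u, v) with 2 ≤ u+v ≤ 4, excluding DC — low enough to
  survive 8×8 support, high enough to carry canopy texture. Configurable.
- **Vegetation indices**: NDVI = (NIR−R)/(NIR+R), SR = NIR/R,
  EVI = 2.5(NIR−R)/(NIR+6R−7.5B+1) (G = 2.5, C1 = 6, C2 = 7.5, L = 1),
  ARVI = (NIR−(2R−B))/(NIR+2R−B) (γ = 1), from block band means.
  Denominators are clamped to magnitude ≥ 1e−6 preserving sign, so indices
  are always finite.
- **Hue circularity**: moments and co-occurrence statistics treat hue as a
  linear [0, 1) variable. This is a known limitation — hue wraps — accepted
  because the red/magenta boundary is rare in vegetation scenes and the
  stumps only need monotone separability.

Extraction is deterministic: identical scene + catalog give a bit-identical
table.

## Weak classifiers

Linear stumps threshold one feature, (x_i − b⁺) ≥ 0, with a mirrored
orientation (−x_i − b⁻) ≥ 0; quadratic stumps apply the same rule to the
product x_i·x_j. Training minimizes unweighted 0-1 error exactly over the
midpoints of consecutive distinct sorted values plus ±∞ sentinels — one
sort and one cumulative pass, O(|T| log |T|). Among equal-error thresholds
the smallest wins (determinism). Both orientations are independent
candidates, giving 2F linear and 2(F + F(F−1)/2) linear-plus-quadratic
candidates. Errors are unweighted despite class imbalance. Constant-feature
(degenerate) stumps collapse to the better constant classifier and are
flagged; they survive filtering only on the same error < 0.5 condition as
everything else. Survivors are ordered by ascending training error (ties by
feature indices, then orientation), which fixes the spin indexing and makes
embeddings reproducible; their outputs are renormalized to ±1/N with N the
survivor count.

For quadratic expansion at scale, a feature subset is chosen by three
pools: the n/3 features whose best surviving quadratic stumps have the
lowest training errors, the n/3 with the highest surviving errors, and the
remainder filled greedily to minimize the maximum pairwise output
correlation against the already-selected set (each feature represented by
its best stump). The exact mixing of these criteria is a design choice;
the intent is a set of weak classifiers expressing diverse opinions.

## The training objective and its Ising form

With outputs c_i(t) ∈ {−1/N, +1/N}, the regulated quadratic loss is
L(w) = Σ_t (Σ_i w_i c_i(t) − y(t))² + λ Σ_i w_i, λ = 2f|T|/N. Substituting
s = 2w − 1 and using w² = w gives fields and couplings

    h_i  = −λ/2 + Σ_t c_i y − ½ Σ_{j,t} c_i c_j      (j runs over ALL j, including j = i)
    J_ij = −½ Σ_t c_i c_j ,

plus a constant offset that this package computes and stores, so
L(w) = H(s(w)) + offset holds as an exact identity — enforced exhaustively
in tests for N ≤ 12. The inclusion of j = i in the field sum is forced by
the w² = w reduction; the affine-equivalence test is what certifies it.
Two consequences used as test anchors: J is independent of λ (so one
embedding serves a whole regulator scan), and perfectly correlated stumps
have J = −|T|/(2N²) exactly. An alternative ±1/√N output normalization
(which suppresses couplings by 1/N relative to the fields, easing regulator
tuning on fully connected problems) is available as
`build_ising(..., normalization="sqrt")`; the ±1/N convention is the
default throughout because it keeps every vote-sum margin in [−1, 1].

## Chimera graphs, embedding, renormalization

C(m, n, k) is an m×n lattice of complete-bipartite K_{k,k} cells; one
partition of each cell links to the vertically adjacent cells, the other
horizontally, so the defect-free maximal degree is k+2 and the edge count
is mnk² + k(n(m−1) + m(n−1)). Vertices are numbered cell-major,
partition-major. Defective qubits are removed with their edges; a
convenience generator draws a given defect count uniformly at random.

The one-spin-per-qubit greedy embedding processes spins in descending total
coupling weight Σ_j |J_ij| (ties by spin index); the first spin takes the
highest-degree functioning qubit (ties by lowest index); each later spin
takes the free qubit maximizing the summed |J| to already-placed neighbors
(ties by lowest qubit index). The ordering and tie-breaks are fixed so the
pipeline is reproducible; they are one reasonable instantiation of the
greedy objective, not a claim of optimality. The embedding accepts any
networkx target graph — embedding into a complete graph is the lossless
reference case used by the planted-recovery tests. Renormalization
restricts couplings to the embedded edges and multiplies them by α; fields
are never rescaled, and the full problem is left untouched.

A spin is *decoupled* when |h_a| strictly exceeds the summed magnitudes of
its retained couplings; its optimal value is then sign(h_a) regardless of
the rest of the configuration (verified against exhaustive ground states).
The `scaling_report` diagnostic shows why α exists: under a degree-k
truncation (an edge is kept when it ranks in the top-k |J| of both
endpoints — a symmetric proxy for a degree-k hardware graph) the decoupled
fraction approaches 1 as N grows at fixed k, and α ~ N/5 restores
competition between fields and couplings. The diagnostic is meaningful at a
working regulator (f near the mean stump-label correlation); at f = 0 the
label-correlation term dominates every field and the comparison is
uninformative.

## Simulated annealing

The solver follows a fixed protocol: random ±1 start; starting temperature
T₀ = max single-flip |ΔE| from the initial configuration; linear schedule
from T₀ to exactly 0 over at most 2000 temperature steps; N single-spin
Metropolis proposals per step, spins chosen uniformly with replacement;
early stop once the running energy is unchanged at three consecutive
temperature steps. The stopping rule reads "no change in energy" as the
*current* energy having frozen — the alternative (best-seen energy
unchanged for three steps) terminates anneals within a handful of steps at
high temperature, long before the schedule cools, and measurably fails to
reach exact optima on small instances; the frozen-system reading matches
the physical intent of an annealing schedule. Energies are maintained
incrementally via local fields (ΔE = 2s_i(h_i + f_i)) and the returned
best-configuration energy is recomputed exactly. The kernel is a numba
routine over a dense coupling matrix — dense is the right representation up
to the few-hundred-spin problems this pipeline produces.

One anneal call is one read. Pools aggregate n independent reads with
per-read seeds derived from the master seed through numpy's SeedSequence
(children are prefix-stable, so read sets nest and pooled best energy is
monotone in the read count); distinct configurations are deduplicated with
multiplicities. Exhaustive enumeration (guarded at N ≤ 24, chunked) returns
every tied optimum in lexicographic order and serves as the ground-truth
oracle.

## Training orchestration

Each (α, f) cell builds the Ising problem, applies the fixed embedding
(computed once per ensemble — valid because J does not depend on f),
rescales by α, samples a solver pool, decodes every distinct configuration
into a candidate classifier (w = (s+1)/2), and keeps the candidate of
minimal validation error; ties break by lower energy, then smaller
cardinality, then lexicographic weights. Selection by validation matters
because annealing samples low-lying states rather than returning a unique
optimum, and the quadratic loss is an imperfect proxy for 0-1 error: the
minimal-energy state need not have minimal validation error.

The default grids step α by factors of 2 from N/64 to N (entries are
arbitrary expressions in N, so non-power-of-two refinements like N/5 are
expressible) and f from 0.1 to 1.0 in steps of 0.1, refined locally when
needed. The bias B is the mean of the signed outputs of the unbiased
classifier on a class-balanced set (the majority class is subsampled,
seeded); averaging raw margins instead is exposed as an option, but votes
are what the classifier thresholds, so the sign convention is the default.
sign(0) := +1 everywhere. Splits mirror a 24000/3000/3000
train/validation/bias proportion, scaled down for synthetic runs.

## Synthetic data

`generate_scene` emulates 1-m 4-band aerial imagery at the level that
matters for this pipeline: a blobby tree mask (smoothed thresholded noise,
quantile-cut to the target cover fraction), class-dependent band means
(trees dark green and NIR-bright; grass, soil and built surfaces
progressively NIR-poor), Gaussian-filtered texture with class-specific
correlation lengths (short-wavelength canopy texture vs smooth background),
a per-band low-frequency illumination/moisture field, optional shadow
darkening, and white pixel noise. The illumination field is the key
realism ingredient: iid pixel noise averages out over an 8×8 block, so
without broad brightness gradients the class band-means would be almost
perfectly separable at block scale. Defaults are calibrated so that on a
512×512 scene at 40% cover the achieved block-level positive fraction is
within 0.05 of target and the trained stumps sit in the weak-classifier
regime (best per-feature error and mean surviving error both within
[0.10, 0.40]). The generator does **not** emulate radiometric calibration,
atmosphere, georeferencing, or real canopy geometry — passing tests
demonstrate the pipeline's mechanics and its qualitative boosting behavior,
not production accuracy on real imagery. Scene labels are pixel-level;
block labels arise through the majority rule, so label noise at canopy
edges appears naturally.

`generate_planted_ensemble` draws abstract ±1/N output matrices: balanced
labels, per-stump flip probabilities 1 − accuracy, and correlation blocks
that share an error source with a mixing weight. For N ≤ 16 the generator
*certifies* the planted subset by exhaustive enumeration of all 2^N weight
vectors: it checks the subset is the unique minimizer of the unregulated
loss at its cardinality and computes the exact open λ window in which it is
the global optimum (from the loss gaps to subsets of other cardinalities),
returning a regulator fraction f★ inside that window. Draws that fail
certification are retried with fresh child seeds and generation errors out
rather than emitting an unverified instance.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to exercise every
mechanism with exact oracles: exhaustive checks at N ≤ 12–16, decoupling
verification at N ≤ 14, solver-equivalence at N = 12 with 20 reads, scene
experiments at 256×256/160×160 with 16-stump ensembles under the exact
solver, and scaling diagnostics up to N = 512. Floating-point tolerances:
the affine identity is asserted at 1e−9 relative; co-occurrence
normalization at 1e−12; pool energies are consistent with exact
recomputation at 1e−9. All randomness flows from explicit integer seeds;
derived seeds stay below 2³¹.

## Known limitations

- Hue statistics ignore circularity (above).
- The greedy embedding has no restarts; different tie-break policies give
  different (valid) embeddings with slightly different retained densities.
- Minor embedding via qubit chains with ferromagnetic intra-chain couplings
  is out of scope, as are higher-order losses and their quadratization.
- The simulated annealer is a classical stand-in for annealing hardware;
  no wall-clock or sampling-distribution comparison to physical devices is
  attempted.
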