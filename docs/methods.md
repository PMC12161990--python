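# Methods

This note records the modelling and numerical choices behind the package:
what each stage assumes, which parameters matter and why their defaults are
what they are, what the synthetic data does and does not emulate, and where
the design was genuinely open.

## Simulator

**Geometry.** Tissue is a rectangular grid of spots with 0-based integer
`(row, col)` coordinates; distances are Euclidean on those raw integers.
Regions are circles or axis-aligned rectangles, pairwise disjoint.  The
bundled three-region layout scales two circles (tumour, normal) and one
rectangle (ductal) with the grid so the same scenario runs at 50×50
(2500 spots) or desk scale (30×30).

**Mixing model.** A spot inside a region is pure: regions model homogeneous
cell populations, and the inverse-distance affinity is undefined at distance
zero, so in-region spots take proportion 1 for their region.  For an
out-of-region spot the affinity to region *r* is the inverse of the distance
to the region's nearest spot plus Gaussian noise with SD `noise_sd`
(default 0.05), clipped below at 1e-6 to stay positive, then normalised
across regions.  The noise subscript is per region; a constant offset per
region would be absorbed by the normalisation, so the draw is independent
per (spot, region) pair with the per-region SD.

**Counts.** Proportions become integer cell counts by flooring
`cells_per_spot × proportion` (flooring, rather than rounding, guarantees
the total never exceeds `cells_per_spot`).  A row that floors to all zeros
receives one cell of its largest-proportion type (ties to the lowest type
index) — otherwise the renormalisation that defines the saved ground truth
would divide by zero.  Ground truth at region level is the renormalised
count table; at fine level it tallies the fine labels of the cells actually
drawn, so the two levels are consistent by construction.

**Expression.** Per spot and region-level type, the simulator draws the
required number of distinct cells from the reference (an override allows
replacement when the reference is small) and retains each read of each
drawn cell independently with probability `downsample_rate` (default 0.10).
Binomial thinning was chosen over exact read subsampling: it is the standard
model of uniform read loss, is exactly mean-preserving
(E[retained] = rate × library), and factorises per gene.  The 10% default
keeps simulated spot libraries at the depth of a typical Visium spot given
the reference depth below.

**Infiltration.** A fraction (default 0.10) of the *pure* tumour spots is
selected uniformly without replacement; each receives an immune proportion
drawn from N(0.5, 0.2) truncated to the open interval (0, 1) by rejection
(the truncation rule is the package's choice; out-of-range draws had no
stated handling).  Truncation at these parameters is mild: it leaves the
mean at 0.5 exactly (symmetric) and shrinks the SD to 0.1909.  The injected
immune cell count is `max(1, floor(q × cells))` and *substitutes* tumour
cells, keeping the spot's total cell count fixed — the alternative
(appending immune cells on top) would let totals exceed the per-spot
capture capacity.  Ground truth is re-derived from the updated counts.

## Region extraction

Counts are divided by the spot library, scaled by the median library, and
log1p-transformed; the embedding is the first `k_pcs` (default 10)
principal components with a deterministic sign convention (each component's
largest-magnitude loading is positive), so repeated runs agree exactly.

The spot graph connects grid neighbours under `neighbor_scheme`
(`grid4` default; `grid8` and `hex6` available because square simulated
grids and hexagonal Visium arrays differ — adjacency was an open choice and
is exposed rather than hard-coded).  Edge weight is the Pearson correlation
of the two spots' embeddings, kept in [−1, 1]; a constant embedding row
gets weight 0.  Geometrically, pure spots of a type sit far from the
embedding origin and correlate strongly with one another, while ambiguous
mixture spots sit near the origin where sampling noise dominates — their
edges are weak, and it is this weak "mixture sea" that the threshold cuts.

ε is selected by scanning percentiles 50–99 of the edge-weight
distribution: for each candidate the coverage is the fraction of spots in
components of size ≥ m; among candidates yielding at least two regions the
chosen ε is the largest whose coverage is within 0.05 of the best, falling
back to the maximum-coverage candidate when no threshold separates the
tissue.  A manual `epsilon` override is available.  Components with at
least `min_region_size` spots (m, default 40 — the Visium-scale default)
become regions with deterministic ids ordered by size then smallest member;
"at least m" is used (the boundary case is immaterial at m = 40 but
documented).

**Boundary erosion.** The coverage-maximising ε necessarily annexes a rim
of near-pure mixture spots around every region.  Because the whole point of
the pseudo-internal reference is to leave likely mixtures out, the pipeline
erodes one ring of boundary spots (spots adjacent to a different label or
to unassigned spots) from each region before building Ω
(`omega_erosion=1`; a region that erosion would erase keeps its spots).
The reported region assignment is not eroded — erosion only filters the
reference material.  On the 30×30 three-region fixture this raises mean Ω
purity from 0.93 to 0.97 and roughly halves the mean per-spot KL of the
final estimates while leaving the median correlation unchanged.

## Deconvolution

Ω rows are the expression profiles of (eroded) region spots labelled with
region-level types.  Signatures are per-type means of library-normalised
rows, restricted to the union of the top `n_top_genes` (default 200)
one-vs-rest log-fold-change genes per type (pseudo-count 1e-5); with small
gene panels this reduces to using all genes.  Each spot is
library-normalised on the signature gene set and fit by non-negative least
squares; coefficients are renormalised to sum to one, so estimates are
invariant to scaling a spot's counts.  A spot whose NNLS solution is
identically zero falls back to uniform proportions with a logged warning.

Estimated proportions are *read* proportions; they coincide with cell
proportions when per-cell libraries are comparable across types, which the
symmetric fixture design guarantees and which real tissues only
approximate.

**Types without a region.**  A region-level type whose cells never form a
spatial domain (scattered immune cells) cannot contribute rows to Ω.  The
pipeline accepts extra signature rows for such types, taken from the
external reference, and appends them before gene selection — the two-step
premise applied at region level.  Those signatures carry the external
reference's platform effects, but thresholded detection of a ~50% immune
component tolerates them comfortably.

**Two-step refinement.**  For each region-level type *T*, subtype
signatures come from the external reference restricted to the subtypes of
*T*; each spot is fit against those alone and the shares renormalised
within the block (single-subtype blocks are constant 1).  The final
fine-level estimate is the product of the parent proportion and the
within-block share.  Block renormalisation is what makes the product
conserve mass exactly — without it the fine rows would not sum to one.

**Region naming.**  Detected regions are anonymous.  Two naming helpers
exist: correlation of the region's mean profile against reference
signatures (the real-data path) and majority vote against a ground-truth
label table (benchmark alignment only; it never alters the estimates).

## Evaluation

Per-spot Pearson ρ compares the estimated and true proportion vectors; a
constant vector has undefined ρ and is recorded as missing (excluded from
summaries, counted in the log) rather than coerced to zero.  Per-spot KL is
taken as KL(truth ‖ estimate) — divergence of the estimate from the truth —
with a 1e-9 pseudo-count added to both rows and renormalised, keeping the
value finite when the estimate has hard zeros.  The direction was an open
choice; truth-first is the convention adopted and fixed here.

Infiltration calling thresholds the estimated immune proportion of tumour
spots at `infiltration_call_threshold` (default 0.05, matching the 5%
display cutoff used for the corresponding visualisation) and scores the
two classes — infiltrated and pure — with per-class precision/recall/F1 and
a class-size-weighted F1.

Spot stratification labels a spot pure when its top proportion reaches 0.9
and an X–Y mixture when the top two types both reach 0.1; the thresholds
are package defaults (no published rule exists to reproduce) and are
exposed.  A mixture category can be split into infiltrated vs peripheral by
a detected region's boundary (spot-set membership).

## Synthetic fixtures

References are negative-binomial: baseline mean 5.0 per gene, dispersion
0.5, 300 genes, 150 cells per fine type, 15 disjoint marker genes per fine
type up-scaled 8-fold.  The marker fold and dispersion are generic sparse
scRNA-seq values; the per-gene baseline is calibrated so that ten cells
thinned to 10% give spot libraries near 2×10³ counts — the Visium-depth
premise of the downsampling step.  (At a 10× lower baseline, spots carry
~170 reads and a one-to-two-cell component's marker signal is routinely
lost to Poisson noise regardless of the reference used; that regime tests
read depth, not reference quality.)  The symmetric design gives every type
the same expected library, so read and cell proportions coincide.

The external-reference emulator regenerates cells from the same type model
and multiplies every gene's mean by a log-normal factor
exp(N(0, σ)), σ = 0.5, shared across types — the simplest mechanism
producing a reference with identical type structure but systematic
gene-level platform effects.

What the fixtures do **not** emulate: hexagonal Visium geometry, spot
diameter and capture-efficiency gene biases, realistic gene-gene
correlation structure, cell-type-specific library differences, ambient RNA,
or any distributional fidelity to real tumour data.  Passing tests
therefore demonstrate the pipeline's correctness and its robustness to
gene-level platform effects, not performance on real tissue.

## Problem sizes and determinism

Every stochastic component draws from one seeded generator per run
(`RunConfig.rng_seed`), and identical configurations reproduce outputs
bit-for-bit.  The bundled end-to-end analyses run the three-region
scenarios at 30×30 (900 spots) and the simulator contract at the full
50×50 (2500 spots); both complete in seconds on a single CPU.

## Known limitations

* Tissues whose cell types never form spatial regions (e.g. interleaved
  neuron/glia mixtures) offer Ω nothing to work with; the method targets
  region-organised samples.
* Types absent from both Ω and ω cannot be estimated — an intrinsic limit
  of reference-based deconvolution.
* The ε selection rule is a documented heuristic over the edge-weight
  distribution, not a reimplementation of any published optimisation; on
  unusual weight distributions the manual override is the safer path.
* The built-in NNLS solver is deliberately simple (no platform-effect
  modelling, no spatial smoothing); Ω export exists precisely so heavier
  external tools can be plugged in.
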