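# resort

Region-based cell sorting (ReSort) for spatial-transcriptomics (ST) cell-type
deconvolution.

Sequencing-based ST platforms such as Visium profile gene expression at
spatial spots that each capture roughly ten cells, so the cell-type
composition of every spot must be inferred computationally.  Reference-based
deconvolution methods estimate those compositions from a single-cell
reference, but references from other experiments carry batch and platform
effects that distort the estimates.  ReSort sidesteps the external reference
for the coarse, region-forming cell types: it extracts molecularly
homogeneous spatial regions from the ST sample itself, uses the spots inside
those regions as a **pseudo-internal reference** Ω, and deconvolves every
spot against Ω.  Cell types that never form a region of their own (immune
subtypes, for instance) are refined in a second step from an external
reference ω, constrained by the region-level estimate.

## The model

For every spot *s* the package estimates a proportion vector over
region-level cell types *T* (rows sum to 1):

1. **Region extraction** — spots are library-normalised and
   log-transformed, embedded with the first *k* principal components, and
   linked to their grid neighbours with edge weights equal to the Pearson
   correlation of their embeddings.  Edges below an automatically selected
   threshold ε are dropped; connected components with at least *m* spots
   (default *m* = 40) become molecular regions, everything else stays
   unassigned.
2. **Pseudo-internal reference** — Ω collects the expression of spots inside
   the detected regions (one round of boundary erosion excludes each
   region's rim, the spots most likely to be partial mixtures), labelled
   with region-level types.
3. **Deconvolution** — per-type signatures are the mean library-normalised
   Ω profiles on a marker-gene set (top one-vs-rest log-fold-change genes);
   each spot is fit by non-negative least squares and the coefficients are
   renormalised: Ỹ_T per spot, Σ_T Ỹ_T = 1.
4. **Finer cell types** — for every subtype *t* of region-level type *T*,
   the within-region share Ỹ_t is estimated against ω's subtype signatures
   and the final estimate is the product Y_t = Ỹ_T · Ỹ_t, which conserves
   Σ_t Y_t = 1 exactly.

A simulator with known ground truth accompanies the method: circular and
rectangular regions on a spot grid, inverse-distance affinity mixing
A_{s,r} = 1/min_{s'∈r} Dist(s,s') + δ_r, integer cell counts
C_{s,r} = ⌊10·P̃_{s,r}⌋, cell draws from a labelled single-cell reference
with 10% binomial read thinning, and optional immune infiltration of pure
tumour spots (immune proportions from N(0.5, 0.2) truncated to (0, 1)).
Per-spot Pearson ρ, per-spot KL divergence, weighted F1 for
infiltrated-vs-pure tumour classification, and the Rand index for region
agreement complete the evaluation battery.

## Worked example

Simulate a 30×30 sample from a synthetic reference (three region-level
types, two fine subtypes each, planted markers), run the full pipeline, and
compare against deconvolution driven by a batch-shifted external reference:

```python
import numpy as np
from resort import scenario, simulate, run_region_pipeline, external_region_pipeline
from resort.evaluation import pearson_per_spot, kl_per_spot, summarize_metrics

scen = scenario("three-region", grid=(30, 30), seed=1)
sim = simulate(scen.reference, scen.layout, scen.config)

truth = sim.truth_region
dominant = np.asarray(truth.type_ids, dtype=object)[truth.values.argmax(1)]
result = run_region_pipeline(sim.counts, scen.config, truth_region_labels=dominant)
print("detected regions:", result.assignment.region_sizes)
print("named as:", result.region_type_map)

est = result.region_props.reorder_types(truth.type_ids)
m = summarize_metrics(pearson_per_spot(truth, est), kl_per_spot(truth, est))
print(f"ReSort   : median rho={m['pearson_median']:.3f}  mean KL={m['kl_mean']:.3f}")

ext = external_region_pipeline(sim.counts, scen.external_reference, types=truth.type_ids)
ext = ext.reorder_types(truth.type_ids)
m = summarize_metrics(pearson_per_spot(truth, ext), kl_per_spot(truth, ext))
print(f"External : median rho={m['pearson_median']:.3f}  mean KL={m['kl_mean']:.3f}")
```

```
detected regions: {'R1': 166, 'R3': 148, 'R2': 152}
named as: {'R1': 'cancer', 'R2': 'normal', 'R3': 'ductal'}
ReSort   : median rho=0.998  mean KL=0.071
External : median rho=0.997  mean KL=0.154
```

Three molecular regions are detected and named after the dominant truth type
of their spots (benchmark alignment; on real data use
`naming_signatures=` to name regions by profile correlation instead).  The
pseudo-internal reference tracks the ground truth closely — median per-spot
correlation 0.998 and mean KL divergence 0.071 — while the same solver
driven by the batch-shifted external reference doubles the divergence.

The same stages are available from the shell:

```
resort fixtures --scenario three-region --out-dir fx
resort simulate --ref-matrix fx/ref.csv --ref-labels fx/ref_labels.tsv \
    --grouping fx/grouping.tsv --layout fx/layout.toml --out-dir sim
resort regions --counts sim/counts.mtx --coords sim/coords.tsv --out regions.tsv
resort build-ref --counts sim/counts.mtx --coords sim/coords.tsv \
    --regions regions.tsv --map region_map.tsv --out-dir omega
resort deconvolve --counts sim/counts.mtx --coords sim/coords.tsv \
    --omega-dir omega --out props.csv
resort evaluate --truth sim/truth_region.csv --est props.csv --out metrics.csv
```

`resort build-ref` also exports Ω as a labelled matrix so external
deconvolution tools (stereoscope, RCTD, cell2location, …) can consume it as
their reference.

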