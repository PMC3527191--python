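# Methods

This note documents the models, algorithms and numerical choices behind
`mycostarve`, the assumptions they rest on, and what the synthetic-data
generators do and do not emulate.

## 1. Hyphal diameter morphometry

### Model and assumptions

Hyphae are treated as tubes of locally constant diameter whose medial axis
is a smooth curve; the diameter at a point is then the length of the chord
through that point orthogonal to the local axis. This holds for dispersed
(non-pelleted) mycelium imaged in a single focal plane and breaks down at
branch points, crossings and tube ends — which is why those regions are
explicitly removed or discarded (see below).

### Stages

1. **Binarization.** Gaussian smoothing (`smoothing_sigma`, default 1 px)
   followed by a global Otsu threshold, with dark pixels as foreground
   (bright-field, Lactophenol-blue staining). Otsu was chosen because it is
   parameter-free, testable, and appropriate for strongly bimodal
   histograms produced by high-contrast staining. Connected components
   smaller than `min_object_px` (default 64 px) are dropped. Holes are
   *not* filled: the unstained lumen of an empty hyphal ghost must never
   count as stained area. The 1-px walls of ghosts are removed by the
   smoothing itself — a 1-px dark line at contrast 0.7 retains ≲30 % of its
   depth after σ = 1 smoothing and lands above the Otsu threshold, while
   the thinnest real hyphae (≈5 px at the default calibration) stay below
   it. Ghost exclusion therefore relies on stain polarity, not on any
   explicit shape classifier.
2. **Outline.** Foreground pixels 8-adjacent to background; the image
   border counts as background so border-touching objects are outlined
   along the border.
3. **Skeletonization.** `skimage.morphology.skeletonize` (topology
   preserving, 1 px wide, 8-connected).
4. **Intersection removal.** Every skeleton pixel with ≥3 8-neighbours is
   deleted, iterated to a fixed point, then isolated pixels are dropped.
   The iteration guarantees the postcondition (only simple paths remain)
   for diagonal junction configurations that a single pass can miss. This
   is the minimal reading of "remove all intersections": no attempt is
   made to re-join paths across a junction.
5. **Fragmentation.** Each simple path is cut into runs of `fragment_len`
   pixels (default 7 — short enough to track curvature, long enough for a
   stable orientation estimate). A terminal remainder of ≥3 px becomes its
   own fragment, shorter remainders merge into the previous fragment;
   paths under 3 px yield nothing. Fragment orientation is the normalized
   endpoint-to-endpoint vector; the center is the middle pixel.
6. **Measurement.** From each fragment center two rays are cast along
   ±(normal to the orientation) in 0.25-px steps with nearest-pixel
   lookup, stopping at the first background pixel. The diameter is
   (d₊ + d₋)·pixel_size. Two-sided casting is robust to the skeleton
   sitting up to a pixel off the true midline (one-sided doubling would
   double that error). Samples are discarded when the center is off the
   foreground, a ray exits the image, or the diameter exceeds
   `max_diameter_um` (default 10 µm) — the latter two rules keep border
   artifacts and blob/crossing chords out of the distribution.

On noiseless straight ribbons of width 3–25 px the ray-cast diameter agrees
with twice the Euclidean distance transform at the same pixel to within
1 px (asserted in the tests); near tube ends the skeleton develops diagonal
spurs and the orthogonality assumption intentionally fails, so the
equivalence is only asserted away from caps.

### Density summarization

Pooled diameters are summarized as a Gaussian KDE on [0, `grid_max_um`]
(default 6 µm, 512 points), renormalized to integrate to 1 on the grid.
The default bandwidth is Silverman's rule; a fixed bandwidth in µm can be
supplied. Population fractions are raw sample proportions below/above
`split_threshold_um` (default 2.0 µm — the midpoint between the ≈1 µm and
≈3 µm populations), reported alongside the threshold. Modes are local
density maxima above 5 % of the peak.

All coordinates are (row, col), origin top-left, 0-based; 8-connectivity is
used throughout. Pixel calibration is always an explicit input — the
package assumes nothing about magnification.

## 2. Synthetic micrographs

The generator renders dark tubes (intensity 0.2) on a bright background
(0.9), mimicking bright-field Lactophenol-blue staining, with i.i.d.
Gaussian pixel noise (default σ = 0.05) clipped to [0, 1]. Tube diameters
are drawn from a configurable normal mixture (default 50/50
N(3.0, 0.3²)/N(1.0, 0.15²) µm — the two populations seen before and during
starvation); paths are random walks with small angular jitter (σ = 0.03
rad/px) that bounce off the borders, giving bounded curvature so the
orthogonal-measurement assumption holds. Tube masks are pixels whose
center lies within d/2 of the continuous midline (exact point distances via
a KD-tree on a densified path), so rendered widths are unbiased to the
sub-pixel level. Overlapping tubes union their masks — crossings are
deliberate, they exercise the intersection-removal stage. A configurable
fraction of tubes is rendered as "ghosts": only the 1-px boundary walls are
drawn and nothing enters the truth mask.

Not emulated: optics (PSF, shading, defocus), conidiophores, septa,
partially-filled compartments, 3-D stacks, uneven staining. Passing the
recovery tests therefore shows the measurement chain is correct under the
stated tube model, not that segmentation is robust to arbitrary real-world
imaging artifacts.

Defaults for the study-condition fixtures: 40 tubes per 768×768 image at
0.2 µm/px, five images (≥200 tubes) for recovery tests; per-image noise
σ = 0.05. Tube lengths are uniform in 150–300 px — long enough for dozens
of fragments per tube, short enough to limit crossings.

## 3. Differential expression

The four cultivation phases are exponential growth (`exp`, triplicate) and
days 1/3/6 after carbon depletion (duplicate each); each starvation group
is contrasted against `exp` independently, matching the per-day columns of
the study design. The matrix is assumed already normalized (RMA or
similar); normalization is out of scope.

**Moderated t.** Per gene, the pooled two-sample variance s²_g has
d_g = n₁+n₀−2 df. The empirical-Bayes prior (d₀, s₀²) is estimated by
moment matching on z_g = log s²_g: with
e_g = z_g − ψ(d_g/2) + log(d_g/2),

* ψ′(d₀/2) = var(e) − ψ′(d_g/2) (solved by a Newton iteration on the
  trigamma inverse), and
* s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).

If the moment equation has no positive solution the gene variances are
effectively equal: d₀ = ∞ and s₀² is the arithmetic mean of the s²_g
(complete shrinkage). The total df is capped at the summed residual df over
all genes — even full shrinkage cannot gain more information than the data
contain. `prior_df=0` recovers the ordinary pooled t exactly (asserted);
the implementation agrees with limma 3.58.1 `lmFit`/`eBayes` to ≈1e-14 on
frozen reference fixtures in both the finite and infinite-d₀ regimes.

**Calls.** q-values are Benjamini–Hochberg per contrast (not pooled across
contrasts — matching per-day q columns); a gene is `up`/`down` when
q < 0.005 strictly and the mean log2 difference is positive/negative. No
minimal fold-change criterion is applied. The boundary q = 0.005 is `ns`:
the threshold wording gives no boundary semantics, strict inequality is the
documented choice.

**Fold changes** are ratios of arithmetic means of linear-scale values,
reported to 1 decimal in outputs (table convention). This deliberately
differs from 2^(Δ log2 mean) — the geometric-mean ratio used by the test
statistic — whenever replicates vary; the statistic uses log2 means, the
reported FC uses linear means, and both are exposed.

**Venn logic.** Up- and down-call sets for the three days are reduced to
the seven exclusive region counts, the conjoint (triple-intersection)
counts, and the fraction of the gene universe differentially expressed at
≥1 time point.

The synthetic expression generator plants a log2 effect of ±log2(FC)
(sign drawn per gene and group, FC uniform in a configurable range) on a
fraction of genes, over a N(7, 1.5²) log2 baseline with N(0, 0.3²)
replicate noise — chosen to match typical array-scale variability. It does
not emulate probe-level effects, heteroskedastic intensity-dependent
variance, or correlation between genes; calibration results (type-I error
≈0.05, sensitivity and empirical FDR at q<0.005) therefore certify the
statistics under i.i.d. Gaussian log-scale noise.

## 4. Ontology enrichment and summarization

Only `is_a` edges are used; the OBO reader (obonet-backed) takes `id`,
`name` and `is_a`, skips obsolete stanzas and other relationship types, and
validates acyclicity and dangling targets. "Distance" between a term and an
ancestor is the shortest directed `is_a` path (the conventional GO-depth
reading). Annotations are closed under ancestors (true-path rule) before
counting, switchable off; flat Pfam/KEGG-style annotation schemes use the
same enrichment code path with no DAG and no propagation.

**Enrichment.** For each term annotating K ≥ 1 population genes, the
one-sided Fisher p is the hypergeometric upper tail P(X ≥ k) with study
size n and population size N. Terms with K = 0 are not tested and do not
inflate the BH denominator. BH adjustment runs across all tested terms;
`enriched` flags q ≤ q_crit (default 0.05).

**Common most-specific terms.** The seven-step summarization: union the
input sets, keep most-specific terms, and for each scan candidates by
increasing distance; the first candidates present in all input sets are
common (ties at a distance all qualify), otherwise the term is non-common;
finally ancestors are removed from the common set. The scan includes the
term itself at distance 0 (default): a most-specific term present in every
input set is its own best summary, and excluding it would absurdly mark a
universally enriched term as non-common. The literal parental-only reading
is available via `include_self=False` / `--no-include-self`. Provenance
(which child selected each common term, at what distance) is retained.

## 5. Pipeline and reproducibility

The two orchestrations (`run-morphometry`, `run-transcriptome`) validate
their configuration before any I/O, write every intermediate as TSV/JSON,
and emit a run report echoing the configuration with per-stage summaries
and timings; the report payload minus timings is bit-stable across reruns.
Every generator takes an explicit seed and owns its RNG (no global state),
so a single seed reproduces every stochastic artifact.

Problem sizes used by the test suite and the acceptance script — five
768×768 images (200 tubes) for morphometry recovery, 2,000 genes × 20
seeds for null calibration, 200 random DAG/set instances and 1,000 random
2×2 tables for the oracle equivalences, an 800-gene end-to-end study —
were chosen so each check is statistically meaningful at desk scale.

## 6. Known limitations

* Diameters at crossings and tube ends are systematically biased (chords
  are not orthogonal there); the max-diameter cap and cap-region behavior
  bound, but do not remove, a small heavy right tail.
* Silverman's bandwidth mildly oversmooths bimodal mixtures, pulling the
  two modes a few percent toward each other; fix the bandwidth explicitly
  when mode positions matter.
* The moderated t assumes Gaussian log-scale noise and equal within-group
  variances per gene; with duplicate starvation samples, d_g = 3 per
  contrast, so variance shrinkage does essentially all the work.
* `common_most_specific` is defined for single-rooted namespaces; with
  multiple roots, terms in different namespaces simply never share
  ancestors.
* No multi-factor designs, no RMA/quantile normalization, no .CEL parsing,
  no branching-rate or hyphal-length morphometry, no GUI.
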