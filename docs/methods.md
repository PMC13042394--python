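# Methods

## Scope and model

`villustat` implements the descriptive spatial and compositional statistics
used to characterize intestinal crypt immune microenvironments in GVHD:
a crypt–villus coordinate system (SAP), crypt-region statistics (positive
rates, polarization deltas, proximity networks), compositional enrichment
(Ro/e) and TCR repertoire clonality/diversity. Upstream steps —
alignment/quantification, clustering, compartment annotation, clonotype
calling — are input contracts, not package responsibilities: spot tables
arrive with compartment (and optionally cell-type) annotations, clonotype
tables with clonotype identifiers.

## SAP coordinates

For spot *s* with centre `(x_s, y_s)`,
`d_sm(s) = min over smooth-muscle spots m of ||s − m||` and
`d_ent(s)` analogously over enterocyte spots; SAP places *s* at
`(X, Y) = (d_ent, d_sm)`. Distances are point-to-point between spot
centres: at 2 µm pitch the centre–boundary discrepancy is below the pitch
and irrelevant to the statistic. Units are µm throughout; coordinates are
0-based with the origin at the section's lower-left corner, and no axis is
flipped. The k-d tree (`scipy.spatial.cKDTree`) implementation is paired
with an exhaustive O(n·m) scan that the tests require to agree within 1e-9
on every randomized instance. Nearest-neighbour ties do not affect the
distance value, so no tie-break rule is needed. An empty reference
compartment is an error naming the compartment, never an infinite distance.

## Crypt regions and assignment

"Crypt region" is operationalized as a connected component of
crypt-annotated spots on the capture grid, using 8-connectivity by default
so that diagonal staircase artifacts of rasterized anatomy do not fragment a
crypt (4-connectivity is available). Components are computed with
`scipy.ndimage.label` and independently checked against a BFS flood fill in
the tests. Region identifiers are assigned in order of each region's
minimum (y, x) member, making identity deterministic. Labelled immune spots
are attributed to the region containing their nearest crypt spot when that
distance is at most the assignment radius (default 3 × spot pitch, exposed
in config); "unassigned" is a legal state, not an error.

## Scoring

Counts are library-size normalized per spot to a fixed total (default
10,000) and log1p-transformed; zero-total spots stay zero with a warning.
The signature score is the plain mean of normalized expression over the
signature genes present in the matrix. No control-gene background
correction is applied — a deliberate simplification that keeps the
statistic exactly reproducible and order/duplicate-invariant; rank-based or
background-binned variants are out of scope. The polarization delta is
`Δ = S_M2 − S_M1` per spot, computed only when both scores cover the same
spot set. Gene positivity is evaluated on raw counts (`count > t`,
default `t = 0`), never on normalized values, because the statistic is
defined as "expression > 0". Default M1/M2 marker sets are the murine
pro-inflammatory (Nfkb1, Rela, Fcgr1, Cd80, Cd86, H2-Aa, H2-Ab1) and
tissue-reparative (Tgfb1, Fabp4, Mrc1, Aldoa, Adgre4, Smad3, Trem2) gene
lists; any GMT file can replace them.

## Ro/e

With observed counts `O_ij` over groups × subsets,
`E_ij = (Σ_j O_ij)(Σ_i O_ij) / Σ_ij O_ij` (chi-square expected counts, via
`scipy.stats.contingency.expected_freq`) and `Ro/e_ij = O_ij / E_ij`.
Row sums of observed and expected agree identically, which the tests assert
to 1e-9. Cells with zero expected count are NaN (undefined), not infinite.
Ro/e operates on raw cell counts; multi-sample groups are pooled by
summation. No statistical test is attached to Ro/e values.

## Repertoire statistics

Clones are defined within a sample (cells sharing `clonotype_id` in the
same sample); there is no cross-sample clone merging. The Gini index uses
the population formula `G = Σ_ij |x_i − x_j| / (2 n² μ)` (computed via the
sorted O(n log n) identity) without the n/(n−1) small-sample correction;
`corrected=True` applies it. Entropy is natural-log by default with a
`base` flag. Both statistics are computed for the whole repertoire and,
optionally, per subset, since either convention is defensible; outputs are
labelled accordingly. Clone-size classes default to {1, 2, >2} with ">2"
flagged expanded; bins must partition the positive integers (contiguous,
starting at 1, last bin open) and fractions are of **cells**, not clones.

## Proximity network

Observed statistic: for each unordered cell-type pair, the number of spot
pairs assigned to the same crypt region with centre distance ≤ radius
(default 3 × spot pitch); same-type pairs count once per unordered spot
pair. The null permutes cell-type labels uniformly among labelled spots
*within each region*, holding positions and per-region label counts fixed —
so the test is conditional on tissue architecture and per-region
composition, and asks only whether labels pair up more than exchangeability
allows. With `n_perm` permutations, `z = (obs − mean_null) / sd_null`
(NaN when `sd_null = 0`) and `p = (1 + #{null ≥ obs}) / (1 + n_perm)`
(one-sided enrichment; depletion by flag), which bounds p below by
`1/(1+n_perm)`. A cell type with fewer than two spots has its self-edge
flagged not-estimable and the run continues. `Unclear` spots participate in
the permutation as a sixth label but are excluded from headline edges by
default. This fixed-radius pair rule and null are this package's explicit
design choices, not a reconstruction of any published procedure; k-NN
graphs and point-process models (Ripley's K, Gibbs) are non-goals.

## Synthetic tissue generator

The generator emulates a jejunum section as a stylized rectilinear layout:
a smooth-muscle band along the bottom (default 30 µm), a crypt band above
it (60 µm) containing one rectangular crypt block per villus separated by
lamina propria, and villus columns (fill fraction 0.7) whose 2-spot
epithelial shell is enterocyte around a lamina propria core; gaps between
villi are lumen and carry no spots. Spots sit on a square grid (default
pitch 2 µm, 500 × 250 µm section, ~25k spots). Small fractions of crypt and
lamina propria spots are relabelled paneth (3%) and fibroblast (3%).

Immune labels (CD4T 3%, CD8T 3%, M1 2%, M2 2%, Monocyte 2%, Unclear 1%)
are placed on crypt and lamina propria spots only — immune spots sit in the
stroma, never on epithelium or muscle. Inside the crypt band each type's
probability is multiplied by its `crypt_enrichment` factor. M1 labels are
assigned in a second pass so that spots in the 8-neighbourhood
(≤ 1.5 × pitch) of a crypt CD8T spot get their M1 probability multiplied by
`cd8_m1_coloc`; the tight radius keeps the planted co-clustering local,
which is what a within-region permutation test can detect. Configurations
whose enriched label probabilities would exceed 1 are rejected up front.

Counts are negative binomial with shared dispersion (mean 0.5, size 2.0 per
gene; drawn as a gamma–Poisson mixture), with dropout implicit in NB zeros.
Each cell type's marker genes are up-scaled by `signature_fc` (default 4)
in that type's spots, and the 12 cell-cycle genes by
`crypt_proliferation_fc` in crypt-compartment spots. The two condition
presets differ only in planted effects: WT-like has M2-dominant crypts
(M2 enrichment 3×, proliferation fold 3); cKO-like has CD8T 3×, M1 3×,
monocyte 2×, M2 0.7×, CD8T–M1 co-placement 3× and proliferation fold 1.

The repertoire generator assigns each cell to an expanded clone with
per-subset probability (presets: 0.05 everywhere; cKO-like raises CD8
effector cells to 0.30); expanded clone sizes are `1 + Geometric`
(mean 4, always ≥ 2) or fixed, and non-expanded cells are singletons. The
composition generator draws multinomial cell counts per sample from
per-group subset probabilities.

What the generator does **not** emulate: histology-faithful crypt/villus
shapes, spatial expression gradients beyond signatures, segmentation noise,
doublets, batch effects, or cross-subset clone sharing. Passing tests
therefore demonstrate correctness of the statistics and their calibration
under a clean, exchangeable-label null — not robustness to annotation error
or platform artifacts in real sections.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed gives byte-identical TSV/MTX/JSON outputs, and run reports
  contain no timings so they are pure functions of inputs.
- TSV dialect: tab-separated, mandatory header, UTF-8, `#` metadata lines
  echoing the config; MatrixMarket coordinate format for counts. Readers
  are strict: missing columns, duplicate ids, inconsistent MTX dimensions
  and unknown labels are errors with file/line context.
- Problem sizes in the acceptance checks: oracle agreement at 1,000 × 500
  points; 100 random occupancy grids; null calibration over 200 replicate
  ~1,500-spot sections at n_perm = 1,000; planted-effect recovery over 20
  seeds of full-size (~25k-spot) sections with 300 genes; the demo pipeline
  at ~25k spots × 1,000 genes per condition. These sizes give stable
  Monte-Carlo estimates on a single CPU in minutes.

## Known limitations

- The signature score has no background correction, so scores shift with
  library composition; comparisons should stay within one normalization.
- Ro/e is descriptive; no uncertainty is attached.
- The proximity null conditions on per-region label counts, so it cannot
  detect co-enrichment expressed purely as regional abundance (that signal
  belongs to the enrichment statistics, not the pairing test).
- Crypt regions assume grid-aligned spot coordinates; irregular platforms
  would need a neighbourhood-graph generalization.
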