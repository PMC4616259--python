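# Methods

## Scope and model

spectrotype implements the analysis half of a whole-cell MALDI-TOF typing
workflow for bacteria such as rhizobia: linear-mode, positive-polarity
profile spectra of intact cells, annotated over 300–20000 m/z, with all
peak-level work confined to 3000–15000 m/z. The working assumption is the
standard one for this kind of fingerprinting: the 3–15 kDa profile is
dominated by abundant, largely ribosomal proteins whose masses are stable
within a taxon, while a minority of peaks vary with growth stage, storage
and stress. Everything downstream — consensus libraries, identification
scores, dendrograms, segment ordination — builds on that split between
constitutive and variable peaks.

## Preprocessing chain

Stages run in a fixed order: block-average compression → Savitzky–Golay
smoothing → polygon baseline subtraction → crop → max-normalization.

- **Compression (factor 10, default).** Non-overlapping blocks of 10
  points are replaced by their mean m/z and mean intensity. Implemented as
  block-averaging rather than decimation because its purpose is spike
  suppression; plain decimation removes points but not spikes.
- **Smoothing (25 Da frame, polynomial order 2).** The frame in daltons is
  converted to an odd window of grid points using the median spacing
  (forced ≥ polyorder + 2). Quadratic order is the conventional default
  where only "one smoothing polynom" is specified. Negative filter outputs
  are clipped to zero — abundances are physically non-negative.
- **Baseline (500 Da windows, 2 passes).** Per pass, the axis is cut into
  contiguous 500 Da windows, the intensity minimum of each window becomes
  a polygon vertex at its own m/z, the vertex polyline is linearly
  interpolated over the grid, subtracted, and negatives clipped. 500 Da
  spans typical peak widths at these masses without swallowing peaks; two
  passes catch curvature that one chord misses.
- **Crop and normalize.** The profile is cropped to the working range
  *before* the final max-normalization so the preprocessed output always
  has maximum exactly 1 inside the range (normalize-then-crop could leave
  a maximum below 1 if the base peak fell outside). This ordering is an
  implementation decision; the chain is otherwise insensitive to it.

The chain is fully deterministic.

## Peak model

Candidate apexes are local maxima above the 5% relative-intensity
threshold. Each candidate is fitted independently by least squares with a
three-parameter Gaussian (height, center, width) over a window of about
±3 estimated half-widths; a diverged fit falls back to the apex sample.
Fits below threshold or outside 3000–15000 m/z are discarded; if more than
100 survive, the 100 highest are kept (ties to lower m/z). Relative
intensities are rescaled to the largest fitted height, so the output obeys
the peak-list invariants (≤ 100 peaks, all ≥ 0.05, max = 1). Centroids are
then rounded to integer Da (half away from zero), merging same-bin peaks
by keeping the larger.

Independent per-peak fitting (no joint deconvolution) matches the flat
resolution of linear-mode data at these masses. Center accuracy depends on
how densely the raw grid samples a peak: with the width model
σ(m/z) = m/z / 2000, peaks near 4000 Da have σ ≈ 2 Da, and after
factor-10 compression of a 1 Da grid they are undersampled; rendering at
0.5 Da or finer restores sub-0.1 Da accuracy. The test suite uses 0.5 Da
grids where it asserts tight center recovery, and 1 Da where only counts
and thresholds matter.

## Composite correlation index

CCI(a, b): interpolate b onto a's grid over the overlapping range, split
the overlap into 10 equal-width m/z intervals, take the Pearson
correlation per interval, average, clip to [0, 1]. The interval count is
configurable; the overlap must hold ≥ 10 grid points per interval (the
floor may be lowered explicitly for hand-sized examples).

Flat intervals need a convention, because after baseline subtraction
peak-free regions are exactly constant. An interval that is flat in *both*
spectra with identical values contributes 1 (two identically empty
regions are perfect conformity); an interval flat in only one spectrum, or
flat at different constants, contributes 0. This keeps the statistic total
while preserving both anchor points: CCI(s, s) = 1 exactly, and profiles
with no shared structure score near 0.

The per-condition replicate consistency is the mean CCI over all
unordered pairs of replicates.

## Log score

The identification score is an open formula on the familiar 0–3 scale:
f1 = matched/|query|, f2 = matched/|reference| under greedy one-to-one
nearest-m/z matching within ±2 Da (closest pairs claimed first);
f3 = (r + 1)/2 with r the Pearson correlation of matched intensity pairs,
set to 0 when fewer than 3 pairs matched (too few points to support a
correlation) and r = 0 when either side is constant. The score is
log10(1000·f1·f2·f3) clipped to [0, 3]; a component product ≤ 0.001 scores
0. A perfect self-match gives exactly 3.0, the top of the secure-species
bin. The ±2 Da tolerance covers 1 Da binning plus ±1 Da calibration
jitter. (r+1)/2 rather than max(r, 0) penalizes anticorrelated intensity
patterns without annihilating an otherwise strong peak-set match.

Interpretation bins are applied exactly as printed: [0, 1.700) no
identification, [1.700, 2.000) probable genus, [2.000, 2.300) secure
genus / probable species, [2.300, 3.000] secure species.

## Consensus main spectra and libraries

Replicate peak lists are pooled and single-linkage clustered along m/z
(adjacent peaks chain while gaps ≤ 2 Da; generator templates keep true
peaks ≥ 8 Da apart so chains never bridge distinct peaks). A cluster
becomes a consensus peak only if its replicates span a fraction strictly
greater than 0.95 of all lists — "greater than 95%" is read literally, so
17/18 fails and 18/18 passes. Consensus m/z is the intensity-weighted mean
re-binned to integer Da; consensus intensity is the mean contributing
intensity, re-normalized to max 1; the recurrence fraction is stored per
peak.

Species- and genus-level entries re-run the same consensus over the pooled
replicate lists of the group (not over intermediate consensus spectra), so
recurrence always means "fraction of individual acquisitions". Genus
entries therefore retain essentially only genus-invariant peaks, which is
what makes the two-step search work: step 1 ranks genus entries (a wrong
genus shares no markers and scores ~0), step 2 ranks only the winning
genus's species. If the best genus score falls in the no-identification
bin the report stops with an explicit unreliable-at-genus flag. A top-k
option widens step 2 to the k best genera.

## Dendrograms

Strain consensus spectra are coded as presence/absence over the union of
observed integer-Da bins. The distance is the mean character difference
(differing characters / total characters) — the conventional choice for
binary data in distance-matrix phylogenetics packages. UPGMA merges the
closest pair, breaking exact ties by the lexicographically smallest member
labels (reproducible Newick output), with size-weighted arithmetic-mean
distance updates and node height = merge distance / 2, so trees are
ultrametric by construction. Bootstrap supports resample character columns
with replacement, rebuild the tree, and report for each internal node of
the original tree the percentage of replicates containing its clade
(Felsenstein mapping onto the original topology, not a consensus tree).

Topologies are compared by the Robinson–Foulds distance over nontrivial
unrooted bipartitions. Recovery of a *multifurcating* generating taxonomy
by a binary tree is measured as the number of truth clades absent from the
tree (0 = every genus and species forms a clade); the symmetric RF
distance is unsuitable there because a binary tree always resolves clades
a multifurcation leaves open.

## Segment richness and correspondence analysis

Peaks are counted per 1-kDa segment, labeled 3K…14K, with half-open
intervals [k·1000, (k+1)·1000); the single closing value 15000 Da counts
in 14K. Correspondence analysis is implemented from first principles:
P = T/n, standardized residuals S = (P − rcᵀ)/√(rcᵀ), SVD of S, principal
coordinates (mass-scaled singular vectors × singular values), total
inertia Σσ² = χ²/n. Principal rather than standard coordinates are
reported, matching the defaults of the classical statistical packages.
All-zero rows/columns are dropped with a warning before analysis (real
profiles often have empty high-mass segments).

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed, not tuned.

- **Taxonomy.** Genus-marker peaks (8 per genus, disjoint across genera,
  identical within), species markers (6), strain markers (3) — all
  constitutive (occurrence 1) and placed in 3–8 kDa — plus 6 variable
  peaks per species in 8–15 kDa with occurrence probabilities uniform in
  0.3–0.8. This mirrors the empirical pattern of constitutive low-mass
  segments versus variable high-mass segments. Positions are drawn without
  replacement on an 8 Da lattice so no two true peaks can collide under
  the 2 Da match tolerance plus ±1 Da jitter. Base intensities: genus
  markers U(0.4, 1.0), species U(0.3, 0.9), strain U(0.2, 0.6), variable
  U(0.1, 0.5), with a small lognormal (CV 5%) strain-specific expression
  shift on shared peaks.
- **Replicates (3 biological × 6 technical).** Peak presence and a
  biological intensity factor (lognormal, CV 0.30) are drawn once per
  biological replicate; calibration jitter (normal, SD 0.5 Da, truncated
  at ±1 Da) and a technical intensity factor (lognormal, CV 0.15) per
  technical replicate — biological replicates vary more than technical
  ones, as in the 3×6 acquisition design.
- **Rendering.** Sum of Gaussians with σ(m/z) = m/z/2000 (linear-mode
  resolution worsening with mass; any monotone width model would do, this
  one is fixed and documented) on a uniform grid over 300–20000 m/z, plus
  an exponential baseline (amplitude 0.05 at the low edge, 3000 Da decay)
  and additive Gaussian noise (SD 0.01).

What the generator does *not* emulate: isotope envelopes and adducts,
detector saturation, matrix cluster ions, chemical noise correlated
across replicates, and mass-dependent intensity response. Passing the
end-to-end tests therefore shows the algorithms are correct and robust to
the modeled variability — not that any particular accuracy will be
attained on a given instrument's data.

## Validation sizes and numerical choices

The parameter-recovery study runs at 4 genera × 5 species × 2 strains
(40 strains, 18 library replicates and 18 held-out queries each, 720
identifications) — a deliberately scaled-down stand-in for a 75-strain
study that keeps the full structure (multiple genera, multiple species
per genus, multiple strains per species). At the default noise model it
yields ≥ 95% (in practice 100%) correct species calls and full recovery
of the generating taxonomy by UPGMA. Oracle-equivalence checks run 1000
random distance matrices (≤ 6 taxa) against a brute-force UPGMA and 1000
random tables against an independent χ² computation.

Other fixed numerical conventions: rounding is half-away-from-zero
everywhere peaks are binned; the 100-peak cap breaks ties toward lower
m/z; UPGMA validates symmetry/non-negativity/zero diagonal and rejects
NaN; CA treats singular values below 1e-12 as null dimensions; all
stochastic components accept a single integer seed and are bit-reproducible
given it.

## Known limitations

- Scores are not comparable to vendor scores on vendor data; only the
  scale and its interpretation bins coincide.
- mzML support is a compact read-only reader for profile spectra
  (32/64-bit float arrays, zlib or no compression); chromatograms,
  indexed-wrapper offsets and vendor raw directories are out of scope.
- No joint deconvolution: heavily overlapping peaks (closer than about
  two widths) are fitted independently and may merge.
- CCI interval count and sub-range are configurable but there is no
  canonical published reference value to calibrate against.
- The 16S reference tree is consumed as Newick only; sequence alignment
  and tree inference belong to other tools.
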