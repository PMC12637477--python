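# Methods

## The analysis model

`chronotime` quantifies how time of harvest (ZT2, early light/inactive
phase, vs ZT18, mid dark/active phase) changes the composition, spatial
organization and activation state of tumor-infiltrating immune cells in
spatial transcriptomic sections.  Three measurements carry the analysis:

1. **Nearest-partner distance.** For every cell of a source type the
   Euclidean distance, in µm between cell centroids, to the closest cell of
   a target type in the same section (k = 1; a k-nearest-mean variant
   exists but is off by default).  Profiles are pooled across whole
   sections and compared between conditions.  No edge correction is
   applied: cells near the section border can only appear farther from
   partners.  The synthetic generator uses the same convention, so planted
   effects and their recovery are internally consistent; on real data the
   bias is shared by both conditions and largely cancels in contrasts.
2. **Distance-quantile expression.** Records of a pooled profile are
   sorted by (distance, stable index) and cut into n = 10 contiguous
   equal-count strata (the first N mod n strata take the extra record).
   Quantile boundaries are computed on the profile pooled over both
   conditions so ZT2 and ZT18 share strata; per-condition boundaries are a
   flag away.  The matrix entry for (gene, measured-in-type, quantile) is
   the mean log-normalized expression over that type's cells in the
   stratum — chemokine rows are measured in myeloid cells against
   myeloid→T distances, effector rows in T cells against T→myeloid
   distances.  The near→far gradient of each row is summarized by
   Spearman's ρ (midranks; constant rows are defined as ρ = 0 and
   flagged).  Row z-scoring is display-only; the raw matrix is always
   retained.
3. **Condition-level inference.** Distances are compared with a
   Mann–Whitney rank-sum test implemented from the definition: U counts
   (x, y) pairs with x > y (ties ½); for combined n ≤ 16 without ties the
   null is enumerated exactly over all C(n, n₁) rank assignments,
   otherwise a normal approximation with tie-corrected variance and ±0.5
   continuity correction is used.  The crossover at 16 keeps enumeration
   instantaneous while the approximation error there is already below
   0.01.  Because cells within a section are not independent replicates,
   the package also provides a section-level permutation test: the
   absolute difference in condition means of a per-section statistic,
   referenced to the label-permutation null (exhaustive when ≤ 10,000
   assignments, with the identity included so p is a multiple of 1/m and
   ≥ 1/m; Monte-Carlo with p = (b+1)/(m+1) otherwise).  With equal group
   sizes the mirror of every assignment duplicates its absolute
   difference, so a 3-vs-3 design bottoms out at p = 0.1; five or more
   sections per arm are needed before α = 0.05 is attainable.  Reports
   print both tests deliberately.

Cell typing is per-cell marker scoring rather than cluster-then-annotate:
score(cell, type) = mean log-normalized expression of the type's markers,
label = argmax, with a margin threshold for abstention (default 0: assign
everything, matching analyses that report no unassigned class).  Scores are
a plain mean with no background subtraction — the simplest defensible
choice, and one that makes the scores invariant to genes outside the
panel.  Log-normalization scales each cell to 10⁴ total counts then
applies ln(1 + x); zero-depth cells map to zero columns.  The default
marker panel anchors types to standard cytometry identities (CD8 T:
Cd3e/Cd8a; cDC: Itgax/H2-Ab1, i.e. CD11c/MHCII; plus broad myeloid, tumor
and stromal markers) but is explicitly replaceable — real analyses should
supply lists matched to their tissue, platform and normalization.

Promoter analysis is exact-word scanning of both strands for E-box motifs
(default CACGTG and the non-canonical CACGTT — literal words, no PWMs).
Hits are reported in forward-strand 0-based half-open coordinates; a
palindromic motif matches both strands at the same span, and that double
report is collapsed to one '+' hit (toggleable) so per-promoter counts are
not doubled.  The `motif` field always holds the motif-set word, with
`strand` recording orientation, so per-motif counts remain meaningful.

## The synthetic generator

No public dataset accompanies the two-timepoint design, so the generator
is a first-class module that emulates its structure and plants every
effect it claims:

- **Geometry.** A rectangular window (default 1 × 1 mm, of the order of a
  whole tumor section).  Tumor and "other" cells are uniform.  Myeloid
  cells follow a Thomas cluster process — Poisson parents (default
  intensity 5 × 10⁻⁵/µm², at least one when offspring are requested),
  Gaussian offspring (σ = 50 µm) — with a fixed offspring total so
  per-type counts are exact.  Each T cell is, with per-condition
  probability, placed at an isotropic Gaussian offset from a uniformly
  chosen myeloid cell, else uniform.  Off-window offsets are resampled,
  not clipped, to avoid boundary pile-up.
- **Condition contrast.** ZT2 defaults: 1.5× immune infiltration
  (myeloid and T counts scaled, rounded half-to-even), attraction
  probability 0.7 at σ = 30 µm, and a 1.5× gain on chemokine/effector
  means.  ZT18: factor 1.0, probability 0.2 at σ = 80 µm, gain 1.  These
  encode "more infiltrated, more co-localized, more activated" at ZT2 as
  single tunable knobs.
- **Expression.** Counts are negative binomial with variance
  μ + μ²/θ, θ = 2 (strong overdispersion typical of UMI counts), mean
  depth 2000 per cell spread uniformly over the 24-gene default panel.
  Marker genes are scaled ×20 in their own type.  Chemokine genes in
  myeloid cells and effector genes in T cells carry the proximity
  multiplier 1 + β·e^(−d/τ)·gain (β = 2, τ = 50 µm), where d is the
  distance to the nearest partner-type cell; β = 0 gives an exact null
  and the effect is monotone in d by construction.
- **Promoters.** I.i.d. background at a chosen GC fraction with motifs
  written at fixed positions/strands; optional rejection sampling
  regenerates the background until scanning recovers exactly the planted
  sites, giving fixtures with zero accidental hits.
- **Reproducibility.** All draws come from one seeded generator per
  section; multi-section experiments derive 31-bit sub-seeds by hashing
  (master seed, condition, section index), so adding sections or
  conditions never reshuffles earlier ones.

What the generator does **not** emulate: platform bin/segmentation
artifacts (it emits idealized cells with exact centroids), cell-type
specific depth differences, spatial expression autocorrelation beyond the
planted proximity effect, doublets, and any circadian structure beyond a
two-condition contrast.  Passing recovery tests therefore demonstrates
that the pipeline measures what it claims on data obeying its own
assumptions — not that those assumptions hold on any particular platform.

Two saturation effects of the defaults are worth knowing.  At mean depth
2000 over 24 genes, nearly every T cell has ≥ 1 count in some effector
gene, so the default expressing fraction (threshold 1) is ≈ 1 in both
conditions; the threshold exists precisely so sparser data or stricter
cutoffs stay meaningful.  And because depth normalization divides by total
counts, a proximity boost that dominates a cell's depth partially
normalizes itself away; with the default panel the marker and housekeeping
genes dominate depth, so the gradient survives normalization.

## Verification choices and problem sizes

Tests verify each statistic against an independent route: the distance
kernel against a plain all-pairs loop (exact equality, including the
KD-tree path used above 4 × 10⁶ candidate pairs, where ties are re-broken
to the lowest index); the rank-sum test against split enumeration for all
n₁ + n₂ ≤ 14 and against a rank-sum counting recurrence at n₁ = n₂ = 15;
Spearman ρ against an independent implementation; the permutation test
against its analytic p-value formulas; and motif scanning against planted
truth on rejection-sampled promoters.

Simulation-based checks use these sizes, chosen to give stable pass/fail
behavior at interactive runtimes: gradient recovery pools cohorts of 40
sections of 400 + 400 immune cells (≈ 1,600 records per quantile, enough
that every chemokine/effector row reaches ρ ≤ −0.9 when β = 2 while
single sections of 300 + 300 cells do not separate the far-quantile
plateau from NB noise); the attraction-contrast power check runs 200
two-section experiments; type-I calibration runs 1000 null experiments of
5 + 5 sections (the smallest balanced design whose exhaustive permutation
null makes α = 0.05 attainable).  Determinism contracts are byte-level on
the data files (cells/matrix/features TSV + MTX, FASTA, BED, result
tables); the metadata sidecar carries a wall-clock timestamp by design and
is excluded from byte-identity.

## Known limitations

- Per-cell marker scoring cannot use co-expression structure the way
  graph clustering does; ambiguous cells are resolved by margin, not by
  neighborhoods.
- Quantile strata pool conditions by default; with very unbalanced
  designs per-condition boundaries (available via flag) may be
  preferable.
- No multiple-testing machinery beyond raw p-values (Benjamini–Hochberg
  is left to post-processing), no survival or multi-group tests.
- Exact string motifs only; degenerate E-box variants beyond the two
  defaults must be listed explicitly, and N in sequences never matches.
- µm coordinates are assumed; the package never rescales units.
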