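# chronotime

Time-of-day analysis of the tumor immune microenvironment (TIME) from
spatial transcriptomic sections.

Tumor immune infiltration is under circadian control: in mice, tumors
harvested early in the light/inactive phase (zeitgeber time ZT2) carry more
myeloid cells and CD8⁺ T cells, in tighter spatial association, than tumors
harvested in the dark/active phase (ZT18). `chronotime` packages the
analyses needed to quantify such a two-timepoint contrast:

- **Cell typing** — per-cell scores from canonical marker panels
  (e.g. Cd3e/Cd8a for CD8⁺ T cells, Itgax/H2-Ab1 for CD11c⁺MHCII⁺ cDCs)
  on log-normalized counts, with margin-based abstention.
- **Proximity profiling** — for each cell of a source type, the Euclidean
  distance *d* to its nearest partner-type cell (T → myeloid and
  myeloid → T), pooled across whole sections and compared between
  conditions.
- **Distance-quantile expression** — cells stratified into *n* = 10
  equal-count distance quantiles; mean expression of chemokines
  (*Cxcl9, Cxcl10, Cxcl16, Ccl4, Ccl5, Xcl1*, measured in myeloid cells)
  and effector cytokines (*Ifng, Gzmb, Tnf, Prf1*, measured in T cells)
  per quantile, with the near→far gradient summarized by Spearman's ρ.
- **Cohort statistics** — Mann–Whitney rank-sum tests (exact enumeration
  for small samples, tie-corrected normal approximation otherwise),
  a pseudoreplication-safe section-level permutation test, per-section
  composition with Wilson intervals, and expressing-fraction summaries.
- **E-box promoter scanning** — exact both-strand scanning for
  BMAL1:CLOCK E-box motifs (CACGTG, CACGTT) with palindrome-aware
  deduplication and BED6 output.
- **Synthetic data** — a generator that emulates the two-condition design:
  myeloid cells from a Thomas cluster process, T cells attracted to myeloid
  cells with per-condition probability and scale, negative-binomial counts
  whose chemokine/effector means carry a planted proximity effect
  1 + β·e^(−d/τ), and promoters with E-boxes planted at known positions.
  Every planted effect is recorded as ground truth, so recovery is testable.

Sections travel as plain-text bundles: a cells TSV (id, x/y in µm, type,
section, condition), a genes × cells MatrixMarket count matrix with a
features TSV, and a JSON metadata sidecar.

## Worked example

```python
import numpy as np
from chronotime import (SimConfig, MarkerPanel, simulate_experiment,
                        annotate_section, nearest_partner_distances,
                        pool_profiles, rank_sum_test,
                        section_permutation_test,
                        mean_nearest_distance_stat)

cfg = SimConfig()                      # ZT2 vs ZT18 defaults
panel = MarkerPanel(cfg.marker_panel())
sections = [annotate_section(s, panel)
            for s, _ in simulate_experiment(cfg, 3, seed=1)]

profiles = {c: pool_profiles([nearest_partner_distances(s, "T", "myeloid")
                              for s in sections if s.condition == c])
            for c in ("ZT2", "ZT18")}
for c, p in profiles.items():
    print(f"{c}: n={len(p)} T cells, "
          f"median distance {np.median(p.distances):.1f} um")

res = rank_sum_test(profiles["ZT2"].distances, profiles["ZT18"].distances)
print(f"cell-level Mann-Whitney: U={res.statistic:.0f}, p={res.p_value:.3g}")
perm = section_permutation_test(
    mean_nearest_distance_stat("T", "myeloid"), sections)
print(f"section-level permutation: diff={perm.statistic:.1f} um, "
      f"p={perm.p_value:.3f}")
```

prints

```
ZT2: n=1576 T cells, median distance 16.2 um
ZT18: n=1052 T cells, median distance 27.3 um
cell-level Mann-Whitney: U=515510, p=4.94e-324
section-level permutation: diff=14.7 um, p=0.100
```

ZT2 sections hold ~50% more T cells than ZT18 (infiltration factor 1.5)
and their T cells sit markedly closer to myeloid partners (16 vs 27 µm
median), exactly the planted co-localization contrast.  The cell-level
rank-sum test on 2628 pooled cells is overwhelming; the section-level
permutation test, which treats the six sections (not the cells) as the
replicates, is at the resolution limit of a 3-vs-3 design (smallest
attainable p = 0.1) — the two tests are reported side by side precisely
because they answer differently sized questions.

The same pipeline is available from the shell:

```bash
chronotime simulate --seed 7 --out run/sim --sections-per-condition 3
chronotime annotate --in run/sim
chronotime report   --in run/sim --out run/report --plots
```

which writes the pooled distance profile, the 10-quantile expression matrix
(raw and row-z-scored), Spearman trends, composition and expressing-fraction
tables, both hypothesis tests, and optional violin/heatmap/bar figures.

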