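# metaorigin

Genome-wide analysis machinery for studying how cohesin and its accessory
factors (Pds5, Wapl, Brca2, Nipped-B) distribute around early DNA replication
origins, reimplemented as a tested, reusable Python library and driven end to
end by a seeded synthetic-data generator.

The package is aimed at chromatin biologists and computational people who
want the analysis stack behind origin-centered cohesin studies as composable,
verifiable functions: sliding-window ChIP enrichment against input chromatin,
meta-origin aggregation with per-bin statistics, percentile-based
binding-region calling with overlap statistics, regulatory-element enrichment
by class, depletion-contrast RNA expression comparison, and dual-label DNA
fiber statistics. Every stage runs on synthetic data with planted ground
truth, so the whole pipeline is testable offline with no downloads.

## The statistics at the core

**Enrichment.** For ChIP coverage $c$ and input coverage $i$ on a sliding
window of $w = 250$ bp advanced every $s = 50$ bp, the anchor value is

$$E_k=\log_2\frac{\sum_{x\in W_k} c(x) + 1}{\alpha\sum_{x\in W_k} i(x) + 1},
\qquad \alpha=\frac{N_\text{ChIP}}{N_\text{input}},$$

the log2 ratio of the window's ChIP counts to its depth-scaled input counts
with a one-count pseudocount. Replicates are averaged anchor-wise and their
agreement summarized by the genome-wide Pearson correlation.

**Meta-origin analysis.** Enrichment is averaged per origin in 10 kb bins
from −100 kb to +100 kb around each of the 78 strongest early-origin centers,
giving a 78 × 20 matrix per factor and condition. From it come the mean
profile, the per-bin factor stoichiometry ratio (for factors A, B the linear
ratio $2^{A_{oj}-B_{oj}}$ per origin and bin, averaged over origins — the
SA:Rad21 ratio is the canonical case), and the per-bin paired Wilcoxon
signed-rank test of depleted minus mock across origins, plotted as
−log10 p.

**Region calling.** Binding regions are maximal runs of anchors at or above
the genome-wide 95th percentile, extended by the full window, merged, and
kept when ≥300 bp. Overlap between two factors' region sets counts a region
as overlapping when it shares ≥1 bp (half-open semantics, as
`bedtools intersect` would report).

**Expression contrasts.** Per-gene log2 fold-change of depleted over mock
mean coverage (pseudocount 1), Welch t test on log2 values, BH q values;
contrasts are compared by genome-wide Pearson correlation of fold-changes and
by directional significant-gene overlap tested with Fisher's exact test.

**Fibers.** Connected IdU/CldU tract pairs; per-fiber CldU/IdU ratios,
group medians, and two-sided rank-sum comparisons.

## A worked example

```bash
python examples/03_metaorigin_analysis.py
```

prints, for a 78-origin, 52 Mb synthetic genome:

```
mock Rad21 mean profile (log2 enrichment, -100kb..+100kb):
  -0.09 -0.14 -0.14 -0.06 +0.03 +0.25 +0.34 +0.59 +0.72 +1.07 +1.13 +0.78 +0.67 +0.33 +0.18 +0.01 -0.08 -0.13 -0.14 -0.06

SA:Rad21 ratio: 1.084 at origin centers vs 0.976 in the outermost bins (elevated center stoichiometry)

mock vs domain-extension depletion, -log10 p per bin:
  5.6 9.1 8.2 7.8 6.8 8.9 6.5 6.2 1.2 12.7 12.7 2.0 7.4 6.8 6.8 6.3 5.7 9.1 8.1 7.9
```

Reading the numbers: occupancy is maximal at the origin-center bins and
decays outward (the meta-origin profile); the SA:Rad21 enrichment ratio is
elevated at origin cores relative to the flanks, the stoichiometry signature
of SA accumulation at origins; and after a simulated Pds5-style depletion
(decay scale ×2, flank amplitude ×1.5) every flanking bin beyond ±20 kb shows
a highly significant *increase* in cohesin — extended binding domains — while
the two central bins change least.

The other examples each exercise one capability: `01` simulation and
replicate agreement, `02` region calling and overlap, `04` element classes,
`05` expression contrasts, `06` fibers. A thin CLI wraps the same functions:

```bash
metaorigin-pipeline run-all --seed 1 --out run1
```

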