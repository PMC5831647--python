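# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic data do and do not establish.

## Analysis conventions

Coordinates are 0-based half-open throughout (BED/bedGraph convention).

**Windowed enrichment.** Anchors tile each chromosome from coordinate 0 with
250 bp windows every 50 bp; trailing bases that do not fill a window are
dropped, so a chromosome of length L has `(L−250)//50 + 1` anchors. The value
is `log2((ChIP_sum + pc) / (input_sum·α + pc))` with pseudocount `pc = 1`
count per window on both numerator and denominator (guarantees finite values)
and `α = total ChIP depth / total input depth` scaling the deeply sequenced
input down to the ChIP library size. Enrichment is stored and manipulated in
log2; wherever a *ratio of enrichments* is taken (stoichiometry profiles,
element ratios) it is computed in the linear domain as `2^(a−b)`, reading
"ratio of mean enrichment" as a ratio of magnitudes.

**Meta-origin binning.** An anchor belongs to a bin when its window midpoint
falls in the half-open bin interval; origin "center" is the single coordinate
of the origin record (midpoint if an interval is supplied). Bins extending
past a chromosome end are missing (NaN), never zero, and all per-bin
statistics are missing-aware. The per-bin test is the paired Wilcoxon
signed-rank over origins, two-sided, with Wilcoxon's original drop-zeros
rule and average ranks for ties; the exact null distribution is used for
≤25 usable pairs and the normal approximation with continuity correction
otherwise. Raw p values are reported per bin (profiles of −log10 p);
Benjamini–Hochberg adjustment is available for decision rules such as the
planted-recovery checks.

**Region calling.** The threshold is the percentile (linear interpolation
between order statistics) of all anchor values pooled across the included
chromosomes jointly — one genome-wide threshold, matching how single
genome-wide site counts are reported. Anchors exactly at the threshold are
included. Runs of consecutive qualifying anchors become intervals from the
first window's start to the last window's end; because the window (250 bp)
exceeds the step (50 bp), two runs separated by a single failing anchor can
overlap after extension, and such intervals are merged before the ≥300 bp
length filter so that called regions are always disjoint. The region's score
is the mean of its qualifying anchors.

**Expression contrasts.** The per-gene test is Welch's t on
`log2(coverage + 1)`; the original study does not name its
differential-expression statistic, so this is a package choice, recorded
here, selected for robustness to unequal replicate counts (three depleted vs
six mock replicates) and unequal variances. BH correction runs across all
genes in the matrix. Directional overlap between two contrasts partitions
genes by significance (p ≤ 0.05 by default; q optional) and fold-change
sign, and tests increase/increase and decrease/decrease overlaps against the
shared gene universe with Fisher's exact test (one-sided enrichment and
two-sided both reported). The wing-disc active-gene rule takes the union of
genes at or above the control median in control means and in mutant means.

**Fibers.** Group comparisons use the unpaired two-sided
Mann-Whitney/Wilcoxon rank-sum (groups are different cells), exact for ≤20
fibers per group and asymptotic with tie correction otherwise. Treated and
untreated fibers are pooled by default (first-label tracts are combined
across treatment in the source experiment design); a flag restricts to
untreated fibers.

## The synthetic-data generator

The generator's defaults define the study conditions every test and the
acceptance script run under.

**Genome.** Chromosome lengths and origin positions are explicit inputs. The
full-scale genome (`full_scale_genome_spec`) places 78 origins (two arms of
39, spaced 160 kb, ≥200 kb from chromosome ends) and adds origin-free
chromosomes carrying 3× the origin-territory mass. The background mass
matters: enrichment is normalized by total library depth, and a depletion
that extends binding domains inflates total ChIP signal; if origin territory
were the whole genome, that inflation would drag baseline regions down far
enough to mask the flanking increases. In the fly genome the strongest early
origins cover a small minority of the euchromatin; 3× background (origin
territory = 25% of the genome) is a computational compromise that preserves
the qualitative behaviour.

**Genes and elements.** Genes tile the chromosomes (5 kb genes, 2.5 kb
spacing); each is active with probability 0.55, raised to 0.8 within
±100 kb of an origin (origins lie in active-gene-rich regions). Each active
gene carries a log-normal strength multiplier (log-SD 0.6) — genes differ
reproducibly in how much factor they bind, which is what gives replicate
tracks their shared genome-wide variance. Promoters are 500 bp elements at
active gene starts; enhancers and PREs are 500 bp elements in intergenic
gaps; random controls are placed uniformly, avoiding an optional exclusion
set.

**ChIP occupancy.** Expected occupancy at position x is
`baseline + amplitude · m(d) · exp(−d / (decay·decay_mult)) · strength(x)`
gated to active genes (elsewhere baseline only, emulating the skipping of
inactive genes and intergenic DNA), where d is the distance to the nearest
origin and `m(d)` interpolates between an origin-core multiplier and a flank
multiplier with a 5 kb core scale. Defaults: baseline 1, amplitude 6 (peak
log2 enrichment ≈ 1–3, matching browser-scale tracks), decay 25 kb.
Factor-intrinsic origin accumulation (the elevated SA:Rad21 center
stoichiometry) is the model's `origin_boost` (SA default 1.6 in the
pipeline). Depletion conditions are multiplier triplets on (decay scale,
origin amplitude, flank amplitude); the mock condition is all ones by
construction. The canonical conditions are: domain extension (decay ×2,
flank ×1.5) for Pds5/Wapl-style loss; origin-SA gain (origin ×1.6) for
Brca2-style loss; origin-SA loss plus domain extension for Pds5-style loss.

**Reads.** Fragment starts are Poisson with per-base rates proportional to
occupancy, normalized to the requested depth, and extended by a fixed 300 bp
fragment (typical sonication size). Replicate-specific biological/technical
noise is a per-500 bp-block gamma multiplier with dispersion 0.02 by default;
`calibrate_dispersion` bisects the dispersion so replicate enrichment
correlation lands in a requested band (the source data report a 0.65–0.9
band, not a noise model). Input tracks are uniform-rate Poisson at 45×
depth; ChIP default depth is 30×. One deep input may be shared as the
normalization reference for several conditions, as is standard when multiple
precipitations are normalized to the same input chromatin.

**Expression.** True per-depletion log2 fold-changes are
`sd · mask · (√ρ·z_shared + √(1−ρ)·z_depletion)` with a shared
affected-gene mask (fraction 0.3, SD 0.5), making the pairwise correlation
between depletion effect vectors exactly ρ (default 0.6, the observed
correlation between paired factors) in expectation. Observed replicates add
N(0, 0.15) log2 noise to a log-normal baseline (log2 SD 2), which puts
replicate correlations above 0.99. Estimation noise attenuates the
recovered between-contrast correlation to ≈0.52–0.59, within the ±0.1
recovery band.

**Fibers.** First-label tracts are log-normal (median 8 µm, log-SD 0.4);
the connected second-label tract is the first times the stall factor (0.5
under treatment by default) times log-normal ratio noise (log-SD 0.25), so
the median second/first ratio equals the stall factor.

All generators draw every random quantity from one explicit seed per call
(numpy `SeedSequence`); a fixed seed reproduces outputs byte for byte.

## Problem sizes

The default test and acceptance problem sizes are: unit oracles on tracks of
10²–10³ anchors; planted-recovery runs on the 52 Mb, 78-origin genome at 30×
ChIP / 45× input depth (50 seeded runs for the domain-extension recovery
rate in the test suite, 12 in the acceptance script's reported fraction);
2,000 null simulations per statistical-calibration check; 5,000 genes for
expression recovery; 200 fibers per group. These sizes were chosen so the
full suite runs comfortably on a single CPU while keeping every planted
effect comfortably inside its detection regime.

## What the synthetic data do not show

The generator reproduces the statistical *structure* the analysis assumes —
origin-centered decay, active-gene gating, stoichiometry boosts, correlated
depletion effects, band-calibrated replicate noise — not real chromatin.
It has no fragment-size variation, GC or mappability bias, duplicate reads,
peak fine structure, chromatin-state heterogeneity, or biological coupling
between the ChIP, expression and fiber layers (they are simulated
independently). Passing tests therefore establish that the implementation
computes its statistics correctly and recovers planted structure at
realistic noise levels, not that the biological conclusions would replicate
on new real data.

## Known limitations

- Region calling follows this package's stated run/merge/filter rule; the
  thresholding tool originally used to draw browser BED files may break ties
  or merge runs differently, so exact site counts are rule-dependent.
- The per-gene expression test is a package choice (see above); q values are
  comparable within, not across, choices of test.
- The bundled 78-record origin file is a synthetic stand-in with fly-like
  chromosome arm names; only its record count and format are meaningful.
- Ratios of enrichment are linear-domain means of per-origin ratios; a
  log-domain convention would give slightly different profile values.
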