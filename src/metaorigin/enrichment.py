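"""Input-normalized sliding-window ChIP enrichment.

Enrichment relative to input chromatin is computed in 250 bp sliding windows
advanced every 50 bp.  For anchor ``i`` on a chromosome the value is

    log2( (chip_window_sum + pc) / (input_window_sum * s + pc) )

where ``s = total_chip_depth / total_input_depth`` scales the (deeply
sequenced) input to the ChIP library depth and ``pc`` is a pseudocount of one
count per window that keeps every value finite.  Replicate tracks are averaged
anchor-wise, replicate agreement is quantified by genome-wide Pearson
correlation, and condition-vs-reference comparisons are per-anchor differences
of log2 enrichment (i.e. log2 fold-changes of enrichment).
"""

from __future__ import annotations

import numpy as np

from .tracks import CoverageTrack, EnrichmentTrack, n_anchors

__all__ = [
    "compute_enrichment",
    "average_replicates",
    "replicate_correlation",
    "fold_change_track",
    "window_sums",
]

DEFAULT_WINDOW = 250
DEFAULT_STEP = 50
DEFAULT_PSEUDOCOUNT = 1.0


def window_sums(depth: np.ndarray, window: int, step: int) -> np.ndarray:
    """Sliding-window sums of a per-base array via a cumulative sum.

    Windows start at 0, window, ... and trailing bases not filling a full
    window are dropped.
    """
    count = n_anchors(len(depth), window, step)
    if count == 0:
        return np.zeros(0)
    cs = np.concatenate([[0.0], np.cumsum(depth, dtype=np.float64)])
    starts = np.arange(count) * step
    return cs[starts + window] - cs[starts]


def compute_enrichment(
    chip: CoverageTrack,
    input_: CoverageTrack,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentTrack:
    """log2 enrichment of ChIP over depth-scaled input on the anchor grid."""
    if window < step:
        raise ValueError("window must be >= step")
    if chip.chrom_lengths != input_.chrom_lengths:
        raise ValueError("ChIP and input tracks have mismatched chromosomes/lengths")
    input_total = input_.total_depth
    if input_total == 0:
        raise ValueError("input track has zero depth genome-wide")
    scale = chip.total_depth / input_total

    values = {}
    for chrom, chip_arr in chip.data.items():
        cs = window_sums(chip_arr, window, step)
        ins = window_sums(input_.data[chrom], window, step)
        values[chrom] = np.log2((cs + pseudocount) / (ins * scale + pseudocount))
    return EnrichmentTrack(
        values=values,
        chrom_lengths=dict(chip.chrom_lengths),
        window=window,
        step=step,
        samples=(chip.sample, input_.sample),
        n_replicates=1,
    )


def average_replicates(tracks: list[EnrichmentTrack]) -> EnrichmentTrack:
    """Anchor-wise arithmetic mean of replicate enrichment tracks."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        first.require_same_grid(t)
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.values
    }
    samples = tuple(s for t in tracks for s in t.samples)
    return EnrichmentTrack(
        values=values,
        chrom_lengths=dict(first.chrom_lengths),
        window=first.window,
        step=first.step,
        samples=samples,
        n_replicates=sum(t.n_replicates for t in tracks),
    )


def replicate_correlation(
    a: EnrichmentTrack,
    b: EnrichmentTrack,
    chromosomes=None,
    region: tuple[str, int, int] | None = None,
) -> float:
    """Pearson correlation of two enrichment tracks.

    Computed genome-wide over all anchors by default.  ``region`` restricts
    the comparison to anchors whose window midpoint lies within
    ``(chrom, start, end)`` — the restricted-region variant used to look at a
    single locus.
    """
    a.require_same_grid(b)
    if region is not None:
        chrom, start, end = region
        mid = a.anchor_midpoints(chrom)
        mask = (mid >= start) & (mid < end)
        x, y = a.values[chrom][mask], b.values[chrom][mask]
    else:
        x = a.concat_values(chromosomes)
        y = b.concat_values(chromosomes)
    if len(x) < 2:
        raise ValueError("need at least two anchors for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance track: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def fold_change_track(cond: EnrichmentTrack, ref: EnrichmentTrack) -> EnrichmentTrack:
    """Per-anchor difference of log2 enrichments (log2 fold-change track)."""
    cond.require_same_grid(ref)
    values = {c: cond.values[c] - ref.values[c] for c in cond.values}
    return EnrichmentTrack(
        values=values,
        chrom_lengths=dict(cond.chrom_lengths),
        window=cond.window,
        step=cond.step,
        samples=cond.samples + ref.samples,
        n_replicates=1,
    )
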