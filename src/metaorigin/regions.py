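"""Percentile-threshold binding-region calling and overlap statistics.

Binding regions are called from an enrichment track with the rule: take the
given percentile (default 95th) of all anchor values on the included
chromosomes jointly, keep maximal runs of consecutive anchors at or above that
threshold, convert each run to the interval from the first anchor's window
start to the last anchor's window end, merge intervals that overlap after this
window extension, and discard intervals shorter than the minimum length
(default 300 bp).  Overlap between two region sets counts an A region as
overlapping when it shares at least one base with any B region (half-open
semantics, as bedtools intersect would report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import EnrichmentTrack

__all__ = [
    "BindingRegion",
    "OverlapReport",
    "call_regions",
    "intersect_region_sets",
    "regions_to_frame",
    "write_regions_bed",
    "read_regions_bed",
]


@dataclass(frozen=True)
class BindingRegion:
    """One called interval, 0-based half-open, with its mean enrichment."""

    chrom: str
    start: int
    end: int
    mean_enrichment: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of region set A with region set B.

    ``fraction`` is overlap count / |A|; ``fraction_pct`` rounds it to the
    nearest percent, the resolution at which such overlaps are usually
    reported.
    """

    n_a: int
    n_b: int
    n_overlap: int

    def __post_init__(self) -> None:
        if self.n_overlap > self.n_a:
            raise ValueError("overlap count exceeds |A|")

    @property
    def fraction(self) -> float:
        return self.n_overlap / self.n_a if self.n_a else 0.0

    @property
    def fraction_pct(self) -> int:
        return int(round(100.0 * self.fraction))

    @classmethod
    def from_counts(cls, n_a: int, n_b: int, n_overlap: int) -> "OverlapReport":
        return cls(n_a=n_a, n_b=n_b, n_overlap=n_overlap)


def call_regions(
    track: EnrichmentTrack,
    percentile: float = 95.0,
    min_len: int = 300,
    chromosomes=None,
) -> list[BindingRegion]:
    """Call binding regions by percentile threshold and minimum length.

    ``chromosomes`` is the include-list over which both the threshold and the
    calls are computed (the "euchromatic" chromosome arms at full scale); by
    default all chromosomes in the track are used.  The percentile uses linear
    interpolation between order statistics and anchors exactly at the
    threshold are kept ("at or greater").
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    chroms = sorted(track.values) if chromosomes is None else list(chromosomes)
    if not chroms:
        raise ValueError("empty chromosome include-list")
    pooled = track.concat_values(chroms)
    if pooled.size == 0:
        raise ValueError("track has no anchors on the included chromosomes")
    threshold = float(np.percentile(pooled, percentile))

    out: list[BindingRegion] = []
    for chrom in chroms:
        vals = track.values[chrom]
        mask = vals >= threshold
        if not mask.any():
            continue
        # maximal runs of consecutive above-threshold anchors
        idx = np.flatnonzero(mask)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = idx[np.concatenate([[0], breaks + 1])]
        run_ends = idx[np.concatenate([breaks, [len(idx) - 1]])]
        intervals = [
            (int(s0) * track.step, int(s1) * track.step + track.window)
            for s0, s1 in zip(run_starts, run_ends)
        ]
        # window extension can make adjacent runs overlap; merge them
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.arange(len(vals)) * track.step
        for s, e in merged:
            if e - s < min_len:
                continue
            inside = (starts >= s) & (starts + track.window <= e) & mask
            out.append(BindingRegion(chrom, s, e, float(vals[inside].mean())))
    return out


def _check_sorted_disjoint(regions: list[BindingRegion], label: str) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[BindingRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    arrays = {}
    for chrom, rs in by_chrom.items():
        starts = np.array([r.start for r in rs])
        ends = np.array([r.end for r in rs])
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"region set {label} is unsorted or overlapping on {chrom}")
        arrays[chrom] = np.stack([starts, ends])
    return arrays


def intersect_region_sets(a: list[BindingRegion], b: list[BindingRegion]) -> OverlapReport:
    """Count A regions sharing >= 1 bp with any B region."""
    a_arr = _check_sorted_disjoint(a, "A")
    b_arr = _check_sorted_disjoint(b, "B")
    n_overlap = 0
    for chrom, (astarts, aends) in a_arr.items():
        if chrom not in b_arr:
            continue
        bstarts, bends = b_arr[chrom]
        # a overlaps some b iff the first b with end > a.start begins before a.end
        idx = np.searchsorted(bends, astarts, side="right")
        hit = (idx < len(bstarts)) & (bstarts[np.minimum(idx, len(bstarts) - 1)] < aends)
        n_overlap += int(hit.sum())
    return OverlapReport(n_a=len(a), n_b=len(b), n_overlap=n_overlap)


# ---------------------------------------------------------------------------
# BED IO (mean enrichment in the score column)
# ---------------------------------------------------------------------------

def regions_to_frame(regions: list[BindingRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, f"region_{i+1}", r.mean_enrichment, ".")
         for i, r in enumerate(regions)],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_regions_bed(regions: list[BindingRegion], path) -> None:
    regions_to_frame(regions).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def read_regions_bed(path) -> list[BindingRegion]:
    df = pd.read_csv(
        path, sep="\t", header=None, dtype={0: str},
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        BindingRegion(row.chrom, int(row.start), int(row.end), float(row.score))
        for row in df.itertuples()
    ]
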