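"""Coverage and enrichment track containers.

A :class:`CoverageTrack` holds per-base read depth for one sequencing sample
(one non-negative integer array per chromosome).  An :class:`EnrichmentTrack`
holds log2 ChIP/input enrichment values anchored on a regular grid: one value
per ``step`` bp, each computed from a ``window`` bp sliding window starting at
the anchor coordinate.  Both are thin wrappers around plain numpy arrays so
that every downstream statistic can be written (and independently re-derived)
with ordinary array operations.

Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "EnrichmentTrack",
    "n_anchors",
    "read_bedgraph_coverage",
    "write_bedgraph_coverage",
    "write_bedgraph_enrichment",
]


def n_anchors(length: int, window: int, step: int) -> int:
    """Number of full sliding windows on a chromosome of ``length`` bp.

    Windows tile left-to-right from coordinate 0; trailing bases that do not
    fit a full window are dropped, so the count is ``(L - window)//step + 1``
    (0 when the chromosome is shorter than one window).
    """
    if length < window:
        return 0
    return (length - window) // step + 1


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample.

    Parameters
    ----------
    data:
        Mapping chromosome name -> integer depth array, one entry per base.
    sample:
        Free-form sample identifier carried through to provenance.
    """

    data: dict[str, np.ndarray]
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"coverage for {chrom!r} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom!r}")
            self.data[chrom] = arr

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    @property
    def total_depth(self) -> float:
        """Total base coverage (sum of per-base depth over the genome)."""
        return float(sum(a.sum() for a in self.data.values()))

    def mean_depth(self) -> float:
        total_len = sum(self.chrom_lengths.values())
        return self.total_depth / total_len if total_len else 0.0


@dataclass
class EnrichmentTrack:
    """log2(ChIP/input) values on a regular anchor grid.

    ``values[chrom][i]`` is the enrichment of the window
    ``[i*step, i*step + window)``.  The window midpoint, used for bin and
    element membership downstream, is ``i*step + window/2``.
    """

    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    window: int = 250
    step: int = 50
    samples: tuple[str, ...] = ()
    n_replicates: int = 1

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            expect = n_anchors(self.chrom_lengths[chrom], self.window, self.step)
            if len(arr) != expect:
                raise ValueError(
                    f"{chrom!r}: {len(arr)} anchors, expected {expect} for "
                    f"length {self.chrom_lengths[chrom]}"
                )
            self.values[chrom] = arr

    def same_grid(self, other: "EnrichmentTrack") -> bool:
        return (
            self.window == other.window
            and self.step == other.step
            and self.chrom_lengths == other.chrom_lengths
            and set(self.values) == set(other.values)
        )

    def require_same_grid(self, other: "EnrichmentTrack") -> None:
        if not self.same_grid(other):
            raise ValueError("enrichment tracks are on different anchor grids")

    def anchor_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.values[chrom])) * self.step

    def anchor_midpoints(self, chrom: str) -> np.ndarray:
        return self.anchor_starts(chrom) + self.window / 2.0

    def concat_values(self, chromosomes=None) -> np.ndarray:
        chroms = sorted(self.values) if chromosomes is None else list(chromosomes)
        missing = [c for c in chroms if c not in self.values]
        if missing:
            raise KeyError(f"unknown chromosomes: {missing}")
        return np.concatenate([self.values[c] for c in chroms]) if chroms else np.array([])


# ---------------------------------------------------------------------------
# bedGraph IO (4-column, 0-based half-open)
# ---------------------------------------------------------------------------

def write_bedgraph_coverage(track: CoverageTrack, path) -> None:
    """Write per-base coverage as run-length-compressed bedGraph."""
    rows = []
    for chrom in sorted(track.data):
        arr = track.data[chrom]
        if len(arr) == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        vals = arr[starts]
        for s, e, v in zip(starts, ends, vals):
            rows.append((chrom, int(s), int(e), int(v)))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph_coverage(path, chrom_lengths: dict[str, int], sample: str = "") -> CoverageTrack:
    """Read a bedGraph into a per-base CoverageTrack.

    ``chrom_lengths`` defines the full array sizes; positions not covered by
    any bedGraph record are zero.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    data = {c: np.zeros(length, dtype=np.int64) for c, length in chrom_lengths.items()}
    for chrom, sub in df.groupby("chrom"):
        if chrom not in data:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom_lengths")
        arr = data[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            if e > len(arr):
                raise ValueError(f"record {chrom}:{s}-{e} exceeds chromosome length")
            arr[s:e] = v
    return CoverageTrack(data=data, sample=sample)


def write_bedgraph_enrichment(track: EnrichmentTrack, path) -> None:
    """Write anchor values as bedGraph intervals of ``step`` bp."""
    rows = []
    for chrom in sorted(track.values):
        starts = track.anchor_starts(chrom)
        for s, v in zip(starts, track.values[chrom]):
            rows.append((chrom, int(s), int(s) + track.step, float(v)))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )
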