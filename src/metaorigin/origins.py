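"""Meta-origin aggregation and per-bin statistics.

Enrichment is aggregated around early replication-origin centers into an
origin x bin matrix: for each origin, the mean enrichment of all anchors whose
window midpoint falls in each 10 kb bin from -100 kb to +100 kb (20 bins at
the defaults).  Bins extending past a chromosome end are missing (NaN), never
zero.  From the matrix the module derives the missing-aware mean profile, the
factor stoichiometry ratio profile (e.g. SA to Rad21, computed per origin and
bin in the linear enrichment domain, then averaged across origins) and the
per-bin paired Wilcoxon signed-rank test between a mock and a depleted
condition, the test behind the -log10 p meta-origin panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import EnrichmentTrack

__all__ = [
    "OriginSet",
    "OriginBinMatrix",
    "BinTestResult",
    "RatioProfile",
    "bin_matrix",
    "mean_profile",
    "ratio_profile",
    "bin_wilcoxon",
]

DEFAULT_FLANK = 100_000
DEFAULT_BIN = 10_000


@dataclass
class OriginSet:
    """Replication-origin centers: (chromosome, center bp) pairs."""

    chroms: list[str]
    centers: list[int]
    label: str = "origins"

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.centers):
            raise ValueError("chroms and centers differ in length")
        self.centers = [int(c) for c in self.centers]

    def __len__(self) -> int:
        return len(self.centers)

    @classmethod
    def from_bed(cls, path, label: str = "origins") -> "OriginSet":
        """Read origins from BED (center = interval midpoint) or a 2-column
        ``chrom<TAB>center`` table."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] >= 3 and pd.api.types.is_numeric_dtype(df[2]):
            centers = ((df[1] + df[2]) // 2).astype(int)
        else:
            centers = df[1].astype(int)
        return cls(chroms=list(df[0]), centers=list(centers), label=label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "center": self.centers})


@dataclass
class OriginBinMatrix:
    """Per-origin x per-bin mean enrichment.

    ``matrix[o, j]`` is the mean anchor enrichment of origin ``o`` in bin
    ``j``; ``bin_offsets[j]`` is the bin's start offset from the origin
    center.  Missing bins (past a chromosome end, or containing no anchor)
    are NaN.
    """

    matrix: np.ndarray
    bin_offsets: np.ndarray
    origins: OriginSet
    label: str = ""

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def bin_size(self) -> int:
        return int(self.bin_offsets[1] - self.bin_offsets[0]) if len(self.bin_offsets) > 1 else 0

    def require_same_shape(self, other: "OriginBinMatrix") -> None:
        if self.matrix.shape != other.matrix.shape or not np.array_equal(
            self.bin_offsets, other.bin_offsets
        ):
            raise ValueError("origin-bin matrices have mismatched shapes/bins")


@dataclass
class BinTestResult:
    """Per-bin paired Wilcoxon signed-rank results (two-sided)."""

    table: pd.DataFrame  # bin_start_offset, bin_end_offset, n, p, minus_log10_p, direction

    def significant_bins(self, alpha: float = 0.05, adjust: bool = False) -> np.ndarray:
        """Boolean mask of significant bins, optionally BH-adjusted."""
        p = self.table["p"].to_numpy()
        if adjust:
            from statsmodels.stats.multitest import multipletests

            ok = np.isfinite(p)
            q = np.full_like(p, np.nan)
            if ok.any():
                q[ok] = multipletests(p[ok], method="fdr_bh")[1]
            return q <= alpha
        return p <= alpha


@dataclass
class RatioProfile:
    """Per-bin mean of per-origin linear-domain enrichment ratios."""

    table: pd.DataFrame  # bin_start_offset, bin_end_offset, ratio, n
    labels: tuple[str, str] = ("num", "den")


def bin_matrix(
    track: EnrichmentTrack,
    origins: OriginSet,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
    label: str = "",
) -> OriginBinMatrix:
    """Mean enrichment per origin in ``bin_size`` bins spanning +/- ``flank``.

    An anchor belongs to bin ``j`` of an origin when its window midpoint lies
    in ``[center - flank + j*bin, center - flank + (j+1)*bin)``.  Bins that
    extend past either chromosome end are NaN.
    """
    if len(origins) == 0:
        raise ValueError("origin set is empty")
    if 2 * flank % bin_size != 0:
        raise ValueError("2*flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    offsets = -flank + np.arange(n_bins) * bin_size
    mat = np.full((len(origins), n_bins), np.nan)

    mids_cache = {c: track.anchor_midpoints(c) for c in track.values}
    for o, (chrom, center) in enumerate(zip(origins.chroms, origins.centers)):
        if chrom not in track.values:
            raise ValueError(f"origin on unknown chromosome {chrom!r}")
        mids = mids_cache[chrom]
        vals = track.values[chrom]
        length = track.chrom_lengths[chrom]
        lo, hi = center - flank, center + flank
        sel = np.searchsorted(mids, [lo, hi])
        m, v = mids[sel[0]:sel[1]], vals[sel[0]:sel[1]]
        bins = ((m - lo) // bin_size).astype(int)
        sums = np.bincount(bins, weights=v, minlength=n_bins)
        counts = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            row = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        # bins past chromosome ends are missing regardless of anchor content
        bin_lo = lo + np.arange(n_bins) * bin_size
        out_of_bounds = (bin_lo < 0) | (bin_lo + bin_size > length)
        row[out_of_bounds] = np.nan
        mat[o] = row
    return OriginBinMatrix(matrix=mat, bin_offsets=offsets, origins=origins, label=label)


def mean_profile(m: OriginBinMatrix) -> pd.DataFrame:
    """Missing-aware column means with per-bin origin counts."""
    if m.matrix.shape[0] < 1:
        raise ValueError("matrix has no origins")
    n = np.sum(np.isfinite(m.matrix), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(np.where(np.isfinite(m.matrix), m.matrix, np.nan), axis=0), np.nan)
    return pd.DataFrame(
        {
            "bin_start_offset": m.bin_offsets,
            "bin_end_offset": m.bin_offsets + m.bin_size,
            "mean_enrichment": mean,
            "n": n,
        }
    )


def ratio_profile(
    num: OriginBinMatrix,
    den: OriginBinMatrix,
    log2_input: bool = True,
) -> RatioProfile:
    """Mean per-origin enrichment ratio per bin, in the linear domain.

    With ``log2_input`` (the default, matching how enrichment tracks are
    stored) the per-origin per-bin ratio is ``2**(num - den)``.  Entries with
    a missing or non-positive denominator are missing.
    """
    num.require_same_shape(den)
    if num.origins.chroms != den.origins.chroms or num.origins.centers != den.origins.centers:
        raise ValueError("ratio_profile requires identical origin sets")
    if log2_input:
        ratios = np.power(2.0, num.matrix - den.matrix)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(den.matrix > 0, num.matrix / den.matrix, np.nan)
    valid = np.isfinite(ratios)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(valid, ratios, 0.0), axis=0) / np.maximum(n, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_start_offset": num.bin_offsets,
            "bin_end_offset": num.bin_offsets + num.bin_size,
            "ratio": mean,
            "n": n,
        }
    )
    return RatioProfile(table=table, labels=(num.label or "num", den.label or "den"))


def bin_wilcoxon(
    mock: OriginBinMatrix,
    depleted: OriginBinMatrix,
    exact_max_n: int = 25,
) -> BinTestResult:
    """Paired Wilcoxon signed-rank test per bin across origins.

    Per bin the paired differences ``depleted - mock`` over origins are
    tested two-sided.  Zero differences are dropped before ranking
    (Wilcoxon's original rule); the exact null distribution is used when the
    effective n is at most ``exact_max_n`` and the normal approximation with
    continuity correction otherwise.  Bins with fewer than two usable pairs
    get a missing p.
    """
    mock.require_same_shape(depleted)
    rows = []
    for j in range(mock.n_bins):
        x = mock.matrix[:, j]
        y = depleted.matrix[:, j]
        ok = np.isfinite(x) & np.isfinite(y)
        d = y[ok] - x[ok]
        d = d[d != 0.0]
        if len(d) < 2:
            p, direction = np.nan, 0
        else:
            method = "exact" if len(d) <= exact_max_n else "approx"
            try:
                res = stats.wilcoxon(
                    d, zero_method="wilcox", alternative="two-sided",
                    correction=True, method=method,
                )
                p = float(res.pvalue)
            except ValueError:
                p = np.nan
            direction = int(np.sign(np.median(d)))
        rows.append(
            (
                int(mock.bin_offsets[j]),
                int(mock.bin_offsets[j] + mock.bin_size),
                int(len(d)),
                p,
                -np.log10(p) if np.isfinite(p) and p > 0 else np.nan,
                direction,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["bin_start_offset", "bin_end_offset", "n", "p", "minus_log10_p", "direction"],
    )
    return BinTestResult(table=table)
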