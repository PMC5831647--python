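"""Factor enrichment at 500 bp regulatory elements, by class.

Elements (active promoters, extragenic enhancers, PREs, and random 500 bp
controls) are scored by the mean enrichment of all anchors whose window
midpoint lies within the element.  Per-element factor ratios are computed in
the linear enrichment domain and summarized by class medians; mock-vs-depleted
differences per class are tested with a paired Wilcoxon signed-rank over
elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import EnrichmentTrack

__all__ = [
    "ElementSet",
    "ElementEnrichment",
    "element_enrichment",
    "element_ratio",
    "sample_random_elements",
    "class_depletion_test",
    "ELEMENT_LENGTH",
]

ELEMENT_LENGTH = 500
ELEMENT_CLASSES = ("promoter", "enhancer", "PRE", "random")


@dataclass
class ElementSet:
    """500 bp regulatory elements with class labels.

    ``table`` has columns chrom, start, end, klass; every element is exactly
    500 bp.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if not (t["end"] - t["start"] == ELEMENT_LENGTH).all():
            raise ValueError(f"all elements must be exactly {ELEMENT_LENGTH} bp")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def class_counts(self) -> pd.Series:
        return self.table["klass"].value_counts()

    @classmethod
    def from_bed(cls, path) -> "ElementSet":
        df = pd.read_csv(
            path, sep="\t", header=None, dtype={0: str},
            names=["chrom", "start", "end", "klass", "score", "strand"],
        )
        return cls(table=df[["chrom", "start", "end", "klass"]])

    def to_bed(self, path) -> None:
        out = self.table.copy()
        out["score"] = 0
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ElementEnrichment:
    """Per-element mean enrichment for one factor/condition.

    ``values`` aligns with ``elements.table`` rows; elements overlapping no
    anchor are NaN.
    """

    elements: ElementSet
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.elements):
            raise ValueError("one value per element required")

    def by_class(self) -> dict[str, np.ndarray]:
        k = self.elements.table["klass"].to_numpy()
        return {c: self.values[k == c] for c in pd.unique(k)}

    def class_medians(self) -> pd.Series:
        return pd.Series({c: float(np.nanmedian(v)) if np.isfinite(v).any() else np.nan
                          for c, v in self.by_class().items()})


def element_enrichment(track: EnrichmentTrack, elements: ElementSet, label: str = "") -> ElementEnrichment:
    """Mean anchor enrichment within each element (window-midpoint rule)."""
    values = np.full(len(elements), np.nan)
    mids_cache = {}
    for chrom, sub in elements.table.groupby("chrom"):
        if chrom not in track.values:
            raise ValueError(f"element on unknown chromosome {chrom!r}")
        if chrom not in mids_cache:
            mids_cache[chrom] = track.anchor_midpoints(chrom)
        mids = mids_cache[chrom]
        vals = track.values[chrom]
        lo = np.searchsorted(mids, sub["start"].to_numpy())
        hi = np.searchsorted(mids, sub["end"].to_numpy())
        for row_idx, a, b in zip(sub.index, lo, hi):
            if b > a:
                values[row_idx] = vals[a:b].mean()
    return ElementEnrichment(elements=elements, values=values, label=label)


def element_ratio(a: ElementEnrichment, b: ElementEnrichment, log2_input: bool = True) -> pd.DataFrame:
    """Per-element linear-domain enrichment ratio a/b with class labels.

    Returns a frame with columns chrom, start, end, klass, ratio; class
    medians are available via ``.groupby("klass")["ratio"].median()``.
    """
    if not a.elements.table.equals(b.elements.table):
        raise ValueError("element sets differ between the two enrichments")
    if log2_input:
        ratio = np.power(2.0, a.values - b.values)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(b.values > 0, a.values / b.values, np.nan)
    out = a.elements.table.copy()
    out["ratio"] = ratio
    return out


def sample_random_elements(
    chrom_lengths: dict[str, int],
    n: int = 6892,
    length: int = ELEMENT_LENGTH,
    seed: int = 0,
    exclusion: ElementSet | None = None,
    chromosomes=None,
    max_tries_per_element: int = 1000,
) -> ElementSet:
    """Place ``n`` random ``length`` bp control elements uniformly.

    Chromosomes are chosen proportionally to length; placements intersecting
    the optional exclusion set are rejected and re-drawn, with a bounded
    retry budget per element.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths) if chromosomes is None else list(chromosomes)
    usable = {c: chrom_lengths[c] - length for c in chroms if chrom_lengths[c] >= length}
    if n > 0 and not usable:
        raise ValueError("no chromosome long enough for an element")

    excl: dict[str, np.ndarray] = {}
    if exclusion is not None:
        for chrom, sub in exclusion.table.groupby("chrom"):
            iv = sub[["start", "end"]].to_numpy()
            iv = iv[np.argsort(iv[:, 0])]
            excl[chrom] = iv

    names = list(usable)
    weights = np.array([usable[c] + 1 for c in names], dtype=float)
    weights /= weights.sum() if names else 1.0

    rows = []
    for _ in range(n):
        for _try in range(max_tries_per_element):
            chrom = names[rng.choice(len(names), p=weights)]
            start = int(rng.integers(0, usable[chrom] + 1))
            end = start + length
            iv = excl.get(chrom)
            if iv is not None and len(iv):
                j = np.searchsorted(iv[:, 0], end)
                if j > 0 and iv[:j, 1].max() > start:
                    continue
            rows.append((chrom, start, end, "random"))
            break
        else:
            raise ValueError(
                f"could not place element after {max_tries_per_element} tries; "
                "exclusion set too dense"
            )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "klass"])
    if n == 0:
        table = pd.DataFrame(columns=["chrom", "start", "end", "klass"]).astype(
            {"start": int, "end": int}
        )
    return ElementSet(table=table)


def class_depletion_test(mock: ElementEnrichment, depleted: ElementEnrichment) -> pd.DataFrame:
    """Paired Wilcoxon per element class for depleted - mock shifts.

    Returns one row per class: n (usable pairs after dropping zeros and
    missing values), median difference, direction, two-sided p.  Classes with
    fewer than two usable elements get a missing p.
    """
    if not mock.elements.table.equals(depleted.elements.table):
        raise ValueError("element sets differ between conditions")
    klass = mock.elements.table["klass"].to_numpy()
    rows = []
    for c in pd.unique(klass):
        sel = klass == c
        d = depleted.values[sel] - mock.values[sel]
        d = d[np.isfinite(d)]
        median = float(np.median(d)) if len(d) else np.nan
        dz = d[d != 0.0]
        if len(dz) < 2:
            p = np.nan
        else:
            method = "exact" if len(dz) <= 25 else "approx"
            p = float(
                stats.wilcoxon(
                    dz, zero_method="wilcox", alternative="two-sided",
                    correction=True, method=method,
                ).pvalue
            )
        rows.append((c, int(len(dz)), median, int(np.sign(median)) if np.isfinite(median) else 0, p))
    return pd.DataFrame(rows, columns=["klass", "n", "median_shift", "direction", "p"])
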