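"""Dual-label DNA fiber tract statistics.

A fiber table holds per-fiber tract lengths (microns) for a first label
(IdU) and a second, connected label (CldU), a group label, and a treatment
flag (e.g. hydroxyurea after the second label).  Statistics: per-fiber
second/first ratios with group medians, and unpaired two-sided
Mann-Whitney/Wilcoxon rank-sum comparisons of tract lengths or ratios
between groups.  Only connected tract pairs should be present; rows with a
non-positive length are rejected and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FiberTable", "tract_ratios", "compare_groups"]

COLUMNS = ["fiber_id", "idu_length_um", "cldu_length_um", "group", "hu_treated"]


@dataclass
class FiberTable:
    """Rows of (first-label length, second-label length, group, treatment)."""

    table: pd.DataFrame
    n_rejected: int = 0

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FiberTable":
        """Build from a raw frame, dropping rows with non-positive lengths."""
        df = df.copy()
        ok = (df["idu_length_um"] > 0) & (df["cldu_length_um"] > 0)
        n_bad = int((~ok).sum())
        if n_bad:
            warnings.warn(f"rejected {n_bad} fiber rows with non-positive tract length")
        return cls(table=df[ok].reset_index(drop=True), n_rejected=n_bad)

    @classmethod
    def from_csv(cls, path) -> "FiberTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    def __len__(self) -> int:
        return len(self.table)


def tract_ratios(t: FiberTable) -> tuple[pd.Series, pd.Series]:
    """Per-fiber second/first (CldU/IdU) ratios and per-group medians."""
    if len(t) == 0:
        raise ValueError("fiber table is empty")
    ratios = t.table["cldu_length_um"] / t.table["idu_length_um"]
    ratios.name = "cldu_idu_ratio"
    medians = ratios.groupby(t.table["group"]).median()
    return ratios, medians


def compare_groups(
    t: FiberTable,
    group_a: str,
    group_b: str,
    quantity: str = "idu_length_um",
    pool_treatment: bool = True,
) -> dict:
    """Two-sided rank-sum comparison of a quantity between two groups.

    ``quantity`` is ``"idu_length_um"``, ``"cldu_length_um"`` or ``"ratio"``
    (second/first).  ``pool_treatment`` pools treated and untreated fibers
    within each group (as done when first-label tracts are combined across
    treatment); set it False to restrict to untreated fibers.  Uses the
    normal approximation with tie correction for n > 20 per group and the
    exact distribution otherwise.
    """
    sub = t.table if pool_treatment else t.table[~t.table["hu_treated"].astype(bool)]
    if quantity == "ratio":
        vals = sub["cldu_length_um"] / sub["idu_length_um"]
    elif quantity in ("idu_length_um", "cldu_length_um"):
        vals = sub[quantity]
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    x = vals[sub["group"] == group_a].to_numpy(dtype=float)
    y = vals[sub["group"] == group_b].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two fibers per group")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        warnings.warn("all values tied between groups; p reported as 1")
        p = 1.0
    else:
        method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
        try:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        except ValueError:  # ties make the exact method unavailable
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "quantity": quantity,
        "n_a": len(x),
        "n_b": len(y),
        "median_a": float(np.median(x)),
        "median_b": float(np.median(y)),
        "p": p,
    }
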