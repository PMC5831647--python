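"""Depletion-vs-mock expression contrasts and gene-set overlap statistics.

Expression values are mean normalized nucleotide coverage per gene (gene x
sample table with a condition label per sample).  A contrast computes the
per-gene log2 fold-change of depleted over mock means (with a pseudocount), a
Welch t-test on log2-transformed values, and Benjamini-Hochberg q values.
Contrasts are compared by genome-wide Pearson correlation of log2
fold-changes and by thresholded gene-set overlap (genes increasing or
decreasing at p <= 0.05 in both contrasts) tested with Fisher's exact test.
The wing-disc active-gene rule defines active genes as the union of genes at
or above the control median in control samples and genes at or above the
control median in mutant samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DepletionContrast",
    "OverlapTable",
    "contrast",
    "correlate_contrasts",
    "overlap_analysis",
    "active_genes",
]

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with per-sample condition labels."""

    values: pd.DataFrame  # index: gene, columns: sample IDs
    conditions: pd.Series  # index: sample IDs, value: condition label

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    @classmethod
    def from_tsv(cls, path, conditions: dict[str, str]) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, conditions=pd.Series(conditions))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class DepletionContrast:
    """Per-gene log2 fold-change with p and BH q for one depletion vs mock."""

    table: pd.DataFrame  # index gene; columns log2fc, p, q
    label: str = ""

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant(self, alpha: float = 0.05, use: str = "p") -> pd.DataFrame:
        if use not in ("p", "q"):
            raise ValueError("use must be 'p' or 'q'")
        return self.table[self.table[use] <= alpha]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


@dataclass
class OverlapTable:
    """Directional overlap of two contrasts' significant gene sets.

    Counts mirror the increase/decrease overlap boxes of a depletion
    comparison: marginal significant-increase and -decrease counts for both
    contrasts, concordant overlaps, discordant overlaps, and Fisher's exact
    p values (one-sided enrichment and two-sided) against the shared gene
    universe.
    """

    n_universe: int
    a_up: int
    a_down: int
    b_up: int
    b_down: int
    up_up: int
    down_down: int
    up_down: int
    down_up: int
    fisher_up_one_sided: float
    fisher_up_two_sided: float
    fisher_down_one_sided: float
    fisher_down_two_sided: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def contrast(
    expr: ExpressionMatrix,
    depleted: str,
    mock: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    label: str | None = None,
) -> DepletionContrast:
    """Depletion-vs-mock contrast: log2 fold-change, Welch t p, BH q."""
    dep_samples = expr.samples_for(depleted)
    mock_samples = expr.samples_for(mock)
    if not dep_samples or not mock_samples:
        raise ValueError(f"missing condition label: {depleted!r} or {mock!r}")
    if len(dep_samples) < 2 or len(mock_samples) < 2:
        raise ValueError("need at least two replicates per condition")
    dep = expr.values[dep_samples].to_numpy(dtype=float)
    moc = expr.values[mock_samples].to_numpy(dtype=float)

    log2fc = np.log2((dep.mean(axis=1) + pseudocount) / (moc.mean(axis=1) + pseudocount))
    ldep = np.log2(dep + pseudocount)
    lmoc = np.log2(moc + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(ldep, lmoc, axis=1, equal_var=False)
    p = np.asarray(t.pvalue, dtype=float)
    # genes with zero variance in both groups and equal means are untestable;
    # they carry no evidence of change
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"log2fc": log2fc, "p": p, "q": q}, index=expr.values.index)
    return DepletionContrast(table=table, label=label or f"{depleted}_vs_{mock}")


def correlate_contrasts(a: DepletionContrast, b: DepletionContrast) -> float:
    """Pearson correlation of log2 fold-changes over the shared genes."""
    shared = a.genes.intersection(b.genes)
    if len(shared) < 2:
        raise ValueError("need at least two shared genes")
    x = a.table.loc[shared, "log2fc"].to_numpy()
    y = b.table.loc[shared, "log2fc"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in log2 fold-changes: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _fisher(k: int, n_a: int, n_b: int, n_u: int) -> tuple[float, float]:
    if n_a == 0 or n_b == 0:
        return 1.0, 1.0
    table = [[k, n_a - k], [n_b - k, n_u - n_a - n_b + k]]
    one = float(stats.fisher_exact(table, alternative="greater")[1])
    two = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return one, two


def overlap_analysis(
    a: DepletionContrast,
    b: DepletionContrast,
    alpha: float = 0.05,
    use: str = "p",
) -> OverlapTable:
    """Directional significant-gene overlap with Fisher's exact test.

    Genes are partitioned by significance (``p <= alpha`` by default; ``use``
    may be ``"q"``) and log2 fold-change sign in each contrast; the
    increase/increase and decrease/decrease overlaps are tested against the
    shared gene universe.
    """
    shared = a.genes.intersection(b.genes)
    ta = a.table.loc[shared]
    tb = b.table.loc[shared]
    a_up = (ta[use] <= alpha) & (ta["log2fc"] > 0)
    a_down = (ta[use] <= alpha) & (ta["log2fc"] < 0)
    b_up = (tb[use] <= alpha) & (tb["log2fc"] > 0)
    b_down = (tb[use] <= alpha) & (tb["log2fc"] < 0)

    n_u = len(shared)
    up_one, up_two = _fisher(int((a_up & b_up).sum()), int(a_up.sum()), int(b_up.sum()), n_u)
    dn_one, dn_two = _fisher(int((a_down & b_down).sum()), int(a_down.sum()), int(b_down.sum()), n_u)
    return OverlapTable(
        n_universe=n_u,
        a_up=int(a_up.sum()),
        a_down=int(a_down.sum()),
        b_up=int(b_up.sum()),
        b_down=int(b_down.sum()),
        up_up=int((a_up & b_up).sum()),
        down_down=int((a_down & b_down).sum()),
        up_down=int((a_up & b_down).sum()),
        down_up=int((a_down & b_up).sum()),
        fisher_up_one_sided=up_one,
        fisher_up_two_sided=up_two,
        fisher_down_one_sided=dn_one,
        fisher_down_two_sided=dn_two,
    )


def active_genes(control: ExpressionMatrix, mutant: ExpressionMatrix) -> pd.Index:
    """Wing-disc active-gene rule.

    Active genes are those expressed at or above the control median in
    control samples, plus those at or above the control median in mutant
    samples (union).  The median is the median over genes of the per-gene
    control mean.
    """
    if control.values.empty or mutant.values.empty:
        raise ValueError("empty expression matrix")
    shared = control.values.index.intersection(mutant.values.index)
    ctrl_mean = control.values.loc[shared].mean(axis=1)
    mut_mean = mutant.values.loc[shared].mean(axis=1)
    med = float(ctrl_mean.median())
    return shared[(ctrl_mean >= med) | (mut_mean >= med)]
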