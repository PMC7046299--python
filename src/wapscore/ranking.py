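"""Differential-expression gene rankings.

Genes are ordered from most (rank 1) to least differentially expressed.
The default statistic is the absolute two-sample t (Welch), optionally
combined with the absolute fold change by rank averaging.  Any callable
``ExpressionDataset -> GeneRanking`` can be plugged into the downstream
scoring modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CONTROL, DISEASE, ExpressionDataset

__all__ = [
    "GeneRanking",
    "rank_by_ttest",
    "rank_by_ttest_and_foldchange",
    "read_ranking",
]


@dataclass(frozen=True)
class GeneRanking:
    """A total order over a gene universe.

    ``genes[0]`` is the most differentially expressed gene (rank 1).
    ``statistic`` is the sort key, non-increasing along ranks; ties are
    broken by ascending gene identifier so rankings are reproducible.
    """

    genes: tuple[str, ...]
    statistic: np.ndarray
    fold_change: np.ndarray | None = None
    _rank_of: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranking contains duplicate genes")
        stat = np.asarray(self.statistic, dtype=float)
        if len(stat) != len(self.genes):
            raise ValueError("statistic length does not match gene count")
        if np.any(np.diff(stat) > 0):
            raise ValueError("statistic must be non-increasing along ranks")
        object.__setattr__(self, "statistic", stat)
        object.__setattr__(
            self, "_rank_of", {g: r for r, g in enumerate(self.genes, start=1)}
        )

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self, gene: str) -> int:
        """1-based rank of a gene (1 = most differentially expressed)."""
        return self._rank_of[gene]

    def top(self, i: int) -> tuple[str, ...]:
        """The top-``i`` gene set (as an ordered tuple)."""
        return self.genes[:i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": self.genes,
                "statistic": self.statistic,
                "rank": np.arange(1, len(self.genes) + 1),
            }
        )
        if self.fold_change is not None:
            df["fold_change"] = self.fold_change
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_ranking(path) -> GeneRanking:
    """Read a ranking TSV (columns gene, statistic, rank[, fold_change])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}).sort_values("rank")
    fc = df["fold_change"].to_numpy() if "fold_change" in df else None
    return GeneRanking(
        tuple(df["gene"]), df["statistic"].to_numpy(dtype=float), fold_change=fc
    )


def _group_arrays(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    if dataset.n_disease < 2 or dataset.n_control < 2:
        raise ValueError(
            f"each group needs >= 2 samples, got disease={dataset.n_disease}, "
            f"control={dataset.n_control}"
        )
    return dataset.group_values(DISEASE), dataset.group_values(CONTROL)


def _abs_tstat(d: np.ndarray, c: np.ndarray, equal_var: bool) -> np.ndarray:
    """|t| per gene; genes with zero variance in both groups get 0 (warned)."""
    degenerate = (np.var(d, axis=1, ddof=1) == 0) & (np.var(c, axis=1, ddof=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(d, c, axis=1, equal_var=equal_var).statistic
    abst = np.abs(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have zero variance in both groups; "
            "their t-statistic is set to 0 (ranked last)",
            stacklevel=3,
        )
        abst = np.where(degenerate, 0.0, abst)
    return abst


def _order(genes: np.ndarray, key: np.ndarray) -> np.ndarray:
    """Ascending-key order with deterministic tie-break by ascending gene id."""
    return np.lexsort((genes, key))


def rank_by_ttest(dataset: ExpressionDataset, equal_var: bool = False) -> GeneRanking:
    """Rank genes by decreasing absolute two-sample t-statistic.

    Welch's unequal-variance t is the default; pass ``equal_var=True`` for
    the pooled-variance Student t.  Ties (including all-zero statistics)
    break by ascending gene identifier.
    """
    d, c = _group_arrays(dataset)
    genes = np.array(dataset.genes)
    abst = _abs_tstat(d, c, equal_var)
    order = _order(genes, -abst)
    fc = d.mean(axis=1) - c.mean(axis=1)
    return GeneRanking(tuple(genes[order]), abst[order], fold_change=fc[order])


def rank_by_ttest_and_foldchange(
    dataset: ExpressionDataset, equal_var: bool = False
) -> GeneRanking:
    """Rank genes by the average of their |t| rank and |fold change| rank.

    Fold change is the difference of group means on the provided (assumed
    log) scale.  Component ranks use average ranks on ties; the final order
    is ascending average rank, ties broken by ascending gene identifier.
    The reported statistic is the negated average rank (so it is
    non-increasing along the final order).
    """
    d, c = _group_arrays(dataset)
    genes = np.array(dataset.genes)
    abst = _abs_tstat(d, c, equal_var)
    fc = d.mean(axis=1) - c.mean(axis=1)
    t_rank = stats.rankdata(-abst, method="average")
    fc_rank = stats.rankdata(-np.abs(fc), method="average")
    avg_rank = (t_rank + fc_rank) / 2.0
    order = _order(genes, avg_rank)
    return GeneRanking(tuple(genes[order]), -avg_rank[order], fold_change=fc[order])
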