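"""Multi-Variate T (MVT): whole-transcriptome separation of two groups.

Samples are compared by Pearson dissimilarity across all genes; the MVT
statistic is the ratio of the mean between-group dissimilarity to the sum
of the mean within-group dissimilarities,

    mvt = d(D, C) / (s(D) + s(C)) ,

analogous to a t-statistic (difference over spread).  Significance is
assessed by shuffling samples between groups: the pairwise dissimilarity
matrix does not depend on the labels, so it is computed once and reused
across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import DISEASE, ExpressionDataset

__all__ = [
    "MvtResult",
    "pearson_dissimilarity",
    "dissimilarity_matrix",
    "mvt_from_dissimilarity",
    "mvt_statistic",
    "mvt_pvalue",
]


@dataclass(frozen=True)
class MvtResult:
    """MVT statistic, its components, and (optionally) a permutation p-value."""

    mvt: float
    d_between: float
    s_disease: float
    s_control: float
    p_value: float | None = None
    n_permutations: int | None = None


def pearson_dissimilarity(x, y, convention: str = "half") -> float:
    """Pearson dissimilarity between two expression vectors.

    ``convention="half"`` (default) returns (1 - r) / 2, mapping the
    correlation range [-1, 1] onto [0, 1]; ``convention="one_minus"``
    returns 1 - r (range [0, 2]).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("expected two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector: Pearson dissimilarity undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return _from_r(r, convention)


def _from_r(r, convention: str):
    if convention == "half":
        return (1.0 - r) / 2.0
    if convention == "one_minus":
        return 1.0 - r
    raise ValueError(f"unknown convention {convention!r}")


def dissimilarity_matrix(
    dataset: ExpressionDataset, convention: str = "half"
) -> np.ndarray:
    """Symmetric samples x samples Pearson dissimilarity matrix, zero diagonal."""
    x = dataset.expression.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 genes to correlate samples")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [s for s, z in zip(dataset.samples, sd == 0) if z]
        raise ValueError(f"zero-variance sample(s): {bad[:5]}")
    r = np.corrcoef(x, rowvar=False)
    d = _from_r(r, convention)
    np.fill_diagonal(d, 0.0)
    return d


def mvt_from_dissimilarity(d: np.ndarray, is_disease: np.ndarray) -> MvtResult:
    """MVT from a precomputed dissimilarity matrix and a boolean group mask."""
    is_disease = np.asarray(is_disease, dtype=bool)
    n_d = int(is_disease.sum())
    n_c = int((~is_disease).sum())
    if n_d < 2 or n_c < 2:
        raise ValueError(f"each group needs >= 2 samples, got {n_d} and {n_c}")
    dd = d[np.ix_(is_disease, is_disease)]
    cc = d[np.ix_(~is_disease, ~is_disease)]
    dc = d[np.ix_(is_disease, ~is_disease)]
    d_between = float(dc.mean())
    s_d = float(dd.sum() / (n_d * (n_d - 1)))  # = 2 sum_{i<j} / (|D|(|D|-1))
    s_c = float(cc.sum() / (n_c * (n_c - 1)))
    spread = s_d + s_c
    if spread == 0:
        raise ValueError("all within-group pairs identical: MVT undefined")
    return MvtResult(d_between / spread, d_between, s_d, s_c)


def mvt_statistic(dataset: ExpressionDataset, convention: str = "half") -> MvtResult:
    """MVT statistic of the observed disease/control grouping (no p-value)."""
    d = dissimilarity_matrix(dataset, convention)
    is_disease = dataset.labels.to_numpy() == DISEASE
    return mvt_from_dissimilarity(d, is_disease)


def mvt_null_distribution(
    dataset: ExpressionDataset,
    n_permutations: int = 1000,
    seed: int = 0,
    convention: str = "half",
) -> np.ndarray:
    """Null MVT values under group-size-preserving label shuffles.

    Useful when many datasets with the same sample structure are scored
    against one shared control distribution (cached-null mode).
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    d = dissimilarity_matrix(dataset, convention)
    is_disease = dataset.labels.to_numpy() == DISEASE
    rng = np.random.default_rng(seed)
    return np.array(
        [
            mvt_from_dissimilarity(d, rng.permutation(is_disease)).mvt
            for _ in range(n_permutations)
        ]
    )


def mvt_pvalue(
    dataset: ExpressionDataset,
    n_permutations: int = 1000,
    seed: int = 0,
    convention: str = "half",
    null_distribution: np.ndarray | None = None,
) -> MvtResult:
    """MVT with a permutation p-value Pr(MVT >= mvt) under label shuffling.

    Group sizes are preserved by each shuffle; the pairwise dissimilarity
    matrix does not depend on the labels and is computed once.  The p-value
    uses the add-one convention (1 + #{null >= observed}) /
    (1 + n_permutations), so it is never exactly zero and remains a valid
    Monte-Carlo p-value.  A precomputed ``null_distribution`` (see
    :func:`mvt_null_distribution`) can be supplied to score many datasets
    against one cached control distribution; ``n_permutations`` and ``seed``
    are then ignored.
    """
    observed = mvt_statistic(dataset, convention)
    if null_distribution is None:
        null_distribution = mvt_null_distribution(
            dataset, n_permutations, seed, convention
        )
    else:
        null_distribution = np.asarray(null_distribution, dtype=float)
        if null_distribution.size < 1:
            raise ValueError("null_distribution must be non-empty")
    exceed = int((null_distribution >= observed.mvt).sum())
    p = (1 + exceed) / (1 + null_distribution.size)
    return MvtResult(
        observed.mvt,
        observed.d_between,
        observed.s_disease,
        observed.s_control,
        p_value=p,
        n_permutations=int(null_distribution.size),
    )
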