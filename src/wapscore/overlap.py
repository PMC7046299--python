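"""Reproducibility of gene rankings: Jaccard overlap profiles, maxR, AUC,
and the dataset partition/perturbation machinery used to sample ranking
pairs from a single study.

For two rankings of the same n genes, the overlap profile records, for
every top-set size i, the intersection I_i, union U_i and Jaccard index
R_i = I_i / U_i of the two top-i sets.  Two summaries condense a profile:

* ``maxR``: the peak R_i over the window a <= U_i <= b (defaults a = 50,
  b = 1000; the lower bound avoids large values due purely to the discrete
  nature of R at small i, the upper bound avoids the trivial rise to
  R_n = 1).
* ``AUC``: the area under R as a function of U between i = 1 and i = b,
  computed on tie-collapsed series (runs of equal U contribute their mean
  R at the run's smallest U) with the weighting
  AUC = w_1 R'_1 + w_b R'_b / 2 + sum_{i=2}^{b-1} w_i R'_i,
  w_i = U'_{i+1} - U'_i.  The asymmetric endpoint weights are reproduced
  as published rather than symmetrized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CONTROL, DISEASE, ExpressionDataset
from .ranking import GeneRanking

__all__ = [
    "OverlapProfile",
    "OverlapSummary",
    "TerminalWeightFallback",
    "overlap_profile",
    "max_r",
    "auc",
    "summarize_overlap",
    "split_dataset",
    "perturb_labels",
    "count_partitions_lower_bound",
]


@dataclass(frozen=True)
class OverlapProfile:
    """Per-top-size overlap of two rankings over a common gene universe."""

    i: np.ndarray
    intersection: np.ndarray
    union: np.ndarray
    jaccard: np.ndarray

    @property
    def n(self) -> int:
        return len(self.i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.i, "I": self.intersection, "U": self.union, "R": self.jaccard}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OverlapSummary:
    max_r: float
    auc: float
    a: int = 50
    b: int = 1000
    auc_terminal_fallback: bool = False


class TerminalWeightFallback(UserWarning):
    """The AUC terminal weight w_b was undefined and a fallback was used.

    This is routine whenever i = b falls inside a tie run of the union-size
    series (the published formula leaves that boundary undefined); the last
    positive increment before b is substituted.
    """


def overlap_profile(ranking_a: GeneRanking, ranking_b: GeneRanking) -> OverlapProfile:
    """Exact I_i, U_i, R_i for every top-set size i, in O(n).

    A gene enters the intersection once both its ranks are <= i, so
    I_i = #{g : max(rank_a(g), rank_b(g)) <= i} and U_i = 2i - I_i.
    """
    if set(ranking_a.genes) != set(ranking_b.genes):
        raise ValueError("rankings cover different gene universes")
    n = len(ranking_a)
    rank_b = {g: r for r, g in enumerate(ranking_b.genes, start=1)}
    max_rank = np.array(
        [max(ra, rank_b[g]) for ra, g in enumerate(ranking_a.genes, start=1)]
    )
    counts = np.bincount(max_rank, minlength=n + 1)
    intersection = np.cumsum(counts)[1:]
    i = np.arange(1, n + 1)
    union = 2 * i - intersection
    return OverlapProfile(i, intersection, union, intersection / union)


def max_r(profile: OverlapProfile, a: int = 50, b: int = 1000) -> float:
    """Peak Jaccard index over the union-size window a <= U_i <= b.

    Returns 0 with a warning when no U_i falls inside the window.
    """
    if a > b:
        raise ValueError(f"window bounds must satisfy a <= b, got a={a}, b={b}")
    mask = (profile.union >= a) & (profile.union <= b)
    if not mask.any():
        warnings.warn(
            f"no union size falls in [{a}, {b}]; maxR is 0 by convention",
            stacklevel=2,
        )
        return 0.0
    return float(profile.jaccard[mask].max())


def _tie_collapse(union: np.ndarray, jaccard: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-index tie-collapsed series U', R'.

    Within each run of equal U, R' is the run's mean R and U' the run's
    (common, smallest) U value; values are broadcast back to every index of
    the run so the published per-index weighting can be applied literally.
    """
    n = len(union)
    run_start = np.concatenate(([True], union[1:] != union[:-1]))
    run_id = np.cumsum(run_start) - 1
    sums = np.bincount(run_id, weights=jaccard)
    sizes = np.bincount(run_id)
    r_prime = (sums / sizes)[run_id]
    u_prime = union.astype(float)  # equal within runs already
    return u_prime, r_prime


def _auc_with_flag(profile: OverlapProfile, b: int) -> tuple[float, bool]:
    n = profile.n
    if b > n:
        warnings.warn(f"b={b} exceeds profile length {n}; clamping to {n}", stacklevel=3)
        b = n
    if b < 2:
        raise ValueError(f"AUC needs b >= 2, got {b}")
    u_prime, r_prime = _tie_collapse(profile.union, profile.jaccard)
    w = np.diff(u_prime)  # w[i-1] = U'_{i+1} - U'_i, defined for i = 1..n-1

    fallback = not (b <= n - 1 and w[b - 1] > 0)
    if fallback:
        positive = w[: b - 1][w[: b - 1] > 0]
        w_b = float(positive[-1]) if len(positive) else 0.0
    else:
        w_b = w[b - 1]
    total = w[0] * r_prime[0] + w_b * r_prime[b - 1] / 2.0
    total += float(np.dot(w[1 : b - 1], r_prime[1 : b - 1]))
    return float(total), fallback


def auc(profile: OverlapProfile, b: int = 1000) -> float:
    """Area under the tie-collapsed overlap profile between i = 1 and i = b.

    ``b`` larger than n is clamped with a warning.  The terminal weight
    w_b needs U'_{b+1}; when that is unavailable (b = n) or zero (i = b
    inside a tie run) the last positive increment before b is used instead
    and a :class:`TerminalWeightFallback` warning flags it.
    """
    value, fallback = _auc_with_flag(profile, b)
    if fallback:
        warnings.warn(
            "terminal AUC weight undefined at i = b; used the last available "
            "increment",
            TerminalWeightFallback,
            stacklevel=2,
        )
    return value


def summarize_overlap(
    profile: OverlapProfile, a: int = 50, b: int = 1000
) -> OverlapSummary:
    """maxR and AUC of a profile; flags any AUC terminal-weight fallback."""
    value, fallback = _auc_with_flag(profile, min(b, profile.n))
    return OverlapSummary(max_r(profile, a, b), value, a, b, fallback)


# ---------------------------------------------------------------------------
# dataset partitioning and label perturbation
# ---------------------------------------------------------------------------


def split_dataset(
    dataset: ExpressionDataset, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Randomly split a dataset into two halves, stratified by group.

    With n disease and m control samples, the halves have sizes
    floor(n/2) + floor(m/2) and ceil(n/2) + ceil(m/2).  The halves are
    disjoint and their union is the input; deterministic given the seed.
    """
    n, m = dataset.n_disease, dataset.n_control
    if n < 2 or m < 2:
        raise ValueError(
            f"both groups need >= 2 samples to split, got disease={n}, control={m}"
        )
    rng = np.random.default_rng(seed)
    disease = list(rng.permutation(np.array(dataset.disease_samples)))
    control = list(rng.permutation(np.array(dataset.control_samples)))
    first = disease[: n // 2] + control[: m // 2]
    second = disease[n // 2 :] + control[m // 2 :]
    return dataset.subset_samples(first), dataset.subset_samples(second)


def perturb_labels(
    dataset: ExpressionDataset, rho: float, seed: int = 0
) -> ExpressionDataset:
    """Randomly swap disease/control state between paired samples.

    Disease and control samples are paired one-to-one by a uniformly random
    matching (up to min(n, m) pairs); each pair swaps its labels
    independently with probability ``rho``.  Group sizes are preserved;
    ``rho = 0`` is the identity and ``rho = 1`` swaps every formed pair.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if dataset.n_disease == 0 or dataset.n_control == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    disease = rng.permutation(np.array(dataset.disease_samples))
    control = rng.permutation(np.array(dataset.control_samples))
    labels = dataset.labels.to_dict()
    for d, c in zip(disease, control):
        if rng.random() < rho:
            labels[d], labels[c] = CONTROL, DISEASE
    return dataset.with_labels(labels)


def count_partitions_lower_bound(n: int) -> int:
    """Lower bound on the number of balanced two-way partitions: n!^2/(n/2)!^4/2.

    Exact integer arithmetic; ``n`` is the (even) size of each group.
    Equivalently C(n, n/2)^2 / 2, the number of unordered pairs of balanced
    splits of n disease and n control samples.
    """
    if n < 2 or n % 2 != 0:
        raise ValueError(f"n must be an even integer >= 2, got {n}")
    numerator = math.factorial(n) ** 2
    denominator = math.factorial(n // 2) ** 4
    assert numerator % denominator == 0
    half = numerator // denominator
    assert half % 2 == 0  # central binomial coefficients are even for n >= 2
    return half // 2
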