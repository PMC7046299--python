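"""Jaccard overlap profiles, maxR/AUC summaries, dataset partitioning."""

import itertools
import numpy as np
import pytest

from wapscore import (
    GeneRanking,
    TerminalWeightFallback,
    auc,
    count_partitions_lower_bound,
    max_r,
    overlap_profile,
    perturb_labels,
    split_dataset,
    summarize_overlap,
)

from .conftest import make_dataset, make_random_ranking


def ranking_of(genes):
    return GeneRanking(tuple(genes), -np.arange(len(genes), dtype=float))


def bruteforce_profile(a, b):
    """Set-operation oracle for I_i, U_i, R_i."""
    out = []
    for i in range(1, len(a.genes) + 1):
        sa, sb = set(a.genes[:i]), set(b.genes[:i])
        inter, union = len(sa & sb), len(sa | sb)
        out.append((inter, union, inter / union))
    return out


class TestOverlapProfile:
    def test_identical_rankings_have_unit_jaccard(self):
        r = ranking_of("abcdefgh")
        profile = overlap_profile(r, r)
        assert np.all(profile.jaccard == 1.0)

    def test_small_example_arithmetic(self):
        a = ranking_of(["a", "b", "c", "d", "e"])
        b = ranking_of(["a", "b", "d", "c", "e"])
        profile = overlap_profile(a, b)
        assert profile.intersection[2] == 2  # top-3: {a,b,c} vs {a,b,d}
        assert profile.union[2] == 4
        assert profile.jaccard[2] == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_set_operation_oracle(self, seed):
        genes = [f"g{i}" for i in range(40)]
        a = make_random_ranking(genes, seed)
        b = make_random_ranking(genes, seed + 100)
        profile = overlap_profile(a, b)
        for i, (inter, union, jac) in enumerate(bruteforce_profile(a, b)):
            assert profile.intersection[i] == inter
            assert profile.union[i] == union
            assert profile.jaccard[i] == jac

    def test_reversed_rankings(self):
        genes = [f"g{i}" for i in range(10)]
        a = ranking_of(genes)
        b = ranking_of(genes[::-1])
        profile = overlap_profile(a, b)
        for i, (inter, union, jac) in enumerate(bruteforce_profile(a, b)):
            assert profile.jaccard[i] == jac

    def test_symmetry(self):
        genes = [f"g{i}" for i in range(25)]
        a, b = make_random_ranking(genes, 1), make_random_ranking(genes, 2)
        ab, ba = overlap_profile(a, b), overlap_profile(b, a)
        assert np.array_equal(ab.jaccard, ba.jaccard)

    def test_universe_mismatch_raises(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_profile(ranking_of("abc"), ranking_of("abd"))

    def test_final_jaccard_is_one_on_shared_universe(self):
        genes = [f"g{i}" for i in range(30)]
        profile = overlap_profile(make_random_ranking(genes, 3), make_random_ranking(genes, 4))
        assert profile.jaccard[-1] == 1.0


class TestMaxR:
    def test_identical_rankings_peak_at_one(self):
        r = ranking_of([f"g{i}" for i in range(120)])
        assert max_r(overlap_profile(r, r), a=50, b=100) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce_window_scan(self, seed):
        genes = [f"g{i}" for i in range(80)]
        profile = overlap_profile(
            make_random_ranking(genes, seed), make_random_ranking(genes, seed + 50)
        )
        a_bound, b_bound = 10, 60
        expected = max(
            r for u, r in zip(profile.union, profile.jaccard) if a_bound <= u <= b_bound
        )
        assert max_r(profile, a_bound, b_bound) == expected

    def test_empty_window_warns_and_returns_zero(self):
        r = ranking_of("abc")
        with pytest.warns(UserWarning, match="maxR is 0"):
            assert max_r(overlap_profile(r, r), a=50, b=1000) == 0.0

    def test_invalid_window(self):
        r = ranking_of("abcdef")
        with pytest.raises(ValueError, match="a <= b"):
            max_r(overlap_profile(r, r), a=10, b=5)


class TestAuc:
    def test_identical_rankings_closed_form(self):
        # all R' = 1 and U' = i, so AUC = 1 + 1/2 + (b - 2) = b - 1/2
        r = ranking_of([f"g{i}" for i in range(200)])
        profile = overlap_profile(r, r)
        for b in (50, 100, 150):
            assert auc(profile, b) == pytest.approx(b - 0.5)

    def test_linear_in_constant_jaccard(self):
        # disjoint-at-top constructed pair: same U series, R scaled
        genes = [f"g{i}" for i in range(60)]
        a = make_random_ranking(genes, 5)
        b = make_random_ranking(genes, 55)
        profile = overlap_profile(a, b)
        from wapscore.overlap import OverlapProfile

        doubled = OverlapProfile(
            profile.i, profile.intersection, profile.union, profile.jaccard * 0.5
        )
        assert auc(doubled, 40) == pytest.approx(0.5 * auc(profile, 40))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_literal_formula_oracle(self, seed):
        genes = [f"g{i}" for i in range(50)]
        profile = overlap_profile(
            make_random_ranking(genes, seed), make_random_ranking(genes, seed + 9)
        )
        b = 30
        u, r = profile.union, profile.jaccard
        # literal re-evaluation: tie-collapse then the published sum
        u_prime, r_prime = [], []
        idx = 0
        runs = []
        while idx < len(u):
            j = idx
            while j < len(u) and u[j] == u[idx]:
                j += 1
            runs.append((u[idx], np.mean(r[idx:j]), idx, j))
            idx = j
        up = np.empty(len(u))
        rp = np.empty(len(u))
        for uval, rmean, lo, hi in runs:
            up[lo:hi] = uval
            rp[lo:hi] = rmean
        w = np.diff(up)
        if b <= len(u) - 1 and w[b - 1] > 0:
            w_b = w[b - 1]
        else:
            pos = w[: b - 1][w[: b - 1] > 0]
            w_b = pos[-1] if len(pos) else 0.0
        expected = w[0] * rp[0] + w_b * rp[b - 1] / 2 + float(
            np.dot(w[1 : b - 1], rp[1 : b - 1])
        )
        assert auc(profile, b) == pytest.approx(expected, rel=1e-12)

    def test_b_beyond_n_clamps_with_warning(self):
        r = ranking_of([f"g{i}" for i in range(20)])
        profile = overlap_profile(r, r)
        with pytest.warns(UserWarning, match="clamp"):
            value = auc(profile, 500)
        # b clamps to n = 20; terminal fallback w_b = 1 recovers b - 1/2
        assert value == pytest.approx(20 - 0.5)

    def test_terminal_fallback_is_flagged(self):
        r = ranking_of([f"g{i}" for i in range(20)])
        profile = overlap_profile(r, r)
        with pytest.warns(TerminalWeightFallback):
            auc(profile, 20)
        summary = summarize_overlap(profile, a=5, b=20)
        assert summary.auc_terminal_fallback

    def test_invariant_to_gene_relabeling(self):
        genes = [f"g{i}" for i in range(60)]
        a, b = make_random_ranking(genes, 12), make_random_ranking(genes, 13)
        rename = {g: f"X{g}" for g in genes}
        a2 = GeneRanking(tuple(rename[g] for g in a.genes), a.statistic)
        b2 = GeneRanking(tuple(rename[g] for g in b.genes), b.statistic)
        assert auc(overlap_profile(a, b), 40) == auc(overlap_profile(a2, b2), 40)
        assert max_r(overlap_profile(a, b), 10, 50) == max_r(
            overlap_profile(a2, b2), 10, 50
        )


class TestSplitDataset:
    def test_floor_ceil_half_sizes(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.standard_normal((5, 9)), n_disease=5)
        half_a, half_b = split_dataset(ds, seed=1)
        assert (half_a.n_disease, half_a.n_control) == (2, 2)
        assert (half_b.n_disease, half_b.n_control) == (3, 2)

    def test_disjoint_union_covers_input(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.standard_normal((6, 14)), n_disease=8)
        half_a, half_b = split_dataset(ds, seed=5)
        sa, sb = set(half_a.samples), set(half_b.samples)
        assert sa.isdisjoint(sb)
        assert sa | sb == set(ds.samples)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.standard_normal((6, 12)))
        assert split_dataset(ds, 9)[0].samples == split_dataset(ds, 9)[0].samples

    def test_tiny_group_is_error(self):
        ds = make_dataset(np.random.default_rng(3).standard_normal((4, 5)), n_disease=1)
        with pytest.raises(ValueError, match=">= 2"):
            split_dataset(ds, 0)


class TestPerturbLabels:
    @pytest.fixture
    def dataset(self):
        return make_dataset(np.random.default_rng(4).standard_normal((5, 20)))

    def test_rho_zero_is_identity(self, dataset):
        out = perturb_labels(dataset, rho=0.0, seed=3)
        assert out.labels.equals(dataset.labels)

    def test_rho_one_swaps_every_pair(self, dataset):
        out = perturb_labels(dataset, rho=1.0, seed=3)
        # equal group sizes: every sample pairs, so every label flips
        assert all(out.labels[s] != dataset.labels[s] for s in dataset.samples)

    def test_group_sizes_preserved(self, dataset):
        out = perturb_labels(dataset, rho=0.6, seed=8)
        assert out.n_disease == dataset.n_disease
        assert out.n_control == dataset.n_control

    def test_swap_fraction_concentrates_at_rho(self, dataset):
        flips = []
        for seed in range(10_000):
            out = perturb_labels(dataset, rho=0.5, seed=seed)
            flips.append(
                sum(out.labels[s] != dataset.labels[s] for s in dataset.disease_samples)
                / dataset.n_disease
            )
        assert np.mean(flips) == pytest.approx(0.5, abs=0.02)

    def test_invalid_rho(self, dataset):
        with pytest.raises(ValueError, match="rho"):
            perturb_labels(dataset, rho=1.5, seed=0)


class TestPartitionCountLowerBound:
    def test_smallest_case(self):
        assert count_partitions_lower_bound(2) == 2

    def test_ten_exceeds_thirty_thousand(self):
        assert count_partitions_lower_bound(10) == 31752
        assert count_partitions_lower_bound(10) > 3 * 10**4

    def test_equals_exhaustive_enumeration_for_n_four(self):
        # unordered pairs of balanced splits of 4 disease + 4 control samples
        disease, control = list("wxyz"), list("WXYZ")
        seen = set()
        for d_half in itertools.combinations(disease, 2):
            for c_half in itertools.combinations(control, 2):
                first = frozenset(d_half) | frozenset(c_half)
                second = frozenset(set(disease) - set(d_half)) | frozenset(
                    set(control) - set(c_half)
                )
                seen.add(frozenset({first, second}))
        assert count_partitions_lower_bound(4) == len(seen)

    def test_odd_or_tiny_n_rejected(self):
        for bad in (1, 3, 0, -2):
            with pytest.raises(ValueError):
                count_partitions_lower_bound(bad)
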