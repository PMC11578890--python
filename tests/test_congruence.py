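"""Dg_M congruence index, constrained null model and process inference."""

import math

import numpy as np
import pytest

from assemblynet import (
    Partition,
    infer_process,
    module_diversity,
    null_distribution,
)
from oracle_utils import dgm_oracle


def parts(func_labels, cooc_labels):
    species = [f"s{i}" for i in range(len(func_labels))]
    func = Partition(dict(zip(species, func_labels)), "functional")
    cooc = Partition(dict(zip(species, cooc_labels)), "cooccurrence")
    return func, cooc


class TestModuleDiversity:
    def test_perfect_congruence_is_exactly_zero(self):
        # every functional group sits inside one co-occurrence module
        func, cooc = parts([0, 0, 0, 1, 1, 2, 2], [0, 0, 0, 1, 1, 0, 0])
        _, dgm = module_diversity(func, cooc)
        assert dgm == 0.0

    def test_perfect_dispersion_is_exactly_one(self):
        # every member of every functional group in a distinct module
        func, cooc = parts([0, 0, 0, 1, 1, 1], [0, 1, 2, 3, 4, 5])
        _, dgm = module_diversity(func, cooc)
        assert dgm == 1.0

    def test_even_two_way_split_gives_half(self):
        # one group of 4 split 2/2: H = ln 2, normalizer ln 4 -> 0.5
        func, cooc = parts([0, 0, 0, 0], [0, 0, 1, 1])
        per_group, dgm = module_diversity(func, cooc)
        assert dgm == pytest.approx(math.log(2) / math.log(4), abs=1e-12)
        assert per_group == {0: pytest.approx(0.5, abs=1e-12)}

    def test_matches_independent_oracle_on_random_labelings(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            f = rng.integers(0, 4, n)
            c = rng.integers(0, 5, n)
            _, f = np.unique(f, return_inverse=True)
            _, c = np.unique(c, return_inverse=True)
            func, cooc = parts(list(f), list(c))
            _, dgm = module_diversity(func, cooc)
            expected = dgm_oracle(list(f), list(c))
            if math.isnan(expected):
                assert math.isnan(dgm)
            else:
                assert dgm == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_module_relabeling_and_species_order(self):
        f = [0, 0, 1, 1, 2, 2, 2]
        c = [0, 1, 1, 1, 0, 2, 2]
        func, cooc = parts(f, c)
        _, base = module_diversity(func, cooc)
        # relabel modules (0<->2 in func, 0<->1 in cooc)
        func2, cooc2 = parts([2 - x for x in f], [{0: 1, 1: 0, 2: 2}[x] for x in c])
        _, relabeled = module_diversity(func2, cooc2)
        assert relabeled == pytest.approx(base, abs=1e-12)
        # permute species jointly
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(f))
        func3, cooc3 = parts([f[i] for i in perm], [c[i] for i in perm])
        _, permuted = module_diversity(func3, cooc3)
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_merging_cooccurrence_modules_never_increases_dg(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(6, 16))
            f = np.zeros(n, dtype=int)  # single functional group
            c = rng.integers(0, 4, n)
            _, c = np.unique(c, return_inverse=True)
            func, cooc = parts(list(f), list(c))
            per_before, _ = module_diversity(func, cooc)
            if c.max() == 0:
                continue
            merged = np.where(c == c.max(), 0, c)
            _, merged = np.unique(merged, return_inverse=True)
            func2, cooc2 = parts(list(f), list(merged))
            per_after, _ = module_diversity(func2, cooc2)
            assert per_after[0] <= per_before[0] + 1e-12

    def test_all_singleton_groups_flagged_undefined(self):
        func, cooc = parts([0, 1, 2], [0, 0, 1])
        per_group, dgm = module_diversity(func, cooc)
        assert math.isnan(dgm) and per_group == {}

    def test_singletons_excluded_from_average_by_default(self):
        # group 0 (pair, split) and group 1 (singleton)
        func, cooc = parts([0, 0, 1], [0, 1, 0])
        _, dgm = module_diversity(func, cooc)
        assert dgm == 1.0
        _, dgm_incl = module_diversity(func, cooc, include_singletons=True)
        assert dgm_incl == pytest.approx(0.5, abs=1e-12)

    def test_per_group_values_reproduce_dgm_when_reaveraged(self):
        rng = np.random.default_rng(3)
        f = rng.integers(0, 3, 15)
        c = rng.integers(0, 4, 15)
        _, f = np.unique(f, return_inverse=True)
        _, c = np.unique(c, return_inverse=True)
        func, cooc = parts(list(f), list(c))
        per_group, dgm = module_diversity(func, cooc)
        assert np.mean(list(per_group.values())) == pytest.approx(dgm, abs=1e-12)


class TestNullDistribution:
    def test_single_cooccurrence_module_forces_all_zero(self):
        func, cooc = parts([0, 0, 1, 1], [0, 0, 0, 0])
        nulls = null_distribution(func, cooc, n_null=50, seed=1)
        assert (nulls == 0.0).all()

    def test_reproducible_and_seed_sensitive(self):
        func, cooc = parts([0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2])
        a = null_distribution(func, cooc, n_null=99, seed=5)
        b = null_distribution(func, cooc, n_null=99, seed=5)
        c = null_distribution(func, cooc, n_null=99, seed=6)
        assert (a == b).all() and not (a == c).all()

    def test_mean_matches_brute_force_permutation_average(self):
        # 12 species, 3 equal co-occurrence modules, 3 equal functional groups
        f = [0] * 4 + [1] * 4 + [2] * 4
        c = [0, 1, 2] * 4
        func, cooc = parts(f, c)
        nulls = null_distribution(func, cooc, n_null=999, seed=7)
        rng = np.random.default_rng(1234)  # independent stream and code path
        ref = []
        for _ in range(2000):
            perm = rng.permutation(12)
            ref.append(dgm_oracle(f, [c[i] for i in perm]))
        se = np.std(ref) / math.sqrt(len(nulls))
        assert abs(nulls.mean() - np.mean(ref)) < 4 * se + np.std(ref) / math.sqrt(2000) * 4

    def test_invalid_replicate_count(self):
        func, cooc = parts([0, 0], [0, 1])
        with pytest.raises(ValueError, match="n_null"):
            null_distribution(func, cooc, n_null=0)


class TestInferProcess:
    def test_observed_below_all_nulls_is_filtering(self):
        p, process = infer_process(0.0, np.linspace(0.1, 0.9, 999))
        assert p == 0.0 and process == "filtering"

    def test_observed_above_all_nulls_is_limiting_similarity(self):
        p, process = infer_process(1.0, np.linspace(0.1, 0.9, 999))
        assert p == 1.0 and process == "limiting_similarity"

    def test_observed_at_null_median_is_stochastic(self):
        nulls = np.linspace(0.0, 1.0, 999)
        p, process = infer_process(0.5, nulls)
        assert 0.45 < p < 0.55 and process == "stochastic"

    def test_strictly_less_counting_on_ties(self):
        nulls = np.array([0.5] * 10)
        p, process = infer_process(0.5, nulls)
        assert p == 0.0 and process == "filtering"

    def test_undefined_observed_propagates(self):
        p, process = infer_process(float("nan"), np.array([0.1, 0.2]))
        assert math.isnan(p) and process == "undefined"

    def test_empty_null_sample_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            infer_process(0.5, np.array([]))
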