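"""Cell-population growth, sampled ancestry, infinite-sites SFS and its binning."""

import math

import numpy as np
import pytest

from bdtree import (
    SFS,
    CellSimConfig,
    TimedTree,
    drop_mutations,
    grow_population,
    sample_tree,
    simulate_dataset,
    summarize,
)


def make_config(**kw):
    base = dict(split_prob=0.7, mutation_rate=5.0, target_size=50, sample_size=10)
    base.update(kw)
    return CellSimConfig(**base)


def three_leaf_tree():
    """Fixed 3-leaf sampled tree: stem 0->1, first split at 1, second at 2, tips at 3."""
    tree = TimedTree(t=3.0, flavor="reconstructed")
    root = tree.add_node(-1, 0.0)
    tree.end_time[root] = 1.0
    tree.end_reason[root] = "split"
    inner = tree.add_node(root, 1.0)
    tree.end_time[inner] = 2.0
    tree.end_reason[inner] = "split"
    leaf_a = tree.add_node(root, 1.0, label=1)
    for v, b in [(tree.add_node(inner, 2.0, label=2), 2.0), (tree.add_node(inner, 2.0, label=3), 2.0)]:
        tree.end_time[v] = 3.0
        tree.end_reason[v] = "observed"
    tree.end_time[leaf_a] = 3.0
    tree.end_reason[leaf_a] = "observed"
    tree.divisions = [0, 1, 1, 1, 1]
    return tree


class TestGrowth:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            make_config(split_prob=1.0)
        with pytest.raises(ValueError):
            make_config(sample_size=60)
        with pytest.raises(ValueError):
            make_config(mutation_rate=-1.0)

    def test_reaches_target_exactly(self):
        tree = grow_population(make_config(), seed=41)
        assert tree.n_extant() == 50
        tree.validate()
        # frozen at the instant of the N-th cell: all leaves at the last split
        assert tree.t == max(t for t, r in zip(tree.end_time, tree.end_reason) if r == "split")

    def test_near_pure_birth_rarely_restarts(self):
        rng = np.random.default_rng(42)
        attempts = [
            grow_population(make_config(split_prob=0.99), rng=rng).metadata["attempts"]
            for _ in range(40)
        ]
        assert np.mean(attempts) < 1.2

    def test_mean_attempts_is_reciprocal_survival(self):
        # attempts ~ geometric with success prob (2p-1)/p
        p = 0.7
        rng = np.random.default_rng(43)
        attempts = np.array(
            [
                grow_population(make_config(split_prob=p, target_size=100), rng=rng).metadata[
                    "attempts"
                ]
                for _ in range(400)
            ]
        )
        q = (2 * p - 1) / p
        se = math.sqrt((1 - q) / q**2 / len(attempts))
        assert abs(attempts.mean() - p / (2 * p - 1)) < 3 * se + 0.05

    def test_pure_birth_growth_time_harmonic(self):
        # p ~ 1: time to N is a sum of Exp(k), mean = H_{N-1}
        rng = np.random.default_rng(44)
        n_target = 40
        times = [
            grow_population(
                make_config(split_prob=0.9999, target_size=n_target, sample_size=5), rng=rng
            ).t
            for _ in range(400)
        ]
        h = sum(1.0 / k for k in range(1, n_target))
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(np.mean(times) - h) < 3 * se + 0.01


class TestSampleTree:
    def test_full_sample_keeps_all_leaves(self):
        pop = grow_population(make_config(), seed=45)
        sub = sample_tree(pop, 50, seed=1)
        assert sub.n_extant() == 50

    def test_pair_sample_is_stem_plus_cherry(self):
        pop = grow_population(make_config(), seed=46)
        sub = sample_tree(pop, 2, seed=2)
        # stem/root ending at the pair MRCA plus two leaf branches
        assert len(sub) == 3
        assert sub.end_reason[0] == "split"
        assert sub.parent[0] == -1 and sub.birth_time[0] == 0.0

    def test_branch_count_and_leaf_identity(self):
        pop = grow_population(make_config(target_size=80, sample_size=15), seed=47)
        n = 15
        sub = sample_tree(pop, n, seed=3)
        assert len(sub) == 2 * n - 1  # branches counting the stem
        assert sub.total_branch_length() > 0
        pop_labels = {pop.label[v] for v in pop.leaves()}
        sub_labels = [sub.label[v] for v in sub.leaves()]
        assert len(set(sub_labels)) == n
        assert set(sub_labels) <= pop_labels

    def test_oversampling_rejected(self):
        pop = grow_population(make_config(), seed=48)
        with pytest.raises(ValueError):
            sample_tree(pop, 51, seed=0)


class TestMutations:
    def test_zero_rate(self):
        sfs = drop_mutations(three_leaf_tree(), 0.0, seed=1)
        assert sfs.total == 0 and np.all(sfs.f == 0)

    def test_total_mutations_mean_is_theta_times_length(self):
        tree = three_leaf_tree()
        theta = 4.0
        length = tree.total_branch_length()
        rng = np.random.default_rng(49)
        totals = np.array([drop_mutations(tree, theta, rng=rng).total for _ in range(1000)])
        mu = theta * length
        assert abs(totals.mean() - mu) < 3 * math.sqrt(mu / 1000)

    def test_singleton_mean_is_theta_times_pendant_length(self):
        tree = three_leaf_tree()
        theta = 4.0
        pendant = 2.0 + 1.0 + 1.0  # leaf branch durations
        rng = np.random.default_rng(50)
        f1 = np.array([drop_mutations(tree, theta, rng=rng).f[0] for _ in range(1000)])
        mu = theta * pendant
        assert abs(f1.mean() - mu) < 3 * math.sqrt(mu / 1000)

    def test_stem_mutations_are_truncal_and_excludable(self):
        tree = three_leaf_tree()
        rng = np.random.default_rng(51)
        with_stem = np.array(
            [drop_mutations(tree, 5.0, rng=rng).truncal for _ in range(500)]
        )
        without = np.array(
            [drop_mutations(tree, 5.0, rng=rng, include_stem=False).truncal for _ in range(500)]
        )
        assert with_stem.mean() > 0
        assert without.sum() == 0  # no non-stem branch subtends all 3 leaves here

    def test_per_division_clock_uses_division_counts(self):
        tree = three_leaf_tree()
        rng = np.random.default_rng(52)
        theta = 3.0
        totals = np.array(
            [drop_mutations(tree, theta, rng=rng, per_division=True).total for _ in range(1000)]
        )
        mu = theta * sum(tree.divisions)
        assert abs(totals.mean() - mu) < 3 * math.sqrt(mu / 1000)


class TestSummarize:
    def test_all_singletons(self):
        f = np.zeros(100, dtype=int)
        f[0] = 37
        s = summarize(SFS(f=f))
        assert s.S == 37 and s.b[0] == 1.0 and np.all(s.b[1:] == 0) and s.truncal == 0

    def test_hand_binned_example(self):
        # n=10: j=1 -> fraction 0.1 in (0, 0.1]; j=5 -> 0.5 in (0.4, 0.5]; j=10 truncal
        f = np.array([4, 0, 0, 0, 2, 0, 0, 0, 0, 4])
        s = summarize(SFS(f=f), n=10)
        assert s.S == 10
        assert s.b[0] == pytest.approx(0.4)
        assert s.b[4] == pytest.approx(0.2)
        assert s.truncal == 4
        # derived b10 = 1 - sum(b1..b9)
        assert 1.0 - s.b.sum() == pytest.approx(0.4)

    def test_empty_spectrum(self):
        s = summarize(SFS(f=np.zeros(10, dtype=int)))
        assert s.S == 0 and np.all(s.b == 0) and s.truncal == 0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            f = rng.poisson(2.0, size=25)
            if f.sum() == 0:
                continue
            s = summarize(SFS(f=f))
            b10 = 1.0 - s.b.sum()
            assert -1e-12 <= b10 <= 1.0 + 1e-12


class TestPipeline:
    def test_reproducible_given_seed(self):
        cfg = make_config()
        a = simulate_dataset(cfg, seed=54)
        b = simulate_dataset(cfg, seed=54)
        assert np.array_equal(a.vector(), b.vector())
        c = simulate_dataset(cfg, seed=55)
        assert not np.array_equal(a.vector(), c.vector())

    def test_total_mutations_scale_with_theta(self):
        # same growth/sampling stream, doubled mutation rate => ~doubled E S
        rng = np.random.default_rng(56)
        n_reps = 80
        s1 = np.empty(n_reps)
        s2 = np.empty(n_reps)
        for r in range(n_reps):
            pop = grow_population(make_config(), rng=rng)
            sub = sample_tree(pop, 10, rng=rng)
            s1[r] = drop_mutations(sub, 5.0, rng=rng).total
            s2[r] = drop_mutations(sub, 10.0, rng=rng).total
        ratio = s2.mean() / s1.mean()
        assert 1.8 < ratio < 2.2

    def test_b1_dominates_at_reference_parameters(self):
        # deep-branching growth makes most mutations near-private
        cfg = CellSimConfig(split_prob=0.722, mutation_rate=11.07, target_size=300, sample_size=50)
        rng = np.random.default_rng(57)
        b1s = [simulate_dataset(cfg, rng=rng).b[0] for _ in range(30)]
        assert np.median(b1s) > 0.5

    def test_conservation(self):
        s = simulate_dataset(make_config(), seed=58)
        assert s.truncal <= s.S
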