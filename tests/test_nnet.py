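"""NeighborNet: ordering, candidate arcs, NNLS weights, Splits-NEXUS IO."""

import itertools

import numpy as np
import pytest

from cognet.distance import DistanceMatrix
from cognet.inference import neighbor_joining
from cognet.nnet import (
    circular_candidate_splits,
    neighbor_net,
    nnet_ordering,
    nnls_split_weights,
)
from cognet.splits import (
    Split,
    SplitSystem,
    read_splits_nexus,
    write_splits_nexus,
)
from cognet.tree import tree_splits

from conftest import GROUP_FRENCH, GROUP_RUSSIAN, caterpillar, random_binary_tree


def adjacency_ok(ordering, *groups):
    """Each group occupies a contiguous arc of the circular ordering."""
    n = len(ordering)
    pos = {t: i for i, t in enumerate(ordering)}
    for g in groups:
        idx = sorted(pos[t] for t in g)
        k = len(idx)
        if not any(
            (idx[s:] + [i + n for i in idx[:s]])[-1]
            - (idx[s:] + [i + n for i in idx[:s]])[0]
            == k - 1
            for s in range(k)
        ):
            return False
    return True


def circular_decomposition_weights(dm, ordering):
    """Independent closed-form oracle for split weights of a circular
    metric: w(arc c_i..c_j) = (d(c_{i-1}, c_j) + d(c_i, c_{j+1})
    - d(c_{i-1}, c_{j+1}) - d(c_i, c_j)) / 2."""
    n = len(ordering)
    pos = {t: i for i, t in enumerate(ordering)}
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            d[a, b] = dm.get(ordering[a], ordering[b])
    weights = {}
    for i in range(1, n):
        for j in range(i, n):
            w = 0.5 * (
                d[i - 1, j] + d[i, (j + 1) % n] - d[i - 1, (j + 1) % n] - d[i, j]
            )
            weights[frozenset(ordering[i : j + 1])] = w
    return weights


class TestOrdering:
    def test_quartet_keeps_cherries_adjacent(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 0.3, 0.3, 0.5], [0.3, 0, 0.4, 0.6], [0.3, 0.4, 0, 0.4], [0.5, 0.6, 0.4, 0]]
        )
        ordering = nnet_ordering(DistanceMatrix(taxa, d))
        assert adjacency_ok(ordering, {"A", "B"}, {"C", "D"})

    def test_equidistant_ties_give_input_order(self):
        taxa = [f"x{i}" for i in range(6)]
        d = np.ones((6, 6)) - np.eye(6)
        assert nnet_ordering(DistanceMatrix(taxa, d)) == taxa

    def test_small_inputs_pass_through(self):
        d = np.array([[0, 1.0, 1], [1, 0, 1], [1, 1, 0.0]])
        assert nnet_ordering(DistanceMatrix(["a", "b", "c"], d)) == ["a", "b", "c"]

    def test_caterpillar_matches_leaf_order(self):
        """Brute-force oracle: of all 12 circular orderings of 5 taxa, only
        those compatible with every tree split are acceptable."""
        names = list("ABCDE")
        t = caterpillar(names)
        dm = t.distance_matrix().subset(names)
        ordering = nnet_ordering(dm)
        sides = [
            s.side_a if len(s.side_a) <= 2 else s.side_b for s in tree_splits(t)
        ]
        assert adjacency_ok(ordering, *sides)
        # oracle sanity: among all 12 distinct circular orderings, the
        # caterpillar leaf order is valid and fully scrambled ones are not
        valid = {
            perm
            for perm in itertools.permutations(names[1:])
            if adjacency_ok([names[0], *perm], *sides)
        }
        assert ("B", "C", "D", "E") in valid
        assert ("C", "E", "B", "D") not in valid

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_metric_orderings_are_split_compatible(self, seed):
        rng = np.random.default_rng(seed)
        t = random_binary_tree(int(rng.integers(5, 9)), rng)
        dm = t.distance_matrix()
        ordering = nnet_ordering(dm)
        sides = [s.side_a for s in tree_splits(t)]
        assert adjacency_ok(ordering, *sides)


class TestCandidateSplits:
    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 6), (5, 10), (7, 21)])
    def test_counts(self, n, expected):
        splits = circular_candidate_splits([f"t{i}" for i in range(n)])
        assert len(splits) == expected
        assert len({s.key() for s in splits}) == expected


class TestNNLSWeights:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.7, 0.8], [0.7, 0, 0.5], [0.8, 0.5, 0]])
        dm = DistanceMatrix(["a", "b", "c"], d)
        system = nnls_split_weights(dm, circular_candidate_splits(dm.taxa))
        assert system.find({"a"}).weight == pytest.approx((0.7 + 0.8 - 0.5) / 2)
        assert system.find({"b"}).weight == pytest.approx((0.7 + 0.5 - 0.8) / 2)
        assert system.find({"c"}).weight == pytest.approx((0.8 + 0.5 - 0.7) / 2)

    def test_quartet_tree_metric_weights(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 0.3, 0.3, 0.5], [0.3, 0, 0.4, 0.6], [0.3, 0.4, 0, 0.4], [0.5, 0.6, 0.4, 0]]
        )
        dm = DistanceMatrix(taxa, d)
        system = neighbor_net(dm)
        internal = system.find({"A", "B"}) or system.find({"C", "D"})
        assert internal is not None
        assert internal.weight == pytest.approx(0.1, abs=1e-8)
        assert system.find({"A"}).weight == pytest.approx(0.1, abs=1e-8)
        assert system.find({"D"}).weight == pytest.approx(0.3, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_metric_residual_vanishes(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_binary_tree(int(rng.integers(4, 9)), rng)
        dm = t.distance_matrix()
        system = neighbor_net(dm)
        resid = max(
            abs(system.fitted_distance(a, b) - dm.get(a, b))
            for a in dm.taxa
            for b in dm.taxa
            if a < b
        )
        assert resid < 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_closed_form_oracle_agrees_on_tree_metrics(self, seed):
        """Dual route: NNLS weights equal the circular-decomposition closed
        form computed directly from the distances."""
        rng = np.random.default_rng(200 + seed)
        t = random_binary_tree(int(rng.integers(4, 9)), rng)
        dm = t.distance_matrix()
        ordering = nnet_ordering(dm)
        system = nnls_split_weights(dm, circular_candidate_splits(ordering))
        oracle = circular_decomposition_weights(dm, ordering)
        for s in system.splits:
            side = s.side_a if s.side_a in oracle else s.side_b
            assert s.weight == pytest.approx(oracle[side], abs=1e-7)


class TestNeighborNet:
    @pytest.mark.parametrize("seed", range(10))
    def test_tree_limit_equals_nj(self, seed):
        """On additive input the retained non-trivial splits are exactly the
        NJ tree's, with matching weights."""
        rng = np.random.default_rng(300 + seed)
        t = random_binary_tree(int(rng.integers(4, 11)), rng)
        dm = t.distance_matrix()
        system = neighbor_net(dm)
        nj_splits = {s: s.weight for s in tree_splits(neighbor_joining(dm))}
        got = {s: s.weight for s in system.splits if not s.is_trivial}
        assert set(got) == set(nj_splits)
        for s, w in got.items():
            assert w == pytest.approx(nj_splits[s], abs=1e-6)

    def test_zero_matrix_has_no_splits(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        assert neighbor_net(dm).splits == []

    def test_worked_example_groups(self, example_distances):
        system = neighbor_net(example_distances)
        for side in (GROUP_RUSSIAN, GROUP_FRENCH, {"Afghan SL"}):
            s = system.find(side)
            assert s is not None and s.weight > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_output_is_circular(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.uniform(0.1, 1.0, (n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        system = neighbor_net(DistanceMatrix([f"t{i}" for i in range(n)], d))
        assert system.cycle is not None
        assert system.is_circular()

    @pytest.mark.parametrize("seed", range(6))
    def test_fits_no_worse_than_nj_tree(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(4, 9))
        x = rng.uniform(0.1, 1.0, (n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"t{i}" for i in range(n)], d)
        system = neighbor_net(dm)
        nj = neighbor_joining(dm)

        def sse(fit):
            return sum(
                (fit(a, b) - dm.get(a, b)) ** 2
                for a in dm.taxa for b in dm.taxa if a < b
            )

        nj_splits = nj.splits(include_trivial=True)
        nj_fit = lambda a, b: sum(s.weight for s in nj_splits if s.separates(a, b))
        assert sse(system.fitted_distance) <= sse(nj_fit) + 1e-9

    def test_taxon_relabelling_invariance(self):
        rng = np.random.default_rng(7)
        t = random_binary_tree(6, rng)
        dm = t.distance_matrix()
        system = neighbor_net(dm)
        perm = [3, 1, 5, 0, 2, 4]
        taxa2 = [dm.taxa[i] for i in perm]
        dm2 = dm.subset(taxa2)
        system2 = neighbor_net(dm2)
        w1 = {s.key(): s.weight for s in system.splits}
        w2 = {s.key(): s.weight for s in system2.splits}
        assert set(w1) == set(w2)
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-8)


class TestSplitsNexus:
    def make_system(self):
        taxa = ["A", "B", "C", "D"]
        universe = frozenset(taxa)
        splits = [
            Split(frozenset({t}), universe - {t}, weight=0.1 * (i + 1))
            for i, t in enumerate(taxa)
        ]
        splits.append(Split(frozenset("AB"), frozenset("CD"), weight=0.5))
        return SplitSystem(taxa=taxa, splits=splits, cycle=["A", "B", "C", "D"])

    def test_counts_with_trivial_splits(self):
        text = write_splits_nexus(self.make_system())
        assert "nsplits=5" in text and "ntax=4" in text

    def test_cycle_line_uses_one_based_indices(self):
        system = self.make_system()
        system.cycle = ["A", "C", "B", "D"]
        assert "CYCLE 1 3 2 4;" in write_splits_nexus(system)

    def test_write_read_write_idempotent(self):
        system = self.make_system()
        system.splits[0] = system.splits[0].replaced(support=0.9)
        text = write_splits_nexus(system)
        back = read_splits_nexus(text)
        assert write_splits_nexus(back) == text
        assert back.cycle == system.cycle
        assert {s.key() for s in back.splits} == {s.key() for s in system.splits}
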