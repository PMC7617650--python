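"""Folding constraints, Nussinov-style folding, decoy design, interchange."""

import itertools

import numpy as np
import pytest

import chimeramap as cm
from chimeramap.contacts import ContactMap
from chimeramap.io import ChimeraRecord
from chimeramap.structure import (
    FoldConstraint,
    dotbracket_from_pairs,
    pairs_from_dotbracket,
    read_ct,
    write_ct,
)

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def brute_force_max_pairs(seq, prohibited=frozenset(), min_loop=3):
    """Independent oracle: exhaustive recursion over all nested pairings."""

    def solve(i, j, memo={}):
        if j - i < min_loop + 1:
            return 0
        key = (seq, i, j)
        if key in memo:
            return memo[key]
        best = solve(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL and (i, k) not in prohibited:
                best = max(best, 1 + solve(i + 1, k - 1) + solve(k + 1, j))
        memo[key] = best
        return best

    return solve(0, len(seq) - 1)


def _sym(mat):
    m = np.triu(mat)
    return m + m.T - np.diag(np.diag(m))


class TestChimeraConstraints:
    def test_empty_map_no_constraints(self):
        m = ContactMap("tx", 10, np.zeros((20, 20)), 100, 200)
        assert cm.chimera_constraints(m) == []

    def test_selection_matches_sort_then_cut_oracle(self):
        rng = np.random.default_rng(3)
        mat = _sym(rng.poisson(2, (30, 30)).astype(float))
        m = ContactMap("tx", 10, mat, 100, 300)
        cons = cm.chimera_constraints(m, top_fraction=0.2)
        iu = np.triu_indices(30)
        cells = sorted(
            ((int(i), int(j), float(mat[i, j])) for i, j in zip(*iu) if mat[i, j] > 0),
            key=lambda c: (-c[2], c[0], c[1]),
        )
        n_take = int(np.ceil(0.2 * len(cells)))
        expected = [
            (i * 10 + 5, j * 10 + 5, w)
            for i, j, w in cells[:n_take]
            if (j * 10 + 5) - (i * 10 + 5) >= 4
        ]
        assert [(c.i, c.j, c.weight) for c in cons] == expected

    def test_near_diagonal_cells_respect_loop_gate(self):
        mat = np.zeros((10, 10))
        mat[2, 2] = 50.0  # same-bin cell: midpoints coincide, no pair
        m = ContactMap("tx", 10, _sym(mat), 100, 100)
        assert cm.chimera_constraints(m, top_fraction=1.0) == []


class TestShuffleConstraints:
    def _cons(self, n=20):
        return [FoldConstraint(i, i + 10, "forced", float(i + 1)) for i in range(n)]

    def test_default_is_1000_shuffles(self):
        import inspect

        sig = inspect.signature(cm.shuffle_constraints)
        assert sig.parameters["n_shuffles"].default == 1000

    def test_subset_sizes(self):
        subsets = cm.shuffle_constraints(self._cons(), n_shuffles=50, subset_fraction=0.5, seed=1)
        assert len(subsets) == 50
        assert all(len(s) == 10 for s in subsets)

    def test_seeded_determinism(self):
        a = cm.shuffle_constraints(self._cons(), n_shuffles=10, seed=3)
        b = cm.shuffle_constraints(self._cons(), n_shuffles=10, seed=3)
        assert a == b

    def test_weight_proportional_sampling(self):
        cons = [FoldConstraint(0, 10, "forced", 100.0)] + [
            FoldConstraint(i, i + 10, "forced", 1.0) for i in range(1, 20)
        ]
        subsets = cm.shuffle_constraints(cons, n_shuffles=200, subset_fraction=0.25, seed=5)
        heavy_rate = np.mean([cons[0] in s for s in subsets])
        assert heavy_rate > 0.9


class TestFoldConstrained:
    def test_canonical_hairpin(self):
        s = cm.fold_constrained("GGGAAACCC")
        assert s.dotbracket == "(((...)))"
        assert s.score == 3

    def test_matches_exhaustive_enumeration(self):
        """200 random sequences <= 12 nt: the DP score equals the
        brute-force maximum over all nested structures."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            s = cm.fold_constrained(seq)
            assert s.score == brute_force_max_pairs(seq), seq

    def test_all_pairs_prohibited_gives_dots(self):
        seq = "GGGAAACCC"
        prohibited = [
            FoldConstraint(i, j, "prohibited")
            for i, j in itertools.combinations(range(len(seq)), 2)
            if j - i >= 4
        ]
        s = cm.fold_constrained(seq, prohibited)
        assert s.dotbracket == "." * len(seq)
        assert s.score == 0

    def test_forced_pair_respected(self):
        # unconstrained optimum pairs the outer stem; forcing a specific
        # complementary pair keeps it in the output
        seq = "GGGAAAACCCAAAGGGAAACCC"
        forced = [FoldConstraint(0, 9, "forced")]
        s = cm.fold_constrained(seq, forced)
        assert (0, 9) in s.pairs

    def test_conflicting_forced_pairs_error(self):
        with pytest.raises(ValueError, match="conflict"):
            cm.fold_constrained("GGGGAAAACCCC", [
                FoldConstraint(0, 11, "forced"),
                FoldConstraint(0, 10, "forced"),
            ])

    def test_score_monotone_in_prohibitions(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGU"), size=40))
        pro = [FoldConstraint(5, 30, "prohibited"), FoldConstraint(2, 20, "prohibited")]
        s_all = cm.fold_constrained(seq, pro)
        s_some = cm.fold_constrained(seq, pro[:1])
        s_none = cm.fold_constrained(seq)
        assert s_all.score <= s_some.score <= s_none.score

    def test_length_cap(self):
        with pytest.raises(ValueError):
            cm.fold_constrained("A" * 3000)

    def test_output_pairs_canonical_and_nested(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=30))
            s = cm.fold_constrained(seq)
            for i, j in s.pairs:
                assert (seq[i], seq[j]) in CANONICAL
                assert j - i >= 4
            for (i1, j1), (i2, j2) in itertools.combinations(s.pairs, 2):
                # nested or disjoint, never crossing
                assert not (i1 < i2 < j1 < j2)


class TestFoldEnsemble:
    def test_consensus_frequencies_bounded(self):
        seq = "GGGAAACCCGGGAAACCC"
        cons = [FoldConstraint(0, 8, "forced"), FoldConstraint(9, 17, "forced")]
        freq = cm.fold_ensemble(seq, cons, n_shuffles=20, subset_fraction=0.5, seed=1)
        assert freq
        assert all(0 < f <= 1 for f in freq.values())


class TestBasepairSupport:
    def test_log2_cpm_values(self):
        s = cm.fold_constrained("GGGAAACCC")
        recs = [ChimeraRecord("r", ("tx", 0, 3), ("tx", 6, 9))]
        support = cm.basepair_support(s, recs, total_mapped=1_000_000)
        assert support[(0, 8)] == pytest.approx(0.0)  # log2(1 CPM)

    def test_count_8_gives_3(self):
        s = cm.fold_constrained("GGGAAACCC")
        recs = [ChimeraRecord(f"r{i}", ("tx", 0, 3), ("tx", 6, 9)) for i in range(8)]
        support = cm.basepair_support(s, recs, total_mapped=1_000_000)
        assert support[(0, 8)] == pytest.approx(3.0)

    def test_assignment_matches_containment_oracle(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGU"), size=60))
        s = cm.fold_constrained(seq)
        recs = []
        for i in range(100):
            s1 = int(rng.integers(0, 25))
            s2 = int(rng.integers(30, 50))
            recs.append(ChimeraRecord(f"r{i}", ("tx", s1, s1 + 8), ("tx", s2, s2 + 8)))
        support = cm.basepair_support(s, recs, total_mapped=1000)
        for i, j in s.pairs:
            n = sum(
                1 for r in recs
                if r.arm1[1] <= i < r.arm1[2] and r.arm2[1] <= j < r.arm2[2]
            )
            if n == 0:
                assert (i, j) not in support
            else:
                assert support[(i, j)] == pytest.approx(np.log2(n * 1e6 / 1000))


class TestDesignDecoy:
    def test_pre_sites_replaced_with_mre(self):
        """Replacing PRE-bearing sites with the let-7 response element
        leaves no PRE and >= 3 MRE copies."""
        unit = "GAAAAUUGUAUAUAAAUCAA"
        linker = "GGGCCC"
        seq = linker + unit + linker + unit + linker + unit + linker
        sites = []
        pos = len(linker)
        for _ in range(3):
            sites.append((pos, pos + len(unit)))
            pos += len(unit) + len(linker)
        out = cm.design_decoy(seq, sites, "CUACCUCA")
        assert cm.count_motif(out, "CUACCUCA") >= 3
        assert cm.count_motif(out, "UGUANAUA") == 0

    def test_zero_sites_unchanged(self):
        assert cm.design_decoy("ACGUACGU", [], "CUACCUCA") == "ACGUACGU"

    def test_output_length_arithmetic(self):
        seq = "A" * 100
        sites = [(10, 30), (50, 70)]
        out = cm.design_decoy(seq, sites, "CUACCUCA")
        assert len(out) == 100 - 40 + 2 * 8

    def test_overlapping_sites_error(self):
        with pytest.raises(ValueError):
            cm.design_decoy("A" * 50, [(10, 30), (20, 40)], "CUACCUCA")


class TestInterchange:
    def test_dotbracket_pairs_round_trip(self):
        db = "((..((...))..))"
        pairs = pairs_from_dotbracket(db)
        assert dotbracket_from_pairs(pairs, len(db)) == db

    def test_ct_round_trip(self, tmp_path):
        seq = "GGGAAACCC"
        s = cm.fold_constrained(seq)
        path = tmp_path / "x.ct"
        write_ct(seq, s.pairs, path)
        seq2, pairs2 = read_ct(path)
        assert seq2 == seq
        assert pairs2 == s.pairs

    def test_unbalanced_dotbracket_rejected(self):
        with pytest.raises(ValueError):
            pairs_from_dotbracket("((.)")
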