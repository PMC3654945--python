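"""Distances, guide trees, marginal reconstruction, ancestral boost."""

import numpy as np
import pytest

from tmsrep.ancestral import (
    MultipleAlignment,
    align_mafft,
    ancestral_repeat_compare,
    default_model,
    nj_tree,
    protein_distance,
    reconstruct_root,
)
from tmsrep.pairwise import AMINO_ACIDS
from tmsrep.synthetic import (
    SequenceRecord,
    diverge,
    make_family,
    sample_ancestor,
    scenario_for_preset,
    three_tms_blueprint,
)

AA = AMINO_ACIDS


class TestProteinDistance:
    def test_identical_rows_have_zero_distance(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEF" * 4, "ACDEF" * 4])
        assert protein_distance(msa)[0, 1] == 0.0

    def test_formula_at_p_ten_percent(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        msa = MultipleAlignment(["a", "b"], [row_a, row_b])
        expect = -np.log(1 - 0.1 - 0.2 * 0.01)
        assert protein_distance(msa)[0, 1] == pytest.approx(expect)

    def test_saturation_capped_with_warning(self):
        msa = MultipleAlignment(["a", "b"], ["A" * 30, "C" * 30])
        with pytest.warns(UserWarning, match="capped"):
            d = protein_distance(msa, max_distance=7.5)
        assert d[0, 1] == 7.5

    def test_gap_columns_excluded(self):
        msa = MultipleAlignment(["a", "b"], ["AAAA----", "AAAACCCC"])
        assert protein_distance(msa)[0, 1] == 0.0


class TestNJTree:
    def test_two_taxa_single_split_edge(self):
        tree = nj_tree(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"a": 0.5, "b": 0.5}

    def test_three_taxa_solves_three_point_equations(self):
        # closed form: branch to a = (d_ab + d_ac - d_bc) / 2, etc.
        d_ab, d_ac, d_bc = 0.6, 0.8, 0.4
        dist = np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, 0.4, 0]])
        dist[2, 1] = d_bc
        tree = nj_tree(dist, ["a", "b", "c"])
        # midpoint rooting preserves tip-to-tip path lengths
        tips = {t.name: t for t in tree.tips()}
        got_ab = tips["a"].distance(tips["b"])
        got_ac = tips["a"].distance(tips["c"])
        got_bc = tips["b"].distance(tips["c"])
        assert got_ab == pytest.approx(d_ab)
        assert got_ac == pytest.approx(d_ac)
        assert got_bc == pytest.approx(d_bc)

    def test_four_taxa_additive_matrix_recovers_topology(self):
        # tree: (a,b) vs (c,d) with internal branch 0.3
        # a-b: 0.2+0.25; a-c: 0.2+0.3+0.15 ...
        ba, bb, bc, bd, internal = 0.2, 0.25, 0.15, 0.35, 0.3
        names = ["a", "b", "c", "d"]
        dist = np.zeros((4, 4))
        def path(i, j):
            lens = {"a": ba, "b": bb, "c": bc, "d": bd}
            same = {("a", "b"), ("c", "d")}
            extra = 0 if (names[i], names[j]) in same or (names[j], names[i]) in same else internal
            return lens[names[i]] + lens[names[j]] + extra
        for i in range(4):
            for j in range(i + 1, 4):
                dist[i, j] = dist[j, i] = path(i, j)
        tree = nj_tree(dist, names)
        tips = {t.name: t for t in tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(ba + bb)
        assert tips["c"].distance(tips["d"]) == pytest.approx(bc + bd)
        assert tips["a"].distance(tips["c"]) == pytest.approx(ba + bc + internal)


class TestSubstitutionModel:
    def test_transition_rows_are_distributions(self):
        m = default_model()
        for t in (0.0, 0.1, 1.0, 10.0):
            P = m.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()

    def test_zero_time_is_identity(self):
        assert np.allclose(default_model().transition(0.0), np.eye(20), atol=1e-10)

    def test_long_time_reaches_equilibrium(self):
        m = default_model()
        P = m.transition(300.0)
        assert np.allclose(P, np.tile(m.pi, (20, 1)), atol=1e-8)

    def test_detailed_balance(self):
        m = default_model()
        P = m.transition(0.5)
        flux = m.pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-10)


class TestReconstructRoot:
    def test_identical_rows_recover_sequence(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        msa = MultipleAlignment(["a", "b", "c"], [seq] * 3)
        tree = nj_tree(np.zeros((3, 3)) + 0.01 - 0.01 * np.eye(3), ["a", "b", "c"])
        res = reconstruct_root(msa, tree)
        assert res.root_sequence == seq
        assert np.nanmin(res.posteriors.max(axis=1)) > 0.5

    def test_posteriors_normalized(self):
        msa = MultipleAlignment(["a", "b"], ["ACDF", "ACEF"])
        tree = nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        res = reconstruct_root(msa, tree)
        sums = res.posteriors[~res.gap_flag].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_column_likelihood_matches_bruteforce_enumeration(self):
        """Pruning == exhaustive sum over internal states on a 4-leaf tree."""
        from skbio import TreeNode

        model = default_model()
        newick = "((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.05):0;"
        tree = TreeNode.read([newick])
        cols = ["ACAC", "LLLV", "WYWF"]
        msa = MultipleAlignment(["a", "b", "c", "d"], ["".join(c) for c in zip(*cols)])
        res = reconstruct_root(msa, tree, model)
        idx = {a: i for i, a in enumerate(AA)}
        P = {}
        for t in (0.2, 0.3, 0.15, 0.25, 0.1, 0.05):
            P[t] = model.transition(t)
        for col, pattern in enumerate(cols):
            la, lb, lc, ld = (idx[c] for c in pattern)
            # brute force: sum over the two internal nodes u (joining a,b)
            # and v (joining c,d), root = r
            post = np.zeros(20)
            for r in range(20):
                total = 0.0
                for u in range(20):
                    for v in range(20):
                        total += (
                            P[0.15][r, u] * P[0.2][u, la] * P[0.3][u, lb]
                            * P[0.05][r, v] * P[0.25][v, lc] * P[0.1][v, ld]
                        )
                post[r] = model.pi[r] * total
            post /= post.sum()
            assert np.allclose(res.posteriors[col], post, atol=1e-10)

    def test_star_simulation_recovers_root(self):
        """30 leaves diverged d=0.3 from a known root: >= 95% recovery."""
        rec, truth = sample_ancestor(three_tms_blueprint(), 42)
        leaves = [
            diverge(SequenceRecord(f"L{i}", rec.seq), truth, 0.3, 0.0, rng_seed=500 + i)[0]
            for i in range(30)
        ]
        msa = MultipleAlignment([l.id for l in leaves], [l.seq for l in leaves])
        tree = nj_tree(protein_distance(msa), msa.ids)
        res = reconstruct_root(msa, tree)
        frac = np.mean([a == b for a, b in zip(res.root_sequence, rec.seq)])
        assert frac >= 0.95

    def test_leaf_mismatch_raises(self):
        msa = MultipleAlignment(["a", "b"], ["ACDF", "ACEF"])
        tree = nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "x"])
        with pytest.raises(ValueError):
            reconstruct_root(msa, tree)

    def test_majority_gap_columns_excluded(self):
        msa = MultipleAlignment(["a", "b", "c"], ["A-CD", "A-CD", "AWCD"])
        tree = nj_tree(np.full((3, 3), 0.1) - 0.1 * np.eye(3), ["a", "b", "c"])
        res = reconstruct_root(msa, tree)
        assert res.gap_flag[1]
        assert res.root_sequence == "ACD"


class TestAncestralBoost:
    def test_gappy_row_dropping(self):
        rows = ["AAAAAAAA", "AAAA----", "AAAAAAA-", "AAAAAA--"]
        msa = MultipleAlignment(list("abcd"), rows)
        kept = msa.drop_gappy_rows(factor=1.5)
        assert "b" not in kept.ids and "a" in kept.ids

    def test_two_member_family_warns(self, annotations_3p3, family_3p3):
        records, _, _ = family_3p3
        with pytest.warns(UserWarning, match="consensus"):
            ancestral_repeat_compare(
                records[:2], annotations_3p3, 3, n_shuffles=40, n_extant_pairs=2, seed=0
            )

    def test_deep_divergence_ancestral_boost(self):
        """Root-vs-root beats the median extant cross-half comparison."""
        sc = scenario_for_preset("3+3", n=25, d=1.2, seed=77)
        records, truths, _ = make_family(sc)
        anns = {t.id: t.tms_intervals for t in truths}
        out = ancestral_repeat_compare(records, anns, 3, n_shuffles=80,
                                       n_extant_pairs=6, seed=1)
        extant_median = np.median([s.z for s in out["extant"]])
        assert out["ancestral"].z > extant_median

    def test_undiverged_family_both_huge(self):
        sc = scenario_for_preset("3+3", n=6, d=0.0, seed=5)
        sc.indel_rate = 0.0
        records, truths, _ = make_family(sc)
        anns = {t.id: t.tms_intervals for t in truths}
        out = ancestral_repeat_compare(records, anns, 3, n_shuffles=40,
                                       n_extant_pairs=3, seed=2)
        assert out["ancestral"].z > 10
        assert min(s.z for s in out["extant"]) > 10


class TestMafft:
    def test_alignment_contains_all_inputs_ungapped(self, family_3p3):
        records, _, _ = family_3p3
        msa = align_mafft(records[:8])
        assert sorted(msa.ids) == sorted(r.id for r in records[:8])
        by_id = dict(zip(msa.ids, msa.rows))
        for rec in records[:8]:
            assert by_id[rec.id].replace("-", "") == rec.seq
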