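"""GRN edge inference, prior/top-k pruning, regulon scoring delegation,
dual-targeting scans and the Venn target partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tonsilflow.datatypes import RegulonSet
from tonsilflow.grn import (find_dual_targeting_tfs, infer_grn_edges,
                            partition_targets, prune_to_regulons,
                            score_regulons)

from conftest import make_count_matrix


def _linear_target_data(seed=91):
    """3 TF genes; target0 is a noiseless function of TF1 only."""
    rng = np.random.default_rng(seed)
    n = 400
    tf_expr = rng.poisson(5, (3, n))
    target = tf_expr[0] * 3  # deterministic in TF1
    noise = rng.poisson(2, (4, n))
    X = np.vstack([tf_expr, target[None, :], noise])
    genes = ["TF1", "TF2", "TF3", "target0"] + [f"n{i}" for i in range(4)]
    return make_count_matrix(X, gene_ids=genes)


class TestInferEdges:
    def test_noiseless_linear_target_attributes_to_driver(self):
        cm = _linear_target_data()
        edges = infer_grn_edges(cm, ["TF1", "TF2", "TF3"], seed=1)
        e = edges[edges["target"] == "target0"].set_index("tf")["weight"]
        assert e.get("TF1", 0.0) >= 0.9

    def test_independent_target_ranks_below_driven_target(self):
        cm = _linear_target_data()
        edges = infer_grn_edges(cm, ["TF1", "TF2", "TF3"], seed=2)
        driven = edges[edges["target"] == "target0"]["weight"].max()
        indep = edges[edges["target"].str.startswith("n")]["weight"]
        assert (indep < driven).all() if len(indep) else True

    def test_single_tf_is_only_parent(self):
        cm = _linear_target_data()
        edges = infer_grn_edges(cm, ["TF1"], seed=3)
        assert set(edges["tf"]) <= {"TF1"}

    def test_constant_target_emits_no_edges(self):
        # constant cell depth, so the target is constant after
        # log-normalization too
        tf = np.random.default_rng(0).poisson(5, 50) + 1
        balance = 100 - tf
        X = np.vstack([tf, np.full(50, 3), balance])
        cm = make_count_matrix(X, gene_ids=["TF1", "const", "fill"])
        edges = infer_grn_edges(cm, ["TF1"], seed=4)
        assert "const" not in set(edges["target"])

    def test_deterministic_under_seed(self):
        cm = _linear_target_data()
        a = infer_grn_edges(cm, ["TF1", "TF2", "TF3"], seed=5)
        b = infer_grn_edges(cm, ["TF1", "TF2", "TF3"], seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPrune:
    @staticmethod
    def _edges():
        return pd.DataFrame({"tf": ["A", "A", "B"],
                             "target": ["x", "y", "x"],
                             "weight": [0.5, 0.3, 0.9]})

    def test_prior_equal_to_edges_is_identity(self):
        e = self._edges()
        prior = e[["tf", "target"]]
        regs = prune_to_regulons(e, prior=prior)
        assert regs.target_sets() == {"A": {"x", "y"}, "B": {"x"}}

    def test_empty_prior_gives_empty_set_with_warning(self):
        with pytest.warns(UserWarning):
            regs = prune_to_regulons(self._edges(),
                                     prior=pd.DataFrame(columns=["tf", "target"]))
        assert len(regs) == 0

    def test_top_k_fallback(self):
        regs = prune_to_regulons(self._edges(), prior=None, top_k=1)
        assert regs.target_sets() == {"A": {"x"}, "B": {"x"}}

    def test_prior_targets_outside_universe_ignored(self):
        prior = pd.DataFrame({"tf": ["A", "A"], "target": ["x", "zzz"]})
        with pytest.warns(UserWarning, match="outside universe"):
            regs = prune_to_regulons(self._edges(), prior=prior,
                                     universe=["x", "y"])
        assert regs.target_sets() == {"A": {"x"}}


class TestScoreRegulons:
    def test_delegation_matches_gene_set_scoring_bitwise(self):
        from tonsilflow.aucell import score_gene_sets_aucell

        rng = np.random.default_rng(92)
        cm = make_count_matrix(rng.poisson(2, (50, 20)))
        regs = RegulonSet({"T": {g: 1.0 for g in cm.gene_ids[5:12]}})
        a = score_regulons(cm, regs)
        b = score_gene_sets_aucell(cm, {"T": list(cm.gene_ids[5:12])})
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())

    def test_planted_regulon_most_active_in_its_state(self, discrete_sim):
        cfg, cm, truth = discrete_sim
        act = score_regulons(cm, truth.regulons_true)
        labels = truth.cells["state"]
        for tf, st_name in truth.tf_active_state.items():
            if st_name is None:
                continue
            means = act.scores.loc[tf].groupby(labels.values).mean()
            assert means.idxmax() == st_name


class TestDualTargeting:
    def test_enumeration_example(self):
        regs = RegulonSet({"A": {"CCL4": 1.0}, "B": {"CCL3": 1.0},
                           "C": {"CCL4": 1.0, "CCL3": 1.0}})
        any_hit, both = find_dual_targeting_tfs(regs)
        assert any_hit == ["A", "B", "C"] and both == ["C"]

    def test_no_hits_gives_empty_lists(self):
        regs = RegulonSet({"A": {"x": 1.0}})
        assert find_dual_targeting_tfs(regs) == ([], [])

    def test_empty_query_raises(self):
        with pytest.raises(ValueError):
            find_dual_targeting_tfs(RegulonSet({}), query_genes=())


class TestPartitionTargets:
    def test_manual_enumeration(self):
        regs = RegulonSet({"A": {g: 1.0 for g in "123"},
                           "B": {g: 1.0 for g in "234"},
                           "C": {g: 1.0 for g in "35"}})
        p = partition_targets(regs, ("A", "B", "C"))
        assert p == {"A-only": {"1"}, "B-only": {"4"}, "C-only": {"5"},
                     "AB": {"2"}, "AC": set(), "BC": set(), "ABC": {"3"}}

    def test_identical_triple_all_in_abc(self):
        regs = RegulonSet({t: {g: 1.0 for g in "abc"} for t in "XYZ"})
        p = partition_targets(regs, ("X", "Y", "Z"))
        assert p["ABC"] == set("abc")
        assert all(not v for k, v in p.items() if k != "ABC")

    def test_disjoint_triple_only_singletons(self):
        regs = RegulonSet({"X": {"a": 1.0}, "Y": {"b": 1.0}, "Z": {"c": 1.0}})
        p = partition_targets(regs, ("X", "Y", "Z"))
        assert p["A-only"] == {"a"} and p["B-only"] == {"b"} and p["C-only"] == {"c"}
        assert not (p["AB"] | p["AC"] | p["BC"] | p["ABC"])

    def test_missing_tf_raises(self):
        with pytest.raises(ValueError, match="missing"):
            partition_targets(RegulonSet({"X": {"a": 1.0}}), ("X", "Y", "Z"))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_disjointness_and_coverage_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(30)]
        regs = RegulonSet({t: {g: 1.0 for g in
                               rng.choice(pool, rng.integers(1, 15), replace=False)}
                           for t in ("A", "B", "C")})
        p = partition_targets(regs, ("A", "B", "C"))
        parts = list(p.values())
        union = set().union(*parts)
        sets = regs.target_sets()
        assert union == sets["A"] | sets["B"] | sets["C"]
        for i in range(7):
            for j in range(i + 1, 7):
                assert not (parts[i] & parts[j])
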