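from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from oracles import bh_step_up, hypergeom_tail_enumeration
from phosmod.enrichment import (
    EnrichmentParams,
    SharedInteractor,
    bh_adjust,
    directionality_filter,
    enrich_annotation,
    find_shared_interactors,
    hypergeom_pvalue,
)
from phosmod.io import AnnotationSets, InteractionNetwork
from phosmod.motifs import Module, Motif


def make_module(module_id, proteins, class_label="A_inc"):
    return Module(
        module_id=module_id,
        class_label=class_label,
        motif=Motif(central="S", fixed=frozenset({(-3, "R")})),
        peptide_ids=frozenset(f"{p}_1" for p in proteins),
        protein_ids=frozenset(proteins),
    )


class TestHypergeomPvalue:
    def test_enumeration_example(self):
        assert hypergeom_pvalue(9, 4, 3, 2) == pytest.approx(34 / 84, abs=1e-15)

    def test_observed_zero(self):
        assert hypergeom_pvalue(10, 4, 3, 0) == 1.0

    def test_all_draws_are_successes(self):
        assert hypergeom_pvalue(5, 5, 2, 2) == 1.0

    def test_matches_scipy_upper_tail(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            population = int(rng.integers(2, 200))
            successes = int(rng.integers(0, population + 1))
            draws = int(rng.integers(0, population + 1))
            observed = int(rng.integers(0, min(successes, draws) + 1))
            ours = hypergeom_pvalue(population, successes, draws, observed)
            ref = stats.hypergeom.sf(observed - 1, population, successes, draws)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "args", [(5, 6, 2, 1), (5, 2, 6, 1), (5, 2, 2, 3), (5, 2, 2, -1)]
    )
    def test_bound_violations(self, args):
        with pytest.raises(ValueError):
            hypergeom_pvalue(*args)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_hand_step_up_rule(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), bh_step_up(ps), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_q_at_least_p_and_monotone(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q = bh_adjust(ps)
        q_perm = bh_adjust([ps[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], atol=1e-12)


class TestFindSharedInteractors:
    def _ten_node_network(self):
        # K1 interacts with P1, P2, P3; filler edges keep all 10 nodes present
        edges = [
            ("K1", "P1", False, "ppi"),
            ("K1", "P2", False, "ppi"),
            ("K1", "P3", False, "ppi"),
        ]
        return InteractionNetwork.build(
            edges, extra_nodes=[f"P{i}" for i in range(1, 9)] + ["K1", "X1"]
        )

    def test_worked_hypergeometric_case(self):
        net = self._ten_node_network()
        module = make_module("m1", {"P1", "P2", "P4"})
        params = EnrichmentParams(fdr_threshold=0.9999, min_overlap=2)
        results = find_shared_interactors(net, [module], params, significant_only=False)
        k1 = [r for r in results if r.protein_id == "K1"]
        assert len(k1) == 1
        r = k1[0]
        assert (r.overlap, r.degree, r.module_size_in_network, r.population) == (2, 3, 3, 9)
        assert r.p_value == pytest.approx(19 / 84, abs=1e-12)

    def test_zero_overlap_candidates_not_tested(self):
        net = self._ten_node_network()
        module = make_module("m1", {"P7", "P8"})
        results = find_shared_interactors(
            net, [module], EnrichmentParams(fdr_threshold=0.9999), significant_only=False
        )
        assert results == []

    def test_planted_kinase_is_unique_significant_interactor(self, noise_free_scenario):
        """With no background edges, each planted kinase is the one
        significant shared interactor of its own substrate module."""
        from phosmod.simulate import SimParams, generate_scenario

        sc = generate_scenario(
            SimParams(
                n_kinases=2,
                substrates_per_kinase=12,
                n_decoy_peptides=30,
                n_network_nodes=100,
                background_edge_prob=0.0,
                seed=3,
            )
        )
        kinases = sorted(sc.kinase_library.entries)
        modules = []
        for k in kinases:
            prots = {p for p, owner in (
                (pid.rsplit("_", 1)[0], kin)
                for pid, kin in sc.truth.kinase_of_peptide.items()
            ) if owner == k}
            modules.append(make_module(f"m_{k}", prots))
        results = find_shared_interactors(sc.network, modules, EnrichmentParams())
        assert {(r.protein_id, r.module_id) for r in results} == {
            (k, f"m_{k}") for k in kinases
        }
        assert all(r.toward_fraction == 1.0 for r in results)

    def test_module_absent_from_network_skipped(self):
        net = self._ten_node_network()
        module = make_module("m1", {"Z1", "Z2"})
        assert find_shared_interactors(net, [module], EnrichmentParams()) == []


def make_si(protein_id="K1", toward=None, **kw):
    defaults = dict(
        protein_id=protein_id,
        module_id="m1",
        class_label="A_inc",
        overlap=3,
        degree=5,
        module_size_in_network=10,
        population=99,
        p_value=1e-4,
        q_value=1e-3,
        toward_fraction=toward,
    )
    defaults.update(kw)
    return SharedInteractor(**defaults)


class TestDirectionalityFilter:
    def test_majority_toward_kept(self):
        kept = directionality_filter([make_si(toward=0.75)], {"K1"}, EnrichmentParams())
        assert len(kept) == 1

    def test_all_undirected_kept(self):
        kept = directionality_filter([make_si(toward=None)], {"K1"}, EnrichmentParams())
        assert len(kept) == 1

    def test_minority_toward_removed(self):
        kept = directionality_filter([make_si(toward=0.25)], {"K1"}, EnrichmentParams())
        assert kept == []

    def test_non_regulators_removed(self):
        kept = directionality_filter([make_si(toward=1.0)], {"K9"}, EnrichmentParams())
        assert kept == []


class TestEnrichAnnotation:
    def _annotations(self):
        background = frozenset(f"g{i}" for i in range(20))
        sets = {"GO:1": frozenset(f"g{i}" for i in range(5))}
        return AnnotationSets(sets, background)

    def test_worked_example(self):
        features = {"g0", "g1", "g2", "g10"}  # overlap 3 with the 5-member set
        table = enrich_annotation(features, self._annotations(), EnrichmentParams())
        assert table.loc[0, "overlap"] == 3
        assert table.loc[0, "p_value"] == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap(self):
        table = enrich_annotation(
            {"g10", "g11"}, self._annotations(), EnrichmentParams()
        )
        assert table.loc[0, "p_value"] == 1.0
        assert table.loc[0, "q_value"] <= 1.0

    def test_feature_set_equal_background(self):
        ann = self._annotations()
        table = enrich_annotation(set(ann.background), ann, EnrichmentParams())
        assert (table["p_value"] == 1.0).all()

    def test_stray_features_rejected(self):
        with pytest.raises(ValueError, match="g99"):
            enrich_annotation({"g99"}, self._annotations(), EnrichmentParams())
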