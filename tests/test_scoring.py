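"""IPX features, tier bonuses and the PPI conservation score."""

import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthowalk import (
    FeatureVector,
    FilterSpec,
    Network,
    ScoringContext,
    Tier,
    collapse_to_putative,
    compute_ipx,
    compute_pcs,
    feature_vector,
    generate_instance,
    joint_nnd,
    joint_opi,
    reference_subnetwork,
    run_walk,
    score_putative_set,
)
from orthowalk.cv import ScoreConfig, default_score_map
from orthowalk.model import CVScoreMap
from orthowalk.scoring import best_evidence_row, ipx_from_features, pair_nnd
from orthowalk.synthetic import SynthConfig

from conftest import gid, inter, ortho_pair

unit = st.floats(0.0, 1.0, allow_nan=False)


def make_context(**kw) -> ScoringContext:
    defaults = dict(cv_scores=default_score_map(), max_nnd=1.0)
    defaults.update(kw)
    return ScoringContext(**defaults)


class TestJointOpi:
    def test_perfect_identity(self):
        assert joint_opi(100.0, 100.0) == 1.0

    @pytest.mark.parametrize("x", [0.0, 12.5, 60.0, 99.0])
    def test_geometric_mean_of_equals(self, x):
        assert joint_opi(x, x) == pytest.approx(x / 100.0)

    def test_worked_value(self):
        # sqrt(80 * 45) = sqrt(3600) = 60 -> 0.6
        assert joint_opi(80.0, 45.0) == pytest.approx(0.6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            joint_opi(101.0, 50.0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_symmetric(self, a, b):
        assert joint_opi(a, b) == joint_opi(b, a)


class TestJointNnd:
    def test_zero_distance_is_maximal(self):
        assert joint_nnd(0.0, 0.0, make_context()) == 1.0

    def test_boundary_at_max(self):
        ctx = make_context(max_nnd=0.5)
        assert joint_nnd(0.5, 0.5, ctx) == 0.0

    def test_worked_value(self):
        # sqrt(0.2 * 0.8) = 0.4; 1 - 0.4/0.8 = 0.5
        ctx = make_context(max_nnd=0.8)
        assert joint_nnd(0.2, 0.8, ctx) == pytest.approx(0.5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            joint_nnd(-0.1, 0.5, make_context())

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0, 5), b=st.floats(0, 5))
    def test_symmetric_and_bounded(self, a, b):
        ctx = make_context(max_nnd=2.0)
        v = joint_nnd(a, b, ctx)
        assert v == joint_nnd(b, a, ctx)
        assert 0.0 <= v <= 1.0


@pytest.fixture
def walked_putative(onto):
    inst = generate_instance(SynthConfig(seed=17))
    result = run_walk(set(inst.genes_i), inst.orthology, inst.ppi_j,
                      FilterSpec(), onto)
    return collapse_to_putative(result.rows)


class TestFeatureVector:
    def test_degenerate_normalisation(self, onto):
        """When every pair has one method and one taxon, the dataset
        maxima equal the values and both multiplicity features are 1."""
        orthology = ortho_pair("g", "x") + ortho_pair("e", "y")
        rows = run_walk({gid("g")}, orthology, [inter("x", "y")],
                        FilterSpec(), onto).rows
        putative = collapse_to_putative(rows)
        ctx = ScoringContext.from_dataset(putative, onto=onto)
        f = feature_vector(putative[0], ctx)
        assert f.m_dm == 1.0 and f.m_taxa == 1.0

    def test_method_count_ratio(self, onto):
        orthology = ortho_pair("g", "x") + ortho_pair("e", "y") \
            + ortho_pair("h", "z")
        ppi = [inter("x", "y", method="MI:0018", ac="t:1"),
               inter("x", "y", method="MI:0004", ac="t:2"),
               inter("x", "y", method="MI:0114", ac="t:3"),
               inter("x", "z", method="MI:0018", ac="t:4")]
        putative = collapse_to_putative(
            run_walk({gid("g")}, orthology, ppi, FilterSpec(), onto).rows)
        ctx = ScoringContext.from_dataset(putative, onto=onto)
        assert ctx.max_n_methods == 3
        by_pair = {p.pair: feature_vector(p, ctx) for p in putative}
        assert by_pair[(gid("e"), gid("g"))].m_dm == 1.0
        assert by_pair[(gid("g"), gid("h"))].m_dm == pytest.approx(1 / 3)

    def test_features_match_brute_force_recomputation(self, walked_putative,
                                                      onto):
        """Every component of every feature vector equals a direct
        recomputation from the pair's evidence rows."""
        sm = default_score_map()
        ctx = ScoringContext.from_dataset(walked_putative, onto=onto)
        for p in walked_putative:
            f = feature_vector(p, ctx)
            i_exp = max(sm.type_score(r.ref_interaction.interaction_type, onto)
                        for r in p.evidence) / ctx.max_type_score
            d_exp = max(sm.method_score(r.ref_interaction.detection_method, onto)
                        for r in p.evidence) / ctx.max_method_score
            assert f.i == pytest.approx(min(i_exp, 1.0))
            assert f.d == pytest.approx(min(d_exp, 1.0))
            assert f.m_dm == pytest.approx(p.n_methods / ctx.max_n_methods)
            assert f.m_taxa == pytest.approx(p.n_taxa / ctx.max_n_taxa)
            best = best_evidence_row(p, sm, onto)
            opi_f = (best.fwd.opi_source + best.fwd.opi_target) / 2
            opi_b = (best.bwd.opi_source + best.bwd.opi_target) / 2
            assert f.j_opi == pytest.approx(math.sqrt(opi_f * opi_b) / 100)
            assert f.j_nnd == pytest.approx(
                1 - min(pair_nnd(best) / ctx.max_nnd, 1.0))

    def test_all_features_bounded(self, walked_putative, onto):
        ctx = ScoringContext.from_dataset(walked_putative, onto=onto)
        for p in walked_putative:
            for v in feature_vector(p, ctx).as_tuple():
                assert 0.0 <= v <= 1.0

    def test_feature_vector_has_six_components(self):
        f = FeatureVector(1, 1, 1, 1, 1, 1)
        assert len(f.as_tuple()) == 6

    def test_out_of_range_feature_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(1.5, 0, 0, 0, 0, 0)


class TestIpx:
    def test_maximum_is_twenty(self):
        ctx = make_context()
        res = ipx_from_features(FeatureVector(1, 1, 1, 1, 1, 1),
                                any_non_spoke=True, all_one_to_one=True,
                                ctx=ctx)
        assert res.ipx == pytest.approx(20.0)
        assert res.tier is Tier.HIGH

    def test_minimum_is_zero_low_tier(self):
        res = ipx_from_features(FeatureVector(0, 0, 0, 0, 0, 0),
                                any_non_spoke=False, all_one_to_one=False,
                                ctx=make_context())
        assert res.ipx == 0.0
        assert res.tier is Tier.LOW

    @pytest.mark.parametrize("non_spoke,one2one", [(True, False),
                                                   (False, True)])
    def test_single_bonus_is_mid_tier(self, non_spoke, one2one):
        res = ipx_from_features(FeatureVector(0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
                                any_non_spoke=non_spoke,
                                all_one_to_one=one2one, ctx=make_context())
        assert res.tier is Tier.MID
        assert res.sigma + res.theta == 7.0

    def test_spoke_only_evidence_zeroes_sigma(self, onto):
        orthology = ortho_pair("g", "x") + ortho_pair("e", "y")
        from orthowalk import Expansion
        ppi = [inter("x", "y", expansion=Expansion.SPOKE)]
        putative = collapse_to_putative(
            run_walk({gid("g")}, orthology, ppi, FilterSpec(), onto).rows)
        ctx = ScoringContext.from_dataset(putative, onto=onto)
        res = compute_ipx(putative[0], ctx)
        assert res.sigma == 0.0

    @settings(max_examples=200, deadline=None)
    @given(f=st.tuples(unit, unit, unit, unit, unit, unit))
    def test_tier_ranges_are_disjoint(self, f):
        """For arbitrary feature vectors in [0,1]^6 the three tiers
        occupy [0,6], [7,13] and [14,20] with no overlap."""
        fv = FeatureVector(*f)
        ctx = make_context()
        bounds = {Tier.LOW: (0, 6), Tier.MID: (7, 13), Tier.HIGH: (14, 20)}
        for sigma_on in (False, True):
            for theta_on in (False, True):
                res = ipx_from_features(fv, sigma_on, theta_on, ctx)
                lo, hi = bounds[res.tier]
                assert lo <= res.ipx <= hi + 1e-9

    @settings(max_examples=100, deadline=None)
    @given(f=st.tuples(unit, unit, unit, unit, unit, unit),
           idx=st.integers(0, 5), delta=st.floats(0.0, 1.0))
    def test_monotone_in_each_feature(self, f, idx, delta):
        vals = list(f)
        bumped = list(f)
        bumped[idx] = min(1.0, bumped[idx] + delta)
        ctx = make_context()
        low = ipx_from_features(FeatureVector(*vals), True, False, ctx)
        high = ipx_from_features(FeatureVector(*bumped), True, False, ctx)
        assert high.ipx >= low.ipx - 1e-12

    def test_monotone_in_bonuses(self):
        f = FeatureVector(0.3, 0.3, 0.3, 0.3, 0.3, 0.3)
        ctx = make_context()
        assert (ipx_from_features(f, True, True, ctx).ipx
                > ipx_from_features(f, True, False, ctx).ipx
                > ipx_from_features(f, False, False, ctx).ipx)

    def test_scale_stability_of_cv_scores(self, walked_putative, onto):
        """Multiplying every CV score by a constant leaves the normalised
        i and d features unchanged."""
        base = default_score_map()
        scaled = CVScoreMap(
            type_scores={k: 3.0 * v for k, v in base.type_scores.items()},
            method_scores={k: 3.0 * v for k, v in base.method_scores.items()},
        )
        ctx_a = ScoringContext.from_dataset(
            walked_putative, ScoreConfig(base), onto)
        ctx_b = ScoringContext.from_dataset(
            walked_putative, ScoreConfig(scaled), onto)
        for p in walked_putative:
            fa, fb = feature_vector(p, ctx_a), feature_vector(p, ctx_b)
            assert fa.i == pytest.approx(fb.i)
            assert fa.d == pytest.approx(fb.d)


def network_from_edges(edges) -> Network:
    net = Network()
    for a, b in edges:
        net.add_edge(gid(a), gid(b), kind="known")
    return net


class TestPcs:
    def test_single_edge(self):
        net = network_from_edges([("x", "y")])
        assert compute_pcs(gid("x"), gid("y"), net) == pytest.approx(1.0)

    def test_complete_graph_k4(self):
        nodes = ["a", "b", "c", "d"]
        net = network_from_edges(
            [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])
        # gamma = 1, E = 6
        assert compute_pcs(gid("a"), gid("b"), net) == pytest.approx(6.0)

    def test_four_nodes_five_edges(self):
        """Two common neighbours without a z-w edge: N=4, E=5, so
        gamma = 5/6 and PCS = 25/6 by the density formula."""
        nodes = ["x", "y", "z", "w"]
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
                 if {u, v} != {"z", "w"}]
        net = network_from_edges(edges)
        sub = reference_subnetwork(gid("x"), gid("y"), net)
        assert sub.n_nodes() == 4 and sub.n_unique_pairs() == 5
        assert compute_pcs(gid("x"), gid("y"), net) == pytest.approx(25 / 6)

    def test_losing_one_spoke_shrinks_the_clique(self):
        """Removing y-z demotes z from common neighbour to one-sided
        neighbour: the subnetwork collapses to the x,y,w triangle."""
        nodes = ["x", "y", "z", "w"]
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
                 if {u, v} != {"z", "w"}]
        net = network_from_edges(edges)
        net.graph.remove_edge(gid("y"), gid("z"))
        assert compute_pcs(gid("x"), gid("y"), net) == pytest.approx(3.0)

    def test_gamma_in_unit_interval_and_complete_equals_e(self, onto):
        inst = generate_instance(SynthConfig(seed=23))
        net = network_from_edges([])
        for r in inst.ppi_j:
            net.add_edge(r.interactor_a, r.interactor_b, kind="known")
        for r in inst.ppi_j:
            a, b = r.interactor_a, r.interactor_b
            if a == b:
                continue
            sub = reference_subnetwork(a, b, net)
            n, e = sub.n_nodes(), sub.n_unique_pairs()
            gamma = 2 * e / (n * (n - 1))
            assert 0.0 < gamma <= 1.0
            assert compute_pcs(a, b, net) == pytest.approx(gamma * e)

    def test_common_neighbour_needs_both_sides(self):
        # z neighbours only x: induced graph is just the xy edge
        net = network_from_edges([("x", "y"), ("x", "z")])
        sub = reference_subnetwork(gid("x"), gid("y"), net)
        assert sub.n_nodes() == 2 and sub.n_unique_pairs() == 1

    def test_absent_edge_is_contract_violation(self):
        net = network_from_edges([("x", "z")])
        with pytest.raises(ValueError):
            compute_pcs(gid("x"), gid("y"), net)


def test_score_putative_set_attaches_pcs(onto):
    from orthowalk.network import known_network

    inst = generate_instance(SynthConfig(seed=31))
    rows = run_walk(set(inst.genes_i), inst.orthology, inst.ppi_j,
                    FilterSpec(), onto).rows
    putative = collapse_to_putative(rows)
    ref = {inst.config.taxid_j: known_network(inst.ppi_j)}
    scored = score_putative_set(putative, onto=onto, ref_networks=ref)
    assert len(scored) == len(putative)
    pcs_values = [pcs for _, _, pcs in scored if not math.isnan(pcs)]
    assert pcs_values and all(v >= 1.0 for v in pcs_values)
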