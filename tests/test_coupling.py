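import numpy as np
import pytest

from helpers import blocked_oracle, structural_classes_oracle

from sccnet import (
    FluxSpace,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    find_blocked,
    kinetic_couplings,
    mass_action_rates,
    merge_couplings,
    ratio_range,
    structural_couplings,
)
from sccnet.coupling import CouplingInconsistency, CouplingRelation, InfeasibleFluxSpace
from sccnet.ratios import RatioCoeff


def parallel_network():
    """0 -> A; A -> B / A -> C in parallel; B, C -> 0."""
    mets = [Metabolite(m) for m in "ABC"]
    rxns = [
        Reaction("R1", {}, {"A": 1}, 0, 1000),
        Reaction("R2", {"A": 1}, {"B": 1}, 0, 1000),
        Reaction("R2p", {"A": 1}, {"C": 1}, 0, 1000),
        Reaction("R3", {"B": 1}, {}, 0, 1000),
        Reaction("R4", {"C": 1}, {}, 0, 1000),
    ]
    return MetabolicNetwork(mets, rxns, id="parallel")


# ---------------------------------------------------------------- blocked


def test_unconstrained_chain_has_no_blocked_reactions(chain_net):
    assert find_blocked(chain_net) == set()


def test_dangling_branch_is_blocked(chain_net):
    net = MetabolicNetwork(
        chain_net.metabolites + [Metabolite("D")],
        chain_net.reactions + [Reaction("RD", {"A": 1}, {"D": 1}, 0, 1000)],
    )
    assert find_blocked(net) == {"RD"}


def test_zero_bound_on_middle_reaction_blocks_whole_chain(chain_net):
    fs = chain_net.flux_space().restrict(1, lb=0.0, ub=0.0)
    assert find_blocked(chain_net, fs) == set(chain_net.reaction_ids())


def test_blocked_matches_ray_enumeration_on_fixtures(chain_net, demo_net, diamond_net):
    for net in (chain_net, demo_net, diamond_net, parallel_network()):
        expected = {net.reactions[j].id for j in blocked_oracle(net.stoichiometry)}
        assert find_blocked(net) == expected


# ---------------------------------------------------------------- ratio range


def test_chain_flux_ratio_is_pinned_to_one(chain_net):
    assert ratio_range(chain_net, None, "R1", "R3") == pytest.approx((1.0, 1.0))


def test_parallel_branch_ratio_reaches_zero():
    net = parallel_network()
    r_min, r_max = ratio_range(net, None, "R2", "R1")
    assert r_min == pytest.approx(0.0, abs=1e-9)
    assert r_max == pytest.approx(1.0)


def test_self_ratio_is_identity(chain_net):
    assert ratio_range(chain_net, None, "R2", "R2") == (1.0, 1.0)


def test_ratio_range_errors_when_denominator_cannot_carry_flux(chain_net):
    fs = chain_net.flux_space().restrict(2, lb=0.0, ub=0.0)
    with pytest.raises(InfeasibleFluxSpace):
        ratio_range(chain_net, fs, "R1", "R3")


# ---------------------------------------------------------------- structural


def test_chain_is_one_structural_class(chain_net):
    rel = structural_couplings(chain_net)
    assert rel.classes() == [{"R1", "R2", "R3"}]
    assert rel.lam("R1", "R3").value() == pytest.approx(1.0)


def test_demo_network_structural_classes(demo_net):
    rel = structural_couplings(demo_net)
    assert rel.nontrivial_classes() == [{"R3", "R4"}, {"R5", "R6"}]
    # stoichiometry 2 on the drains halves the coupled flux
    assert rel.lam("R3", "R4").value() == pytest.approx(0.5)


def test_two_independent_chains_stay_separate():
    mets = [Metabolite(m) for m in ("A", "B")]
    rxns = [
        Reaction("u1", {}, {"A": 1}, 0, 1000),
        Reaction("u2", {"A": 1}, {}, 0, 1000),
        Reaction("w1", {}, {"B": 1}, 0, 1000),
        Reaction("w2", {"B": 1}, {}, 0, 1000),
    ]
    net = MetabolicNetwork(mets, rxns)
    rel = structural_couplings(net)
    assert rel.nontrivial_classes() == [{"u1", "u2"}, {"w1", "w2"}]


def test_structural_classes_match_ray_oracle_on_small_networks(
    chain_net, demo_net, diamond_net
):
    for net in (chain_net, demo_net, diamond_net, parallel_network()):
        assert net.n_reactions <= 8
        rel = structural_couplings(net)
        got = sorted(
            [sorted(c) for c in rel.classes()], key=lambda c: c[0]
        )
        idx_classes = structural_classes_oracle(
            net.stoichiometry, list(range(net.n_reactions))
        )
        ids = net.reaction_ids()
        expected = sorted(
            [sorted(ids[j] for j in c) for c in idx_classes], key=lambda c: c[0]
        )
        assert got == expected


# ---------------------------------------------------------------- kinetic


def test_shared_substrate_columns_couple_kinetically(demo_net):
    rel = kinetic_couplings(demo_net)
    assert rel.nontrivial_classes() == [{"R2", "R3", "R5"}]
    lam = rel.lam("R3", "R5")
    assert lam.powers == {"R5": 1, "R3": -1}  # v5 = (theta5/theta3) v3
    assert lam.value({"R3": 0.7, "R5": 1.3}) == pytest.approx(1.3 / 0.7)


def test_two_zero_order_imports_are_coupled():
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("iA", {}, {"A": 1}, 0, 10),
        Reaction("iB", {}, {"B": 1}, 0, 10),
        Reaction("xA", {"A": 1}, {}, 0, 10),
        Reaction("xB", {"B": 1}, {}, 0, 10),
    ]
    net = MetabolicNetwork(mets, rxns)
    rel = kinetic_couplings(net)
    assert rel.same_class("iA", "iB")
    assert rel.lam("iA", "iB").powers == {"iB": 1, "iA": -1}


def test_different_stoichiometry_does_not_couple():
    mets = [Metabolite("A")]
    rxns = [
        Reaction("r1", {"A": 1}, {}, 0, 10),
        Reaction("r2", {"A": 2}, {}, 0, 10),
    ]
    rel = kinetic_couplings(MetabolicNetwork(mets, rxns))
    assert not rel.same_class("r1", "r2")


def test_kinetic_coupling_holds_off_steady_state(demo_net, demo_th):
    rng = np.random.default_rng(7)
    rel = kinetic_couplings(demo_net)
    for _ in range(5):
        x = rng.uniform(0.1, 5.0, size=demo_net.n_metabolites)
        v = dict(zip(demo_net.reaction_ids(), mass_action_rates(demo_net, demo_th, x)))
        lam = rel.lam("R3", "R5").value(demo_th)
        assert v["R5"] == pytest.approx(lam * v["R3"], rel=1e-12)


# ---------------------------------------------------------------- merging


def test_merge_of_stated_pairs_gives_single_class():
    rel_a = CouplingRelation(["R3", "R4", "R5", "R6"])
    rel_a.add_pair("R3", "R4", RatioCoeff.number(0.5), "structural")
    rel_a.add_pair("R5", "R6", RatioCoeff.number(0.5), "structural")
    rel_b = CouplingRelation(["R3", "R4", "R5", "R6"])
    rel_b.add_pair("R3", "R5", RatioCoeff.theta_ratio("R5", "R3"), "kinetic")
    merged = merge_couplings(rel_a, rel_b)
    assert merged.classes() == [{"R3", "R4", "R5", "R6"}]
    assert merged.provenance("R3", "R4") == "structural"
    assert merged.provenance("R4", "R6") == "transitive"
    lam = merged.lam("R4", "R6")  # v6 = lam * v4, through R3 and R5
    assert lam.powers == {"R5": 1, "R3": -1} and lam.coeff == pytest.approx(1.0)


def test_merge_keeps_disjoint_relations_disjoint():
    a = CouplingRelation(["x", "y"])
    a.add_pair("x", "y", RatioCoeff.number(2.0), "structural")
    b = CouplingRelation(["u", "w"])
    b.add_pair("u", "w", RatioCoeff.number(3.0), "structural")
    merged = merge_couplings(a, b)
    assert merged.classes() == [{"u", "w"}, {"x", "y"}]


def test_inconsistent_cycle_raises():
    rel = CouplingRelation(["a", "b", "c"])
    rel.add_pair("a", "b", RatioCoeff.number(2.0), "structural")
    rel.add_pair("b", "c", RatioCoeff.number(3.0), "structural")
    with pytest.raises(CouplingInconsistency):
        rel.add_pair("a", "c", RatioCoeff.number(1 / 5), "structural")


def test_merge_is_idempotent_and_commutative(demo_net):
    sc = structural_couplings(demo_net)
    kc = kinetic_couplings(demo_net)
    ab = merge_couplings(sc, kc)
    ba = merge_couplings(kc, sc)
    twice = merge_couplings(ab, ab)
    assert ab.classes() == ba.classes() == twice.classes()
    assert ab.lam("R4", "R6").agrees_with(twice.lam("R4", "R6"))


def test_coupling_report_frame_lists_pairs(demo_net):
    rel = merge_couplings(structural_couplings(demo_net), kinetic_couplings(demo_net))
    frame = rel.to_frame()
    assert set(frame.columns) == {"reaction_a", "reaction_b", "lambda", "provenance"}
    assert len(frame) == 10  # 5-reaction class: all unordered pairs
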