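import numpy as np
import pytest

from helpers import scc_triples_oracle

from sccnet import (
    Metabolite,
    MetabolicNetwork,
    Reaction,
    certificate_summary,
    find_scc,
    kinetic_couplings,
    lacks_one_substrate,
    merge_couplings,
    structural_couplings,
)
from sccnet.simulate import SyntheticSpec, generate_network


def merged(net):
    return merge_couplings(structural_couplings(net), kinetic_couplings(net))


# ---------------------------------------------------------------- lack relation


@pytest.mark.parametrize(
    "k,l,i,expected",
    [
        ("R7", "R2", "B", True),   # one fewer B, all other rows equal
        ("R7", "R3", "B", True),
        ("R7", "R5", "B", True),
        ("R2", "R7", "B", False),  # direction matters
        ("R2", "R3", "B", False),  # identical columns differ by zero
        ("R4", "R2", "B", False),  # columns differ in more than one row
    ],
)
def test_lacks_one_substrate_on_demo_network(demo_net, k, l, i, expected):
    assert lacks_one_substrate(demo_net, k, l, i) is expected


def test_lacks_one_substrate_against_zero_order_import(chain_net):
    # R1 (no substrates) lacks one A in comparison to R2 (A -> B)
    assert lacks_one_substrate(chain_net, "R1", "R2", "A")
    assert not lacks_one_substrate(chain_net, "R1", "R3", "A")


# ---------------------------------------------------------------- detection


def test_chain_detection_finds_both_metabolites(chain_net, chain_certs):
    by_target = {}
    for cert in chain_certs:
        by_target.setdefault(cert.target, []).append(cert)
    assert set(by_target) == {"A", "B"}
    # A is its own witness (R1 lacks one A vs R2) and also provable from B's ODE
    assert {(c.witness, c.case) for c in by_target["A"]} == {("A", "II"), ("B", "I")}
    assert [(c.witness, c.case) for c in by_target["B"]] == [("B", "II")]


def test_demo_network_has_sole_scc_metabolite_with_two_witnesses(demo_net, demo_certs):
    assert {c.target for c in demo_certs} == {"B"}
    by_witness = {c.witness: c for c in demo_certs}
    assert set(by_witness) == {"A", "C"}
    cert_a, cert_c = by_witness["A"], by_witness["C"]
    assert cert_a.ratio_pair == ("R4", "R7") and cert_a.relevant_thetas == ("R3", "R7")
    assert cert_c.ratio_pair == ("R6", "R7") and cert_c.relevant_thetas == ("R5", "R7")
    assert cert_a.case == cert_c.case == "I"
    assert cert_a.lack_map() == {"R3": ("R7",)}


def test_uncoupled_lack_reactions_block_the_certificate():
    # two consumers of A whose lack partners (two imports with *different*
    # substrate columns) are not mutually coupled
    mets = [Metabolite(m) for m in ("A", "B", "E")]
    rxns = [
        Reaction("i1", {}, {"A": 1}, 0, 10),          # lacks one A vs c1
        Reaction("i2", {"E": 1}, {"A": 1}, 0, 10),    # lacks one A vs c2
        Reaction("c1", {"A": 1}, {"B": 1}, 0, 10),
        Reaction("c2", {"A": 1, "E": 1}, {"B": 1}, 0, 10),
        Reaction("iE", {}, {"E": 1}, 0, 10),
        Reaction("xB", {"B": 1}, {}, 0, 10),
    ]
    net = MetabolicNetwork(mets, rxns)
    cr = merged(net)
    assert not cr.same_class("i1", "i2")
    targets = {c.target for c in find_scc(net, cr)}
    assert "A" not in targets


def test_detection_agrees_with_literal_condition_scan(chain_net, demo_net):
    nets = [chain_net, demo_net]
    for seed in range(4):
        nets.append(
            generate_network(
                SyntheticSpec(seed=seed, n_chain=1, n_shared=1, n_branch=0, n_background=2),
                verify=False,
            ).network
        )
    for net in nets:
        cr = merged(net)
        got = {(c.target, c.witness, c.case) for c in find_scc(net, cr)}
        assert got == scc_triples_oracle(net, cr)


def test_certificates_invariant_under_relabeling(demo_net):
    met_map = {"A": "mX", "B": "mY", "C": "mZ"}
    rxn_map = {r: f"q{9 - int(r[1])}" for r in demo_net.reaction_ids()}
    mets = [Metabolite(met_map[m.id]) for m in demo_net.metabolites][::-1]
    rxns = [
        Reaction(
            rxn_map[r.id],
            {met_map[m]: c for m, c in r.substrates.items()},
            {met_map[m]: c for m, c in r.products.items()},
            r.lb,
            r.ub,
        )
        for r in demo_net.reactions
    ][::-1]
    relabeled = MetabolicNetwork(mets, rxns)
    orig = find_scc(demo_net, merged(demo_net))
    new = find_scc(relabeled, merged(relabeled))
    expected = {
        (met_map[c.target], met_map[c.witness], c.case, rxn_map[c.num_rep], rxn_map[c.den_rep])
        for c in orig
    }
    got = {(c.target, c.witness, c.case, c.num_rep, c.den_rep) for c in new}
    assert got == expected


def test_never_consumed_metabolites_are_skipped():
    mets = [Metabolite("A"), Metabolite("D")]
    rxns = [
        Reaction("i", {}, {"A": 1}, 0, 10),
        Reaction("x", {"A": 1}, {"D": 1}, 0, 10),  # D never consumed
    ]
    net = MetabolicNetwork(mets, rxns)
    certs = find_scc(net, merged(net))
    assert "D" not in {c.target for c in certs}


# ---------------------------------------------------------------- summary


def test_summary_rows(demo_net, demo_certs, chain_certs, chain_net):
    frame = certificate_summary(demo_certs, demo_net)
    assert len(frame) == 1
    row = frame.iloc[0]
    assert row["metabolite"] == "B" and row["n_certificates"] == 2
    assert row["witnesses"] == "A;C"
    assert row["n_relevant_thetas"] == 3  # union of {R3,R7} and {R5,R7}
    assert row["in_degree"] == 1 and row["out_degree"] == 4

    chain_frame = certificate_summary(chain_certs, chain_net)
    assert len(chain_frame) == 2

    assert certificate_summary([]).empty
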