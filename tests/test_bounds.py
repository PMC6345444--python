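import numpy as np
import pytest
from hypothesis import given, strategies as st

from sccnet import (
    RateConstants,
    intersect_ranges,
    point_concentration,
    range_over_fluxes,
    sigma_pair,
    substitute_missing_ratios,
)
from sccnet.ratios import MissingRateConstant


def cert_by(certs, target, witness):
    return next(c for c in certs if c.target == target and c.witness == witness)


# ---------------------------------------------------------------- sigma


def test_chain_sigma_constants(chain_net, chain_cr, chain_certs, chain_theta):
    cert_a = cert_by(chain_certs, "A", "A")
    s = sigma_pair(cert_a, chain_theta, chain_cr, chain_net)
    assert s.sigma_num == pytest.approx(1.0)
    assert s.sigma_den == pytest.approx(chain_theta["R2"] / chain_theta["R1"])
    cert_b = cert_by(chain_certs, "B", "B")
    s = sigma_pair(cert_b, chain_theta, chain_cr, chain_net)
    assert s.sigma_num == pytest.approx(1.0)
    assert s.sigma_den == pytest.approx(chain_theta["R3"] / chain_theta["R1"])


def test_demo_sigma_matches_hand_derivation(demo_net, demo_cr, demo_certs, demo_th):
    # witness A: x_B = (2 theta7 / theta3) * v4 / v7
    cert = cert_by(demo_certs, "B", "A")
    s = sigma_pair(cert, demo_th, demo_cr, demo_net)
    assert s.ratio == pytest.approx(2.0 * demo_th["R7"] / demo_th["R3"])


def test_missing_theta_is_reported(demo_net, demo_cr, demo_certs):
    cert = cert_by(demo_certs, "B", "A")
    partial = {"R7": 0.5}
    with pytest.raises(MissingRateConstant) as err:
        sigma_pair(cert, partial, demo_cr, demo_net)
    assert "R3" in err.value.missing


def test_sigma_num_invariant_to_theta_when_couplings_structural(demo_net, demo_cr, demo_certs):
    cert = cert_by(demo_certs, "B", "A")
    rng = np.random.default_rng(3)
    values = set()
    for _ in range(5):
        theta = {r: float(rng.uniform(0.1, 10)) for r in demo_net.reaction_ids()}
        values.add(round(sigma_pair(cert, theta, demo_cr, demo_net).sigma_num, 12))
    assert values == {2.0}  # N-[A, R4] = 2; S_A = {R4} needs no theta


# ---------------------------------------------------------------- point


def test_chain_point_concentrations(chain_net, chain_cr, chain_certs, chain_theta):
    v = {"R1": 2.0, "R2": 2.0, "R3": 2.0}
    for cert in chain_certs:
        s = sigma_pair(cert, chain_theta, chain_cr, chain_net)
        x = point_concentration(cert, s, v)
        expected = 2.0 if cert.target == "A" else 0.5
        assert x == pytest.approx(expected)


def test_zero_denominator_flux_raises(chain_net, chain_cr, chain_certs, chain_theta):
    cert = cert_by(chain_certs, "B", "B")
    s = sigma_pair(cert, chain_theta, chain_cr, chain_net)
    with pytest.raises(ValueError):
        point_concentration(cert, s, {"R1": 0.0, "R2": 1.0, "R3": 1.0})


# ---------------------------------------------------------------- ranges


def test_single_flux_vector_gives_degenerate_interval(chain_net, chain_cr, chain_certs, chain_theta):
    cert = cert_by(chain_certs, "B", "B")
    lo, hi = range_over_fluxes(cert, chain_theta, chain_cr, chain_net, [{"R1": 1, "R2": 1, "R3": 1}])
    assert lo == pytest.approx(hi)


def test_two_flux_vectors_span_scaled_interval(chain_net, chain_cr, chain_certs, chain_theta):
    # witness B for A: sigma ratio theta1/theta2 = 2, relevant ratio v3/v1
    cert = cert_by(chain_certs, "A", "B")
    flux_set = [{"R1": 1.0, "R2": 1.0, "R3": 1.0}, {"R1": 1.0, "R2": 3.0, "R3": 3.0}]
    lo, hi = range_over_fluxes(cert, chain_theta, chain_cr, chain_net, flux_set)
    assert (lo, hi) == pytest.approx((2.0, 6.0))


def test_ratio_interval_is_scaled_monotonically(chain_net, chain_cr, chain_certs, chain_theta):
    cert = cert_by(chain_certs, "A", "B")
    lo, hi = range_over_fluxes(cert, chain_theta, chain_cr, chain_net, (0.5, 2.0))
    assert (lo, hi) == pytest.approx((1.0, 4.0))


def test_all_members_unusable_raises(chain_net, chain_cr, chain_certs, chain_theta):
    cert = cert_by(chain_certs, "A", "B")
    with pytest.raises(ValueError):
        range_over_fluxes(cert, chain_theta, chain_cr, chain_net, [{"R1": 0.0, "R3": 1.0}])


def test_adding_flux_vectors_only_widens(chain_net, chain_cr, chain_certs, chain_theta):
    cert = cert_by(chain_certs, "A", "B")
    rng = np.random.default_rng(11)
    fluxes = [
        {"R1": float(rng.uniform(0.1, 5)), "R3": float(rng.uniform(0.1, 5))}
        for _ in range(8)
    ]
    prev = range_over_fluxes(cert, chain_theta, chain_cr, chain_net, fluxes[:1])
    for k in range(2, len(fluxes) + 1):
        cur = range_over_fluxes(cert, chain_theta, chain_cr, chain_net, fluxes[:k])
        assert cur[0] <= prev[0] + 1e-12 and cur[1] >= prev[1] - 1e-12
        prev = cur


# ---------------------------------------------------------------- intersection


@pytest.mark.parametrize(
    "intervals,expected,feasible",
    [
        ({"a": (1, 5), "b": (2, 8)}, (2, 5), True),
        ({"a": (1, 2), "b": (3, 4)}, (3, 2), False),
        ({"a": (1, 4)}, (1, 4), True),
    ],
)
def test_intersection_examples(intervals, expected, feasible):
    rng = intersect_ranges(intervals)
    assert (rng.lower, rng.upper) == expected
    assert rng.feasible is feasible


interval = st.tuples(
    st.floats(0.01, 100), st.floats(0.01, 100)
).map(lambda ab: (min(ab), max(ab)))


@given(st.lists(interval, min_size=1, max_size=6))
def test_intersection_never_wider_than_any_member(intervals):
    rng = intersect_ranges(dict(enumerate(intervals)))
    for lo, hi in intervals:
        assert rng.lower >= lo and rng.upper <= hi


@given(st.lists(interval, min_size=1, max_size=5), interval)
def test_intersection_shrinks_monotonically(intervals, extra):
    base = intersect_ranges(dict(enumerate(intervals)))
    more = intersect_ranges(dict(enumerate(intervals + [extra])))
    assert more.lower >= base.lower and more.upper <= base.upper


# ---------------------------------------------------------------- substitution


@pytest.mark.parametrize(
    "scheme,known,expected",
    [
        ("mean", {"R3": 2.0}, None),  # value computed below per-case
        ("one", {}, 1.0),
    ],
)
def test_substitution_schemes_fill_missing_ratios(
    demo_net, demo_cr, demo_certs, scheme, known, expected
):
    cert = cert_by(demo_certs, "B", "A")
    ratios, subbed = substitute_missing_ratios(cert, known, scheme, demo_cr, demo_net)
    assert subbed  # theta3/theta7 cannot be formed
    if expected is not None:
        assert all(v == expected for v in ratios.values())


def test_substitution_mean_and_median_arithmetic():
    assert float(np.mean([2.0, 4.0])) == 3.0
    assert float(np.median([1.0, 2.0, 10.0])) == 2.0
    # wire the arithmetic through a real certificate: a chain target with two
    # coupled import partners gives two ratio slots
    from sccnet import find_scc, kinetic_couplings, merge_couplings, structural_couplings
    from sccnet.network import Metabolite, MetabolicNetwork, Reaction

    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("i1", {}, {"A": 1}, 0, 10),
        Reaction("i2", {}, {"B": 1}, 0, 10),
        Reaction("cA", {"A": 1}, {}, 0, 10),
        Reaction("cB", {"B": 1}, {}, 0, 10),
    ]
    net = MetabolicNetwork(mets, rxns)
    cr = merge_couplings(structural_couplings(net), kinetic_couplings(net))
    certs = find_scc(net, cr)
    cert = next(c for c in certs if c.target == "A")
    # full knowledge: no substitution recorded
    theta = {"i1": 1.0, "i2": 2.0, "cA": 3.0, "cB": 4.0}
    ratios, subbed = substitute_missing_ratios(cert, theta, "median", cr, net)
    assert subbed == []
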