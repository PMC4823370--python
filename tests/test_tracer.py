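"""Atom-mapped label propagation: structure, diagnostics, invariants."""

import numpy as np
import pytest

from sirmkit.tracer import (
    CarbonPool,
    PathwayConfig,
    build_default_network,
    mid_of,
    propagate,
    reactions_from_csv,
    reactions_to_csv,
    scramble_symmetric,
    simulate_experiment,
)


@pytest.fixture(scope="module")
def net():
    return build_default_network()


def shifts_present(state, pool, tol=1e-12):
    return set(np.nonzero(mid_of(state[pool]).fractions > tol)[0].tolist())


def test_network_validates_and_has_expected_chemistry(net):
    net.validate()  # every product carbon from exactly one source; conservation
    assert net.pools["glutamate"] == 5
    assert net.pools["citrate"] == 6
    assert set(net.symmetric_pools) == {"succinate", "fumarate"}


def test_glycolysis_only_labels_only_upper_pools(net):
    cfg = PathwayConfig(tracer="glucose", acetyl_from_pyruvate=0.0)
    state = propagate(net, cfg)
    labeled = {p for p in net.update_order if mid_of(state[p]).fractions[0] < 1 - 1e-9}
    assert labeled == {"pg3", "serine", "glycine", "pep", "pyruvate", "lactate", "alanine"}


def test_first_condensation_from_glucose_gives_m2(net):
    state = propagate(net, PathwayConfig(tracer="glucose", turns=1))
    assert shifts_present(state, "citrate") == {2}


def test_partial_glucose_fraction_mixes_m0_and_m2(net):
    state = propagate(net, PathwayConfig(tracer="glucose", g=0.7, turns=1))
    cit = mid_of(state["citrate"]).fractions
    assert shifts_present(state, "citrate") == {0, 2}
    assert cit[2] == pytest.approx(0.7, abs=1e-12)


def test_second_turn_from_glucose_gives_m4_exactly(net):
    # hand-derived: turn-2 citrate combines M+2 acetyl with the scrambled
    # M+2 oxaloacetate returning from the first turn
    state = propagate(net, PathwayConfig(tracer="glucose", turns=2))
    cit = mid_of(state["citrate"]).fractions
    assert cit[4] == pytest.approx(1.0, abs=1e-12)
    dist = state["citrate"].dist
    # equal mass on the two positional isotopomers 110011 and 001111
    support = {i for i in range(64) if dist[i] > 1e-12}
    assert support == {0b110011, 0b001111}
    assert dist[0b110011] == pytest.approx(0.5, abs=1e-12)


def test_steady_state_reaches_m6_and_never_m1(net):
    state = propagate(net, PathwayConfig(tracer="glucose"))
    s = shifts_present(state, "citrate")
    assert max(s) == 6
    assert 1 not in s
    # turn-limited runs never show M+1 either
    for turns in (1, 2, 5, 20):
        st = propagate(net, PathwayConfig(tracer="glucose", turns=turns))
        assert 1 not in shifts_present(st, "citrate")


def test_glutamine_oxidative_first_turn_m4_no_m3_no_m5(net):
    cfg = PathwayConfig(
        tracer="glutamine", glutamine_anaplerosis=1.0, acetyl_from_pyruvate=0.0, turns=1
    )
    assert shifts_present(propagate(net, cfg), "citrate") == {4}


def test_glutamine_oxidative_steady_state_m3_is_structurally_zero(net):
    for anap in (1.0, 0.6, 0.3):
        cfg = PathwayConfig(
            tracer="glutamine", glutamine_anaplerosis=anap, acetyl_from_pyruvate=0.0
        )
        cit = mid_of(propagate(net, cfg)["citrate"]).fractions
        assert cit[3] == 0.0


def test_reductive_carboxylation_adds_citrate_m5(net):
    base = PathwayConfig(
        tracer="glutamine", glutamine_anaplerosis=1.0, acetyl_from_pyruvate=0.0
    )
    ox = shifts_present(propagate(net, base), "citrate")
    red = shifts_present(
        propagate(
            net,
            PathwayConfig(
                tracer="glutamine",
                glutamine_anaplerosis=1.0,
                acetyl_from_pyruvate=0.0,
                reductive_fraction=0.3,
            ),
        ),
        "citrate",
    )
    assert red - ox == {5}


def test_pyruvate_carboxylase_gives_citrate_m3_m5(net):
    cfg = PathwayConfig(tracer="glucose", pc_fraction=0.3)
    cit = mid_of(propagate(net, cfg)["citrate"]).fractions
    assert cit[3] > 0 or cit[5] > 0


def test_glutamine_synthetase_labels_glutamine_from_glucose(net):
    cfg = PathwayConfig(tracer="glucose", q=0.4, gs_fraction=0.3,
                        glutamine_anaplerosis=0.2)
    mid = mid_of(propagate(net, cfg)["glutamine"]).fractions
    assert mid[5] > 0


def test_succinate_less_glucose_derived_than_isocitrate(net):
    from sirmkit.isotopes import fractional_enrichment

    cfg = PathwayConfig(
        tracer="glucose", g=0.8, glutamine_anaplerosis=0.4, q=1.0
    )
    state = propagate(net, cfg)
    e_succ = fractional_enrichment(mid_of(state["succinate"]))
    e_iso = fractional_enrichment(mid_of(state["isocitrate"]))
    assert e_succ < e_iso


def test_distributions_stay_on_simplex_and_sum_conserved(net):
    cfg = PathwayConfig(tracer="glucose", g=0.63, pc_fraction=0.2,
                        glutamine_anaplerosis=0.35, gs_fraction=0.3, turns=3)
    state = propagate(net, cfg)
    for pool in state.values():
        assert np.all(pool.dist >= -1e-15)
        assert pool.dist.sum() == pytest.approx(1.0, abs=1e-9)


def test_steady_state_independent_of_update_order(net):
    import dataclasses

    cfg = PathwayConfig(tracer="glucose", g=0.7, pc_fraction=0.1,
                        glutamine_anaplerosis=0.3, gs_fraction=0.2)
    ref = propagate(net, cfg)
    rng = np.random.default_rng(0)
    for _ in range(3):
        order = list(net.update_order)
        rng.shuffle(order)
        permuted = dataclasses.replace(net, update_order=tuple(order))
        state = propagate(permuted, cfg)
        for pool in net.update_order:
            assert np.allclose(state[pool].dist, ref[pool].dist, atol=1e-8)


def test_scramble_symmetric_properties(net):
    rng = np.random.default_rng(3)
    d = rng.dirichlet(np.ones(16))
    pool = CarbonPool("succinate", 4, d, symmetric=True)
    s1 = scramble_symmetric(pool)
    # 1100 (0b0011) and 0011 (0b1100) both end at the mean of their inputs
    assert s1.dist[0b0011] == pytest.approx((d[0b0011] + d[0b1100]) / 2)
    assert s1.dist[0b1100] == pytest.approx(s1.dist[0b0011])
    # idempotent
    s2 = scramble_symmetric(s1)
    assert np.allclose(s1.dist, s2.dist)
    # MID unchanged
    assert np.allclose(mid_of(pool).fractions, mid_of(s1).fractions)
    with pytest.raises(ValueError):
        scramble_symmetric(CarbonPool("malate", 4, d, symmetric=False))


def test_mid_of_counts_bits():
    uniform = CarbonPool("x", 2, np.full(4, 0.25))
    assert np.allclose(mid_of(uniform).fractions, [0.25, 0.5, 0.25])
    unlabeled = CarbonPool("x", 3, np.eye(1, 8, 0).ravel())
    assert np.allclose(mid_of(unlabeled).fractions, [1, 0, 0, 0])


def test_pathway_config_validation():
    with pytest.raises(ValueError):
        PathwayConfig(tracer="acetate").validate()
    with pytest.raises(ValueError):
        PathwayConfig(g=1.5).validate()
    with pytest.raises(ValueError):
        PathwayConfig(turns=0).validate()


def test_simulate_experiment_table(net):
    table = simulate_experiment(PathwayConfig(tracer="glucose", q=0.4,
                                              gs_fraction=0.3,
                                              glutamine_anaplerosis=0.2))
    mids = table[table["kind"] == "mid"]
    sums = mids.groupby("metabolite")["value"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    gln_m5 = mids[(mids.metabolite == "glutamine") & (mids["shift"] == 5)]["value"].iloc[0]
    assert gln_m5 > 0


def test_reaction_table_round_trip(net):
    text = reactions_to_csv(net)
    back = reactions_from_csv(text)
    assert back == net.reactions
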