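"""Community assembly, coupling behaviour and exchange decomposition."""

import numpy as np
import pytest

from gutflux.community import (
    CommunityMember,
    CouplingConfig,
    Diet,
    EmptyCommunityError,
    apply_diet,
    assemble_community,
    decompose_exchanges,
    aggregate_taxon_fluxes,
    microbial_exchange_value,
    screen_members,
    simulate_community,
)
from gutflux.core import MetabolicModel, Metabolite, Reaction, fba
from gutflux.synth import TEMPLATES, make_default_diet, make_toy_bacterium, taxonomy_of


def _member(template, abundance, rng=None):
    return CommunityMember(make_toy_bacterium(template, rng), abundance,
                           taxonomy_of(template))


@pytest.fixture
def diet() -> Diet:
    return make_default_diet()


@pytest.fixture
def six_members(diet):
    ab = {
        "butyrate_producer": 0.3, "lactate_crossfeeder": 0.15,
        "amino_acid_producer": 0.1, "bile_deconjugator": 0.1,
        "generalist": 0.25, "starch_degrader": 0.1,
    }
    return screen_members([_member(t, a) for t, a in ab.items()], diet)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_screen_drops_non_grower_and_renormalizes(diet):
    # the lactate crossfeeder cannot grow without lactate
    no_lac = Diet({k: v for k, v in diet.bounds.items() if k != "lac"})
    cands = [_member("butyrate_producer", 0.6),
             _member("lactate_crossfeeder", 0.2),
             _member("amino_acid_producer", 0.2)]
    kept = screen_members(cands, no_lac)
    assert [m.id for m in kept] == ["butyrate_producer", "amino_acid_producer"]
    assert [m.abundance for m in kept] == pytest.approx([0.75, 0.25])


def test_screen_cutoff_is_strict(diet):
    # growth exactly at the cutoff is retained ("<" is strict)
    m = make_toy_bacterium("butyrate_producer")
    solo = fba(apply_diet(m, diet)).objective_value
    cfg = CouplingConfig(min_growth=solo)  # cutoff == growth
    kept = screen_members([CommunityMember(m, 1.0)], diet, cfg)
    assert len(kept) == 1 and kept[0].abundance == pytest.approx(1.0)


def test_screen_all_removed_raises():
    starving = Diet({})
    with pytest.raises(EmptyCommunityError):
        screen_members([_member("generalist", 1.0)], starving)


# ---------------------------------------------------------------------------
# assembly + coupling
# ---------------------------------------------------------------------------

def test_default_coupling_constants():
    cfg = CouplingConfig()
    assert cfg.c == 200.0
    assert cfg.u == 0.01
    assert cfg.min_growth == 1e-3


def test_single_member_community_reduces_to_solo_fba(diet):
    m = _member("butyrate_producer", 1.0)
    solo = fba(apply_diet(m.model, diet)).objective_value
    cm = assemble_community([m], diet)
    sol = simulate_community(cm)
    assert sol.objective_value == pytest.approx(solo, rel=1e-6)


def test_member_biomass_proportional_to_abundance(six_members, diet):
    cm = assemble_community(six_members, diet)
    sol = simulate_community(cm)
    assert sol.status == "optimal"
    for mem in cm.members:
        v_bio = sol.fluxes[cm.biomass_vars[mem.id]]
        assert v_bio == pytest.approx(mem.abundance * sol.objective_value, abs=1e-6)


def test_zero_biomass_member_fluxes_bounded_by_u(six_members, diet):
    cfg = CouplingConfig()
    cm = assemble_community(six_members, diet, cfg)
    # force one member's biomass to zero and maximise each of its fluxes
    victim = cm.members[0].id
    bio = cm.biomass_vars[victim]
    cm.lp.set_bounds(bio, 0.0, 0.0)
    # also silence the community biomass requirement for that member
    # by zeroing its abundance contribution is not possible post-hoc;
    # instead just check feasible flux ranges with biomass pinned at 0
    for (mid, rid), var in cm.member_vars.items():
        if mid != victim or var == bio:
            continue
        st, vmax, _ = cm.lp.solve({var: 1.0}, sense="max")
        st2, vmin, _ = cm.lp.solve({var: 1.0}, sense="min")
        if st == "optimal":
            assert vmax <= cfg.u + 1e-9
        if st2 == "optimal":
            assert vmin >= -cfg.u - 1e-9


def test_cross_feeding_pair_grows_only_together():
    """The propionate producer cannot grow alone on glucose, but grows
    in a community with the lactate-secreting glucose fermenter."""
    glc_only = Diet({"glc": 10.0, "nh4": 10.0})
    # abundances chosen so the fermenter's lactate output covers the
    # cross-feeder's demand (0.85/0.45*0.3 > 0.15/0.35)
    feeder = _member("butyrate_producer", 0.85)
    eater = _member("lactate_crossfeeder", 0.15)
    solo = fba(apply_diet(eater.model, glc_only))
    assert solo.objective_value == pytest.approx(0.0, abs=1e-9)
    cm = assemble_community([feeder, eater], glc_only)
    sol = simulate_community(cm)
    assert sol.status == "optimal"
    for mem in cm.members:
        assert sol.fluxes[cm.biomass_vars[mem.id]] > 1e-3


def test_all_zero_diet_gives_zero_growth(six_members):
    cm = assemble_community(six_members, Diet({}))
    sol = simulate_community(cm)
    assert sol.status != "optimal" or sol.objective_value == pytest.approx(0, abs=1e-9)


# ---------------------------------------------------------------------------
# exchange decomposition
# ---------------------------------------------------------------------------

def test_microbial_exchange_identity_on_fixed_vectors():
    # A secretes 6, B takes up 4, host receives 2:
    # sum|v_int| - |v_host| = 10 - 2 = 8 = 2 * min(6, 4)
    assert microbial_exchange_value({"A": 6.0, "B": -4.0}, 2.0) == pytest.approx(8.0)
    # only secretion to host: no cross-feeding
    assert microbial_exchange_value({"A": 5.0}, 5.0) == pytest.approx(0.0)
    # all zero
    assert microbial_exchange_value({}, 0.0) == pytest.approx(0.0)


def test_microbial_exchange_equals_twice_min_secretion_uptake(rng):
    for _ in range(200):
        v = rng.normal(0, 3, size=int(rng.integers(1, 6)))
        host = v.sum()  # steady state: host exchange = net of members
        P = v[v > 0].sum()
        C = -v[v < 0].sum()
        lhs = microbial_exchange_value({f"m{i}": x for i, x in enumerate(v)}, host)
        assert lhs == pytest.approx(2 * min(P, C), abs=1e-9)


def test_decomposition_conservation(six_members, diet):
    cm = assemble_community(six_members, diet)
    sol = simulate_community(cm)
    summ = decompose_exchanges(cm, sol)
    for met, host in summ.host_exchange.items():
        internal = sum(summ.member_exchange[met].values())
        assert internal == pytest.approx(host, abs=1e-6)
        assert summ.microbial_exchange[met] >= -1e-12


def test_taxon_aggregation_sums_to_host_exchange(six_members, diet):
    cm = assemble_community(six_members, diet)
    sol = simulate_community(cm)
    summ = decompose_exchanges(cm, sol)
    for met in ("but", "lac", "glc"):
        totals = aggregate_taxon_fluxes(cm, sol, met, "class")
        assert sum(totals.values()) == pytest.approx(
            summ.host_exchange[met], abs=1e-6
        )


def test_taxon_aggregation_unknown_rank_rejected(six_members, diet):
    cm = assemble_community(six_members, diet)
    sol = simulate_community(cm)
    with pytest.raises(ValueError, match="rank"):
        aggregate_taxon_fluxes(cm, sol, "but", "kingdom")


def test_member_without_rank_label_counted_as_other(diet):
    plain = CommunityMember(make_toy_bacterium("generalist"), 0.5, {})
    other = _member("butyrate_producer", 0.5)
    cm = assemble_community([other, plain], diet)
    sol = simulate_community(cm)
    totals = aggregate_taxon_fluxes(cm, sol, "lac", "class")
    assert "Other" in totals


def test_overall_flux_sums_shared_reaction_ids(six_members, diet):
    cm = assemble_community(six_members, diet)
    sol = simulate_community(cm)
    summ = decompose_exchanges(cm, sol)
    manual = sum(
        sol.fluxes[cm.member_vars[(mem.id, "CATABOLISM")]]
        for mem in cm.members
        if (mem.id, "CATABOLISM") in cm.member_vars
    )
    assert summ.overall_flux["CATABOLISM"] == pytest.approx(manual, abs=1e-9)


# ---------------------------------------------------------------------------
# random communities: the coupled-model invariants at scale
# ---------------------------------------------------------------------------

def test_invariants_on_random_communities(rng):
    diet = make_default_diet()
    templates = sorted(TEMPLATES)
    for _ in range(10):
        k = int(rng.integers(2, 6))
        chosen = list(rng.choice(templates, size=k, replace=False))
        raw = rng.dirichlet(np.ones(k))
        members = [
            CommunityMember(make_toy_bacterium(t, rng), float(a), taxonomy_of(t))
            for t, a in zip(chosen, raw)
        ]
        members = screen_members(members, diet)
        cm = assemble_community(members, diet)
        sol = simulate_community(cm)
        if sol.status != "optimal":
            continue
        for mem in cm.members:
            v_bio = sol.fluxes[cm.biomass_vars[mem.id]]
            assert v_bio == pytest.approx(
                mem.abundance * sol.objective_value, abs=1e-6
            )
        summ = decompose_exchanges(cm, sol)
        for met in summ.host_exchange:
            per = summ.member_exchange[met]
            assert sum(per.values()) == pytest.approx(
                summ.host_exchange[met], abs=1e-6
            )
            P = sum(v for v in per.values() if v > 0)
            C = -sum(v for v in per.values() if v < 0)
            assert summ.microbial_exchange[met] == pytest.approx(
                2 * min(P, C), abs=1e-6
            )
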