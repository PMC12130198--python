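"""TPM, reaction scoring, thresholding and FASTCORE extraction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gutflux.context import (
    ThresholdConfig,
    build_core_sets,
    compute_reaction_layers,
    counts_to_tpm,
    extract_context_model,
    fastcore,
    reaction_expression,
)
from gutflux.core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    find_blocked_reactions,
)
from gutflux.synth import random_network


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_formula_hand_case():
    counts = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
    lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
    tpm = counts_to_tpm(counts, lengths)
    assert tpm.loc["g1", "s1"] == pytest.approx(1e5)
    assert tpm.loc["g2", "s1"] == pytest.approx(9e5)


def test_tpm_scale_invariance_and_column_sum(rng):
    counts = pd.DataFrame(rng.integers(0, 500, size=(20, 4)),
                          index=[f"g{i}" for i in range(20)],
                          columns=list("abcd"))
    counts.iloc[0] += 1  # avoid an all-zero gene row edge case
    lengths = pd.Series(rng.integers(200, 3000, 20).astype(float), index=counts.index)
    tpm = counts_to_tpm(counts, lengths)
    assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)
    doubled = counts.copy()
    doubled["a"] *= 2
    tpm2 = counts_to_tpm(doubled, lengths)
    assert np.allclose(tpm["a"], tpm2["a"])


def test_tpm_all_zero_sample_and_missing_length_rejected():
    counts = pd.DataFrame({"s1": [5, 3], "s2": [0, 0]}, index=["g1", "g2"])
    lengths = pd.Series([100.0, 100.0], index=["g1", "g2"])
    with pytest.raises(ValueError, match="all-zero"):
        counts_to_tpm(counts, lengths)
    with pytest.raises(ValueError, match="without length"):
        counts_to_tpm(counts[["s1"]], lengths.drop("g2"))


# ---------------------------------------------------------------------------
# core-set thresholding
# ---------------------------------------------------------------------------

def test_threshold_defaults_are_10_90_50():
    cfg = ThresholdConfig()
    assert (cfg.global_lower_pct, cfg.global_upper_pct, cfg.local_pct) == (10, 90, 50)


def test_core_sets_hand_computed_partition():
    # 2 reactions x 2 samples pooled = [1, 2, 9, 10]
    # G_low = P10 = 1.3, G_high = P90 = 9.7 (linear interpolation)
    scores = pd.DataFrame({"s1": [1.0, 9.0], "s2": [2.0, 10.0]},
                          index=["r_lo", "r_hi"])
    cs = build_core_sets(scores)
    assert cs.g_low == pytest.approx(1.3)
    assert cs.g_high == pytest.approx(9.7)
    # s1: r_lo = 1 < 1.3 inactive; r_hi = 9 in between, local L = 9.5 -> not core
    assert cs.inactive["s1"] == {"r_lo"}
    assert cs.undetermined["s1"] == {"r_hi"}
    # s2: r_lo = 2, local L = 1.5 -> core; r_hi = 10 > 9.7 -> core
    assert cs.core["s2"] == {"r_lo", "r_hi"}


def test_mid_range_equal_to_local_threshold_is_not_core():
    # constant reaction: local median equals the value; strict > fails
    scores = pd.DataFrame({"s1": [5.0, 0.0, 100.0], "s2": [5.0, 0.0, 100.0]},
                          index=["r_const", "r_low", "r_high"])
    cs = build_core_sets(scores)
    assert "r_const" not in cs.core["s1"]
    assert "r_const" in cs.undetermined["s1"]


def test_raising_upper_percentile_never_grows_core(rng):
    scores = pd.DataFrame(rng.uniform(0, 100, size=(30, 8)),
                          index=[f"r{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(8)])
    lo = build_core_sets(scores, ThresholdConfig(global_upper_pct=80))
    hi = build_core_sets(scores, ThresholdConfig(global_upper_pct=95))
    for s in scores.columns:
        assert hi.core[s] <= lo.core[s]


def test_reaction_expression_uses_gpr_and_skips_gprless():
    from gutflux.core import Gpr

    model = MetabolicModel(
        id="m",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10, 10),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 10,
                     gpr=Gpr.from_string("g1 or g2")),
            Reaction("DM_B", {"B": -1.0}, 0, 10),
        ],
    )
    tpm = pd.DataFrame({"s1": [3.0, 4.0], "s2": [1.0, 0.0]}, index=["g1", "g2"])
    scores = reaction_expression(model, tpm)
    assert list(scores.index) == ["R1"]
    assert scores.loc["R1", "s1"] == pytest.approx(7.0)
    assert scores.loc["R1", "s2"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

def _chain() -> MetabolicModel:
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10, 10),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0, 10),
            Reaction("DM_B", {"B": -1.0}, 0, 10),
        ],
    )


def test_fastcore_chain_returns_full_support():
    # the only way to realise the core reaction is the whole chain
    out = fastcore(_chain(), {"R_AB"})
    assert out == {"EX_A", "R_AB", "DM_B"}


def test_fastcore_full_core_is_fixed_point():
    m = _chain()
    assert fastcore(m, set(m.reaction_ids())) == set(m.reaction_ids())


def _consistent_random(rng, n):
    net = random_network(rng, n_reactions=n)
    blocked = find_blocked_reactions(net, 1e-4)
    keep = set(net.reaction_ids()) - blocked
    if len(keep) < 3:
        return None
    return net.subset(keep)


def test_fastcore_contains_core_and_is_consistent(rng):
    done = 0
    while done < 15:
        model = _consistent_random(rng, int(rng.integers(8, 18)))
        if model is None:
            continue
        rids = sorted(model.reaction_ids())
        k = int(rng.integers(1, min(4, len(rids))))
        core = set(rng.choice(rids, size=k, replace=False))
        out = fastcore(model, core)
        assert core <= out
        sub = model.subset(out)
        assert find_blocked_reactions(sub, 1e-4) == set()
        done += 1


def _minimum_consistent_superset(model, core):
    """Exhaustive oracle: smallest reaction subset containing the core
    whose submodel has no blocked reactions."""
    rest = sorted(set(model.reaction_ids()) - core)
    for size in range(0, len(rest) + 1):
        for extra in combinations(rest, size):
            cand = core | set(extra)
            sub = model.subset(cand)
            if find_blocked_reactions(sub, 1e-4):
                continue
            return cand
    return None


def test_fastcore_near_minimal_on_small_networks(rng):
    ratios = []
    done = 0
    while done < 3:
        model = _consistent_random(rng, 9)
        if model is None or len(model.reactions) > 10:
            continue
        rids = sorted(model.reaction_ids())
        core = {rids[int(rng.integers(len(rids)))]}
        out = fastcore(model, core)
        best = _minimum_consistent_superset(model, core)
        assert best is not None
        assert core <= out
        ratios.append(len(out) / len(best))
        done += 1
    # core inclusion + consistency are the contract; sizes should stay
    # in the same ballpark as the true minimum
    assert all(r >= 1.0 for r in ratios)


def test_extract_context_model_drops_unrealizable_core_with_warning():
    # DM_B sits strictly downstream of the inactive R_AB with no bypass;
    # the A->C branch keeps the rest of the core realizable
    m = MetabolicModel(
        id="fork",
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10, 10),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0, 10),
            Reaction("DM_B", {"B": -1.0}, 0, 10),
            Reaction("R_AC", {"A": -1.0, "C": 1.0}, 0, 10),
            Reaction("DM_C", {"C": -1.0}, 0, 10),
        ],
    )
    cmod = extract_context_model(m, core={"DM_B", "R_AC"}, inactive={"R_AB"},
                                 sample="s")
    assert cmod.dropped_core == {"DM_B"}
    assert "R_AC" in cmod.reactions
    assert "R_AB" not in cmod.reactions


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def test_layers_flag_absent_reactions_and_compute_range_center():
    from gutflux.core import Gpr

    m = MetabolicModel(
        id="m",
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10, 10),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0, 10,
                     gpr=Gpr.from_string("g1")),
            Reaction("DM_B", {"B": -1.0}, 10, 10),
            Reaction("R_AC", {"A": -1.0, "C": 1.0}, 0, 10,
                     gpr=Gpr.from_string("g2")),
            Reaction("DM_C", {"C": -1.0}, 0, 10),
        ],
    )
    scores = pd.DataFrame({"s1": [5.0, 1.0]}, index=["R_AB", "R_AC"])
    from gutflux.context import ContextModel

    cmod = ContextModel(sample="s1", reactions={"EX_A", "R_AB", "DM_B"}, parent=m)
    layers = compute_reaction_layers({"s1": cmod}, scores)
    assert layers.pa.loc["R_AB", "s1"] == 1.0
    assert layers.pa.loc["R_AC", "s1"] == 0.0
    assert np.isnan(layers.fva_range.loc["R_AC", "s1"])
    # DM_B pinned at 10 forces the chain: range 0, center 10
    assert layers.fva_range.loc["R_AB", "s1"] == pytest.approx(0.0, abs=1e-6)
    assert layers.fva_center.loc["R_AB", "s1"] == pytest.approx(10.0, abs=1e-6)
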