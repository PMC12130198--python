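"""Metadata preparation, preprocessing, mixed models, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gutflux.stats import (
    LayerAssociation,
    PreprocessConfig,
    adjust_bh,
    enrich_gsea,
    enrich_hypergeometric,
    permutation_overlap_test,
    prepare_metadata,
    preprocess_features,
    test_taxon_contribution as taxon_contribution,
)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _md(rows):
    return pd.DataFrame(rows, columns=["sample", "patient", "time",
                                       "disease_score"])


def test_score_censored_at_16():
    md = prepare_metadata(_md([("s1", "p1", 0.0, 20.0), ("s2", "p1", 2.0, 12.0)]))
    assert md["disease_score"].max() == 16.0


def test_missing_score_imputed_from_patient_line():
    md = prepare_metadata(_md([
        ("s1", "p1", 0.0, 8.0), ("s2", "p1", 7.0, np.nan), ("s3", "p1", 14.0, 4.0),
    ]))
    assert md.loc[md["sample"] == "s2", "disease_score"].item() == pytest.approx(6.0)
    assert md.loc[md["sample"] == "s2", "score_imputed"].item()


def test_single_observation_carried_constant():
    md = prepare_metadata(_md([
        ("s1", "p1", 0.0, 5.0), ("s2", "p1", 7.0, np.nan),
    ]))
    assert md.loc[md["sample"] == "s2", "disease_score"].item() == pytest.approx(5.0)


def test_patient_without_scores_excluded():
    md = prepare_metadata(_md([
        ("s1", "p1", 0.0, 5.0), ("s2", "p2", 0.0, np.nan),
    ]))
    assert set(md["patient"]) == {"p1"}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_near_zero_variance_feature_dropped(rng):
    n = 100
    feats = pd.DataFrame(
        {f"s{i}": [0.0, rng.normal()] for i in range(n)},
        index=["flat", "noisy"],
    )
    feats.loc["flat", "s0"] = 1.0  # 99% identical values
    res = preprocess_features(feats)
    assert "flat" in res.dropped_nzv
    assert "noisy" not in res.dropped_nzv


def test_collinear_triplet_forms_one_cluster(rng):
    base = rng.normal(size=30)
    feats = pd.DataFrame(
        [base, 2 * base + 1, -3 * base] + [rng.normal(size=30) for _ in range(5)],
        index=["a", "b", "c"] + [f"n{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(30)],
    )
    res = preprocess_features(feats)
    reps = {res.representative[f] for f in ("a", "b", "c")}
    assert len(reps) == 1  # rho = +-1 -> d = 0 -> one DBSCAN cluster
    assert len({res.representative[f] for f in feats.index}) >= 5


def test_anticorrelated_cluster_member_inherits_flipped_estimate(rng):
    """Clusters form on |rho|; a member with rho = -1 to the medoid must
    inherit the medoid's result with the estimate sign flipped."""
    base = rng.normal(size=40)
    feats = pd.DataFrame(
        [base, base * 1.5, -base] + [rng.normal(size=40) for _ in range(4)],
        index=["a", "b", "anti"] + [f"n{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(40)],
    )
    res = preprocess_features(feats)
    rep = res.representative["anti"]
    assert res.representative["a"] == rep
    assert res.rep_sign["anti"] == -res.rep_sign["a"] or res.rep_sign["anti"] == -1
    table = pd.DataFrame(
        {"estimate": [2.0], "conf_low": [1.0], "conf_high": [3.0],
         "t_value": [4.0], "p": [0.001], "p_adj": [0.004]},
        index=[rep],
    )
    full = res.expand(table)
    sign = res.rep_sign["anti"]
    assert full.loc["anti", "estimate"] == pytest.approx(sign * 2.0)
    if sign < 0:
        assert full.loc["anti", "conf_low"] == pytest.approx(-3.0)
        assert full.loc["anti", "conf_high"] == pytest.approx(-1.0)
    assert full.loc["anti", "p"] == pytest.approx(0.001)


def test_scaled_features_have_zero_mean_unit_sd(rng):
    feats = pd.DataFrame(rng.normal(2, 5, size=(4, 40)),
                         index=list("abcd"),
                         columns=[f"s{i}" for i in range(40)])
    res = preprocess_features(feats)
    assert np.allclose(res.features.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(res.features.std(axis=1, ddof=1), 1, atol=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_closed_form_hand_case():
    out = adjust_bh([0.01, 0.02, 0.04])
    assert out == pytest.approx([0.03, 0.03, 0.04])


def test_bh_single_and_equal_p_unchanged():
    assert adjust_bh([0.2]) == pytest.approx([0.2])
    assert adjust_bh([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])


def test_bh_nan_passthrough_and_monotonicity(rng):
    p = np.array([0.01, np.nan, 0.5, 0.001])
    out = adjust_bh(p)
    assert np.isnan(out[1])
    assert np.all(out[~np.isnan(out)] >= p[~np.isnan(p)])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
@settings(deadline=None, derandomize=True)
def test_bh_properties_hold_for_arbitrary_p_vectors(p):
    out = adjust_bh(p)
    assert np.all(out >= np.asarray(p) - 1e-12)   # never below raw p
    assert np.all(out <= 1.0 + 1e-12)             # capped at 1
    # monotone in the order statistics
    order = np.argsort(p)
    assert np.all(np.diff(out[order]) >= -1e-12)


@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=8))
@settings(deadline=None, derandomize=True)
def test_microbial_exchange_identity_algebraic(v):
    from gutflux.community import microbial_exchange_value

    host = float(np.sum(v))  # steady state
    P = float(np.sum([x for x in v if x > 0]))
    C = float(-np.sum([x for x in v if x < 0]))
    got = microbial_exchange_value({f"m{i}": x for i, x in enumerate(v)}, host)
    assert got == pytest.approx(2 * min(P, C), abs=1e-9)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _cohort_frame(rng, n_pat=30, n_time=4, beta=0.0, sd_pat=1.0, sd_e=0.5):
    """score = beta * feature + patient intercept + noise."""
    rows = []
    for p in range(n_pat):
        u = rng.normal(0, sd_pat)
        for t in range(n_time):
            x = rng.normal()
            y = beta * x + u + rng.normal(0, sd_e) + 8.0
            rows.append((f"p{p}_t{t}", f"p{p}", float(t), x, y))
    df = pd.DataFrame(rows, columns=["sample", "patient", "time", "x", "score"])
    feats = pd.DataFrame([df["x"].to_numpy()], index=["x"],
                         columns=df["sample"])
    md = df.set_index("sample")[["patient", "time", "score"]].rename(
        columns={"score": "disease_score"})
    return feats, md


def test_planted_fixed_effect_recovered(rng):
    ests, cover = [], 0
    n_rep = 40
    for _ in range(n_rep):
        feats, md = _cohort_frame(rng, beta=0.8)
        res = LayerAssociation(feats, md).fit()
        row = res.table.loc["x"]
        ests.append(row["estimate"])
        cover += row["conf_low"] <= 0.8 <= row["conf_high"]
    assert abs(np.mean(ests) - 0.8) < 0.05
    assert cover / n_rep >= 0.9


def test_feature_identical_to_score_is_detected(rng):
    feats, md = _cohort_frame(rng, beta=0.0)
    feats.loc["x"] = md["disease_score"].to_numpy()
    res = LayerAssociation(feats, md).fit()
    assert res.table.loc["x", "p"] < 1e-10
    assert res.table.loc["x", "estimate"] == pytest.approx(1.0, abs=1e-6)


def test_null_rejection_rate_near_alpha(rng):
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        feats, md = _cohort_frame(rng, beta=0.0)
        res = LayerAssociation(feats, md).fit()
        rejections += res.table.loc["x", "p"] < 0.05
    assert 0.02 <= rejections / n_rep <= 0.09


def test_outcome_model_recovers_planted_log_odds_direction(rng):
    # patient-level outcome driven by a patient-level feature
    rows = []
    for p in range(40):
        x = rng.normal()
        prob = 1 / (1 + np.exp(-(1.5 * x)))
        y = "yes" if rng.random() < prob else "no"
        for t in range(3):
            rows.append((f"p{p}_t{t}", f"p{p}", float(t), x + rng.normal(0, 0.1),
                         8.0, y, y))
    df = pd.DataFrame(rows, columns=["sample", "patient", "time", "x",
                                     "disease_score", "response", "remission"])
    md = df.set_index("sample").drop(columns="x")
    feats = pd.DataFrame([df["x"].to_numpy()], index=["x"], columns=df["sample"])
    res = LayerAssociation(feats, md, outcome="response").fit()
    row = res.table.loc["x"]
    assert row["estimate"] > 0
    assert row["p"] < 0.05


def test_remission_excludes_week14_samples(rng):
    rows = []
    for p in range(12):
        for t in (0.0, 2.0, 14.0):
            rows.append((f"p{p}_t{int(t)}", f"p{p}", t, rng.normal(), 5.0,
                         "yes", "yes" if p % 2 else "no"))
    df = pd.DataFrame(rows, columns=["sample", "patient", "time", "x",
                                     "disease_score", "response", "remission"])
    md = df.set_index("sample")
    feats = pd.DataFrame([df["x"].to_numpy()], index=["x"], columns=df["sample"])
    res = LayerAssociation(feats, md, outcome="remission").fit()
    assert res.table.loc["x", "n_samples"] == 24  # 12 patients x 2 timepoints


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_closed_form():
    # universe 10, set 5, query 4, overlap 4: p = C(5,4)/C(10,4) = 5/210
    uni = {f"x{i}" for i in range(10)}
    s = {f"x{i}" for i in range(5)}
    q = {f"x{i}" for i in range(4)}
    df = enrich_hypergeometric(q, {"s": s}, uni)
    assert df.loc["s", "p"] == pytest.approx(5 / 210)


def test_query_equal_universe_gives_p_one():
    uni = {f"x{i}" for i in range(8)}
    df = enrich_hypergeometric(uni, {"a": set(list(uni)[:3])}, uni)
    assert df.loc["a", "p"] == pytest.approx(1.0)


def test_hypergeometric_matches_enumeration(rng):
    """Exhaustive oracle on universes <= 12: enumerate all draws."""
    from itertools import combinations

    for _ in range(5):
        M = int(rng.integers(6, 13))
        uni = [f"u{i}" for i in range(M)]
        set_sz = int(rng.integers(2, M))
        q_sz = int(rng.integers(1, M))
        s = set(rng.choice(uni, size=set_sz, replace=False))
        q = set(rng.choice(uni, size=q_sz, replace=False))
        k = len(s & q)
        total = hits = 0
        for draw in combinations(uni, q_sz):
            total += 1
            hits += len(set(draw) & s) >= k
        df = enrich_hypergeometric(q, {"s": s}, set(uni))
        assert df.loc["s", "p"] == pytest.approx(hits / total, abs=1e-12)


def test_gsea_top_ranked_set_scores_positive(rng):
    effects = pd.Series(np.linspace(3, -3, 50), index=[f"f{i}" for i in range(50)])
    top = {f"f{i}" for i in range(8)}
    df = enrich_gsea(effects, {"top": top}, n_perm=500, seed=1)
    assert df.loc["top", "ES"] > 0
    assert df.loc["top", "p"] <= 0.05


def test_gsea_deterministic_under_seed(rng):
    effects = pd.Series(rng.normal(size=40), index=[f"f{i}" for i in range(40)])
    sets = {"a": {f"f{i}" for i in range(5)}}
    a = enrich_gsea(effects, sets, n_perm=200, seed=7)
    b = enrich_gsea(effects, sets, n_perm=200, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_substrate_product_direction_tabulation():
    from gutflux.core import MetabolicModel, Metabolite, Reaction
    from gutflux.stats import substrate_product_direction_table

    m = MetabolicModel(
        id="m",
        metabolites=[Metabolite(x) for x in "ABC"],
        reactions=[
            Reaction("R_up", {"A": -1.0, "B": 1.0}, 0, 10),     # A substrate
            Reaction("R_down", {"B": -1.0, "A": 1.0}, 0, 10),   # A product
            Reaction("R_rev", {"A": -1.0, "C": 1.0}, -10, 10),  # A both
        ],
    )
    tab = substrate_product_direction_table(
        m, up_reactions={"R_up", "R_rev"}, down_reactions={"R_down"},
        metabolites=["A"],
    )
    counts = tab.set_index(["role", "direction"])["count"]
    assert counts[("substrate", "up")] == 1
    assert counts[("product", "down")] == 1
    assert counts[("both", "up")] == 1


# ---------------------------------------------------------------------------
# permutation overlap
# ---------------------------------------------------------------------------

def test_overlap_maximal_but_forced_gives_p_one():
    uni = {f"x{i}" for i in range(6)}
    assert permutation_overlap_test(uni, uni, uni, uni, n_perm=100, seed=0) == 1.0


def test_planted_overlap_significant():
    uni_a = {f"a{i}" for i in range(100)} | {f"c{i}" for i in range(10)}
    uni_b = {f"b{i}" for i in range(100)} | {f"c{i}" for i in range(10)}
    hits_a = {f"c{i}" for i in range(10)} | {f"a{i}" for i in range(10)}
    hits_b = {f"c{i}" for i in range(10)} | {f"b{i}" for i in range(10)}
    p = permutation_overlap_test(hits_a, hits_b, uni_a, uni_b,
                                 n_perm=2000, seed=0)
    assert p < 0.01


# ---------------------------------------------------------------------------
# taxon contribution
# ---------------------------------------------------------------------------

def _taxon_frame(rng, producer_mean=5.0, n_samples=30):
    rows = []
    for i in range(n_samples):
        pat = f"p{i % 10}"
        rows.append((f"s{i}", pat, "Clostridia", producer_mean + rng.normal(0, 1)))
        rows.append((f"s{i}", pat, "Bacteroidia", rng.normal(0, 1)))
        if i < 4:  # rare taxon in only 4 samples -> must be pooled
            rows.append((f"s{i}", pat, "Rare", rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["sample", "patient", "taxon", "flux"])


def test_rare_taxon_grouped_to_other(rng):
    res = taxon_contribution(_taxon_frame(rng))
    assert "Rare" not in res.index
    assert "Other" in res.index


def test_planted_producer_detected_nulls_controlled(rng):
    res = taxon_contribution(_taxon_frame(rng))
    assert res.loc["Clostridia", "p_adj"] < 0.05
    assert res.loc["Clostridia", "estimate"] == pytest.approx(5.0, abs=0.7)
    assert res.loc["Bacteroidia", "p_adj"] > 0.05


def test_all_zero_fluxes_nothing_significant(rng):
    df = _taxon_frame(rng)
    df["flux"] = 0.0
    res = taxon_contribution(df)
    assert not (res["p_adj"] < 0.05).any()
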