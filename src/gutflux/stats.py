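"""Longitudinal association statistics for arbitrary feature layers.

Any feature x sample matrix (microbial exchange fluxes, host reaction
layers, metabolite concentrations) is tested against disease activity
with per-feature linear mixed models

    disease_score ~ feature + covariates + (1 | patient)

fitted by REML; the feature coefficient, its Wald statistic and a
normal-approximation p-value are reported and Benjamini-Hochberg
adjusted across the layer.  Features are z-scaled beforehand so
coefficients are comparable across features; estimates above zero mean
higher activity with higher inflammation.

Therapy outcome (response / remission) uses logistic mixed models
(variational Bayes fit) with an optional disease-activity control.

The module also carries the shared machinery: metadata preparation
(HBI censoring at 16, per-patient linear imputation of missing
scores), near-zero-variance filtering + correlation-distance DBSCAN
clustering, BH adjustment, hypergeometric and GSEA enrichment, the
permutation overlap test, and the per-taxon contribution models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import DBSCAN
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PreprocessConfig",
    "prepare_metadata",
    "preprocess_features",
    "LayerAssociation",
    "AssociationResult",
    "associate_disease_activity",
    "associate_outcome",
    "adjust_bh",
    "enrich_hypergeometric",
    "enrich_gsea",
    "permutation_overlap_test",
    "test_taxon_contribution",
    "metabolite_reaction_sets",
    "substrate_product_direction_table",
]

log = logging.getLogger(__name__)

HBI_CAP = 16.0


# ---------------------------------------------------------------------------
# Metadata preparation
# ---------------------------------------------------------------------------

def prepare_metadata(
    raw: pd.DataFrame,
    score_col: str = "disease_score",
    patient_col: str = "patient",
    time_col: str = "time",
    cap: float = HBI_CAP,
) -> pd.DataFrame:
    """Censor disease scores at ``cap`` and impute missing scores from
    each patient's score ~ time least-squares line (a single observed
    score is carried as a constant).  Patients without any observed
    score are excluded with a warning.  Adds a boolean
    ``score_imputed`` column."""
    md = raw.copy()
    md[score_col] = md[score_col].clip(upper=cap)
    md["score_imputed"] = md[score_col].isna()
    keep_patients = []
    for pat, grp in md.groupby(patient_col, sort=False):
        obs = grp.dropna(subset=[score_col])
        if obs.empty:
            log.warning("patient %s has no observed %s; excluded", pat, score_col)
            continue
        keep_patients.append(pat)
        miss = grp.index[grp[score_col].isna()]
        if len(miss) == 0:
            continue
        t = obs[time_col].to_numpy(dtype=float)
        y = obs[score_col].to_numpy(dtype=float)
        if len(obs) == 1 or np.ptp(t) == 0:
            pred = np.full(len(miss), y.mean())
        else:
            slope, intercept = np.polyfit(t, y, 1)
            pred = intercept + slope * md.loc[miss, time_col].to_numpy(dtype=float)
        md.loc[miss, score_col] = np.clip(pred, 0.0, cap)
    md = md[md[patient_col].isin(keep_patients)].copy()
    return md


# ---------------------------------------------------------------------------
# Feature preprocessing: NZV filter, scaling, correlation clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    freq_ratio_cutoff: float = 95.0 / 5.0
    unique_pct_cutoff: float = 10.0
    dbscan_eps: float = 0.1
    dbscan_min_pts: int = 3

    def __post_init__(self) -> None:
        if self.dbscan_eps <= 0 or self.dbscan_min_pts < 2:
            raise ValueError("eps > 0 and min_pts >= 2 required")


def _near_zero_variance(row: np.ndarray, cfg: PreprocessConfig) -> bool:
    vals, counts = np.unique(row, return_counts=True)
    if len(vals) == 1:
        return True
    counts = np.sort(counts)[::-1]
    freq_ratio = counts[0] / counts[1]
    unique_pct = 100.0 * len(vals) / len(row)
    return freq_ratio > cfg.freq_ratio_cutoff and unique_pct < cfg.unique_pct_cutoff


@dataclass
class PreprocessResult:
    features: pd.DataFrame           # scaled, representatives + singletons
    dropped_nzv: list[str]
    clusters: dict[int, list[str]]   # cluster label -> member features
    representative: dict[str, str]   # feature -> its cluster representative
    rep_sign: dict[str, int] = None  # feature -> sign of rho(feature, rep)

    def expand(self, table: pd.DataFrame) -> pd.DataFrame:
        """Propagate per-representative test results to all cluster
        members.  Clusters form on |rho|, so an anti-correlated member
        inherits the representative's result with the estimate (and CI
        and t) sign-flipped by its correlation sign with the medoid."""
        out = table.reindex(sorted(self.representative))
        for feat, rep in self.representative.items():
            if feat == rep or rep not in table.index:
                continue
            row = table.loc[rep].copy()
            sign = (self.rep_sign or {}).get(feat, 1)
            if sign < 0:
                for col in ("estimate", "t_value"):
                    if col in row:
                        row[col] = -row[col]
                if "conf_low" in row and "conf_high" in row:
                    row["conf_low"], row["conf_high"] = (
                        -row["conf_high"], -row["conf_low"])
            out.loc[feat] = row
        return out


def preprocess_features(
    features: pd.DataFrame, cfg: PreprocessConfig = PreprocessConfig()
) -> PreprocessResult:
    """Drop near-zero-variance features (frequency-ratio AND
    unique-percent rule), z-scale the rest, and cluster highly
    correlated features with DBSCAN on d = 1 - sqrt(rho^2).

    Each cluster is represented by its medoid (largest mean |rho| to
    the other members); cluster members map to that representative so
    downstream tests run once per cluster and members inherit the
    result."""
    if features.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = features.to_numpy(dtype=float)
    nzv = [
        f for f, row in zip(features.index, X) if _near_zero_variance(row, cfg)
    ]
    kept = features.drop(index=nzv)
    scaled = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=1), axis=0)
    if scaled.empty:
        return PreprocessResult(scaled, nzv, {}, {}, {})
    rho = np.corrcoef(scaled.to_numpy())
    rho = np.nan_to_num(np.atleast_2d(rho))
    dist = 1.0 - np.sqrt(rho**2)
    np.fill_diagonal(dist, 0.0)
    labels = DBSCAN(
        eps=cfg.dbscan_eps, min_samples=cfg.dbscan_min_pts, metric="precomputed"
    ).fit_predict(dist)
    clusters: dict[int, list[str]] = {}
    representative: dict[str, str] = {}
    rep_sign: dict[str, int] = {}
    names = list(scaled.index)
    for lab in sorted(set(labels)):
        members = [names[i] for i in range(len(names)) if labels[i] == lab]
        if lab == -1:
            for m in members:
                representative[m] = m
                rep_sign[m] = 1
            continue
        idx = [names.index(m) for m in members]
        mean_abs_rho = np.abs(rho[np.ix_(idx, idx)]).mean(axis=1)
        medoid = members[int(np.argmax(mean_abs_rho))]
        mi = names.index(medoid)
        clusters[lab] = members
        for m, i in zip(members, idx):
            representative[m] = medoid
            rep_sign[m] = 1 if rho[i, mi] >= 0 else -1
    reps = sorted(set(representative.values()))
    return PreprocessResult(scaled.loc[reps], nzv, clusters, representative,
                            rep_sign)


# ---------------------------------------------------------------------------
# Mixed-model association (statsmodels-style Model -> Results)
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "estimate", "std_error", "conf_low", "conf_high",
    "t_value", "df", "p", "p_adj", "n_samples", "model",
]


@dataclass
class AssociationResult:
    """Per-feature association estimates with BH-adjusted p-values."""

    table: pd.DataFrame
    layer: str = ""
    outcome: str = "activity"

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]

    def summary(self) -> str:
        t = self.table
        n_sig = int((t["p_adj"] < 0.05).sum())
        lines = [
            f"Association layer: {self.layer or '(unnamed)'}  outcome: {self.outcome}",
            f"features tested: {len(t)}   significant (BH < 0.05): {n_sig}",
            "",
            t.sort_values("p").head(10).to_string(float_format="%.4g"),
        ]
        return "\n".join(lines)


class LayerAssociation:
    """Longitudinal mixed-model association of one feature layer.

    Parameters
    ----------
    features : DataFrame, features x samples (already preprocessed/scaled)
    metadata : DataFrame indexed by sample with at least ``patient`` and
        ``disease_score`` columns; ``response`` / ``remission`` for
        outcome models.
    covariates : extra fixed-effect columns from the metadata.
    outcome : "activity" (linear: score ~ feature), "response" or
        "remission" (logistic: outcome ~ feature [+ score]).
    control_disease_activity : include disease_score as a covariate in
        outcome models.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        metadata: pd.DataFrame,
        covariates: tuple[str, ...] = (),
        outcome: str = "activity",
        control_disease_activity: bool = False,
        remission_week: float = 14.0,
    ):
        if outcome not in ("activity", "response", "remission"):
            raise ValueError(f"unknown outcome {outcome!r}")
        missing = [s for s in features.columns if s not in metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        self.features = features
        self.metadata = metadata.loc[list(features.columns)]
        self.covariates = tuple(covariates)
        self.outcome = outcome
        self.control_disease_activity = control_disease_activity
        self.remission_week = remission_week

    def fit(self, layer: str = "") -> AssociationResult:
        if self.outcome == "activity":
            table = self._fit_activity()
        else:
            table = self._fit_outcome()
        table["p_adj"] = adjust_bh(table["p"].to_numpy())
        return AssociationResult(table=table, layer=layer, outcome=self.outcome)

    # -- linear mixed model: score ~ feature + covars + (1|patient) --
    def _fit_activity(self) -> pd.DataFrame:
        md = self.metadata
        rows = {}
        for feat, values in self.features.iterrows():
            df = pd.DataFrame({
                "score": md["disease_score"].to_numpy(dtype=float),
                "feature": values.to_numpy(dtype=float),
                "patient": md["patient"].to_numpy(),
            })
            for c in self.covariates:
                df[c] = md[c].to_numpy()
            df = df.dropna()
            rows[feat] = _fit_lmm_row(df, self.covariates)
        out = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["estimate", "std_error", "conf_low", "conf_high",
                     "t_value", "df", "p", "n_samples"],
        )
        out["model"] = "score ~ feature + (1|patient)"
        out.index.name = "feature"
        return out

    # -- logistic mixed model: outcome ~ feature [+ score] + (1|pat) --
    def _fit_outcome(self) -> pd.DataFrame:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        md = self.metadata.copy()
        if self.outcome == "remission" and "time" in md.columns:
            # the remission-defining week is excluded from testing
            md = md[md["time"] != self.remission_week]
        y_raw = md[self.outcome]
        ok = y_raw.notna() & y_raw.astype(str).isin(["yes", "no", "True", "False", "0", "1"])
        md = md[ok]
        y = y_raw[ok].astype(str).isin(["yes", "True", "1"]).astype(float)
        rows = {}
        desc = f"{self.outcome} ~ feature"
        if self.control_disease_activity:
            desc += " + disease_score"
        desc += " + (1|patient)"
        for feat, values in self.features.iterrows():
            df = pd.DataFrame({
                "y": y.to_numpy(),
                "feature": values.reindex(md.index).to_numpy(dtype=float),
                "patient": md["patient"].to_numpy(),
            })
            if self.control_disease_activity:
                df["score"] = md["disease_score"].to_numpy(dtype=float)
            df = df.dropna()
            n = len(df)
            try:
                exog = pd.DataFrame({"Intercept": 1.0, "feature": df["feature"]})
                if self.control_disease_activity:
                    exog["score"] = df["score"]
                vc = pd.get_dummies(df["patient"]).to_numpy(dtype=float)
                model = BinomialBayesMixedGLM(
                    df["y"].to_numpy(), exog.to_numpy(), vc,
                    ident=np.zeros(vc.shape[1], dtype=int),
                    vcp_p=2.0, fe_p=2.0,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model.fit_vb()
                i = 1  # feature column
                est = fit.fe_mean[i]
                se = fit.fe_sd[i]
                z = est / se if se > 0 else np.nan
                p = 2 * sps.norm.sf(abs(z))
                ci = sps.norm.ppf(0.975) * se
                rows[feat] = (est, se, est - ci, est + ci, z, np.nan, p, n)
            except Exception as exc:  # separation / singular designs
                log.warning("outcome fit failed for %s: %s", feat, exc)
                rows[feat] = (np.nan,) * 7 + (n,)
        out = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["estimate", "std_error", "conf_low", "conf_high",
                     "t_value", "df", "p", "n_samples"],
        )
        out["model"] = desc
        out.index.name = "feature"
        return out


def _fit_any(model: MixedLM, reml: bool = False):
    """ML/REML fit with optimizer fallback for singular Hessians."""
    last: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            return model.fit(reml=reml, method=method)
        except np.linalg.LinAlgError as exc:
            last = exc
    raise last  # type: ignore[misc]


def _fit_lmm_row(df: pd.DataFrame, covariates: tuple[str, ...]) -> tuple:
    """One REML mixed-model fit; NA-safe on singular fits."""
    n = len(df)
    if n < 4 or df["feature"].std(ddof=0) == 0 or df["patient"].nunique() < 2:
        return (np.nan,) * 7 + (n,)
    exog = pd.DataFrame({"Intercept": np.ones(n), "feature": df["feature"]})
    for c in covariates:
        col = df[c]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            exog = pd.concat([exog, dummies], axis=1)
        else:
            exog[c] = col.to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(df["score"].to_numpy(), exog.to_numpy(),
                            groups=df["patient"].to_numpy())
            fit = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    fit = model.fit(reml=True, method=method)
                    break
                except np.linalg.LinAlgError:
                    continue
            if fit is None:
                return (np.nan,) * 7 + (n,)
        i = 1
        est = float(fit.fe_params[i])
        se = float(fit.bse_fe[i])
        if not np.isfinite(se) or se <= 0:
            return (np.nan,) * 7 + (n,)
        t = est / se
        # normal approximation for the reference distribution; residual
        # df reported for orientation
        dof = float(n - exog.shape[1] - 1)
        p = 2 * sps.norm.sf(abs(t))
        ci = sps.norm.ppf(0.975) * se
        return (est, se, est - ci, est + ci, t, dof, p, n)
    except Exception as exc:
        log.debug("LMM fit failed: %s", exc)
        return (np.nan,) * 7 + (n,)


def associate_disease_activity(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    layer: str = "",
) -> AssociationResult:
    """Convenience wrapper: LayerAssociation(...).fit() for activity."""
    return LayerAssociation(features, metadata, covariates, "activity").fit(layer)


def associate_outcome(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    outcome: str,
    control_disease_activity: bool = True,
    layer: str = "",
) -> AssociationResult:
    return LayerAssociation(
        features, metadata, (), outcome, control_disease_activity
    ).fit(layer)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def adjust_bh(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through and do
    not enter the denominator."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    if (p[mask] < 0).any() or (p[mask] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    name: str
    overlap: int
    set_size: int
    universe: int
    p: float
    es: float = np.nan
    nes: float = np.nan
    n_up: int = 0
    n_down: int = 0


def enrich_hypergeometric(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
    directions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each set.

    ``directions`` optionally maps query members to +1/-1 to tabulate
    up/down counts per set."""
    query = set(query) & set(universe)
    rows = []
    M = len(universe)
    for name, s in sorted(sets.items()):
        s = set(s) & set(universe)
        if not s:
            log.info("enrich: set %s empty in universe; skipped", name)
            continue
        k = len(query & s)
        p = float(sps.hypergeom.sf(k - 1, M, len(s), len(query)))
        n_up = n_down = 0
        if directions:
            n_up = sum(1 for m in query & s if directions.get(m, 0) > 0)
            n_down = sum(1 for m in query & s if directions.get(m, 0) < 0)
        rows.append((name, k, len(s), M, p, n_up, n_down))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "universe", "p", "n_up", "n_down"]
    ).set_index("set")
    df["p_adj"] = adjust_bh(df["p"].to_numpy())
    return df


def _gsea_es(ranked: np.ndarray, member: np.ndarray, weight: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score."""
    w = np.abs(ranked) ** weight
    hit = member.astype(float) * w
    denom_hit = hit.sum()
    if denom_hit == 0:
        return 0.0
    n_miss = (~member).sum()
    steps = hit / denom_hit - (~member).astype(float) / max(n_miss, 1)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def enrich_gsea(
    effects: pd.Series,
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """GSEA on a ranked effect-size vector with a seeded permutation
    null over feature labels."""
    rng = np.random.default_rng(seed)
    effects = effects.dropna().sort_values(ascending=False)
    names = np.array(effects.index)
    vals = effects.to_numpy()
    rows = []
    for name, s in sorted(sets.items()):
        member = np.isin(names, list(s))
        k = int(member.sum())
        if k == 0:
            log.info("gsea: set %s has no members in ranking; skipped", name)
            continue
        es = _gsea_es(vals, member, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(len(names), dtype=bool)
            perm[rng.choice(len(names), size=k, replace=False)] = True
            null[b] = _gsea_es(vals, perm, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.mean(np.abs(same)) if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        if es >= 0:
            p = (1 + np.sum(null >= es)) / (n_perm + 1)
        else:
            p = (1 + np.sum(null <= es)) / (n_perm + 1)
        rows.append((name, k, es, nes, float(p)))
    df = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "p"]).set_index("set")
    df["p_adj"] = adjust_bh(df["p"].to_numpy())
    return df


def metabolite_reaction_sets(model) -> dict[str, set[str]]:
    """Incidence annotation for hub-metabolite enrichment: for every
    metabolite, the set of reactions that involve it."""
    sets: dict[str, set[str]] = {}
    for r in model.reactions:
        for m in r.stoichiometry:
            sets.setdefault(m, set()).add(r.id)
    return sets


def substrate_product_direction_table(
    model, up_reactions: set[str], down_reactions: set[str], metabolites: list[str]
) -> pd.DataFrame:
    """For each metabolite, count the up-/down-regulated reactions in
    which it appears as substrate, product, or both (reversible use)."""
    rows = []
    for met in metabolites:
        counts = {("substrate", "up"): 0, ("substrate", "down"): 0,
                  ("product", "up"): 0, ("product", "down"): 0,
                  ("both", "up"): 0, ("both", "down"): 0}
        for r in model.reactions:
            c = r.stoichiometry.get(met)
            if c is None:
                continue
            direction = "up" if r.id in up_reactions else (
                "down" if r.id in down_reactions else None)
            if direction is None:
                continue
            role = "both" if r.reversible else ("substrate" if c < 0 else "product")
            counts[(role, direction)] += 1
        for (role, direction), n in counts.items():
            rows.append((met, role, direction, n))
    return pd.DataFrame(rows, columns=["metabolite", "role", "direction", "count"])


# ---------------------------------------------------------------------------
# Permutation overlap test
# ---------------------------------------------------------------------------

def permutation_overlap_test(
    hits_a: set[str],
    hits_b: set[str],
    universe_a: set[str],
    universe_b: set[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """P(overlap >= observed) under independent uniform draws of |A|
    from universe_a and |B| from universe_b (add-one estimator)."""
    rng = np.random.default_rng(seed)
    ua, ub = sorted(universe_a), sorted(universe_b)
    observed = len(set(hits_a) & set(hits_b))
    na, nb = len(hits_a), len(hits_b)
    count = 0
    for _ in range(n_perm):
        da = set(rng.choice(len(ua), size=na, replace=False))
        db = {ub[i] for i in rng.choice(len(ub), size=nb, replace=False)}
        overlap = sum(1 for i in da if ua[i] in db)
        if overlap >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Taxon contribution models
# ---------------------------------------------------------------------------

def test_taxon_contribution(
    flux_long: pd.DataFrame,
    min_samples: int = 5,
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mixed-model test of per-taxon internal-exchange contributions.

    ``flux_long`` has columns sample, patient, taxon, flux (one row per
    member-level contribution).  Taxa observed in fewer than
    ``min_samples`` distinct samples are pooled into "Other".  A mixed
    model flux ~ 0 + taxon (+ covariates) with a patient random
    intercept yields per-taxon marginal means tested against zero (BH
    adjusted); a likelihood-ratio test for the taxonomy factor as a
    whole is reported in the frame attrs."""
    df = flux_long.copy()
    counts = df.groupby("taxon")["sample"].nunique()
    rare = set(counts.index[counts < min_samples])
    if rare:
        df.loc[df["taxon"].isin(rare), "taxon"] = "Other"
    taxa = sorted(df["taxon"].unique())
    design = pd.get_dummies(df["taxon"], dtype=float)[taxa]
    for c in covariates:
        design[c] = pd.to_numeric(df[c], errors="coerce")
    y = df["flux"].to_numpy(dtype=float)
    groups = df["patient"].to_numpy()
    rows = {}
    lrt_p = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = _fit_any(MixedLM(y, design.to_numpy(), groups=groups))
            if len(taxa) > 1:
                null_design = np.column_stack(
                    [np.ones(len(y))] + [design[c].to_numpy() for c in covariates]
                )
                fit0 = _fit_any(MixedLM(y, null_design, groups=groups))
                lr = 2 * (fit.llf - fit0.llf)
                lrt_p = float(sps.chi2.sf(max(lr, 0.0), df=len(taxa) - 1))
        for i, taxon in enumerate(taxa):
            est = float(fit.fe_params[i])
            se = float(fit.bse_fe[i])
            t = est / se if se > 0 else np.nan
            p = 2 * sps.norm.sf(abs(t)) if np.isfinite(t) else np.nan
            rows[taxon] = (est, se, t, p)
    except Exception as exc:
        log.warning("taxon contribution fit failed: %s", exc)
        for taxon in taxa:
            rows[taxon] = (np.nan,) * 4
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["estimate", "std_error", "t_value", "p"]
    )
    out.index.name = "taxon"
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    out.attrs["lrt_p"] = lrt_p
    return out
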