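"""In-silico dietary intervention screen.

Every dietary metabolite is perturbed one at a time — removed (uptake
bound set to zero) or doubled (maximum uptake bound doubled) — each
community is re-simulated, and the host-side and within-community
exchange fluxes of the inflammation-associated target metabolites are
compared before/after with paired Wilcoxon signed-rank tests (exact
for n <= 25 pairs).  Effects are summarised as
FC = mean over communities of log2(flux_after / flux_before) and
classified against the target's inflammation sign:

  desired        significant change opposing the target's association
                 (e.g. increased flux of a negatively associated
                 metabolite),
  undesired      significant change reinforcing it,
  direction_flip the flux changes sign (microbiome->host becomes
                 diet->microbiome or vice versa),
  ns             otherwise.

Fold changes must exceed 5% (|FC| > log2(1.05)) to count as relevant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._lp import OPTIMAL
from .community import CommunityModel, decompose_exchanges, simulate_community
from .stats import adjust_bh

__all__ = [
    "Target",
    "TargetSet",
    "Intervention",
    "select_targets",
    "apply_intervention",
    "run_intervention_screen",
    "summarize_interventions",
    "paired_wilcoxon",
    "FC_THRESHOLD",
]

log = logging.getLogger(__name__)

#: "exceeding 5%" on the mean-log2 scale
FC_THRESHOLD = math.log2(1.05)

SCOPES = ("host_exchange", "community_exchange")
MODES = ("remove", "double")


@dataclass(frozen=True)
class Target:
    metabolite: str
    sign: int                 # +1 / -1 association with inflammation
    scope: str                # host_exchange | community_exchange
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("target sign must be +1 or -1")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")


TargetSet = list[Target]


@dataclass(frozen=True)
class Intervention:
    metabolite: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown intervention mode {self.mode!r}")


def select_targets(
    association_tables: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
) -> TargetSet:
    """Consistent-direction target selection.

    ``association_tables`` maps (method, proxy) — e.g. ("coupling",
    "activity") — to per-metabolite association frames indexed by
    (scope, metabolite) or metabolite with columns estimate / p_adj.
    A metabolite becomes a target when it is significant for at least
    one proxy and every significant estimate across methods and
    proxies shares one sign; any sign conflict excludes it."""
    votes: dict[tuple[str, str], list[float]] = {}
    for (method, proxy), table in association_tables.items():
        for key, row in table.iterrows():
            if isinstance(key, tuple):
                scope, met = key
            else:
                scope, met = "host_exchange", key
            if not np.isfinite(row.get("p_adj", np.nan)):
                continue
            if row["p_adj"] < alpha and row["estimate"] != 0:
                votes.setdefault((scope, met), []).append(float(row["estimate"]))
    targets: TargetSet = []
    for (scope, met), ests in sorted(votes.items()):
        signs = {1 if e > 0 else -1 for e in ests}
        if len(signs) > 1:
            log.info("target %s/%s excluded: inconsistent signs", scope, met)
            continue
        targets.append(Target(met, signs.pop(), scope, provenance=f"{len(ests)} hits"))
    return targets


def apply_intervention(community: CommunityModel, iv: Intervention) -> CommunityModel:
    """Return a perturbed copy; the original community is untouched."""
    if iv.metabolite not in community.community_exchange_vars:
        log.info("intervention %s skipped: metabolite not exchanged", iv)
        return community.copy()
    out = community.copy()
    current = out.diet.get(iv.metabolite, 0.0)
    if iv.mode == "remove":
        out.set_uptake_bound(iv.metabolite, 0.0)
    else:
        if current == 0.0:
            log.info("doubling %s with zero bound: vacuous", iv.metabolite)
        out.set_uptake_bound(iv.metabolite, 2.0 * current)
    return out


def run_intervention_screen(
    communities: dict[str, CommunityModel],
    targets: TargetSet,
    diet_metabolites: list[str] | None = None,
) -> pd.DataFrame:
    """Before/after target fluxes for every diet metabolite x mode x
    community, as a long frame.  Baseline-infeasible communities are
    excluded; intervention-infeasible runs are recorded as missing."""
    rows = []
    baselines: dict[str, dict] = {}
    for cid, cm in sorted(communities.items()):
        sol = simulate_community(cm)
        if sol.status != OPTIMAL:
            log.warning("community %s baseline infeasible; excluded", cid)
            continue
        baselines[cid] = decompose_exchanges(cm, sol)
    if not baselines:
        raise RuntimeError("no community has a feasible baseline")
    any_cm = communities[next(iter(baselines))]
    diet_mets = diet_metabolites or sorted(
        m for m, b in any_cm.diet.bounds.items() if b > 0
    )
    for met in diet_mets:
        for mode in MODES:
            iv = Intervention(met, mode)
            for cid in baselines:
                base = baselines[cid]
                pert = apply_intervention(communities[cid], iv)
                sol = simulate_community(pert)
                feasible = sol.status == OPTIMAL
                summ = decompose_exchanges(pert, sol) if feasible else None
                for tg in targets:
                    pool = (
                        base.host_exchange
                        if tg.scope == "host_exchange"
                        else base.microbial_exchange
                    )
                    before = pool.get(tg.metabolite, np.nan)
                    if feasible:
                        pool2 = (
                            summ.host_exchange
                            if tg.scope == "host_exchange"
                            else summ.microbial_exchange
                        )
                        after = pool2.get(tg.metabolite, np.nan)
                    else:
                        after = np.nan
                    rows.append(
                        (met, mode, tg.metabolite, tg.scope, tg.sign, cid, before, after)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "intervention", "mode", "target", "scope", "target_sign",
            "community", "before", "after",
        ],
    )


def paired_wilcoxon(before: np.ndarray, after: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value: exact for
    n <= 25 non-tied pairs, normal approximation with continuity
    correction above; all-tied data gives p = 1."""
    diff = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    diff = diff[np.isfinite(diff)]
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", method=method, correction=True)
    return float(res.pvalue)


def summarize_interventions(
    screen: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = 0.05,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Paired Wilcoxon + fold-change classification per
    (intervention, mode, target, scope) cell.

    FC = mean(log2(after/before)) over communities with same-sign
    nonzero pairs; zero-baseline and sign-flipping pairs are excluded
    from the mean and counted separately.  Classification follows the
    module docstring; cells with fewer than ``min_pairs`` complete
    pairs are flagged (tested anyway, ``low_n`` = True)."""
    rows = []
    for (iv, mode, tgt, scope), grp in screen.groupby(
        ["intervention", "mode", "target", "scope"], sort=True
    ):
        ok = grp.dropna(subset=["before", "after"])
        n = len(ok)
        before = ok["before"].to_numpy(dtype=float)
        after = ok["after"].to_numpy(dtype=float)
        p = paired_wilcoxon(before, after) if n else np.nan
        ratio_ok = (before != 0) & (after != 0) & (np.sign(before) == np.sign(after))
        n_flip = int(((np.sign(before) != np.sign(after)) & (after != 0) & (before != 0)).sum())
        n_zero = int((before == 0).sum())
        fc = (
            float(np.mean(np.log2(np.abs(after[ratio_ok] / before[ratio_ok]))))
            if ratio_ok.any()
            else np.nan
        )
        delta = float(np.median(after - before)) if n else np.nan
        sign = int(grp["target_sign"].iloc[0])
        rows.append(
            (iv, mode, tgt, scope, sign, n, n_flip, n_zero, p, fc, delta, n < min_pairs)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "intervention", "mode", "target", "scope", "target_sign", "n",
            "n_flip", "n_zero_baseline", "p", "fc", "median_change", "low_n",
        ],
    )
    out["p_adj"] = adjust_bh(out["p"].to_numpy())

    def classify(row) -> str:
        if not np.isfinite(row["p_adj"]) or row["p_adj"] >= alpha:
            return "ns"
        big_fc = np.isfinite(row["fc"]) and abs(row["fc"]) > fc_threshold
        flips = row["n_flip"] > row["n"] / 2
        if flips:
            return "direction_flip"
        if not big_fc:
            return "ns"
        increased = row["median_change"] > 0
        opposes = (row["target_sign"] < 0 and increased) or (
            row["target_sign"] > 0 and not increased
        )
        return "desired" if opposes else "undesired"

    out["class"] = out.apply(classify, axis=1)
    return out
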