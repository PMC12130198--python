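"""Context-specific host models from expression data.

Workflow: read counts -> TPM -> reaction-expression scores through the
GPR rules (OR -> sum, AND -> min) -> core/inactive partition with
global (10th/90th pooled percentile) and local (per-reaction 50th
percentile) thresholds -> FASTCORE extraction of a flux-consistent
subnetwork containing the core -> four per-reaction activity layers
(rxnExpr, PA, FVA.range, FVA.center).

Tissues are processed independently: thresholds are computed over the
score matrix that is passed in, which should hold one tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lp import OPTIMAL, LinearProgram, SolverError
from .core import (
    CONSISTENCY_EPS,
    MetabolicModel,
    build_lp,
    find_blocked_reactions,
    fva,
)

__all__ = [
    "ThresholdConfig",
    "CoreSets",
    "ContextModel",
    "ReactionLayers",
    "counts_to_tpm",
    "reaction_expression",
    "build_core_sets",
    "fastcore",
    "extract_context_model",
    "compute_reaction_layers",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression handling
# ---------------------------------------------------------------------------

def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bases).

    TPM_gs = (count_gs / length_g) / sum_g'(count_g's / length_g') * 1e6
    """
    expressed = counts.index[(counts.sum(axis=1) > 0)]
    missing = [g for g in expressed if g not in gene_lengths.index]
    if missing:
        raise ValueError(f"genes without length: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    lengths = gene_lengths.reindex(counts.index)
    if (lengths.fillna(1) <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad[:10]}")
    rate = counts.div(lengths.fillna(1.0), axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum.index[colsum == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples (TPM undefined): {zero}")
    return rate.div(colsum, axis=1) * 1e6


def reaction_expression(
    model: MetabolicModel, tpm: pd.DataFrame, absent_value: float = 0.0
) -> pd.DataFrame:
    """Reaction x sample expression scores from GPR rules.

    Reactions without a GPR are excluded (they carry no expression
    evidence); genes absent from the TPM table score ``absent_value``
    (default 0: not detected ~ not expressed), which is logged.
    """
    rows = {}
    absent: set[str] = set()
    for r in model.reactions:
        if r.gpr is None:
            continue
        absent |= r.gpr.genes() - set(tpm.index)
        scores = []
        for s in tpm.columns:
            gv = tpm[s]
            vals = {g: float(gv.get(g, absent_value)) for g in r.gpr.genes()}
            scores.append(r.gpr.score(vals, absent=absent_value))
        rows[r.id] = scores
    if absent:
        log.info(
            "reaction_expression: %d GPR genes absent from expression "
            "table, scored %.3g", len(absent), absent_value,
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tpm.columns))


# ---------------------------------------------------------------------------
# Core-set thresholding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdConfig:
    """Global pooled percentiles and the per-reaction local percentile."""

    global_lower_pct: float = 10.0
    global_upper_pct: float = 90.0
    local_pct: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.global_lower_pct < self.global_upper_pct <= 100:
            raise ValueError("require 0 <= lower < upper <= 100")


@dataclass
class CoreSets:
    """Per-sample partition of GPR-scored reactions."""

    core: dict[str, set[str]]
    inactive: dict[str, set[str]]
    undetermined: dict[str, set[str]]
    g_low: float
    g_high: float
    local_thresholds: pd.Series

    def samples(self) -> list[str]:
        return list(self.core)


def build_core_sets(scores: pd.DataFrame, cfg: ThresholdConfig = ThresholdConfig()) -> CoreSets:
    """Partition reactions per sample into core / inactive / undetermined.

    Global bounds are pooled percentiles over the whole reaction x
    sample score matrix (linear interpolation); the local threshold
    L_r is the per-reaction percentile across samples.  A score below
    G_low (strict) is inactive, above G_high (strict) is core, and in
    between it is core iff it exceeds (strict) L_r.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 samples to build core sets")
    pooled = scores.to_numpy().ravel()
    g_low, g_high = np.percentile(pooled, [cfg.global_lower_pct, cfg.global_upper_pct])
    local = scores.quantile(cfg.local_pct / 100.0, axis=1)
    if np.isclose(g_low, g_high):
        log.warning("degenerate score distribution: G_low == G_high == %.4g", g_low)
    core: dict[str, set[str]] = {}
    inactive: dict[str, set[str]] = {}
    undet: dict[str, set[str]] = {}
    for s in scores.columns:
        col = scores[s]
        is_inactive = col < g_low
        is_core = (col > g_high) | (~is_inactive & (col <= g_high) & (col > local))
        core[s] = set(col.index[is_core])
        inactive[s] = set(col.index[is_inactive])
        undet[s] = set(col.index[~is_core & ~is_inactive])
    return CoreSets(core, inactive, undet, float(g_low), float(g_high), local)


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

def _lp7(model: MetabolicModel, targets: set[str], eps: float) -> dict[str, float]:
    """Maximise the number of target reactions with forward flux >= eps."""
    lp = build_lp(model)
    obj = {}
    for rid in sorted(targets):
        z = f"__z_{rid}"
        lp.add_var(z, 0.0, eps)
        lp.add_le({z: 1.0, rid: -1.0}, 0.0)
        obj[z] = 1.0
    status, _, x = lp.solve(obj, sense="max")
    if status != OPTIMAL:
        raise SolverError(f"LP7 not optimal: {status}")
    fx = dict(zip(lp.names, x))
    return {r.id: fx[r.id] for r in model.reactions}


def _lp10(
    model: MetabolicModel, force: set[str], penalty: set[str], eps: float
) -> dict[str, float]:
    """Minimise the l1-norm of the penalty reactions while forcing the
    reactions in ``force`` to carry flux >= eps (bounds scaled by 1e5
    as in the original formulation so support detection at ~eps works)."""
    sf = 1e5
    lp = LinearProgram()
    for r in model.reactions:
        lb, ub = r.lower_bound * sf, r.upper_bound * sf
        if r.id in force:
            lb = max(lb, eps * sf)
        lp.add_var(r.id, lb, ub)
    rows: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        for m, c in r.stoichiometry.items():
            rows.setdefault(m, {})[r.id] = rows.setdefault(m, {}).get(r.id, 0.0) + c
    for row in rows.values():
        lp.add_eq(row, 0.0)
    obj = {}
    for rid in sorted(penalty):
        r = model.reaction(rid)
        z = f"__z_{rid}"
        cap = sf * max(abs(r.lower_bound), abs(r.upper_bound))
        lp.add_var(z, 0.0, cap)
        lp.add_le({rid: 1.0, z: -1.0}, 0.0)
        lp.add_le({rid: -1.0, z: -1.0}, 0.0)
        obj[z] = 1.0
    status, _, x = lp.solve(obj, sense="min")
    if status != OPTIMAL:
        raise SolverError(f"LP10 not optimal: {status}")
    fx = dict(zip(lp.names, x))
    return {r.id: fx[r.id] for r in model.reactions}


def _find_sparse_mode(
    model: MetabolicModel, J: set[str], P: set[str], singleton: bool, eps: float
) -> set[str]:
    if not J:
        return set()
    J2 = {sorted(J)[0]} if singleton else set(J)
    v = _lp7(model, J2, eps)
    K = {j for j in J2 if v[j] >= 0.99 * eps}
    if not K:
        return set()
    v = _lp10(model, K, P, eps)
    return {rid for rid, f in v.items() if abs(f) >= 0.99 * eps}


class InconsistentCoreError(RuntimeError):
    """A core reaction cannot carry flux in the consistent network."""


def fastcore(
    model: MetabolicModel, core: set[str], eps: float = CONSISTENCY_EPS
) -> set[str]:
    """The FASTCORE algorithm: a compact flux-consistent subnetwork of a
    consistent ``model`` containing every reaction in ``core``.

    The input model must itself be flux-consistent at ``eps``
    (pre-prune with :func:`~gutflux.core.find_blocked_reactions`).
    """
    all_ids = set(model.reaction_ids())
    if not core:
        raise ValueError("empty core set")
    if not core <= all_ids:
        raise ValueError(f"core not in model: {sorted(core - all_ids)[:5]}")
    irrev = {r.id for r in model.reactions if r.lower_bound >= 0}
    flipped = False
    singleton = False
    work = model  # bounds get flipped on copies as the algorithm runs

    J = core & irrev
    P = all_ids - core
    A = _find_sparse_mode(work, J, P, singleton, eps)
    if not J <= A:
        raise InconsistentCoreError(
            f"irreversible core reactions blocked: {sorted(J - A)[:5]}"
        )
    J = core - A
    while J:
        P = P - A
        supp = _find_sparse_mode(work, J, P, singleton, eps)
        A |= supp
        if J & A:
            J -= A
            flipped = False
            singleton = False
            continue
        target = {sorted(J)[0]} if singleton else J
        to_flip = target - irrev
        if flipped or not to_flip:
            if singleton:
                raise InconsistentCoreError(
                    f"core reaction {sorted(J)[0]!r} cannot be activated"
                )
            singleton = True
            flipped = False
        else:
            work = _flip_reactions(work, to_flip)
            flipped = True
    return A


def _flip_reactions(model: MetabolicModel, rids: set[str]) -> MetabolicModel:
    """Reverse the written direction of reactions: negate stoichiometry
    and mirror the bounds (support magnitudes are unchanged)."""
    from dataclasses import replace as _replace

    rxns = [
        _replace(
            r,
            stoichiometry={m: -c for m, c in r.stoichiometry.items()},
            lower_bound=-r.upper_bound,
            upper_bound=-r.lower_bound,
        )
        if r.id in rids
        else r
        for r in model.reactions
    ]
    return MetabolicModel(model.id, list(model.metabolites), rxns,
                          set(model.genes), model.objective)


# ---------------------------------------------------------------------------
# Context-model extraction and layers
# ---------------------------------------------------------------------------

@dataclass
class ContextModel:
    sample: str
    reactions: set[str]
    parent: MetabolicModel
    dropped_core: set[str] = field(default_factory=set)

    def submodel(self) -> MetabolicModel:
        return self.parent.subset(self.reactions, model_id=f"{self.parent.id}|{self.sample}")


def extract_context_model(
    host: MetabolicModel,
    core: set[str],
    inactive: set[str],
    sample: str = "",
    eps: float = CONSISTENCY_EPS,
) -> ContextModel:
    """Remove inactive reactions, restore flux consistency, and run
    FASTCORE on the realizable core.

    Core reactions that become blocked once the inactive set is removed
    cannot be realised; they are dropped from the core with a warning
    and reported in ``dropped_core``.
    """
    if not core:
        raise ValueError(f"sample {sample!r}: empty core set")
    keep = set(host.reaction_ids()) - (set(inactive) - set(core))
    sub = host.subset(keep)
    blocked = find_blocked_reactions(sub, eps)
    consistent = sub.subset(keep - blocked)
    realizable = set(core) & set(consistent.reaction_ids())
    dropped = set(core) - realizable
    if dropped:
        log.warning(
            "sample %s: %d core reactions unrealizable after pruning: %s",
            sample, len(dropped), sorted(dropped)[:5],
        )
    if not realizable:
        raise InconsistentCoreError(f"sample {sample!r}: no realizable core")
    A = fastcore(consistent, realizable, eps)
    return ContextModel(sample=sample, reactions=A, parent=host, dropped_core=dropped)


@dataclass
class ReactionLayers:
    """The four activity layers, each reactions x samples (NaN where a
    reaction is absent from the sample's context model)."""

    rxn_expr: pd.DataFrame
    pa: pd.DataFrame
    fva_range: pd.DataFrame
    fva_center: pd.DataFrame

    LAYER_NAMES = ("rxnExpr", "PA", "FVA.range", "FVA.center")

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {
            "rxnExpr": self.rxn_expr,
            "PA": self.pa,
            "FVA.range": self.fva_range,
            "FVA.center": self.fva_center,
        }


def compute_reaction_layers(
    context_models: dict[str, ContextModel],
    scores: pd.DataFrame,
    fva_fraction: float = 0.0,
) -> ReactionLayers:
    """rxnExpr from the score matrix, PA from context-model membership,
    FVA range/center per context model (fraction 0: raw capabilities)."""
    samples = list(context_models)
    rids = list(scores.index)
    pa = pd.DataFrame(0.0, index=rids, columns=samples)
    rng_ = pd.DataFrame(np.nan, index=rids, columns=samples)
    ctr = pd.DataFrame(np.nan, index=rids, columns=samples)
    for s, cmod in context_models.items():
        present = [r for r in rids if r in cmod.reactions]
        pa.loc[present, s] = 1.0
        sub = cmod.submodel()
        try:
            res = fva(sub, fraction_of_optimum=fva_fraction, reactions=present)
        except SolverError as exc:
            log.warning("FVA failed for sample %s: %s", s, exc)
            continue
        for r in present:
            rng_.loc[r, s] = res.range(r)
            ctr.loc[r, s] = res.center(r)
    expr = scores.reindex(columns=samples)
    return ReactionLayers(rxn_expr=expr, pa=pa, fva_range=rng_, fva_center=ctr)
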