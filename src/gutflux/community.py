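"""Per-sample microbial community models with coupling constraints.

A community merges the member models into one LP: each member keeps its
own metabolite compartment, the members' exchange reactions are rewired
into *internal exchanges* against a shared environmental compartment,
and one *community exchange* per environmental metabolite connects the
environment to the outside (the host/diet side).  Member growth is tied
to the observed relative abundances through an abundance-weighted
community biomass reaction, and every non-biomass member reaction j of
member i carries coupling constraints

    -c * v_bio_i - u  <=  v_j  <=  c * v_bio_i + u

(c = 200, u = 0.01 mmol/gDW/h by default) so that non-growing members
cannot carry free-riding flux.

Exchange decomposition: for a metabolite m with internal exchange
fluxes v_int (positive = secretion into the environment) and community
exchange flux v_host (positive = secretion to the host side),

    host_exchange      = v_host
    microbial_exchange = sum_i |v_int_{i,m}| - |v_host|
                       = 2 * min(total secretion, total uptake)

i.e. twice the amount cross-fed within the community.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import pandas as pd

from ._lp import OPTIMAL, LinearProgram
from .core import DEFAULT_BOUND, FluxResult, MetabolicModel, fba

__all__ = [
    "CouplingConfig",
    "Diet",
    "CommunityMember",
    "CommunityModel",
    "ExchangeSummary",
    "EmptyCommunityError",
    "AssemblyError",
    "apply_diet",
    "screen_members",
    "assemble_community",
    "simulate_community",
    "decompose_exchanges",
    "aggregate_taxon_fluxes",
]

log = logging.getLogger(__name__)

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")


class EmptyCommunityError(RuntimeError):
    """Screening removed every candidate member."""


class AssemblyError(RuntimeError):
    """Community could not be merged (e.g. namespace collision)."""


@dataclass(frozen=True)
class CouplingConfig:
    """Coupling factor c, threshold u, and the solo-growth screening cutoff."""

    c: float = 200.0
    u: float = 0.01
    min_growth: float = 1e-3

    def __post_init__(self) -> None:
        if self.c <= 0 or self.u < 0 or self.min_growth < 0:
            raise ValueError("require c > 0, u >= 0, min_growth >= 0")


@dataclass
class Diet:
    """Maximum uptake flux per metabolite (non-negative, mmol/gDW/h)."""

    bounds: dict[str, float]
    name: str = "diet"

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.bounds.items() if v < 0}
        if bad:
            raise ValueError(f"negative diet bounds: {bad}")

    def get(self, met: str, default: float = 0.0) -> float:
        return self.bounds.get(met, default)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "Diet":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: diet TSV needs metabolite + bound columns")
        mets, vals = df.iloc[:, 0], df.iloc[:, 1]
        return cls({str(m): float(v) for m, v in zip(mets, vals)},
                   name=name or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"metabolite": list(self.bounds), "max_uptake": list(self.bounds.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class CommunityMember:
    model: MetabolicModel
    abundance: float
    taxonomy: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.model.id


def apply_diet(model: MetabolicModel, diet: Diet) -> MetabolicModel:
    """Limit a solo model's exchange uptake to the diet (secretion open)."""
    bounds = {}
    for r in model.exchanges():
        met = next(iter(r.stoichiometry))
        bounds[r.id] = (-diet.get(met, 0.0), max(r.upper_bound, 0.0))
    return model.with_bounds(bounds)


def screen_members(
    candidates: list[CommunityMember],
    diet: Diet,
    cfg: CouplingConfig = CouplingConfig(),
) -> list[CommunityMember]:
    """Drop members whose solo growth on the diet is below the cutoff
    (strictly < cfg.min_growth) and renormalise abundances to sum 1."""
    kept: list[CommunityMember] = []
    for cand in candidates:
        sol = fba(apply_diet(cand.model, diet))
        growth = sol.objective_value if sol.status == OPTIMAL else 0.0
        if sol.status != OPTIMAL or growth < cfg.min_growth:
            log.info("screen_members: dropping %s (growth %.3g)", cand.id, growth)
            continue
        kept.append(cand)
    if not kept:
        raise EmptyCommunityError(
            f"no member grows >= {cfg.min_growth} on diet {diet.name!r}"
        )
    total = sum(m.abundance for m in kept)
    if total <= 0:
        raise EmptyCommunityError("retained members have zero total abundance")
    return [
        CommunityMember(m.model, m.abundance / total, dict(m.taxonomy)) for m in kept
    ]


COMMUNITY_BIOMASS = "community_biomass"


@dataclass
class CommunityModel:
    """Merged multi-member LP; see module docstring for structure."""

    members: list[CommunityMember]
    diet: Diet
    coupling: CouplingConfig
    lp: LinearProgram
    # var-name maps
    member_vars: dict[tuple[str, str], str]          # (member, reaction) -> var
    internal_exchange_vars: dict[tuple[str, str], str]  # (member, metabolite) -> var
    community_exchange_vars: dict[str, str]          # metabolite -> var
    biomass_vars: dict[str, str]                     # member -> var

    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def environment_metabolites(self) -> list[str]:
        return sorted(self.community_exchange_vars)

    def copy(self) -> "CommunityModel":
        return copy.deepcopy(self)

    def set_uptake_bound(self, met: str, bound: float) -> None:
        """Set the community's maximum uptake of a diet metabolite."""
        var = self.community_exchange_vars[met]
        _, ub = self.lp.get_bounds(var)
        self.lp.set_bounds(var, -abs(bound), ub)
        self.diet.bounds[met] = abs(bound)


def assemble_community(
    members: list[CommunityMember],
    diet: Diet,
    cfg: CouplingConfig = CouplingConfig(),
) -> CommunityModel:
    """Merge screened members into one coupled community LP."""
    if not members:
        raise EmptyCommunityError("cannot assemble an empty community")
    total = sum(m.abundance for m in members)
    if abs(total - 1.0) > 1e-9:
        raise AssemblyError(f"abundances must sum to 1 (got {total})")
    ids = [m.id for m in members]
    if len(set(ids)) != len(ids):
        raise AssemblyError(f"duplicate member ids: {ids}")

    lp = LinearProgram()
    member_vars: dict[tuple[str, str], str] = {}
    internal_ex: dict[tuple[str, str], str] = {}
    biomass_vars: dict[str, str] = {}
    # mass-balance rows accumulated as {met-key: {var: coeff}}
    rows: dict[str, dict[str, float]] = {}

    def _row(key: str) -> dict[str, float]:
        return rows.setdefault(key, {})

    env_mets: set[str] = set()
    for mem in members:
        mid = mem.id
        model = mem.model
        if not model.objective:
            raise AssemblyError(f"member {mid!r} has no objective (biomass) reaction")
        for r in model.reactions:
            var = f"{mid}|{r.id}"
            lp.add_var(var, r.lower_bound, r.upper_bound)
            member_vars[(mid, r.id)] = var
            if r.is_exchange and r.id != model.objective:
                # rewire: exchange becomes member <-> environment transfer
                met, coeff = next(iter(r.stoichiometry.items()))
                _row(f"{mid}|{met}")[var] = coeff
                _row(f"env|{met}")[var] = -coeff
                # positive flux = secretion into environment under the
                # met -> (outside) convention (coeff < 0)
                internal_ex[(mid, met)] = var
                env_mets.add(met)
            else:
                for met, coeff in r.stoichiometry.items():
                    row = _row(f"{mid}|{met}")
                    row[var] = row.get(var, 0.0) + coeff
            if r.id == model.objective:
                biomass_vars[mid] = var
                _row(f"bio|{mid}")[var] = 1.0  # produces member biomass unit

    # community exchanges: environment <-> outside; positive = secretion
    community_ex: dict[str, str] = {}
    for met in sorted(env_mets):
        var = f"EX_comm|{met}"
        lp.add_var(var, -diet.get(met, 0.0), DEFAULT_BOUND)
        community_ex[met] = var
        _row(f"env|{met}")[var] = -1.0

    # abundance-weighted community biomass
    lp.add_var(COMMUNITY_BIOMASS, 0.0, DEFAULT_BOUND)
    for mem in members:
        _row(f"bio|{mem.id}")[COMMUNITY_BIOMASS] = -mem.abundance

    for row in rows.values():
        lp.add_eq(row, 0.0)

    # coupling rows for every non-biomass member reaction
    for mem in members:
        bio = biomass_vars[mem.id]
        for (mid, rid), var in member_vars.items():
            if mid != mem.id or var == bio:
                continue
            lp.add_le({var: 1.0, bio: -cfg.c}, cfg.u)
            lp.add_le({var: -1.0, bio: -cfg.c}, cfg.u)

    return CommunityModel(
        members=members,
        diet=Diet(dict(diet.bounds), diet.name),
        coupling=cfg,
        lp=lp,
        member_vars=member_vars,
        internal_exchange_vars=internal_ex,
        community_exchange_vars=community_ex,
        biomass_vars=biomass_vars,
    )


def simulate_community(cm: CommunityModel) -> FluxResult:
    """Maximise community biomass; returns all member/exchange fluxes."""
    status, value, x = cm.lp.solve({COMMUNITY_BIOMASS: 1.0}, sense="max")
    if status != OPTIMAL:
        diag = (
            f"community infeasible/unbounded (status {status}); diet "
            f"{cm.diet.name!r} with {len(cm.diet.bounds)} metabolites, "
            f"coupling c={cm.coupling.c} u={cm.coupling.u}"
        )
        log.warning(diag)
        return FluxResult(status=status, objective_value=value, fluxes={})
    return FluxResult(status=status, objective_value=value,
                      fluxes=dict(zip(cm.lp.names, x)))


@dataclass
class ExchangeSummary:
    """Per-metabolite host/microbial exchange plus per-member detail."""

    host_exchange: dict[str, float]
    microbial_exchange: dict[str, float]
    member_exchange: dict[str, dict[str, float]]  # met -> member -> flux
    overall_flux: dict[str, float]                # reaction id -> summed flux

    def to_frame(self) -> pd.DataFrame:
        mets = sorted(self.host_exchange)
        return pd.DataFrame(
            {
                "metabolite": mets,
                "host_exchange": [self.host_exchange[m] for m in mets],
                "microbial_exchange": [self.microbial_exchange[m] for m in mets],
            }
        )


def microbial_exchange_value(member_fluxes: dict[str, float], host_flux: float) -> float:
    """sum_i |v_int| - |v_host|; equals 2*min(secretion, uptake) at steady
    state and is clamped at 0 against LP round-off."""
    return max(0.0, sum(abs(v) for v in member_fluxes.values()) - abs(host_flux))


def decompose_exchanges(cm: CommunityModel, flux: FluxResult) -> ExchangeSummary:
    if flux.status != OPTIMAL:
        raise ValueError("exchange decomposition needs an optimal flux state")
    host: dict[str, float] = {}
    micro: dict[str, float] = {}
    member_ex: dict[str, dict[str, float]] = {}
    for met, var in cm.community_exchange_vars.items():
        host[met] = flux.fluxes[var]
        per_member = {
            mid: flux.fluxes[v]
            for (mid, m), v in cm.internal_exchange_vars.items()
            if m == met
        }
        member_ex[met] = per_member
        micro[met] = microbial_exchange_value(per_member, host[met])
    overall: dict[str, float] = {}
    for (mid, rid), var in cm.member_vars.items():
        overall[rid] = overall.get(rid, 0.0) + flux.fluxes[var]
    return ExchangeSummary(
        host_exchange=host,
        microbial_exchange=micro,
        member_exchange=member_ex,
        overall_flux=overall,
    )


def aggregate_taxon_fluxes(
    cm: CommunityModel,
    flux: FluxResult,
    metabolite: str,
    level: str,
) -> dict[str, float]:
    """Signed internal-exchange totals per taxon at the given rank;
    members without a label at that rank are pooled under "Other"."""
    if level not in TAXONOMY_RANKS:
        raise ValueError(f"unknown taxonomy rank {level!r}; use {TAXONOMY_RANKS}")
    if metabolite not in cm.community_exchange_vars:
        raise KeyError(f"metabolite {metabolite!r} not exchanged by the community")
    totals: dict[str, float] = {}
    for mem in cm.members:
        var = cm.internal_exchange_vars.get((mem.id, metabolite))
        if var is None:
            continue
        taxon = mem.taxonomy.get(level) or "Other"
        totals[taxon] = totals.get(taxon, 0.0) + flux.fluxes[var]
    return totals
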