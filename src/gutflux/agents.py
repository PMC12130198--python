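"""Minimal individual-based spatial community simulation.

Complements the coupled community LP with a competition-oriented view:
individuals of each member species sit on a rectangular grid of cells,
each cell holding metabolite pools.  Per time step (in seeded random order)
every individual solves its own FBA with uptake bounds derived from its
cell's pools, consumes and secretes accordingly, grows, and duplicates
into a neighbouring cell when its accumulated biomass doubles.  Pools
diffuse to the four neighbours at a fixed rate per step.

This is a deliberately small, documented variant of the
individual-based modeling idea: placement is random (seeded), uptake
kinetics are a simple pool/step bound, diffusion is a single-rate
4-neighbour exchange.  Defaults: a 100x100 grid, 3 time steps, and
1 mM chorismate, indole and salicylate supplements on top of the diet
(these supplements secure the initial growth of fastidious members).

After the run, per-metabolite fluxes are aggregated over individuals
and steps into an :class:`~gutflux.community.ExchangeSummary`: the host
exchange of a metabolite is the summed net exchange of all individuals
and the microbial exchange is ``sum |v_i| - |sum v_i|``, the same
decomposition used for the coupled models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._lp import OPTIMAL
from .community import CommunityMember, Diet, ExchangeSummary
from .core import MetabolicModel, build_lp

__all__ = ["AgentConfig", "run_agent_simulation"]

_DIRS = ((0, 1), (0, -1), (1, 0), (-1, 0))

DEFAULT_SUPPLEMENTS = {"chorismate": 1.0, "indole": 1.0, "salicylate": 1.0}


@dataclass(frozen=True)
class AgentConfig:
    """Arena geometry, duration and unit-conversion constants.

    ``supplements`` are concentrations in mM added to every cell on top
    of the diet.  A concentration of 1 mM in a cell of nominal volume
    ``cell_volume_l`` holds ``1e-3 * cell_volume_l * 1e3`` mmol; uptake
    bounds are pool / (gdw_per_individual * dt_h) so pools, biomass and
    fluxes stay on the mmol / gDW / h scale of the models.
    """

    grid: tuple[int, int] = (100, 100)
    steps: int = 3
    supplements: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPPLEMENTS)
    )
    capacity: int = 100
    seed: int = 0
    diffusion_rate: float = 0.5
    cell_volume_l: float = 0.01
    gdw_per_individual: float = 1e-3
    dt_h: float = 1.0
    diet_concentration_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid dimensions must be >= 1")


def _mm_to_mmol(conc_mm: float, cfg: AgentConfig) -> float:
    # mM = mmol/L; pool per cell in mmol
    return conc_mm * cfg.cell_volume_l


def _diffuse(pool: np.ndarray, rate: float) -> np.ndarray:
    """4-neighbour diffusion with reflecting edges; mass conserving."""
    if pool.shape[0] * pool.shape[1] == 1:
        return pool
    out = pool * (1.0 - rate)
    share = pool * rate
    # split the outgoing share over existing neighbours
    nnb = np.full(pool.shape, 4.0)
    nnb[0, :] -= 1
    nnb[-1, :] -= 1
    nnb[:, 0] -= 1
    nnb[:, -1] -= 1
    per = np.divide(share, nnb, out=np.zeros_like(share), where=nnb > 0)
    out[1:, :] += per[:-1, :]
    out[:-1, :] += per[1:, :]
    out[:, 1:] += per[:, :-1]
    out[:, :-1] += per[:, 1:]
    return out


class _Individual:
    __slots__ = ("member_idx", "x", "y", "biomass")

    def __init__(self, member_idx: int, x: int, y: int, biomass: float):
        self.member_idx = member_idx
        self.x = x
        self.y = y
        self.biomass = biomass


def run_agent_simulation(
    members: list[CommunityMember],
    diet: Diet,
    cfg: AgentConfig = AgentConfig(),
) -> ExchangeSummary:
    """Run the arena and aggregate individual exchanges over all steps."""
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.grid

    # environment metabolites: everything any member can exchange
    env_mets: list[str] = sorted(
        {
            next(iter(r.stoichiometry))
            for mem in members
            for r in mem.model.exchanges()
            if r.id != mem.model.objective
        }
    )
    met_idx = {m: i for i, m in enumerate(env_mets)}

    pools = np.zeros((len(env_mets), w, h))
    for met, i in met_idx.items():
        conc = 0.0
        if met in diet.bounds and diet.bounds[met] > 0:
            conc += cfg.diet_concentration_mm
        conc += cfg.supplements.get(met, 0.0)
        pools[i, :, :] = _mm_to_mmol(conc, cfg)

    # per-member LP and exchange bookkeeping built once
    lps = []
    ex_info = []  # list of dict met -> (var, orig_lb, orig_ub)
    for mem in members:
        model: MetabolicModel = mem.model
        lp = build_lp(model)
        info = {}
        for r in model.exchanges():
            if r.id == model.objective:
                continue
            met = next(iter(r.stoichiometry))
            info[met] = (r.id, r.lower_bound, r.upper_bound)
        lps.append((lp, model.objective))
        ex_info.append(info)

    # placement proportional to abundance (largest-remainder rounding)
    abund = np.array([m.abundance for m in members], dtype=float)
    abund = abund / abund.sum()
    counts = np.floor(abund * cfg.capacity).astype(int)
    rest = cfg.capacity - counts.sum()
    if rest > 0:
        order = np.argsort(-(abund * cfg.capacity - counts))
        for i in order[:rest]:
            counts[i] += 1
    individuals: list[_Individual] = []
    for mi, n in enumerate(counts):
        for _ in range(n):
            individuals.append(
                _Individual(mi, int(rng.integers(w)), int(rng.integers(h)), 1.0)
            )
    if not individuals:
        raise ValueError("no individuals placed (capacity too small?)")

    # aggregated per-metabolite per-individual net exchanges (flux units)
    agg_abs: dict[str, float] = {m: 0.0 for m in env_mets}
    agg_net: dict[str, float] = {m: 0.0 for m in env_mets}

    for _step in range(cfg.steps):
        order = rng.permutation(len(individuals))
        newborn: list[_Individual] = []
        for idx in order:
            ind = individuals[idx]
            lp, objective = lps[ind.member_idx]
            info = ex_info[ind.member_idx]
            gdw = cfg.gdw_per_individual * ind.biomass
            # uptake limited by the local pool over this step
            for met, (rid, lb, ub) in info.items():
                avail = pools[met_idx[met], ind.x, ind.y]
                max_uptake = avail / (gdw * cfg.dt_h)
                lp.set_bounds(rid, max(lb, -max_uptake), ub)
            status, growth, x = lp.solve({objective: 1.0}, sense="max")
            if status != OPTIMAL:
                continue
            names = lp.names
            fx = dict(zip(names, x))
            for met, (rid, lb, ub) in info.items():
                v = fx[rid]  # positive = secretion
                amount = v * gdw * cfg.dt_h
                pools[met_idx[met], ind.x, ind.y] = max(
                    0.0, pools[met_idx[met], ind.x, ind.y] + amount
                )
                agg_abs[met] += abs(v) * ind.biomass
                agg_net[met] += v * ind.biomass
                lp.set_bounds(rid, lb, ub)
            ind.biomass += growth * ind.biomass * cfg.dt_h
            if ind.biomass >= 2.0:
                dx, dy = _DIRS[int(rng.integers(4))]
                nx = min(max(ind.x + int(dx), 0), w - 1)
                ny = min(max(ind.y + int(dy), 0), h - 1)
                ind.biomass /= 2.0
                newborn.append(
                    _Individual(ind.member_idx, nx, ny, ind.biomass)
                )
        individuals.extend(newborn)
        for i in range(pools.shape[0]):
            pools[i] = _diffuse(pools[i], cfg.diffusion_rate)

    host = {m: agg_net[m] for m in env_mets}
    micro = {
        m: max(0.0, agg_abs[m] - abs(agg_net[m])) for m in env_mets
    }
    member_ex: dict[str, dict[str, float]] = {m: {} for m in env_mets}
    return ExchangeSummary(
        host_exchange=host,
        microbial_exchange=micro,
        member_exchange=member_ex,
        overall_flux={},
    )
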