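"""Constraint-based metabolic model container and LP primitives.

The data model is deliberately small: a :class:`MetabolicModel` is a
stoichiometric matrix with flux bounds, gene-protein-reaction (GPR)
rules and subsystem labels.  Exchange reactions follow the dominant
sign convention: they are written ``metabolite <-> (outside)`` so that
negative flux is uptake and positive flux is secretion; diets act on
exchange lower bounds.

FBA, FVA and blocked-reaction detection run on the package's HiGHS
layer (:mod:`gutflux._lp`).  SBML import/export goes through cobrapy.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass, field, replace

from ._lp import (
    OPTIMAL,
    REPORT_TOL,
    UNBOUNDED,
    LinearProgram,
    SolverError,
)

__all__ = [
    "Gpr",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxResult",
    "FVAResult",
    "ValidationError",
    "FormatError",
    "read_model",
    "write_model",
    "fba",
    "fva",
    "find_blocked_reactions",
    "build_lp",
    "DEFAULT_BOUND",
    "CONSISTENCY_EPS",
]

DEFAULT_BOUND = 1000.0
#: epsilon for flux-consistency checks (FASTCC/FASTCORE scale)
CONSISTENCY_EPS = 1e-4


class ValidationError(ValueError):
    """Model violates a structural invariant."""


class FormatError(ValueError):
    """File could not be parsed in the requested format."""


# ---------------------------------------------------------------------------
# GPR expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gpr:
    """Boolean gene-reaction rule as an AND/OR tree.

    ``op`` is ``"gene"`` (leaf, ``gene`` set), ``"and"`` or ``"or"``
    (``children`` set).  Evaluation for expression scoring maps OR to a
    sum and AND to a minimum of the children's values (isozymes add up,
    complex subunits are limited by the scarcest member).
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValidationError("GPR leaf requires a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValidationError(f"GPR {self.op!r} node needs >= 2 children")
        else:
            raise ValidationError(f"unknown GPR op {self.op!r}")

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def score(self, gene_values: dict[str, float], absent: float = 0.0) -> float:
        """Reaction-expression score: OR -> sum, AND -> min of children."""
        if self.op == "gene":
            return float(gene_values.get(self.gene, absent))
        vals = [c.score(gene_values, absent) for c in self.children]
        return float(sum(vals)) if self.op == "or" else float(min(vals))

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = " or " if self.op == "or" else " and "
        return "(" + sep.join(c.to_string() for c in self.children) + ")"

    @staticmethod
    def from_string(rule: str) -> "Gpr | None":
        """Parse a boolean rule string via cobrapy's GPR parser."""
        if rule is None or not rule.strip():
            return None
        from cobra.core.gene import GPR as CobraGPR

        try:
            tree = CobraGPR.from_string(rule)
        except Exception as exc:  # cobra raises several parse error types
            raise FormatError(f"cannot parse GPR rule {rule!r}: {exc}") from exc
        if tree.body is None:
            return None
        return _from_ast(tree.body)


def _from_ast(node: ast.AST) -> Gpr:
    if isinstance(node, ast.Name):
        return Gpr("gene", gene=node.id)
    if isinstance(node, ast.BoolOp):
        op = "or" if isinstance(node.op, ast.Or) else "and"
        kids = tuple(_from_ast(v) for v in node.values)
        return Gpr(op, children=kids)
    if isinstance(node, ast.Expression):
        return _from_ast(node.body)
    raise FormatError(f"unsupported GPR syntax node {type(node).__name__}")


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: empty compartment")


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry (negative = consumed), bounds, GPR."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: Gpr | None = None
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} > "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: set[str] = field(default_factory=set)
    objective: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        rids = [r.id for r in self.reactions]
        if len(set(mids)) != len(mids):
            dup = sorted({x for x in mids if mids.count(x) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        known = set(mids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )
        if self.objective and self.objective not in set(rids):
            raise ValidationError(
                f"objective reaction {self.objective!r} not in model"
            )
        self._rxn_index = {r.id: r for r in self.reactions}
        self.genes = set(self.genes) | {g for r in self.reactions for g in r.genes()}

    # -- editing (returns new model; containers stay lightweight) ----
    def subset(self, reaction_ids: set[str], model_id: str | None = None) -> "MetabolicModel":
        """Sub-model with the given reactions and the metabolites they use."""
        keep = [r for r in self.reactions if r.id in reaction_ids]
        used = {m for r in keep for m in r.stoichiometry}
        mets = [m for m in self.metabolites if m.id in used]
        obj = self.objective if self.objective in reaction_ids else ""
        return MetabolicModel(
            id=model_id or self.id,
            metabolites=mets,
            reactions=keep,
            genes=set(),
            objective=obj,
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        rxns = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds else r
            for r in self.reactions
        ]
        return MetabolicModel(self.id, list(self.metabolites), rxns,
                              set(self.genes), self.objective)


@dataclass
class FluxResult:
    status: str
    objective_value: float
    fluxes: dict[str, float]

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FVAResult:
    min_flux: dict[str, float]
    max_flux: dict[str, float]

    def range(self, rid: str) -> float:
        return self.max_flux[rid] - self.min_flux[rid]

    def center(self, rid: str) -> float:
        return 0.5 * (self.max_flux[rid] + self.min_flux[rid])


# ---------------------------------------------------------------------------
# LP primitives
# ---------------------------------------------------------------------------

def build_lp(model: MetabolicModel) -> LinearProgram:
    """LP with one variable per reaction and S.v = 0 per metabolite."""
    lp = LinearProgram()
    for r in model.reactions:
        lp.add_var(r.id, r.lower_bound, r.upper_bound)
    rows: dict[str, dict[str, float]] = {m.id: {} for m in model.metabolites}
    for r in model.reactions:
        for m, coeff in r.stoichiometry.items():
            rows[m][r.id] = rows[m].get(r.id, 0.0) + coeff
    for m, row in rows.items():
        if row:
            lp.add_eq(row, 0.0)
    return lp


def fba(model: MetabolicModel, objective: str | None = None) -> FluxResult:
    """Maximise the objective reaction's flux at steady state."""
    obj = objective or model.objective
    if not obj:
        raise ValidationError(f"model {model.id!r} has no objective reaction")
    lp = build_lp(model)
    status, value, x = lp.solve({obj: 1.0}, sense="max")
    fluxes = dict(zip(lp.names, x)) if status == OPTIMAL else {}
    return FluxResult(status=status, objective_value=value, fluxes=fluxes)


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 0.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Per-reaction flux min/max with the objective held at a fraction
    of its optimum (fraction 0 probes raw capabilities)."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    lp = build_lp(model)
    if fraction_of_optimum > 0.0:
        sol = fba(model)
        if sol.status != OPTIMAL:
            raise SolverError(
                f"FVA requires an optimal FBA solution, got {sol.status}"
            )
        lb, ub = lp.get_bounds(model.objective)
        target = fraction_of_optimum * sol.objective_value
        # pad by report tolerance so the optimum itself stays feasible
        lp.set_bounds(model.objective, min(target - REPORT_TOL, ub), ub)
    todo = reactions if reactions is not None else model.reaction_ids()
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    for rid in todo:
        st, vmin, _ = lp.solve({rid: 1.0}, sense="min")
        if st != OPTIMAL:
            raise SolverError(f"FVA min LP for {rid!r}: {st}")
        st, vmax, _ = lp.solve({rid: 1.0}, sense="max")
        if st != OPTIMAL:
            raise SolverError(f"FVA max LP for {rid!r}: {st}")
        mins[rid], maxs[rid] = float(min(vmin, vmax)), float(max(vmin, vmax))
    return FVAResult(min_flux=mins, max_flux=maxs)


def find_blocked_reactions(
    model: MetabolicModel, epsilon: float = CONSISTENCY_EPS
) -> set[str]:
    """Reactions that cannot carry |flux| >= epsilon in any feasible state.

    A first LP7-style pass (maximise the number of reactions carrying
    forward flux >= epsilon simultaneously) clears most reactions; the
    rest are settled by individual min/max LPs, so the result is exact.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    unblocked: set[str] = set()
    v = _lp7(model, model.reaction_ids(), epsilon)
    if v is not None:
        unblocked |= {rid for rid, f in v.items() if abs(f) >= 0.99 * epsilon}
    lp = build_lp(model)
    blocked: set[str] = set()
    for r in model.reactions:
        if r.id in unblocked:
            continue
        st, vmax, x = lp.solve({r.id: 1.0}, sense="max")
        if st == UNBOUNDED or (st == OPTIMAL and vmax >= epsilon * (1 - 1e-6)):
            unblocked.add(r.id)
            if st == OPTIMAL:
                unblocked |= {
                    n for n, f in zip(lp.names, x) if abs(f) >= 0.99 * epsilon
                }
            continue
        st, vmin, x = lp.solve({r.id: 1.0}, sense="min")
        if st == UNBOUNDED or (st == OPTIMAL and vmin <= -epsilon * (1 - 1e-6)):
            unblocked.add(r.id)
            if st == OPTIMAL:
                unblocked |= {
                    n for n, f in zip(lp.names, x) if abs(f) >= 0.99 * epsilon
                }
            continue
        blocked.add(r.id)
    return blocked


def _lp7(
    model: MetabolicModel, targets: list[str], epsilon: float
) -> dict[str, float] | None:
    """FASTCORE's LP7: maximise the number of target reactions carrying
    forward flux >= epsilon (soft, via auxiliary variables z in [0, eps],
    z_j <= v_j)."""
    lp = build_lp(model)
    obj: dict[str, float] = {}
    for rid in targets:
        z = f"__z_{rid}"
        lp.add_var(z, 0.0, epsilon)
        lp.add_le({z: 1.0, rid: -1.0}, 0.0)  # z_j - v_j <= 0
        obj[z] = 1.0
    status, _, x = lp.solve(obj, sense="max")
    if status != OPTIMAL:
        return None
    fluxes = dict(zip(lp.names, x))
    return {rid: fluxes[rid] for rid in model.reaction_ids()}


# ---------------------------------------------------------------------------
# I/O: JSON dialect and SBML (via cobrapy)
# ---------------------------------------------------------------------------

def _to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective": model.objective,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
    }


def _from_json_dict(d: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in d["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=Gpr.from_string(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
            )
            for r in d["reactions"]
        ]
    except KeyError as exc:
        raise FormatError(f"JSON model missing required field {exc}") from exc
    return MetabolicModel(
        id=d.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        genes=set(d.get("genes", [])),
        objective=d.get("objective", ""),
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and as a bridge to
    cobrapy's analysis functions in cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    comp_of = {m.id: m.compartment for m in model.metabolites}
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    cm.add_metabolites(list(cmets.values()))
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({cmets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
        if r.subsystem:
            cr.subsystem = r.subsystem
    if model.objective:
        cm.objective = model.objective
    _ = comp_of
    return cm


def from_cobra(cm) -> MetabolicModel:
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "c") for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=Gpr.from_string(r.gene_reaction_rule),
                subsystem=r.subsystem or "",
            )
        )
    objective = ""
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    return MetabolicModel(
        id=cm.id or "model",
        metabolites=mets,
        reactions=rxns,
        genes={g.id for g in cm.genes},
        objective=objective,
    )


def read_model(path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from the JSON dialect or SBML (L3 + fbc bounds)."""
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if fmt == "json":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return _from_json_dict(d)
    if fmt == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(path)
        except Exception as exc:
            raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
        return from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_to_json_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if fmt == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), path)
        return
    raise ValueError(f"unknown model format {fmt!r}")


def steady_state_residual(model: MetabolicModel, fluxes: dict[str, float]) -> float:
    """max_m |sum_r S_mr v_r| — should be ~0 for any valid flux state."""
    worst = 0.0
    acc: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for r in model.reactions:
        v = fluxes.get(r.id, 0.0)
        for m, c in r.stoichiometry.items():
            acc[m] += c * v
    for val in acc.values():
        worst = max(worst, abs(val))
    return worst
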