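"""Stoichiometric models and flux-balance analysis.

A metabolic network with *m* metabolites and *n* reactions is represented
by its stoichiometric matrix ``S`` (m x n).  A feasible steady-state flux
distribution is a vector ``v`` with ``S @ v = 0`` and per-reaction bounds
``lb <= v <= ub``; flux balance analysis (FBA) optimises one reaction's
flux (typically export of a biomass pseudo-metabolite) over that polytope
with a linear program.  Gene knockouts are simulated by constraining the
flux through the affected reactions to zero.

Linear programs are solved with scipy's HiGHS interface.  Only objective
values and flux extrema are contractual: at a degenerate optimum the
returned flux vector is one optimal vertex among many.

Units are declared per model and default to mmol/gDW/h for fluxes and 1/h
for biomass export; no conversion is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .gpr import GeneRule

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "FluxSolution",
    "InfeasibleModelError",
    "solve_fba",
    "flux_extremum",
    "flux_variability",
    "knockout_reaction",
    "knockout_gene",
]

#: mass-balance slack tolerated in a reported optimal solution, per metabolite
MASS_BALANCE_TOL = 1e-6
#: bound violation tolerated in a reported optimal solution
BOUND_TOL = 1e-9
#: relative tolerance used when fixing a reaction at a previously solved optimum
FIX_RTOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """The linear program has no feasible point under the given constraints."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    """One column of S: signed stoichiometry, flux bounds and a gene rule."""

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: GeneRule = field(default_factory=GeneRule)
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.id}: lower bound exceeds upper bound")
        if not self.stoichiometry or any(c == 0 for c in self.stoichiometry.values()):
            raise ValueError(f"{self.id}: stoichiometry must be non-empty with no zeros")
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValueError(f"{self.id}: exchange reactions touch exactly one metabolite")

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


class StoichiometricModel:
    """A metabolic network with declared objective and growth medium.

    The medium maps exchange-reaction ids to maximal uptake fluxes and is
    applied on construction; it can only tighten exchange bounds.
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        objective_reaction: str,
        medium: Optional[Mapping[str, float]] = None,
        name: str = "",
        flux_units: str = "mmol/gDW/h",
    ):
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective_reaction = objective_reaction
        self.medium: Dict[str, float] = dict(medium or {})
        self.name = name
        self.flux_units = flux_units
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._validate()
        if self.medium:
            self._apply_medium()

    # -- construction / validation ------------------------------------
    def _validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        if self.objective_reaction not in self._rxn_index:
            raise ValueError(f"objective reaction {self.objective_reaction!r} not in model")
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in self._met_index:
                    raise ValueError(f"reaction {r.id} references undeclared metabolite {met}")

    def _apply_medium(self) -> None:
        for rid, cap in self.medium.items():
            r = self.get_reaction(rid)
            if not r.is_exchange:
                raise ValueError(f"medium entry {rid} is not an exchange reaction")
            coeff = next(iter(r.stoichiometry.values()))
            if coeff > 0:  # forward flux imports the metabolite
                self._set_reaction(rid, r.with_bounds(r.lower_bound, min(r.upper_bound, cap)))
            else:  # reverse flux imports the metabolite
                self._set_reaction(rid, r.with_bounds(max(r.lower_bound, -cap), r.upper_bound))

    def _set_reaction(self, rid: str, reaction: Reaction) -> None:
        self.reactions[self._rxn_index[rid]] = reaction

    # -- accessors ------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def compartments(self) -> frozenset:
        return frozenset(m.compartment for m in self.metabolites)

    @property
    def genes(self) -> frozenset:
        out = frozenset()
        for r in self.reactions:
            out |= r.gene_rule.genes
        return out

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.name or '<unnamed>'}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction_index(self, rid: str) -> int:
        self.get_reaction(rid)
        return self._rxn_index[rid]

    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[self._met_index[met], j] = coeff
        return S

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- copies and edits ----------------------------------------------
    def copy(self, name: Optional[str] = None) -> "StoichiometricModel":
        m = StoichiometricModel.__new__(StoichiometricModel)
        m.metabolites = list(self.metabolites)
        m.reactions = list(self.reactions)
        m.objective_reaction = self.objective_reaction
        m.medium = dict(self.medium)
        m.name = self.name if name is None else name
        m.flux_units = self.flux_units
        m._met_index = dict(self._met_index)
        m._rxn_index = dict(self._rxn_index)
        return m

    def with_reaction_bounds(self, rid: str, lower: float, upper: float) -> "StoichiometricModel":
        m = self.copy()
        m._set_reaction(rid, m.get_reaction(rid).with_bounds(lower, upper))
        return m

    # -- solution checking ----------------------------------------------
    def check_fluxes(self, fluxes: Mapping[str, float]) -> Tuple[float, float]:
        """Return (max mass-balance residual, max bound violation) of a flux vector."""
        v = np.array([fluxes[r.id] for r in self.reactions])
        S = self.stoichiometric_matrix()
        lb, ub = self.bounds_arrays()
        balance = float(np.max(np.abs(S @ v))) if len(v) else 0.0
        violation = float(max(np.max(lb - v, initial=0.0), np.max(v - ub, initial=0.0)))
        return balance, violation


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------

def _solve_lp(model: StoichiometricModel, c: np.ndarray) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
    """Minimise c @ v over the model's flux polytope."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 0:
        return "optimal", res.x, float(res.fun)
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise RuntimeError(f"LP solver failure: {res.message}")  # pragma: no cover


def solve_fba(model: StoichiometricModel, target: Optional[str] = None, sense: str = "max") -> FluxSolution:
    """Optimise the flux through *target* (default: the model's objective).

    Returns one optimal vertex; at a degenerate optimum only the objective
    value is unique.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    target = model.objective_reaction if target is None else target
    j = model.reaction_index(target)
    c = np.zeros(len(model.reactions))
    c[j] = -1.0 if sense == "max" else 1.0
    status, x, fun = _solve_lp(model, c)
    if status != "optimal":
        return FluxSolution(fluxes={}, objective_value=None, status=status)
    objective = -fun if sense == "max" else fun
    return FluxSolution(
        fluxes=dict(zip(model.reaction_ids, map(float, x))),
        objective_value=objective,
        status="optimal",
    )


def _fix_bounds(value: float, rtol: float) -> Tuple[float, float]:
    lo, hi = value * (1 - rtol), value * (1 + rtol)
    return (min(lo, hi), max(lo, hi))


def _with_fixed(model: StoichiometricModel, fixed: Mapping[str, Tuple[float, float]]) -> StoichiometricModel:
    m = model.copy()
    for rid, (value, rtol) in fixed.items():
        lo, hi = _fix_bounds(value, rtol)
        m._set_reaction(rid, m.get_reaction(rid).with_bounds(lo, hi))
    return m


def flux_extremum(
    model: StoichiometricModel,
    target: str,
    sense: str = "min",
    fixed: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> float:
    """Extremum of *target*'s flux with other reactions fixed at given values.

    ``fixed`` maps reaction ids to ``(value, relative_tolerance)`` pairs; a
    fixed reaction is constrained to the two-sided band ``value * (1 +- tol)``.
    Unlike the flux vector of :func:`solve_fba`, the returned scalar is
    well-defined regardless of LP degeneracy.
    """
    fixed = dict(fixed or {})
    constrained = _with_fixed(model, fixed)
    sol = solve_fba(constrained, target, sense)
    if sol.status == "infeasible":
        blamed = [
            rid
            for rid in fixed
            if solve_fba(_with_fixed(model, {k: v for k, v in fixed.items() if k != rid}), target, sense).optimal
        ]
        detail = f" (relaxing {', '.join(blamed)} restores feasibility)" if blamed else ""
        raise InfeasibleModelError(
            f"fixing {sorted(fixed)} makes model {model.name or '<unnamed>'} infeasible{detail}"
        )
    if sol.status == "unbounded":
        raise InfeasibleModelError(f"{target} is unbounded under the given constraints")
    return sol.objective_value


def flux_variability(
    model: StoichiometricModel,
    reactions: Optional[Iterable[str]] = None,
    fixed: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction [min, max] flux ranges, optionally with reactions fixed."""
    constrained = _with_fixed(model, fixed) if fixed else model
    rids = list(reactions) if reactions is not None else constrained.reaction_ids
    out = {}
    for rid in rids:
        lo = flux_extremum(constrained, rid, "min")
        hi = flux_extremum(constrained, rid, "max")
        out[rid] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------

def knockout_reaction(model: StoichiometricModel, rid: str) -> StoichiometricModel:
    """Copy of *model* with the reaction's flux constrained to zero."""
    model.get_reaction(rid)  # raise early on unknown id
    return model.with_reaction_bounds(rid, 0.0, 0.0)


def knockout_gene(model: StoichiometricModel, genes: Iterable[str]) -> StoichiometricModel:
    """Knock out every reaction whose gene rule fails without *genes*.

    Gene ids absent from the model are ignored with a warning (treated as
    genes acting elsewhere).
    """
    deleted = set(genes)
    unknown = deleted - model.genes
    if unknown:
        warnings.warn(f"gene ids not in model, ignored: {sorted(unknown)}", stacklevel=2)
    out = model.copy()
    for r in model.reactions:
        if not r.gene_rule.is_empty and not r.gene_rule.evaluate(deleted):
            out._set_reaction(r.id, r.with_bounds(0.0, 0.0))
    return out
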