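"""Monoculture FBA and steady-state community growth (SteadyCom-style).

The community problem: each member k has abundance ``X_k >= 0`` and
abundance-scaled fluxes ``V_k,j`` obeying

* per-member mass balance ``S_k . V_k = 0``,
* scaled capacity bounds ``lb_k,j * X_k <= V_k,j <= ub_k,j * X_k``,
* growth coupling ``V_k,biomass = mu * X_k``,
* ``sum_k X_k = 1`` and absolute nutrient bounds on the community
  exchanges ``EX_<met>(u)``.

All members share one growth rate ``mu``; the maximal feasible ``mu`` is
located by bisection on a feasibility LP (maximise ``sum_k X_k`` at fixed
``mu``; ``mu`` is feasible iff the optimum reaches 1).  Because the system
is homogeneous in ``(V, X)`` except for the absolute community-exchange
bounds, any solution with ``sum X >= 1`` can be scaled down to
``sum X = 1``, so capping ``X_k`` keeps the feasibility LP bounded without
changing the test.

Flux variability and all secondary objectives (product maxima, uptake
minimisation, total-flux minimisation) are solved over the same feasible
set with ``mu`` clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import cobra
from optlang import Constraint, Model as OptModel, Objective, Variable

from .community import CommunityModel
from .exceptions import ConfigurationError, InfeasibleError
from .io import biomass_id

__all__ = [
    "CommunitySolution",
    "FluxRange",
    "fba",
    "CommunityLP",
    "solve_steadycom",
    "steadycom_fva",
]

_X_CAP = 2.0  # feasibility-phase abundance cap; see module docstring
_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    minimum: float
    maximum: float


@dataclass
class CommunitySolution:
    """Result of a community growth optimisation.

    ``fluxes`` are community-scaled (mmol per gDW of *total* community
    biomass per hour).  ``member_growth`` maps each member to its biomass
    production rate ``mu * X_k``, the quantity compared against monoculture
    growth for interaction typing and viability.
    """

    mu: float
    abundances: Dict[str, float]
    fluxes: Dict[str, float]
    member_growth: Dict[str, float]

    def to_json(self) -> Dict:
        return {
            "mu": self.mu,
            "abundances": self.abundances,
            "member_growth": self.member_growth,
        }


def fba(model: cobra.Model, objective_id: Optional[str] = None,
        ) -> Tuple[float, Dict[str, float]]:
    """Plain FBA: optimum of an objective reaction plus the flux vector.

    A feasible model with zero attainable objective returns 0, not an
    error; contradictory bounds raise :class:`InfeasibleError`.
    """
    with model as m:
        m.objective = objective_id or biomass_id(m)
        solution = m.optimize()
        if solution.status != "optimal":
            raise InfeasibleError(
                f"FBA on {model.id!r} ended with status {solution.status!r}"
            )
        return solution.objective_value, solution.fluxes.to_dict()


class CommunityLP:
    """Reusable LP over the SteadyCom feasible set of a community model.

    The LP is built once per (community model, bounds) state; callers that
    mutate reaction bounds (knockouts, blocked transfers) rebuild on a
    copied community.  Community-level reactions can be temporarily pinned
    through ``extra_bounds`` without rebuilding.
    """

    def __init__(self, cm: CommunityModel):
        self.cm = cm
        self._mu = 0.0
        prob = OptModel(name=f"steadycom_{cm.model.id}")
        self.v: Dict[str, Variable] = {}
        self.x: Dict[str, Variable] = {}
        member_of = {}
        for member, rids in cm.member_reactions.items():
            for rid in rids:
                member_of[rid] = member

        for rxn in cm.model.reactions:
            if rxn.id in member_of:
                self.v[rxn.id] = Variable(f"v_{rxn.id}")
            else:  # community exchange: absolute bounds
                self.v[rxn.id] = Variable(
                    f"v_{rxn.id}", lb=rxn.lower_bound, ub=rxn.upper_bound
                )
        for member in cm.member_ids:
            self.x[member] = Variable(f"x_{member}", lb=0.0, ub=_X_CAP)

        constraints = []
        for met in cm.model.metabolites:
            terms = {}
            for rxn in met.reactions:
                terms[self.v[rxn.id]] = rxn.metabolites[met]
            c = Constraint(0, lb=0.0, ub=0.0, name=f"mass_{met.id}")
            constraints.append((c, terms))

        self._capacity = {}
        for member, rids in cm.member_reactions.items():
            xk = self.x[member]
            for rid in rids:
                rxn = cm.model.reactions.get_by_id(rid)
                lo = Constraint(0, lb=0.0, name=f"cap_lo_{rid}")
                hi = Constraint(0, ub=0.0, name=f"cap_hi_{rid}")
                constraints.append((lo, {self.v[rid]: 1.0, xk: -rxn.lower_bound}))
                constraints.append((hi, {self.v[rid]: 1.0, xk: -rxn.upper_bound}))
                self._capacity[rid] = (lo, hi)

        self._coupling = {}
        for member, bio in cm.biomass_ids.items():
            c = Constraint(0, lb=0.0, ub=0.0, name=f"grow_{member}")
            constraints.append((c, {self.v[bio]: 1.0, self.x[member]: 0.0}))
            self._coupling[member] = c

        self._sumx = Constraint(0, name="sum_x")
        constraints.append(
            (self._sumx, {x: 1.0 for x in self.x.values()})
        )

        prob.add(list(self.v.values()) + list(self.x.values()))
        prob.add([c for c, _ in constraints])
        prob.update()
        for c, terms in constraints:
            c.set_linear_coefficients(terms)
        self.prob = prob
        self._objective_vars: Tuple[Variable, ...] = ()
        self._abs_vars: Dict[str, Variable] = {}

    # -- state ---------------------------------------------------------------

    def set_mu(self, mu: float) -> None:
        if mu == self._mu:
            return
        for member, c in self._coupling.items():
            c.set_linear_coefficients({self.x[member]: -mu})
        self._mu = mu

    def fix_total_abundance(self, total: Optional[float]) -> None:
        """Pin sum(X) to ``total`` (or release when None)."""
        self._sumx.lb = total
        self._sumx.ub = total

    def _set_objective(self, coefficients: Mapping[Variable, float],
                       direction: str) -> None:
        self.prob.objective = Objective(0, direction=direction)
        self.prob.update()
        self.prob.objective.set_linear_coefficients(dict(coefficients))
        self._objective_vars = tuple(coefficients)

    def _optimize(self) -> str:
        return self.prob.optimize()

    # -- queries -------------------------------------------------------------

    def max_total_abundance(self, mu: float) -> float:
        """Optimum of sum(X) at fixed mu (feasibility phase; X capped)."""
        self.set_mu(mu)
        self.fix_total_abundance(None)
        self._set_objective({x: 1.0 for x in self.x.values()}, "max")
        status = self._optimize()
        if status != "optimal":
            return 0.0
        return float(self.prob.objective.value)

    def optimize(
        self,
        mu: float,
        objective: Mapping[str, float],
        direction: str = "max",
        extra_bounds: Optional[Mapping[str, Tuple[Optional[float],
                                                  Optional[float]]]] = None,
    ) -> Tuple[str, float, Dict[str, float], Dict[str, float]]:
        """Optimise a linear flux objective at fixed mu with sum(X) = 1.

        ``objective`` maps reaction ids to coefficients; an empty mapping
        solves a pure feasibility problem.  ``extra_bounds`` temporarily
        overrides variable bounds of community-level reactions.

        Returns (status, objective value, fluxes, abundances).
        """
        self.set_mu(mu)
        self.fix_total_abundance(1.0)
        saved = {}
        if extra_bounds:
            for rid, (lb, ub) in extra_bounds.items():
                var = self.v[rid]
                saved[rid] = (var.lb, var.ub)
                var.lb, var.ub = lb, ub
        try:
            self._set_objective(
                {self.v[rid]: c for rid, c in objective.items()}, direction
            )
            status = self._optimize()
            if status != "optimal":
                return status, float("nan"), {}, {}
            value = float(self.prob.objective.value)
            fluxes = {rid: var.primal for rid, var in self.v.items()}
            abundances = {m: var.primal for m, var in self.x.items()}
            return status, value, fluxes, abundances
        finally:
            for rid, (lb, ub) in saved.items():
                var = self.v[rid]
                var.lb, var.ub = lb, ub

    def parsimonious_fluxes(
        self,
        mu: float,
        extra_bounds: Optional[Mapping[str, Tuple[Optional[float],
                                                  Optional[float]]]] = None,
    ) -> Tuple[str, Dict[str, float], Dict[str, float]]:
        """Feasible fluxes at fixed mu minimising total member |flux|.

        Deterministic representative of the (often degenerate) solution set,
        used for flux profiles in enforced-objective scanning.
        """
        if not self._abs_vars:
            additions = []
            links = []
            for member, rids in self.cm.member_reactions.items():
                for rid in rids:
                    t = Variable(f"t_{rid}", lb=0.0)
                    self._abs_vars[rid] = t
                    up = Constraint(0, lb=0.0, name=f"abs_up_{rid}")
                    dn = Constraint(0, lb=0.0, name=f"abs_dn_{rid}")
                    additions.extend([up, dn])
                    links.append((up, {t: 1.0, self.v[rid]: -1.0}))
                    links.append((dn, {t: 1.0, self.v[rid]: 1.0}))
            self.prob.add(list(self._abs_vars.values()))
            self.prob.add(additions)
            self.prob.update()
            for c, terms in links:
                c.set_linear_coefficients(terms)
        self.set_mu(mu)
        self.fix_total_abundance(1.0)
        saved = {}
        if extra_bounds:
            for rid, (lb, ub) in extra_bounds.items():
                var = self.v[rid]
                saved[rid] = (var.lb, var.ub)
                var.lb, var.ub = lb, ub
        try:
            self._set_objective(
                {t: 1.0 for t in self._abs_vars.values()}, "min"
            )
            status = self._optimize()
            if status != "optimal":
                return status, {}, {}
            fluxes = {rid: var.primal for rid, var in self.v.items()}
            abundances = {m: var.primal for m, var in self.x.items()}
            return status, fluxes, abundances
        finally:
            for rid, (lb, ub) in saved.items():
                var = self.v[rid]
                var.lb, var.ub = lb, ub


def solve_steadycom(
    cm: CommunityModel,
    mu_tolerance: float = 1e-6,
    mu_bracket: Tuple[float, float] = (0.0, 50.0),
    lp: Optional[CommunityLP] = None,
    parsimonious: bool = True,
) -> CommunitySolution:
    """Maximise community growth by bisection on the feasibility LP.

    With ``parsimonious`` (default) the reported flux vector is the
    minimum-total-|flux| representative of the optimal face, which makes
    downstream single-solution analyses (cross-feeding, scan baselines)
    deterministic; abundances and growth are unaffected.

    Raises
    ------
    InfeasibleError
        If not even zero growth is feasible (e.g. maintenance cannot be
        met on the applied medium).
    ConfigurationError
        If growth is still feasible at the top of the bracket, indicating
        missing substrate caps.
    """
    lp = lp or CommunityLP(cm)
    lo, hi = mu_bracket

    def feasible(mu: float) -> bool:
        return lp.max_total_abundance(mu) >= 1.0 - _FEAS_TOL

    if not feasible(lo):
        raise InfeasibleError(
            f"community {cm.model.id!r}: no feasible growth state at mu={lo}"
        )
    if feasible(hi):
        raise ConfigurationError(
            f"community {cm.model.id!r}: growth feasible at mu={hi}; "
            "substrate uptake appears uncapped"
        )
    while hi - lo > mu_tolerance:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    mu = lo

    status, _, fluxes, abundances = lp.optimize(mu, {}, "max")
    if status != "optimal":
        # numerically marginal at the bracket edge; back off slightly
        mu *= 1.0 - 1e-9
        status, _, fluxes, abundances = lp.optimize(mu, {}, "max")
        if status != "optimal":
            raise InfeasibleError(
                f"community {cm.model.id!r}: LP {status} at bisection optimum"
            )
    if parsimonious:
        pstatus, pfluxes, pabundances = lp.parsimonious_fluxes(mu)
        if pstatus == "optimal":
            fluxes, abundances = pfluxes, pabundances
    member_growth = {m: mu * abundances[m] for m in cm.member_ids}
    return CommunitySolution(
        mu=mu, abundances=abundances, fluxes=fluxes,
        member_growth=member_growth,
    )


def steadycom_fva(
    cm: CommunityModel,
    reaction_id: str,
    mu_fixed: float,
    lp: Optional[CommunityLP] = None,
) -> FluxRange:
    """Min/max flux of one reaction over the feasible set at clamped mu."""
    lp = lp or CommunityLP(cm)
    for attempt_mu in (mu_fixed, mu_fixed * (1.0 - 1e-6)):
        results = []
        for direction in ("min", "max"):
            status, value, _, _ = lp.optimize(
                attempt_mu, {reaction_id: 1.0}, direction
            )
            if status != "optimal":
                results = None
                break
            results.append(value)
        if results is not None:
            return FluxRange(reaction_id, results[0], results[1])
    raise InfeasibleError(
        f"FVA for {reaction_id!r} infeasible at mu={mu_fixed}"
    )
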