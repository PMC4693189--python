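"""Linear-programming layer: solve the diurnal FBA problem and derive
reported quantities (transition biomass composition, per-phase fluxes).

All LPs are solved with HiGHS via ``scipy.optimize.linprog``; the solver
is deterministic for a fixed problem, so repeated runs on identical
inputs give identical solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .diurnal_core import EXPORT, PHASE, TRANSFER, ExtendedProblem, phase_fluxes
from .model_io import DiurnalConfig, MetabolicNetwork

FEASIBILITY_RTOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


class SolverFailure(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


@dataclass
class DiuSolution:
    """A solved diurnal FBA instance.

    ``delta_c`` is the full extended variable vector (concentration
    changes); ``transfers`` maps each carry-over species to the amount
    moved light -> dark (negative means dark -> light); ``exports`` maps
    each exportable species to the amount removed from the cycle;
    ``fluxes`` holds the recovered per-phase flux vectors.
    """

    status: str
    objective_value: float | None
    delta_c: np.ndarray | None
    transfers: dict[str, float] = field(default_factory=dict)
    exports: dict[str, float] = field(default_factory=dict)
    fluxes: dict[str, np.ndarray] = field(default_factory=dict)
    problem: ExtendedProblem | None = field(default=None, repr=False)

    def mass_balance_residual(self) -> float:
        """Infinity norm of the steady-state residual, relative to the
        solution magnitude."""
        if self.delta_c is None or self.problem is None:
            return float("nan")
        res = np.abs(self.problem.S_ext @ self.delta_c).max() if \
            self.problem.S_ext.shape[0] else 0.0
        return float(res / max(1.0, np.abs(self.delta_c).max()))


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds, method="highs")


def solve_diufba(problem: ExtendedProblem,
                 secondary: str = "none") -> DiuSolution:
    """Maximize ``w . v`` subject to the extended steady state and bounds.

    With ``secondary="min_total_flux"`` a second LP minimizes the total
    absolute concentration change at the fixed optimal objective value,
    selecting a parsimonious representative among alternate optima.
    Infeasibility and unboundedness are reported in ``status``, never
    raised.
    """
    if secondary not in {"none", "min_total_flux"}:
        raise ValueError(f"unknown secondary objective {secondary!r}")
    n = problem.n_cols
    bounds = list(zip(problem.v_lb, problem.v_ub))
    b_eq = np.zeros(problem.S_ext.shape[0])
    res = _solve_lp(-problem.w, problem.S_ext, b_eq, bounds)
    status = _STATUS.get(res.status, "solver_failure")
    if status in {"infeasible", "unbounded"}:
        return DiuSolution(status=status, objective_value=None, delta_c=None,
                           problem=problem)
    if status != "optimal":
        raise SolverFailure(
            f"HiGHS returned status {res.status} ({res.message}); "
            f"residual info: {getattr(res, 'con', None)}")
    v = res.x
    obj = float(problem.w @ v)

    if secondary == "min_total_flux":
        # variables [v, t]; minimize sum(t) s.t. steady state, w.v = obj,
        # and -t <= v <= t
        A_eq_v = sp.vstack([problem.S_ext, sp.csr_matrix(problem.w)])
        A_eq2 = sp.hstack([A_eq_v, sp.csc_matrix((A_eq_v.shape[0], n))],
                          format="csc")
        b_eq2 = np.concatenate([b_eq, [obj]])
        eye = sp.eye(n, format="csc")
        A_ub = sp.bmat([[eye, -eye], [-eye, -eye]], format="csc")
        b_ub = np.zeros(2 * n)
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        bounds2 = bounds + [(0, None)] * n
        res2 = _solve_lp(c2, A_eq2, b_eq2, bounds2, A_ub=A_ub, b_ub=b_ub)
        if res2.status == 0:
            v = res2.x[:n]
            obj = float(problem.w @ v)

    transfers, exports = {}, {}
    for j, entry in enumerate(problem.col_map):
        if entry[0] == TRANSFER:
            transfers[entry[1]] = float(v[j])
        elif entry[0] == EXPORT:
            exports[entry[1]] = float(v[j])
    sol = DiuSolution(status="optimal", objective_value=obj, delta_c=v,
                      transfers=transfers, exports=exports,
                      fluxes=phase_fluxes(v, problem), problem=problem)
    resid = sol.mass_balance_residual()
    if resid > FEASIBILITY_RTOL:
        raise SolverFailure(
            f"optimal solution violates mass balance: relative residual {resid:.3e}")
    return sol


def fba_single_phase(network: MetabolicNetwork,
                     bound_overrides: dict[str, tuple[float, float]] | None = None,
                     objective: dict[str, float] | None = None
                     ) -> tuple[np.ndarray | None, float | None, str]:
    """Classical single-phase FBA: maximize the objective over S v = 0.

    ``objective`` maps reaction id -> weight; if omitted the network's own
    objective coefficients are used.  Returns ``(fluxes, objective_value,
    status)``.
    """
    lb = network.lb.copy()
    ub = network.ub.copy()
    for rid, (lo, hi) in (bound_overrides or {}).items():
        j = network.reaction_index(rid)
        lb[j], ub[j] = lo, hi
    w = network.objective_coeffs.copy()
    if objective is not None:
        w = np.zeros(network.n_reactions)
        for rid, weight in objective.items():
            w[network.reaction_index(rid)] = weight
    res = _solve_lp(-w, network.stoich, np.zeros(network.n_species),
                    list(zip(lb, ub)))
    status = _STATUS.get(res.status, "solver_failure")
    if status in {"infeasible", "unbounded"}:
        return None, None, status
    if status != "optimal":
        raise SolverFailure(f"HiGHS returned status {res.status} ({res.message})")
    return res.x, float(w @ res.x), "optimal"


@dataclass
class BiomassComposition:
    """Biomass composition at the light -> dark transition.

    Functional components are counted by their net production during the
    light phase; storage components by the amount transferred into the
    dark phase.  Fractions are computed over the combined total.
    """

    amounts: dict[str, float]
    fractions: dict[str, float]
    labels: dict[str, str]  # species -> "functional" | "storage"

    @property
    def functional_fraction(self) -> float:
        return sum(f for sid, f in self.fractions.items()
                   if self.labels[sid] == "functional")

    @property
    def storage_fraction(self) -> float:
        return sum(f for sid, f in self.fractions.items()
                   if self.labels[sid] == "storage")


def transition_composition(solution: DiuSolution, config: DiurnalConfig,
                           component_labels: dict[str, str]) -> BiomassComposition:
    """Biomass composition at the day/night transition.

    The amount of each functional component is its net light-phase
    production (accumulated storage of viable biomass); the amount of each
    storage component is the value of its transfer column.  The labels map
    is ``species_id -> "functional" | "storage"`` and is a reporting
    classification only — both kinds are carry-over species at the matrix
    level.
    """
    if solution.status != "optimal" or solution.delta_c is None:
        raise ValueError("transition composition requires an optimal solution")
    problem = solution.problem
    network = problem.network
    bad = set(component_labels.values()) - {"functional", "storage"}
    if bad:
        raise ValueError(f"labels must be 'functional' or 'storage', got {sorted(bad)}")

    r = network.n_reactions
    light_cols = [j for j, e in enumerate(problem.col_map)
                  if e[0] == PHASE and e[1] == 0]
    dc_light = solution.delta_c[light_cols]
    net_light_production = network.stoich @ dc_light  # per species, length s

    amounts: dict[str, float] = {}
    for sid, label in component_labels.items():
        if label == "functional":
            amounts[sid] = float(net_light_production[network.species_index(sid)])
        else:
            amounts[sid] = float(solution.transfers.get(sid, 0.0))
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("total transition biomass is zero; fractions undefined")
    fractions = {sid: a / total for sid, a in amounts.items()}
    return BiomassComposition(amounts=amounts, fractions=fractions,
                              labels=dict(component_labels))
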