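"""Balance testing by linear programming.

A complex C_j is balanced iff the net flux through it, e_j^T A v, is zero
for every steady-state flux v in F(G) = {v : Y A v = 0, v_l <= v <= v_u}.
This module minimises and maximises that net flux (the primal pair), solves
the corresponding Lagrange duals explicitly (a zero optimum of both duals is
an equivalent certificate, by strong duality), and runs flux-variability
scans for blocked and fixated reactions.

All problems are solved with scipy's HiGHS backend.  Optima are compared to
zero at a tolerance scaled by the largest absolute stoichiometric
coefficient of the network, so that rescaling a model's stoichiometry does
not silently change the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .crn import CRN, FluxBounds

#: default tolerance on LP optima (applied after stoichiometric scaling)
DEFAULT_TOL = 1e-8

OPTIMAL = "optimal"
UNBOUNDED = "unbounded"
INFEASIBLE = "infeasible"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


class InfeasibleModelError(RuntimeError):
    """The steady-state flux set is empty (contradictory non-canonical bounds)."""


class NumericalInconsistencyError(RuntimeError):
    """Primal, dual or factorization verdicts disagree beyond tolerance."""


@dataclass
class LPOutcome:
    status: str
    value: Optional[float]
    x: Optional[np.ndarray]


@dataclass
class BalanceResult:
    """Per-complex outcome of the balance test (class label added later)."""

    complex_index: int
    formula: str
    min_opt: Optional[float]
    max_opt: Optional[float]
    status_min: str
    status_max: str
    balanced: bool
    class_label: Optional[str] = None
    certificate: Optional[dict] = None
    flags: list[str] = field(default_factory=list)


def stoich_scale(crn: CRN) -> float:
    """max(1, largest |Y| entry) -- the scale on which optima are compared."""
    if crn.n == 0:
        return 1.0
    top = max((float(c) for ms in crn.complexes for c in ms.values()), default=1.0)
    return max(1.0, top)


def _solve(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None) -> LPOutcome:
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    status = _STATUS.get(res.status, INFEASIBLE)
    if status == OPTIMAL:
        return LPOutcome(OPTIMAL, float(res.fun), np.asarray(res.x))
    return LPOutcome(status, None, None)


def feasibility_lp(A_eq, b_eq, A_ub=None, b_ub=None, bounds=None, nvar=None) -> LPOutcome:
    """Zero-objective LP; any feasible point is returned as a certificate."""
    if nvar is None:
        nvar = np.shape(A_eq)[1]
    return _solve(np.zeros(nvar), A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)


def net_flux_extrema(
    crn: CRN, bounds: FluxBounds, j: int
) -> tuple[Optional[float], Optional[float], tuple[str, str], tuple[Optional[np.ndarray], Optional[np.ndarray]]]:
    """Optima of min / max e_j^T A v over the steady-state flux set.

    Returns (min_opt, max_opt, (status_min, status_max), (v_min, v_max));
    an unbounded or infeasible direction reports value None with the
    corresponding status.
    """
    if not 0 <= j < crn.n:
        raise IndexError(f"complex index {j} out of range")
    if bounds.r != crn.r:
        raise ValueError("bounds dimension does not match reaction count")
    c = crn.A[j, :]
    N = crn.N
    box = list(zip(bounds.lb, bounds.ub))
    lo = _solve(c, A_eq=N, b_eq=np.zeros(crn.m), bounds=box)
    hi = _solve(-c, A_eq=N, b_eq=np.zeros(crn.m), bounds=box)
    hi_val = -hi.value if hi.value is not None else None
    return lo.value, hi_val, (lo.status, hi.status), (lo.x, hi.x)


def is_balanced(crn: CRN, bounds: FluxBounds, j: int, tol: float = DEFAULT_TOL) -> bool:
    """True iff both net-flux optima at complex j exist and are ~0.

    An unbounded net flux means not balanced; an empty feasible set raises
    :class:`InfeasibleModelError` (the definition quantifies over F(G); we
    refuse to call vacuous balance "balanced" silently).
    """
    lo, hi, (s1, s2), _ = net_flux_extrema(crn, bounds, j)
    if INFEASIBLE in (s1, s2):
        raise InfeasibleModelError("empty steady-state flux set")
    if UNBOUNDED in (s1, s2):
        return False
    eps = tol * stoich_scale(crn)
    return abs(lo) <= eps and abs(hi) <= eps


def balance_result(crn: CRN, bounds: FluxBounds, j: int, tol: float = DEFAULT_TOL) -> BalanceResult:
    lo, hi, (s1, s2), _ = net_flux_extrema(crn, bounds, j)
    if INFEASIBLE in (s1, s2):
        raise InfeasibleModelError("empty steady-state flux set")
    eps = tol * stoich_scale(crn)
    balanced = (
        s1 == OPTIMAL and s2 == OPTIMAL and abs(lo) <= eps and abs(hi) <= eps
    )
    return BalanceResult(
        complex_index=j,
        formula=crn.complex_formula(j),
        min_opt=lo,
        max_opt=hi,
        status_min=s1,
        status_max=s2,
        balanced=balanced,
    )


def _dual_problem(crn: CRN, bounds: FluxBounds, j: int, sign: int) -> tuple[LPOutcome, dict]:
    """One dual problem: sign=+1 duals the minimisation, -1 the maximisation.

    Variables are (zeta, lambda_u, lambda_l); a lambda component multiplying
    an infinite bound is pinned to zero (dual feasibility for an absent
    constraint), which keeps the objective finite in unbounded regimes.
    Constraint:  sign * A^T e_j - A^T Y^T zeta + lambda_u - lambda_l = 0.
    Objective :  maximize lambda_l^T v_l - lambda_u^T v_u.
    """
    m, r = crn.m, crn.r
    At = crn.A.T
    AtYt = At @ crn.Y.T
    aj = At[:, j]
    nvar = m + 2 * r
    A_eq = np.hstack([-AtYt, np.eye(r), -np.eye(r)])
    b_eq = -sign * aj
    lo = np.concatenate([np.full(m, -np.inf), np.zeros(2 * r)])
    hi = np.full(nvar, np.inf)
    c = np.zeros(nvar)
    vl, vu = np.asarray(bounds.lb), np.asarray(bounds.ub)
    for k in range(r):
        if np.isinf(vu[k]):
            hi[m + k] = 0.0  # lambda_u,k := 0
        else:
            c[m + k] = vu[k]  # minimize -(−λu·vu) → +vu in min form
        if np.isneginf(vl[k]):
            hi[m + r + k] = 0.0  # lambda_l,k := 0
        else:
            c[m + r + k] = -vl[k]
    out = _solve(c, A_eq=A_eq, b_eq=b_eq, bounds=list(zip(lo, hi)))
    wit = {}
    if out.x is not None:
        wit = {
            "zeta": out.x[:m],
            "lambda_u": out.x[m : m + r],
            "lambda_l": out.x[m + r :],
        }
        out = LPOutcome(out.status, -out.value, out.x)  # back to max form
    return out, wit


def dual_balance_check(
    crn: CRN, bounds: FluxBounds, j: int, tol: float = DEFAULT_TOL
) -> tuple[bool, dict]:
    """Balance verdict from the two dual LPs; must agree with is_balanced.

    Returns (flag, witnesses) where witnesses holds the (zeta, lambda_u,
    lambda_l) vectors of each direction when the duals are solvable.  A dual
    that is infeasible corresponds to an unbounded primal net flux (not
    balanced); an unbounded dual corresponds to an empty flux set and raises.
    """
    out_min, wit_min = _dual_problem(crn, bounds, j, sign=+1)
    out_max, wit_max = _dual_problem(crn, bounds, j, sign=-1)
    if UNBOUNDED in (out_min.status, out_max.status):
        raise InfeasibleModelError("dual unbounded: empty steady-state flux set")
    eps = tol * stoich_scale(crn)
    flag = (
        out_min.status == OPTIMAL
        and out_max.status == OPTIMAL
        and abs(out_min.value) <= eps
        and abs(out_max.value) <= eps
    )
    witnesses = {
        "min_direction": {"status": out_min.status, "value": out_min.value, **wit_min},
        "max_direction": {"status": out_max.status, "value": out_max.value, **wit_max},
    }
    return flag, witnesses


def flux_variability(
    crn: CRN, bounds: FluxBounds, k: int
) -> tuple[Optional[float], Optional[float], tuple[str, str]]:
    """Min and max of v_k over the steady-state flux set."""
    c = np.zeros(crn.r)
    c[k] = 1.0
    box = list(zip(bounds.lb, bounds.ub))
    N = crn.N
    lo = _solve(c, A_eq=N, b_eq=np.zeros(crn.m), bounds=box)
    hi = _solve(-c, A_eq=N, b_eq=np.zeros(crn.m), bounds=box)
    if INFEASIBLE in (lo.status, hi.status):
        raise InfeasibleModelError("empty steady-state flux set")
    hi_val = -hi.value if hi.value is not None else None
    return lo.value, hi_val, (lo.status, hi.status)


def blocked_reactions(crn: CRN, bounds: FluxBounds, tol: float = DEFAULT_TOL) -> set[int]:
    """Reactions forced to zero flux everywhere in the steady-state flux set."""
    blocked = set()
    for k in range(crn.r):
        lo, hi, (s1, s2) = flux_variability(crn, bounds, k)
        if s1 == OPTIMAL and s2 == OPTIMAL and abs(lo) <= tol and abs(hi) <= tol:
            blocked.add(k)
    return blocked


def fixated_reactions(
    crn: CRN, bounds: FluxBounds, tol: float = DEFAULT_TOL
) -> dict[int, float]:
    """Reactions carrying one fixed flux value everywhere; maps k -> value.

    Blocked reactions appear with value 0 (a blocked reaction is one fixated
    at zero).
    """
    fixed: dict[int, float] = {}
    for k in range(crn.r):
        lo, hi, (s1, s2) = flux_variability(crn, bounds, k)
        if s1 == OPTIMAL and s2 == OPTIMAL and hi - lo <= tol:
            f = 0.5 * (lo + hi)
            fixed[k] = 0.0 if abs(f) <= tol else f
    return fixed
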