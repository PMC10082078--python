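"""The four nested factorizations and the class label of each balanced complex.

A balanced complex (BC) can arise from four increasingly general mechanisms,
each expressed as a feasibility problem over the complex indicator e_j:

  strictly stoichiometric   e_j = Y^T zeta                        (stoichiometry)
  stoichiometric            e_j = Y^T zeta + U xi                 (+ linkage)
  type-I nonstoichiometric  the theta-relaxed pair with
                            A_rev^T theta = 0, A_irr^T theta >= 0 (+ irreversibility)
  type-II nonstoichiometric the dual pair with bound-weighted
                            complementarity terms                 (+ bound values)

Each solution set contains the previous one; in a canonical flux regime the
type-I problem captures exactly the balanced complexes, and the type-II
problem does so in any regime.  The first two problems are pure linear
systems and are decided by exact rational elimination; the last two are LP
feasibility problems solved in floating point, with every returned witness
re-verified by direct substitution before it is reported.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from . import _ratlin
from .crn import CRN, FluxBounds, LinkageStructure, linkage_classes
from .lp import (
    DEFAULT_TOL,
    OPTIMAL,
    BalanceResult,
    InfeasibleModelError,
    NumericalInconsistencyError,
    balance_result,
    feasibility_lp,
)

# class labels
STRICTLY_STOICHIOMETRIC = "strictly_stoichiometric"
STOICHIOMETRIC = "stoichiometric"
TYPE_I = "type_I_nonstoichiometric"
TYPE_II = "type_II_nonstoichiometric"
NOT_BALANCED = "not_balanced"

CLASS_LABELS = (STRICTLY_STOICHIOMETRIC, STOICHIOMETRIC, TYPE_I, TYPE_II, NOT_BALANCED)

#: residual threshold for re-verifying float LP certificates
EPS_EXACT = 1e-9


def _e(n: int, j: int) -> list[Fraction]:
    v = [Fraction(0)] * n
    v[j] = Fraction(1)
    return v


def strict_factorization(crn: CRN, j: int) -> Optional[dict]:
    """Strictly stoichiometric factorization: e_j = Y^T zeta.

    Decided exactly over the rationals; returns {"kind": "strict",
    "zeta": ...} on success, None when e_j is outside the row space of Y.
    """
    Yt = [list(col) for col in zip(*crn.Y_exact)] if crn.m else [[] for _ in range(crn.n)]
    zeta = _ratlin.solve(Yt, _e(crn.n, j))
    if zeta is None:
        return None
    return {"kind": "strict", "zeta": zeta}


def stoich_factorization(crn: CRN, linkage: LinkageStructure, j: int) -> Optional[dict]:
    """Stoichiometric factorization: e_j = Y^T zeta + U xi (exact)."""
    Y_exact, U_exact = crn.Y_exact, linkage.U_exact
    M = [
        [Y_exact[i][row] for i in range(crn.m)] + list(U_exact[row])
        for row in range(crn.n)
    ]
    sol = _ratlin.solve(M, _e(crn.n, j))
    if sol is None:
        return None
    return {"kind": "stoichiometric", "zeta": sol[: crn.m], "xi": sol[crn.m :]}


def _split_incidence(crn: CRN, bounds: FluxBounds) -> tuple[np.ndarray, np.ndarray]:
    A = crn.A
    rev = sorted(bounds.rev)
    irr = sorted(bounds.irr)
    return A[:, rev], A[:, irr]


def type1_factorization(
    crn: CRN,
    linkage: LinkageStructure,
    bounds: FluxBounds,
    j: int,
    tol: float = DEFAULT_TOL,
) -> Optional[dict]:
    """Type-I (irreversibility-aware) factorization as an LP feasibility test.

    Finds zeta_1, zeta_2, xi_1, xi_2, theta_1, theta_2 with

        e_j = Y^T zeta_1 + U xi_1 + theta_1,
        e_j = Y^T zeta_2 + U xi_2 - theta_2,
        A_rev^T theta_t = 0,   A_irr^T theta_t >= 0   (t = 1, 2).

    The equivalence with balance holds under a canonical flux regime; the
    test itself only uses the reversible/irreversible split, so it can be
    run (as an advisory) in any regime.
    """
    m, n, ell = crn.m, crn.n, linkage.ell
    Yt, U = crn.Y.T, linkage.U
    A_rev, A_irr = _split_incidence(crn, bounds)
    nvar = 2 * m + 2 * ell + 2 * n
    # variable layout: zeta1 zeta2 xi1 xi2 theta1 theta2
    z1, z2 = slice(0, m), slice(m, 2 * m)
    x1, x2 = slice(2 * m, 2 * m + ell), slice(2 * m + ell, 2 * m + 2 * ell)
    t1, t2 = slice(2 * m + 2 * ell, 2 * m + 2 * ell + n), slice(
        2 * m + 2 * ell + n, nvar
    )

    ej = np.zeros(n)
    ej[j] = 1.0
    rows = []
    rhs = []
    for t_sl, z_sl, x_sl, sgn in ((t1, z1, x1, +1.0), (t2, z2, x2, -1.0)):
        block = np.zeros((n, nvar))
        block[:, z_sl] = Yt
        block[:, x_sl] = U
        block[:, t_sl] = sgn * np.eye(n)
        rows.append(block)
        rhs.append(ej)
    for t_sl in (t1, t2):
        if A_rev.shape[1]:
            block = np.zeros((A_rev.shape[1], nvar))
            block[:, t_sl] = A_rev.T
            rows.append(block)
            rhs.append(np.zeros(A_rev.shape[1]))
    A_eq = np.vstack(rows)
    b_eq = np.concatenate(rhs)
    A_ub = b_ub = None
    if A_irr.shape[1]:
        ubs = []
        for t_sl in (t1, t2):
            block = np.zeros((A_irr.shape[1], nvar))
            block[:, t_sl] = -A_irr.T
            ubs.append(block)
        A_ub = np.vstack(ubs)
        b_ub = np.zeros(A_ub.shape[0])
    out = feasibility_lp(A_eq, b_eq, A_ub, b_ub, bounds=[(None, None)] * nvar)
    if out.status != OPTIMAL:
        return None
    x = out.x
    cert = {
        "kind": "type_I",
        "zeta1": x[z1],
        "zeta2": x[z2],
        "xi1": x[x1],
        "xi2": x[x2],
        "theta1": x[t1],
        "theta2": x[t2],
    }
    resid = verify_type1_certificate(crn, linkage, bounds, j, cert)
    if resid > EPS_EXACT * max(1.0, float(np.abs(x).max())):
        raise NumericalInconsistencyError(
            f"type-I certificate for complex {j} failed re-verification "
            f"(residual {resid:.2e})"
        )
    cert["residual"] = resid
    return cert


def verify_type1_certificate(
    crn: CRN,
    linkage: LinkageStructure,
    bounds: FluxBounds,
    j: int,
    cert: dict,
) -> float:
    """Max violation of the type-I constraint blocks by direct substitution."""
    Yt, U = crn.Y.T, linkage.U
    A_rev, A_irr = _split_incidence(crn, bounds)
    ej = np.zeros(crn.n)
    ej[j] = 1.0
    th1 = np.asarray(cert["theta1"], dtype=float)
    th2 = np.asarray(cert["theta2"], dtype=float)
    r1 = Yt @ np.asarray(cert["zeta1"], dtype=float) + U @ np.asarray(
        cert["xi1"], dtype=float
    ) + th1 - ej
    r2 = Yt @ np.asarray(cert["zeta2"], dtype=float) + U @ np.asarray(
        cert["xi2"], dtype=float
    ) - th2 - ej
    worst = max(np.abs(r1).max(), np.abs(r2).max())
    for th in (th1, th2):
        if A_rev.shape[1]:
            worst = max(worst, np.abs(A_rev.T @ th).max())
        if A_irr.shape[1]:
            worst = max(worst, float(-(A_irr.T @ th).min()), 0.0)
    return float(worst)


def type2_factorization(
    crn: CRN, bounds: FluxBounds, j: int, tol: float = DEFAULT_TOL
) -> Optional[dict]:
    """Type-II (bound-value-dependent) factorization as an LP feasibility test.

    Finds zeta_1, zeta_2 and nonnegative multipliers with

        A^T e_j = A^T Y^T zeta_1 + lambda_l1 - lambda_u1,
        v_l^T lambda_l1 - v_u^T lambda_u1 = 0,
        A^T e_j = A^T Y^T zeta_2 + lambda_u2 - lambda_l2,
        v_l^T lambda_l2 - v_u^T lambda_u2 = 0.

    A multiplier attached to an infinite bound is pinned to zero, which is
    the dual-feasibility convention for an absent constraint.  Feasibility
    is equivalent to balance in any flux regime.
    """
    m, r = crn.m, crn.r
    At = crn.A.T
    AtYt = At @ crn.Y.T
    aj = At[:, j]
    vl, vu = np.asarray(bounds.lb), np.asarray(bounds.ub)
    # layout: zeta1 zeta2 | ll1 lu1 ll2 lu2
    nvar = 2 * m + 4 * r
    z1, z2 = slice(0, m), slice(m, 2 * m)
    ll1 = slice(2 * m, 2 * m + r)
    lu1 = slice(2 * m + r, 2 * m + 2 * r)
    ll2 = slice(2 * m + 2 * r, 2 * m + 3 * r)
    lu2 = slice(2 * m + 3 * r, 2 * m + 4 * r)

    A_eq = np.zeros((2 * r + 2, nvar))
    b_eq = np.zeros(2 * r + 2)
    A_eq[:r, z1] = AtYt
    A_eq[:r, ll1] = np.eye(r)
    A_eq[:r, lu1] = -np.eye(r)
    b_eq[:r] = aj
    A_eq[r : 2 * r, z2] = AtYt
    A_eq[r : 2 * r, lu2] = np.eye(r)
    A_eq[r : 2 * r, ll2] = -np.eye(r)
    b_eq[r : 2 * r] = aj
    # complementarity rows (finite bounds only; pinned variables contribute 0)
    for k in range(r):
        if not np.isneginf(vl[k]):
            A_eq[2 * r, ll1.start + k] = vl[k]
            A_eq[2 * r + 1, ll2.start + k] = vl[k]
        if not np.isinf(vu[k]):
            A_eq[2 * r, lu1.start + k] = -vu[k]
            A_eq[2 * r + 1, lu2.start + k] = -vu[k]

    box: list[tuple[Optional[float], Optional[float]]] = [(None, None)] * (2 * m)
    for _sl, is_lower in ((ll1, True), (lu1, False), (ll2, True), (lu2, False)):
        for k in range(r):
            pin = (is_lower and np.isneginf(vl[k])) or (not is_lower and np.isinf(vu[k]))
            box.append((0.0, 0.0) if pin else (0.0, None))
    out = feasibility_lp(A_eq, b_eq, bounds=box)
    if out.status != OPTIMAL:
        return None
    x = out.x
    cert = {
        "kind": "type_II",
        "zeta1": x[z1],
        "zeta2": x[z2],
        "lambda_l1": x[ll1],
        "lambda_u1": x[lu1],
        "lambda_l2": x[ll2],
        "lambda_u2": x[lu2],
    }
    resid = verify_type2_certificate(crn, bounds, j, cert)
    scale = max(1.0, float(np.abs(x).max()), *(abs(v) for v in vl if np.isfinite(v)),
                *(abs(v) for v in vu if np.isfinite(v)))
    if resid > EPS_EXACT * scale:
        raise NumericalInconsistencyError(
            f"type-II certificate for complex {j} failed re-verification "
            f"(residual {resid:.2e})"
        )
    cert["residual"] = resid
    return cert


def verify_type2_certificate(
    crn: CRN, bounds: FluxBounds, j: int, cert: dict
) -> float:
    """Max violation of the type-II constraint blocks by direct substitution."""
    At = crn.A.T
    AtYt = At @ crn.Y.T
    aj = At[:, j]
    vl, vu = np.asarray(bounds.lb), np.asarray(bounds.ub)
    ll1 = np.asarray(cert["lambda_l1"], dtype=float)
    lu1 = np.asarray(cert["lambda_u1"], dtype=float)
    ll2 = np.asarray(cert["lambda_l2"], dtype=float)
    lu2 = np.asarray(cert["lambda_u2"], dtype=float)
    z1 = np.asarray(cert["zeta1"], dtype=float)
    z2 = np.asarray(cert["zeta2"], dtype=float)
    fin_l = np.where(np.isneginf(vl), 0.0, vl)
    fin_u = np.where(np.isinf(vu), 0.0, vu)
    worst = 0.0
    worst = max(worst, float(np.abs(AtYt @ z1 + ll1 - lu1 - aj).max(initial=0.0)))
    worst = max(worst, float(np.abs(AtYt @ z2 + lu2 - ll2 - aj).max(initial=0.0)))
    worst = max(worst, abs(float(fin_l @ ll1 - fin_u @ lu1)))
    worst = max(worst, abs(float(fin_l @ ll2 - fin_u @ lu2)))
    for lam, pinned in (
        (ll1, np.isneginf(vl)),
        (lu1, np.isinf(vu)),
        (ll2, np.isneginf(vl)),
        (lu2, np.isinf(vu)),
    ):
        worst = max(worst, float((-lam).max(initial=0.0)))  # nonnegativity
        if pinned.any():
            worst = max(worst, float(np.abs(lam[pinned]).max(initial=0.0)))
    return worst


def _jsonable(cert: Optional[dict]) -> Optional[dict]:
    if cert is None:
        return None
    out = {}
    for key, val in cert.items():
        if isinstance(val, np.ndarray):
            out[key] = [float(x) for x in val]
        elif isinstance(val, list) and val and isinstance(val[0], Fraction):
            out[key] = [str(x) for x in val]
        elif isinstance(val, Fraction):
            out[key] = str(val)
        else:
            out[key] = val
    return out


def classify(
    crn: CRN, bounds: FluxBounds, tol: float = DEFAULT_TOL
) -> list[BalanceResult]:
    """Balance test plus class label and certificate for every complex.

    Labels are assigned by the first feasible factorization in the nesting
    order (strict, stoichiometric, type-I, type-II); a balanced complex for
    which even the type-II test reports infeasible trips a
    NumericalInconsistencyError, because the type-II problem is equivalent
    to balance.  With an empty steady-state flux set every complex is
    reported not balanced and flagged "infeasible_model".
    """
    linkage = linkage_classes(crn)
    canonical = bounds.canonical
    results: list[BalanceResult] = []
    empty_classes = {
        linkage.class_of(j) for j, ms in enumerate(crn.complexes) if not ms
    }
    try:
        base = [balance_result(crn, bounds, j, tol) for j in range(crn.n)]
    except InfeasibleModelError:
        for j in range(crn.n):
            res = BalanceResult(
                complex_index=j,
                formula=crn.complex_formula(j),
                min_opt=None,
                max_opt=None,
                status_min="infeasible",
                status_max="infeasible",
                balanced=False,
                class_label=NOT_BALANCED,
            )
            res.flags.append("infeasible_model")
            results.append(res)
        return results

    for res in base:
        j = res.complex_index
        if not res.balanced:
            res.class_label = NOT_BALANCED
            results.append(res)
            continue
        cert = strict_factorization(crn, j)
        if cert is not None:
            res.class_label = STRICTLY_STOICHIOMETRIC
        else:
            cert = stoich_factorization(crn, linkage, j)
            if cert is not None:
                res.class_label = STOICHIOMETRIC
            else:
                cert = type1_factorization(crn, linkage, bounds, j, tol)
                if cert is not None:
                    res.class_label = TYPE_I
                    if not canonical:
                        res.flags.append("type_I_assigned_in_noncanonical_regime")
                else:
                    cert = type2_factorization(crn, bounds, j, tol)
                    if cert is None:
                        raise NumericalInconsistencyError(
                            f"complex {j} is balanced by LP but the type-II "
                            "factorization reports infeasible"
                        )
                    res.class_label = TYPE_II
        if linkage.class_of(j) in empty_classes:
            res.flags.append("linkage_class_contains_empty_complex")
        res.certificate = _jsonable(cert)
        results.append(res)
    return results


def class_counts(results: Sequence[BalanceResult]) -> dict[str, int]:
    counts = {label: 0 for label in CLASS_LABELS}
    for res in results:
        counts[res.class_label or NOT_BALANCED] += 1
    return counts
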