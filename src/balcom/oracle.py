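"""Brute-force verification layer for small networks.

For a canonical unbounded flux regime the steady-state flux set is a
polyhedral cone generated by the elementary flux modes (support-minimal
kernel vectors of N respecting irreversibility).  Enumerating them exactly
over the rationals gives an independent decision procedure for balance:
a complex is balanced iff its net flux vanishes on every generator.  The
enumeration is exhaustive over reaction supports and is intended for desk
scale (r <= ~14), as a cross-check of the LP layer, never as the primary
detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Sequence

from . import _ratlin
from .crn import CRN, FluxBounds

DEFAULT_SUPPORT_CAP = 14


@dataclass(frozen=True)
class ConeGenerators:
    """Exact extreme rays / elementary flux modes of the steady-state cone."""

    generators: tuple[tuple[Fraction, ...], ...]
    r: int

    def __len__(self) -> int:
        return len(self.generators)


def _normalize(v: list[Fraction]) -> tuple[Fraction, ...]:
    scale = None
    for x in v:
        if x != 0:
            scale = abs(x)
            break
    if scale is None:
        return tuple(v)
    return tuple(x / scale for x in v)


def enumerate_elementary_modes(
    crn: CRN, bounds: FluxBounds, cap: int = DEFAULT_SUPPORT_CAP
) -> ConeGenerators:
    """All elementary flux modes of {v : N v = 0, v_irr >= 0}, exactly.

    A support S carries an elementary mode iff the kernel of N restricted to
    S is one-dimensional with a nowhere-zero generator; the generator (and
    its negation, when the support is sign-feasible in both directions) is
    emitted.  Support-minimality is automatic: a kernel vector of smaller
    support would contradict the one-dimensionality.

    Requires the canonical unbounded regime (the cone description) and
    r <= cap.
    """
    if not (bounds.canonical and bounds.unbounded):
        raise ValueError("elementary-mode oracle requires a canonical unbounded regime")
    if crn.r > cap:
        raise ValueError(f"reaction count {crn.r} exceeds oracle cap {cap}")
    N = crn.N_exact
    irr = bounds.irr
    gens: list[tuple[Fraction, ...]] = []
    seen: set[tuple[Fraction, ...]] = set()
    for size in range(1, crn.r + 1):
        for support in combinations(range(crn.r), size):
            sub = [[N[i][k] for k in support] for i in range(crn.m)]
            kernel = _ratlin.nullspace(sub, ncols=size)
            if len(kernel) != 1:
                continue
            g = kernel[0]
            if any(x == 0 for x in g):
                continue  # true support is smaller; handled at its own size
            full = [Fraction(0)] * crn.r
            for pos, k in enumerate(support):
                full[k] = g[pos]
            for cand in (full, [-x for x in full]):
                if all(cand[k] > 0 for k in irr if cand[k] != 0):
                    key = _normalize(cand)
                    if key not in seen:
                        seen.add(key)
                        gens.append(key)
    return ConeGenerators(tuple(gens), crn.r)


def oracle_is_balanced(generators: ConeGenerators, crn: CRN, j: int) -> bool:
    """Exact balance decision: e_j^T A g = 0 for every cone generator."""
    row = crn.A_exact[j]
    return all(
        sum(row[k] * g[k] for k in range(crn.r)) == 0 for g in generators.generators
    )


def oracle_blocked_reactions(generators: ConeGenerators) -> set[int]:
    """Reactions with zero flux in every generator (hence in the whole cone)."""
    blocked = set(range(generators.r))
    for g in generators.generators:
        blocked -= {k for k in range(generators.r) if g[k] != 0}
    return blocked


def check_counterexample_flux(
    crn: CRN, bounds: FluxBounds, v: Sequence, j: int
) -> tuple[bool, bool, Fraction]:
    """Evaluate a candidate flux vector exactly.

    Returns (is_steady, within_bounds, net_flux_at_j): whether N v = 0,
    whether v_l <= v <= v_u entrywise, and the exact value of e_j^T A v.
    """
    if len(v) != crn.r:
        raise ValueError(f"flux vector has length {len(v)}, expected {crn.r}")
    vv = [Fraction(x) for x in v]
    N = crn.N_exact
    is_steady = all(
        sum(N[i][k] * vv[k] for k in range(crn.r)) == 0 for i in range(crn.m)
    )
    within = all(
        (bounds.lb[k] == float("-inf") or Fraction(bounds.lb[k]) <= vv[k])
        and (bounds.ub[k] == float("inf") or vv[k] <= Fraction(bounds.ub[k]))
        for k in range(crn.r)
    )
    row = crn.A_exact[j]
    net = sum(row[k] * vv[k] for k in range(crn.r))
    return is_steady, within, net
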