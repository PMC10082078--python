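"""Exact linear algebra over the rationals.

Small, dependency-free Gaussian elimination used wherever a rank/membership
decision must not hinge on a floating-point tolerance: deciding whether a
complex indicator lies in the row space of the stoichiometric map (and its
extension by linkage indicators), and enumerating exact kernel vectors for
the brute-force oracle.  Matrices are lists of lists of fractions.Fraction;
sizes here are desk-scale (tens of rows/columns), so clarity wins over speed.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

Mat = list[list[Fraction]]
Vec = list[Fraction]


def _as_fraction_matrix(M: Sequence[Sequence]) -> Mat:
    return [[Fraction(x) for x in row] for row in M]


def rref(M: Sequence[Sequence]) -> tuple[Mat, list[int]]:
    """Reduced row echelon form; returns (R, pivot column indices)."""
    R = _as_fraction_matrix(M)
    if not R:
        return R, []
    nrows, ncols = len(R), len(R[0])
    pivots: list[int] = []
    row = 0
    for col in range(ncols):
        if row >= nrows:
            break
        piv = next((i for i in range(row, nrows) if R[i][col] != 0), None)
        if piv is None:
            continue
        R[row], R[piv] = R[piv], R[row]
        inv = R[row][col]
        R[row] = [x / inv for x in R[row]]
        for i in range(nrows):
            if i != row and R[i][col] != 0:
                f = R[i][col]
                R[i] = [a - f * b for a, b in zip(R[i], R[row])]
        pivots.append(col)
        row += 1
    return R, pivots


def rank(M: Sequence[Sequence]) -> int:
    return len(rref(M)[1])


def solve(M: Sequence[Sequence], b: Sequence) -> Optional[Vec]:
    """One exact solution x of M x = b, or None if the system is inconsistent.

    Free variables are set to zero, so the returned solution is the minimal
    certificate produced by back-substitution on the pivot columns.
    """
    A = _as_fraction_matrix(M)
    bb = [Fraction(x) for x in b]
    if not A:
        return [] if all(x == 0 for x in bb) else None
    ncols = len(A[0])
    aug = [row + [rhs] for row, rhs in zip(A, bb)]
    R, pivots = rref(aug)
    # inconsistent iff a pivot lands in the RHS column
    if pivots and pivots[-1] == ncols:
        return None
    x: Vec = [Fraction(0)] * ncols
    for i, col in enumerate(pivots):
        x[col] = R[i][ncols]
    return x


def nullspace(M: Sequence[Sequence], ncols: Optional[int] = None) -> list[Vec]:
    """Exact basis of the right kernel of M."""
    A = _as_fraction_matrix(M)
    if ncols is None:
        ncols = len(A[0]) if A else 0
    if not A:
        return [[Fraction(int(i == j)) for i in range(ncols)] for j in range(ncols)]
    R, pivots = rref(A)
    free = [c for c in range(ncols) if c not in pivots]
    basis: list[Vec] = []
    for f in free:
        v = [Fraction(0)] * ncols
        v[f] = Fraction(1)
        for i, col in enumerate(pivots):
            v[col] = -R[i][f]
        basis.append(v)
    return basis
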