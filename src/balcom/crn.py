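"""Complex-level representation of a chemical reaction network.

A network is a triple (species, complexes, reactions): complexes are
multisets of species (the substrate or product side of a reaction) and each
reaction is an ordered pair of complex indices.  The module builds the three
standard matrices

    Y : m x n  stoichiometric map (column j = composition of complex j),
    A : n x r  incidence matrix (one -1 at the substrate, +1 at the product),
    N = Y A : m x r stoichiometry matrix,

with exact rational entries, plus the linkage-class structure (connected
components of the undirected complex graph) whose indicator matrix U spans
the left nullspace of A.

Reversible reactions occupy a single signed column of A; the reversible /
irreversible split lives in FluxBounds, not in the incidence structure.  By
convention no two columns of A or of N may be collinear, and a reaction may
not have identical substrate and product complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np

from ._ratlin import Mat

Number = Union[int, float, str, Fraction]
Multiset = dict[str, Fraction]

#: canonical text for the empty (exchange) complex
EMPTY_COMPLEX_SYMBOL = "∅"


def _normalize_multiset(ms: Mapping[str, Number]) -> Multiset:
    out: Multiset = {}
    for sp, coeff in ms.items():
        c = Fraction(coeff)
        if c < 0:
            raise ValueError(f"negative coefficient {coeff} for species {sp!r}")
        if c != 0:
            out[str(sp)] = c
    return out


def _complex_key(ms: Multiset) -> tuple:
    return tuple(sorted(ms.items()))


def format_complex(ms: Mapping[str, Fraction]) -> str:
    """Human-readable complex formula, e.g. ``A + 2 B`` (``∅`` when empty)."""
    if not ms:
        return EMPTY_COMPLEX_SYMBOL
    parts = []
    for sp, c in sorted(ms.items()):
        parts.append(sp if c == 1 else f"{c} {sp}")
    return " + ".join(parts)


@dataclass(frozen=True)
class CRN:
    """A chemical reaction network at the complex level."""

    species: tuple[str, ...]
    complexes: tuple[Multiset, ...]
    reactions: tuple[tuple[int, int], ...]

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def n(self) -> int:
        return len(self.complexes)

    @property
    def r(self) -> int:
        return len(self.reactions)

    # --- exact matrices -------------------------------------------------
    @property
    def Y_exact(self) -> Mat:
        idx = {sp: i for i, sp in enumerate(self.species)}
        Y = [[Fraction(0)] * self.n for _ in range(self.m)]
        for j, ms in enumerate(self.complexes):
            for sp, c in ms.items():
                Y[idx[sp]][j] = c
        return Y

    @property
    def A_exact(self) -> Mat:
        A = [[Fraction(0)] * self.r for _ in range(self.n)]
        for k, (sub, prod) in enumerate(self.reactions):
            A[sub][k] -= 1
            A[prod][k] += 1
        return A

    @property
    def N_exact(self) -> Mat:
        Y, A = self.Y_exact, self.A_exact
        return [
            [sum(Y[i][j] * A[j][k] for j in range(self.n)) for k in range(self.r)]
            for i in range(self.m)
        ]

    # --- float views for the LP layer -----------------------------------
    @property
    def Y(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.Y_exact])

    @property
    def A(self) -> np.ndarray:
        A = np.zeros((self.n, self.r))
        for k, (sub, prod) in enumerate(self.reactions):
            A[sub, k] -= 1.0
            A[prod, k] += 1.0
        return A

    @property
    def N(self) -> np.ndarray:
        return self.Y @ self.A

    def complex_formula(self, j: int) -> str:
        return format_complex(self.complexes[j])

    def complex_index(self, ms: Mapping[str, Number]) -> int:
        """Index of the complex equal (as an exact multiset) to ``ms``."""
        key = _complex_key(_normalize_multiset(ms))
        for j, c in enumerate(self.complexes):
            if _complex_key(c) == key:
                return j
        raise KeyError(f"no such complex: {format_complex(_normalize_multiset(ms))}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CRN(m={self.m}, n={self.n}, r={self.r})"


@dataclass(frozen=True)
class FluxBounds:
    """Lower/upper flux bounds; the reversibility split is derived from them.

    A reaction is irreversible iff its lower bound is nonnegative.  The
    regime is *canonical* when every irreversible lower bound is exactly
    zero, and *unbounded* when additionally no finite bound constrains the
    network (ub = +inf everywhere, lb = -inf on reversible reactions).
    """

    lb: tuple[float, ...]
    ub: tuple[float, ...]

    def __post_init__(self):
        if len(self.lb) != len(self.ub):
            raise ValueError("lb and ub must have equal length")
        for k, (lo, hi) in enumerate(zip(self.lb, self.ub)):
            if lo > hi:
                raise ValueError(f"reaction {k}: lb {lo} > ub {hi}")
            if not hi > 0:
                raise ValueError(f"reaction {k}: upper bound must be positive, got {hi}")

    @classmethod
    def canonical_unbounded(cls, reversible: Sequence[bool]) -> "FluxBounds":
        lb = tuple(-np.inf if rev else 0.0 for rev in reversible)
        ub = tuple(np.inf for _ in reversible)
        return cls(lb, ub)

    @property
    def r(self) -> int:
        return len(self.lb)

    @property
    def irr(self) -> frozenset[int]:
        return frozenset(k for k, lo in enumerate(self.lb) if lo >= 0)

    @property
    def rev(self) -> frozenset[int]:
        return frozenset(range(self.r)) - self.irr

    @property
    def canonical(self) -> bool:
        return all(self.lb[k] == 0 for k in self.irr)

    @property
    def unbounded(self) -> bool:
        return all(np.isinf(u) for u in self.ub) and all(
            np.isneginf(self.lb[k]) for k in self.rev
        )

    @property
    def reversible_flags(self) -> tuple[bool, ...]:
        irr = self.irr
        return tuple(k not in irr for k in range(self.r))

    def subset(self, keep: Sequence[int]) -> "FluxBounds":
        return FluxBounds(
            tuple(self.lb[k] for k in keep), tuple(self.ub[k] for k in keep)
        )

    def scaled(self, factor: float) -> "FluxBounds":
        if factor <= 0:
            raise ValueError("scaling factor must be positive")
        return FluxBounds(
            tuple(lo * factor for lo in self.lb),
            tuple(hi * factor for hi in self.ub),
        )


@dataclass(frozen=True)
class LinkageStructure:
    """Partition of complexes into linkage classes with indicator matrix U."""

    classes: tuple[tuple[int, ...], ...]
    n: int

    @property
    def ell(self) -> int:
        return len(self.classes)

    @property
    def U_exact(self) -> Mat:
        U = [[Fraction(0)] * self.ell for _ in range(self.n)]
        for l, cls in enumerate(self.classes):
            for j in cls:
                U[j][l] = Fraction(1)
        return U

    @property
    def U(self) -> np.ndarray:
        U = np.zeros((self.n, self.ell))
        for l, cls in enumerate(self.classes):
            for j in cls:
                U[j, l] = 1.0
        return U

    def class_of(self, j: int) -> int:
        for l, cls in enumerate(self.classes):
            if j in cls:
                return l
        raise IndexError(j)


ReactionTriple = tuple[Mapping[str, Number], Mapping[str, Number], bool]


def build_crn(reactions: Iterable[ReactionTriple]) -> CRN:
    """Construct a CRN from (substrate, product, reversible) triples.

    Complexes are enumerated in first-appearance order (substrate before
    product, reactions in input order); duplicate multisets map to the same
    complex index.  The reversible flag does not enter the incidence
    structure (a reversible reaction is a single signed column) -- use
    :func:`canonical_bounds` or :class:`FluxBounds` to carry it.

    Raises ``ValueError`` for a reaction whose two sides are the same
    multiset (zero incidence column), for a duplicate unordered complex
    pair (collinear columns of A), and for collinear columns of N.
    """
    complexes: list[Multiset] = []
    index: dict[tuple, int] = {}
    pairs: list[tuple[int, int]] = []
    seen_pairs: set[frozenset[int]] = set()

    def intern(ms: Mapping[str, Number]) -> int:
        norm = _normalize_multiset(ms)
        key = _complex_key(norm)
        if key not in index:
            index[key] = len(complexes)
            complexes.append(norm)
        return index[key]

    for k, (sub, prod, _reversible) in enumerate(reactions):
        i, j = intern(sub), intern(prod)
        if i == j:
            raise ValueError(
                f"reaction {k}: substrate and product are the same complex "
                f"({format_complex(complexes[i])}); zero incidence column"
            )
        pair = frozenset((i, j))
        if pair in seen_pairs:
            raise ValueError(
                f"reaction {k}: duplicate reaction between complexes "
                f"{format_complex(complexes[i])} and {format_complex(complexes[j])}"
            )
        seen_pairs.add(pair)
        pairs.append((i, j))

    species = sorted({sp for ms in complexes for sp in ms})
    crn = CRN(tuple(species), tuple(complexes), tuple(pairs))
    _check_no_collinear_n_columns(crn)
    return crn


def _check_no_collinear_n_columns(crn: CRN) -> None:
    N = crn.N_exact
    cols = [tuple(N[i][k] for i in range(crn.m)) for k in range(crn.r)]
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            if _collinear(cols[a], cols[b]):
                raise ValueError(
                    f"columns {a} and {b} of N are collinear; the convention "
                    "requires reversible reactions as single columns and no "
                    "duplicated conversions"
                )


def _collinear(u: Sequence[Fraction], v: Sequence[Fraction]) -> bool:
    # u, v are nonzero (guaranteed: distinct complexes on each reaction give
    # nonzero A columns, but N columns can vanish only for stoichiometrically
    # silent conversions, which we treat as collinear with everything).
    if all(x == 0 for x in u) or all(x == 0 for x in v):
        return True
    ratio: Optional[Fraction] = None
    for a, b in zip(u, v):
        if a == 0 and b == 0:
            continue
        if a == 0 or b == 0:
            return False
        q = a / b
        if ratio is None:
            ratio = q
        elif q != ratio:
            return False
    return True


def canonical_bounds(reactions: Iterable[ReactionTriple]) -> FluxBounds:
    """Canonical unbounded FluxBounds from the reversible flags of triples."""
    return FluxBounds.canonical_unbounded([bool(rev) for _, _, rev in reactions])


def build_network(reactions: Sequence[ReactionTriple]) -> tuple[CRN, FluxBounds]:
    """Convenience: CRN plus canonical unbounded bounds in one call."""
    return build_crn(reactions), canonical_bounds(reactions)


def linkage_classes(crn: CRN) -> LinkageStructure:
    """Connected components of the undirected complex graph.

    Classes are ordered by their smallest complex index, members ascending,
    so the structure is deterministic for a given CRN.
    """
    g = nx.Graph()
    g.add_nodes_from(range(crn.n))
    g.add_edges_from(crn.reactions)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return LinkageStructure(tuple(comps), crn.n)


def remove_blocked(
    crn: CRN, bounds: FluxBounds, blocked: Iterable[int]
) -> tuple[CRN, FluxBounds]:
    """Drop the given reactions; prune complexes left with no reaction.

    Complex indices are re-derived (first-appearance order over the kept
    reactions); the linkage structure must be recomputed by the caller.
    """
    blocked = set(blocked)
    if not blocked <= set(range(crn.r)):
        raise ValueError("blocked set contains invalid reaction indices")
    keep = [k for k in range(crn.r) if k not in blocked]
    triples = [
        (crn.complexes[crn.reactions[k][0]], crn.complexes[crn.reactions[k][1]], False)
        for k in keep
    ]
    return build_crn(triples), bounds.subset(keep)
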