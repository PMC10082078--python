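"""Built-in toy networks and a seeded random-network generator.

The four named fixtures reproduce the small illustration networks used to
exercise every balance class.  Their figures are published only as diagrams,
so the edge lists here are reconstructions frozen as code constants; each
one was checked against all printed anchors simultaneously (species /
complex / reaction counts, the complex ordering and U matrix of the type-I
example, its printed factorization certificate, the printed counterexample
flux vector, and the identity of the blocked irreversible pair).  The
expected class-label maps are asserted end-to-end by the test suite.
"""

from __future__ import annotations

import random
from fractions import Fraction
from typing import Optional

from .crn import CRN, FluxBounds, build_crn, canonical_bounds
from .factorize import (
    NOT_BALANCED,
    STOICHIOMETRIC,
    STRICTLY_STOICHIOMETRIC,
    TYPE_I,
)

FIXTURE_NAMES = ("fig1b", "fig2", "fig3", "fig4")
FIG3_VARIANTS = ("base", "dashed", "dotted")

# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

# Unique-species network: complex B contains a species found nowhere else,
# so it is balanced for any kinetics (synthetic reconstruction; the source
# figure prints no edge list, only the highlighted balanced complex).
_FIG1B = [
    ({"A": 2}, {"B": 1}, False),
    ({"B": 1}, {"A": 1, "C": 1}, False),
    ({"A": 1, "C": 1}, {"C": 2}, True),
]

# Three pairwise-linked complexes in one linkage class; the species S makes
# a unimolecular appearance in two of them, which balances the class.
_FIG2 = [
    ({"S": 1}, {"S": 1, "P": 1}, True),
    ({"S": 1, "P": 1}, {"P": 2}, True),
    ({"P": 2}, {"S": 1}, True),
]

# m=5, n=7, r=6 base network, two reversible reactions.  Balanced: A+B and
# 2B (strictly stoichiometric), 2C and C+D (stoichiometric).  The dashed
# reaction stays within a linkage class (all four BCs survive); the dotted
# reaction merges the two classes (only the strict pair survives).
_FIG3_BASE = [
    ({"A": 1, "B": 1}, {"B": 2}, True),
    ({"B": 2}, {"D": 1, "E": 1}, True),
    ({"B": 2}, {"E": 2}, False),
    ({"B": 2}, {"D": 2}, False),
    ({"D": 1, "E": 1}, {"E": 2}, False),
    ({"C": 2}, {"C": 1, "D": 1}, False),
]
_FIG3_DASHED = ({"A": 1, "B": 1}, {"D": 1, "E": 1}, False)
_FIG3_DOTTED = ({"D": 1, "E": 1}, {"C": 2}, False)

# m=6, n=9, r=8 network; complexes ordered (A+B, A+C, C+D, C+E, C+F, B+D,
# 2E, 2F, 2A); the two irreversible reactions (A+C -> C+D and B+D -> 2E,
# the "brown" pair) are blocked, and 2A is the unique balanced complex
# (type-I nonstoichiometric).
_FIG4 = [
    ({"A": 1, "B": 1}, {"A": 1, "C": 1}, True),
    ({"A": 1, "C": 1}, {"C": 1, "D": 1}, False),
    ({"C": 1, "D": 1}, {"C": 1, "E": 1}, True),
    ({"C": 1, "F": 1}, {"B": 1, "D": 1}, True),
    ({"B": 1, "D": 1}, {"E": 2}, False),
    ({"E": 2}, {"F": 2}, True),
    ({"A": 1, "C": 1}, {"A": 2}, True),
    ({"A": 1, "B": 1}, {"A": 2}, True),
]

#: printed type-I certificate for the 2A complex of fig4 (species order
#: A..F, classes ordered {C1..C4, C9}, {C5..C8})
FIG4_PRINTED_CERTIFICATE = {
    "zeta1": [1, 0, 0, 0, 0, 0],
    "zeta2": [1, 0, 0, 1, 1, 1],
    "xi1": [-1, 0],
    "xi2": [-1, -1],
    "theta1": [0, 0, 1, 1, 0, 0, 0, 0, 0],
    "theta2": [0, 0, 0, 0, 0, 0, 1, 1, 0],
}

#: printed counterexample flux for fig4 in this package's reaction order
#: (nonzero on C1->C2, C2->C3, C5->C6, C6->C7, C7->C8, C2->C9)
FIG4_COUNTEREXAMPLE_FLUX = [1, -1, 0, 2, 1, 1, -1, 0]


def _expected(labels: dict[int, str], n: int) -> dict[int, str]:
    return {j: labels.get(j, NOT_BALANCED) for j in range(n)}


def make_fixture(
    name: str, variant: Optional[str] = None
) -> tuple[CRN, FluxBounds, dict[int, str]]:
    """Construct a named fixture.

    Returns (crn, bounds, expected) where expected maps every complex index
    to its class label.  ``variant`` applies to fig3 only (base, dashed,
    dotted; default base).
    """
    if name == "fig1b":
        triples = list(_FIG1B)
        labels = {1: STRICTLY_STOICHIOMETRIC}
    elif name == "fig2":
        triples = list(_FIG2)
        labels = {0: STOICHIOMETRIC, 1: STOICHIOMETRIC, 2: STOICHIOMETRIC}
    elif name == "fig3":
        variant = variant or "base"
        if variant not in FIG3_VARIANTS:
            raise ValueError(f"unknown fig3 variant {variant!r}")
        triples = list(_FIG3_BASE)
        if variant == "dashed":
            triples.append(_FIG3_DASHED)
        elif variant == "dotted":
            triples.append(_FIG3_DOTTED)
        labels = {0: STRICTLY_STOICHIOMETRIC, 1: STRICTLY_STOICHIOMETRIC}
        if variant != "dotted":
            labels.update({5: STOICHIOMETRIC, 6: STOICHIOMETRIC})
    elif name == "fig4":
        if variant is not None:
            raise ValueError("fig4 has no variants")
        triples = list(_FIG4)
        labels = {8: TYPE_I}
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    crn = build_crn(triples)
    return crn, canonical_bounds(triples), _expected(labels, crn.n)


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------


def random_crn(
    seed: int,
    m: int = 5,
    n_per_class: int = 4,
    classes: int = 2,
    extra_edges: int = 1,
    p_reversible: float = 0.5,
    max_attempts: int = 200,
) -> tuple[CRN, FluxBounds]:
    """Seeded random network in a canonical unbounded regime.

    Complexes are random multisets (1-3 species, coefficients 1-2); each
    linkage class is a uniform random spanning tree over its complexes plus
    ``extra_edges`` random chords; reaction reversibility is i.i.d. with
    probability ``p_reversible``.  Duplicate complexes, duplicate reactions
    and collinear stoichiometry columns are avoided by rejection sampling,
    so the output is always a valid network; the construction is
    deterministic for a given seed.
    """
    if n_per_class < 1 or classes < 1 or m < 1:
        raise ValueError("degenerate generator parameters")
    rng = random.Random(seed)
    species = [f"S{i+1}" for i in range(m)]
    for _ in range(max_attempts):
        try:
            triples = _sample_triples(
                rng, species, n_per_class, classes, extra_edges, p_reversible
            )
            crn = build_crn(triples)
        except ValueError:
            continue
        return crn, canonical_bounds(triples)
    raise RuntimeError("could not sample a valid network; relax the parameters")


def _sample_triples(rng, species, n_per_class, classes, extra_edges, p_reversible):
    def sample_complex(existing: set) -> dict[str, Fraction]:
        for _ in range(100):
            k = rng.randint(1, min(3, len(species)))
            chosen = rng.sample(species, k)
            ms = {sp: Fraction(rng.randint(1, 2)) for sp in chosen}
            key = tuple(sorted(ms.items()))
            if key not in existing:
                existing.add(key)
                return ms
        raise ValueError("complex sampling exhausted")

    existing: set = set()
    triples = []
    for _ in range(classes):
        members = [sample_complex(existing) for _ in range(n_per_class)]
        edges: set[frozenset[int]] = set()
        # random spanning tree: attach each node to a random earlier node
        for idx in range(1, len(members)):
            other = rng.randrange(idx)
            edges.add(frozenset((other, idx)))
            triples.append((members[other], members[idx], rng.random() < p_reversible))
        budget = extra_edges
        guard = 0
        while budget > 0 and guard < 50 and len(members) >= 2:
            a, b = rng.sample(range(len(members)), 2)
            guard += 1
            if frozenset((a, b)) in edges:
                continue
            edges.add(frozenset((a, b)))
            triples.append((members[a], members[b], rng.random() < p_reversible))
            budget -= 1
    return triples


# ---------------------------------------------------------------------------
# planted motifs
# ---------------------------------------------------------------------------

MOTIFS = ("trivial", "linkage", "type1", "type2")

# 4-cycle over two species with every flux pinned to 1: each complex is
# balanced only because of the bound values (type-II); all four reactions
# are irreversible with a positive lower bound (non-canonical regime) and
# fixated at that bound.
_TYPE2_COMPLEXES = [
    {"P": 1},
    {"Q": 1},
    {"P": 2, "Q": 1},
    {"P": 1, "Q": 3},
]


def plant_motif(
    crn: CRN, bounds: FluxBounds, motif: str, seed: int = 0
) -> tuple[CRN, FluxBounds, int]:
    """Append a motif with a known balance class to a host network.

    Motif species are renamed until fresh, so the planted component cannot
    interact with the host stoichiometry.  Returns the augmented network,
    the augmented bounds, and the index of the complex whose expected class
    matches the motif name (trivial -> strictly stoichiometric, linkage ->
    stoichiometric, type1 -> type-I, type2 -> type-II).  Other complexes may
    gain or keep balance; only the planted index is guaranteed.
    """
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}")
    host = set(crn.species)

    def fresh(base: str) -> str:
        name = base
        tag = 0
        while name in host:
            tag += 1
            name = f"{base}_{tag}"
        host.add(name)
        return name

    host_triples = [
        (crn.complexes[sub], crn.complexes[prod], rev)
        for (sub, prod), rev in zip(crn.reactions, bounds.reversible_flags)
    ]

    extra_lb: list[float] = []
    extra_ub: list[float] = []
    if motif == "trivial":
        t, w = fresh("T"), fresh("W")
        motif_triples = [({t: 1}, {w: 1}, True)]
        planted = {t: 1}
    elif motif == "linkage":
        s, p = fresh("S"), fresh("P")
        motif_triples = [
            ({s: 1}, {s: 1, p: 1}, True),
            ({s: 1, p: 1}, {p: 2}, True),
            ({p: 2}, {s: 1}, True),
        ]
        planted = {p: 2}
    elif motif == "type1":
        names = {sp: fresh(sp) for sp in "ABCDEF"}
        motif_triples = [
            ({names[sp]: c for sp, c in sub.items()},
             {names[sp]: c for sp, c in prod.items()},
             rev)
            for sub, prod, rev in _FIG4
        ]
        planted = {names["A"]: 2}
    else:  # type2
        p, q = fresh("P"), fresh("Q")
        rename = {"P": p, "Q": q}
        cx = [{rename[sp]: c for sp, c in ms.items()} for ms in _TYPE2_COMPLEXES]
        motif_triples = [
            (cx[0], cx[1], False),
            (cx[1], cx[2], False),
            (cx[2], cx[3], False),
            (cx[3], cx[0], False),
        ]
        extra_lb = [1.0] * 4
        extra_ub = [1.0] * 4
        planted = cx[0]

    new_crn = build_crn(host_triples + motif_triples)
    if not extra_lb:
        extra_lb = [
            -float("inf") if rev else 0.0 for _, _, rev in motif_triples
        ]
        extra_ub = [float("inf")] * len(motif_triples)
    new_bounds = FluxBounds(tuple(bounds.lb) + tuple(extra_lb),
                            tuple(bounds.ub) + tuple(extra_ub))
    return new_crn, new_bounds, new_crn.complex_index(planted)
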