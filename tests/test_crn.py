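"""Construction and validation of the complex-level network representation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balcom import (
    FluxBounds,
    build_crn,
    build_network,
    linkage_classes,
    random_crn,
    remove_blocked,
)
from balcom.lp import blocked_reactions


def exact_equal_zero(mat):
    return all(x == 0 for row in mat for x in row)


class TestBuildCrn:
    def test_single_reaction_matrices(self):
        crn = build_crn([({"A": 1}, {"B": 1}, False)])
        assert (crn.m, crn.n, crn.r) == (2, 2, 1)
        assert np.array_equal(crn.Y, np.eye(2))
        assert np.array_equal(crn.A, np.array([[-1.0], [1.0]]))

    def test_fig3_counts(self, fig3_base):
        crn, _, _ = fig3_base
        assert (crn.m, crn.n, crn.r) == (5, 7, 6)

    def test_fig4_counts(self, fig4):
        crn, _, _ = fig4
        assert (crn.m, crn.n, crn.r) == (6, 9, 8)

    def test_duplicate_multisets_share_index(self):
        crn = build_crn(
            [({"A": 1}, {"B": 1}, False), ({"B": 1}, {"A": 1, "C": 1}, False)]
        )
        # B appears twice but is a single complex
        assert crn.n == 3

    def test_rejects_identical_sides(self):
        with pytest.raises(ValueError, match="same complex"):
            build_crn([({"A": 1}, {"A": 1.0}, False)])

    def test_rejects_duplicate_reaction_pair(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_crn([({"A": 1}, {"B": 1}, False), ({"B": 1}, {"A": 1}, True)])

    def test_rejects_collinear_stoichiometry_columns(self):
        # D+E -> 2E and 2D -> D+E convert E-D and D-E: collinear in N
        with pytest.raises(ValueError, match="collinear"):
            build_crn(
                [
                    ({"D": 1, "E": 1}, {"E": 2}, False),
                    ({"D": 2}, {"D": 1, "E": 1}, False),
                ]
            )

    def test_exchange_complex_is_shared(self):
        crn = build_crn([({}, {"A": 1}, False), ({"B": 1}, {}, False)])
        assert crn.n == 3  # one shared empty complex
        empty = crn.complex_index({})
        assert all(c == 0 for c in crn.Y[:, empty])

    def test_rational_coefficients_distinguish_complexes(self):
        crn = build_crn(
            [({"A": 2}, {"B": 1}, False), ({"A": 1}, {"B": 2}, False)]
        )
        assert crn.complex_index({"A": 2}) != crn.complex_index({"A": 1})


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_n_equals_ya_exactly(seed):
    """N = Y.A holds entrywise in exact arithmetic for any generated network."""
    crn, _ = random_crn(seed, m=4, n_per_class=3, classes=2, extra_edges=1)
    Y, A, N = crn.Y_exact, crn.A_exact, crn.N_exact
    for i in range(crn.m):
        for k in range(crn.r):
            assert N[i][k] == sum(Y[i][j] * A[j][k] for j in range(crn.n))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_incidence_columns_are_signed_pairs(seed):
    crn, _ = random_crn(seed, m=4, n_per_class=3, classes=2, extra_edges=1)
    A = crn.A_exact
    for k in range(crn.r):
        col = [A[j][k] for j in range(crn.n)]
        assert sorted(x for x in col if x != 0) == [Fraction(-1), Fraction(1)]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_build_is_deterministic(seed):
    a, _ = random_crn(seed, m=4, n_per_class=3, classes=2, extra_edges=1)
    b, _ = random_crn(seed, m=4, n_per_class=3, classes=2, extra_edges=1)
    assert a == b


class TestLinkageClasses:
    def test_fig4_partition_matches_printed_basis(self, fig4):
        crn, _, _ = fig4
        L = linkage_classes(crn)
        assert L.ell == 2
        expected = np.array(
            [[1, 1, 1, 1, 0, 0, 0, 0, 1], [0, 0, 0, 0, 1, 1, 1, 1, 0]]
        )
        assert np.array_equal(L.U.T, expected)

    def test_fig2_single_class_all_ones(self, fig2):
        crn, _, _ = fig2
        L = linkage_classes(crn)
        assert L.ell == 1
        assert np.array_equal(L.U, np.ones((3, 1)))

    def test_disjoint_reactions_give_two_classes(self):
        crn = build_crn(
            [({"A": 1}, {"B": 1}, False), ({"C": 1}, {"D": 1}, False)]
        )
        L = linkage_classes(crn)
        assert L.classes == ((0, 1), (2, 3))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_indicators_span_left_nullspace(self, seed):
        """U^T A = 0: every class indicator annihilates the incidence matrix."""
        crn, _ = random_crn(seed, m=4, n_per_class=4, classes=2, extra_edges=2)
        L = linkage_classes(crn)
        U, A = L.U_exact, crn.A_exact
        prod = [
            [sum(U[j][l] * A[j][k] for j in range(crn.n)) for k in range(crn.r)]
            for l in range(L.ell)
        ]
        assert exact_equal_zero(prod)
        # columns of U partition the complexes
        assert all(sum(row) == 1 for row in U)


class TestRemoveBlocked:
    def test_empty_set_is_identity(self, fig3_base):
        crn, bounds, _ = fig3_base
        crn2, bounds2 = remove_blocked(crn, bounds, set())
        assert crn2 == crn and bounds2 == bounds

    def test_orphan_complexes_are_pruned(self):
        crn, bounds = build_network(
            [({"A": 1}, {"B": 1}, True), ({"B": 1}, {"C": 1}, True)]
        )
        crn2, _ = remove_blocked(crn, bounds, {1})
        formulas = [crn2.complex_formula(j) for j in range(crn2.n)]
        assert formulas == ["A", "B"]  # C dropped with its only reaction

    def test_fig4_blocked_removal_changes_linkage(self, fig4):
        crn, bounds, _ = fig4
        blocked = blocked_reactions(crn, bounds)
        crn2, _ = remove_blocked(crn, bounds, blocked)
        assert linkage_classes(crn2).ell > linkage_classes(crn).ell

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10**6), drop=st.integers(0, 2))
    def test_removing_edges_never_merges_components(self, seed, drop):
        crn, bounds = random_crn(seed, m=4, n_per_class=4, classes=1, extra_edges=2)
        before = linkage_classes(crn)
        crn2, _ = remove_blocked(crn, bounds, {drop % crn.r})
        after = linkage_classes(crn2)
        # map surviving complexes back to their original indices
        orig = {tuple(sorted(ms.items())): j for j, ms in enumerate(crn.complexes)}
        for cls in after.classes:
            olds = {before.class_of(orig[tuple(sorted(crn2.complexes[j].items()))])
                    for j in cls}
            assert len(olds) == 1  # a new class never straddles two old ones


class TestFluxBounds:
    def test_regime_flags(self):
        b = FluxBounds.canonical_unbounded([True, False])
        assert b.canonical and b.unbounded
        assert b.irr == {1} and b.rev == {0}

    def test_positive_lower_bound_is_noncanonical(self):
        b = FluxBounds((1.0, 0.0), (10.0, float("inf")))
        assert b.irr == {0, 1}
        assert not b.canonical

    def test_validation(self):
        with pytest.raises(ValueError, match="lb .* > ub|> ub"):
            FluxBounds((2.0,), (1.0,))
        with pytest.raises(ValueError, match="positive"):
            FluxBounds((-1.0,), (0.0,))
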