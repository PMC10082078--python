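"""The four factorizations, their nesting, and the class assignment."""

from fractions import Fraction

import pytest

from balcom import (
    NOT_BALANCED,
    STOICHIOMETRIC,
    TYPE_I,
    build_network,
    classify,
    is_balanced,
    linkage_classes,
    random_crn,
    remove_blocked,
    strict_factorization,
    stoich_factorization,
    type1_factorization,
    type2_factorization,
    verify_type1_certificate,
)
from balcom.fixtures import FIG4_PRINTED_CERTIFICATE
from balcom.lp import blocked_reactions


def labels_of(crn, bounds):
    return {r.complex_index: r.class_label for r in classify(crn, bounds)}


class TestStrictFactorization:
    def test_unique_species_gives_basis_certificate(self, fig1b):
        crn, _, _ = fig1b
        j = crn.complex_index({"B": 1})
        cert = strict_factorization(crn, j)
        assert cert is not None
        i = crn.species.index("B")
        expected = [Fraction(0)] * crn.m
        expected[i] = Fraction(1)
        assert cert["zeta"] == expected

    def test_fig3_strict_pair(self, fig3_base):
        crn, _, _ = fig3_base
        assert strict_factorization(crn, crn.complex_index({"A": 1, "B": 1})) is not None
        assert strict_factorization(crn, crn.complex_index({"B": 2})) is not None

    def test_fig3_stoichiometric_pair_is_not_strict(self, fig3_base):
        crn, _, _ = fig3_base
        assert strict_factorization(crn, crn.complex_index({"C": 2})) is None
        assert strict_factorization(crn, crn.complex_index({"C": 1, "D": 1})) is None

    def test_certificate_reconstructs_indicator(self, fig3_base):
        crn, _, _ = fig3_base
        j = crn.complex_index({"B": 2})
        zeta = strict_factorization(crn, j)["zeta"]
        Y = crn.Y_exact
        recon = [
            sum(Y[i][col] * zeta[i] for i in range(crn.m)) for col in range(crn.n)
        ]
        assert recon == [Fraction(int(col == j)) for col in range(crn.n)]


class TestStoichiometricFactorization:
    def test_fig2_linkage_certificate(self, fig2):
        crn, _, _ = fig2
        L = linkage_classes(crn)
        j = crn.complex_index({"P": 2})
        cert = stoich_factorization(crn, L, j)
        assert cert is not None
        # the motif certificate: zeta = -e_S, xi = 1 on the single class
        Y, U = crn.Y_exact, L.U_exact
        s = crn.species.index("S")
        zeta = [Fraction(0)] * crn.m
        zeta[s] = Fraction(-1)
        recon = [
            sum(Y[i][col] * zeta[i] for i in range(crn.m)) + U[col][0]
            for col in range(crn.n)
        ]
        assert recon == [Fraction(int(col == j)) for col in range(crn.n)]

    def test_fig3_stoichiometric_pair(self, fig3_base):
        crn, _, _ = fig3_base
        L = linkage_classes(crn)
        for ms in ({"C": 2}, {"C": 1, "D": 1}):
            assert stoich_factorization(crn, L, crn.complex_index(ms)) is not None

    def test_fig4_has_no_stoichiometric_factorization(self, fig4):
        crn, _, _ = fig4
        L = linkage_classes(crn)
        assert all(stoich_factorization(crn, L, j) is None for j in range(crn.n))


class TestTypeIFactorization:
    def test_fig4_printed_certificate_verifies(self, fig4):
        crn, bounds, _ = fig4
        L = linkage_classes(crn)
        resid = verify_type1_certificate(
            crn, L, bounds, crn.complex_index({"A": 2}), FIG4_PRINTED_CERTIFICATE
        )
        assert resid == 0.0

    def test_fig4_balanced_complex_is_feasible(self, fig4):
        crn, bounds, _ = fig4
        L = linkage_classes(crn)
        cert = type1_factorization(crn, L, bounds, crn.complex_index({"A": 2}))
        assert cert is not None and cert["residual"] <= 1e-9

    def test_fig4_unbalanced_complex_is_infeasible(self, fig4):
        crn, bounds, _ = fig4
        L = linkage_classes(crn)
        assert type1_factorization(crn, L, bounds, crn.complex_index({"A": 1, "B": 1})) is None

    def test_stoichiometric_implies_type_i_with_zero_theta(self, fig3_base):
        crn, bounds, _ = fig3_base
        L = linkage_classes(crn)
        for ms in ({"C": 2}, {"C": 1, "D": 1}):
            cert = type1_factorization(crn, L, bounds, crn.complex_index(ms))
            assert cert is not None


class TestTypeIIFactorization:
    def test_every_detected_bc_is_feasible(self, all_fixtures):
        for name, (crn, bounds, _) in all_fixtures.items():
            for j in range(crn.n):
                if is_balanced(crn, bounds, j):
                    assert type2_factorization(crn, bounds, j) is not None, (name, j)

    def test_unbalanced_complex_is_infeasible(self, fig3_dotted):
        crn, bounds, _ = fig3_dotted
        j = crn.complex_index({"C": 2})  # loses balance in the dotted variant
        assert type2_factorization(crn, bounds, j) is None

    def test_lambda_construction_from_type_i_certificate(self, fig4):
        """lambda_l = A^T theta, lambda_u = 0 embeds a type-I witness in type-II."""
        import numpy as np

        from balcom.factorize import verify_type2_certificate

        crn, bounds, _ = fig4
        j = crn.complex_index({"A": 2})
        c12 = FIG4_PRINTED_CERTIFICATE
        At = crn.A.T
        irr = sorted(bounds.irr)
        lam = {}
        for t in (1, 2):
            v = At @ np.asarray(c12[f"theta{t}"], dtype=float)
            lam[t] = v
            # theta feasibility makes these nonnegative on irreversible columns
            assert (v[irr] >= 0).all()
        cert13 = {
            "zeta1": c12["zeta1"],
            "zeta2": c12["zeta2"],
            "lambda_l1": np.maximum(lam[1], 0.0),
            "lambda_u1": np.zeros(crn.r),
            "lambda_l2": np.maximum(lam[2], 0.0),
            "lambda_u2": np.zeros(crn.r),
        }
        # in the canonical unbounded regime only irreversible lambda_l entries
        # survive the infinite-bound pinning; theta is zero on reversible cuts
        assert verify_type2_certificate(crn, bounds, j, cert13) <= 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "name,variant",
        [
            ("fig1b", None),
            ("fig2", None),
            ("fig3", "base"),
            ("fig3", "dashed"),
            ("fig3", "dotted"),
            ("fig4", None),
        ],
    )
    def test_fixture_expected_labels(self, name, variant):
        from balcom import make_fixture

        crn, bounds, expected = make_fixture(name, variant)
        assert labels_of(crn, bounds) == expected

    def test_fig4_pruned_promotes_type_i_to_stoichiometric(self, fig4):
        crn, bounds, _ = fig4
        crn2, bounds2 = remove_blocked(crn, bounds, blocked_reactions(crn, bounds))
        labels = labels_of(crn2, bounds2)
        j = crn2.complex_index({"A": 2})
        assert labels[j] == STOICHIOMETRIC
        assert TYPE_I not in labels.values()

    def test_infeasible_model_flags_every_complex(self):
        from balcom import FluxBounds

        crn, _ = build_network([({"A": 1}, {"B": 1}, False)])
        results = classify(crn, FluxBounds((1.0,), (1.0,)))
        assert all(r.class_label == NOT_BALANCED for r in results)
        assert all("infeasible_model" in r.flags for r in results)


NESTING_SEEDS = range(40)


@pytest.mark.parametrize("seed", NESTING_SEEDS)
def test_factorization_nesting_on_random_networks(seed):
    """Each factorization's solution set is contained in the next one."""
    crn, bounds = random_crn(seed, m=5, n_per_class=4, classes=2, extra_edges=1)
    L = linkage_classes(crn)
    for j in range(crn.n):
        f10 = strict_factorization(crn, j) is not None
        f11 = stoich_factorization(crn, L, j) is not None
        f12 = type1_factorization(crn, L, bounds, j) is not None
        f13 = type2_factorization(crn, bounds, j) is not None
        assert (not f10 or f11) and (not f11 or f12) and (not f12 or f13), (seed, j)


@pytest.mark.parametrize("seed", range(20))
def test_stoichiometric_factorization_is_sufficient_for_balance(seed):
    """A stoichiometric factorization keeps a complex balanced under any
    reversibility draw (it never uses the irreversibility pattern)."""
    import random as _random

    from balcom import FluxBounds

    crn, bounds = random_crn(seed, m=4, n_per_class=4, classes=2, extra_edges=1)
    L = linkage_classes(crn)
    winners = [j for j in range(crn.n) if stoich_factorization(crn, L, j) is not None]
    rng = _random.Random(seed)
    for _ in range(3):
        rev = [rng.random() < 0.5 for _ in range(crn.r)]
        alt = FluxBounds.canonical_unbounded(rev)
        for j in winners:
            assert is_balanced(crn, alt, j), (seed, j, rev)
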