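# balcom — balanced complexes in reaction networks

`balcom` detects **balanced complexes** in chemical/metabolic reaction
networks with arbitrary kinetics and explains *why* each one is balanced.
It is aimed at people working with constraint-based metabolic models and
chemical reaction network theory (CRNT): balanced complexes are the handle
behind several network-reduction schemes that preserve steady-state
properties, and knowing the mechanism behind each one tells you how robust
it is to changes in reversibility assignments or flux bounds.

## The model

A network is a triple of species, complexes and reactions, with

- `Y` (m×n): the stoichiometric map, column *j* the composition of complex
  *C_j*;
- `A` (n×r): the incidence matrix, one −1/+1 pair per reaction column
  (reversible reactions are single signed columns);
- `N = YA` (m×r): the usual stoichiometry matrix.

The steady-state flux set is `F = {v : N v = 0, v_l ≤ v ≤ v_u}`.  A complex
*C_j* is **balanced** iff its net flux `e_jᵀ A v` is zero for every `v ∈ F`.
`balcom` decides this by minimising and maximising `e_jᵀ A v` over `F`
(both optima zero ⇔ balanced) and, as a cross-check, by solving the two
Lagrange dual programs, whose optima must coincide by strong duality.

Each balanced complex is then assigned the most specific of four nested
feasibility problems:

| class | certificate | balancing mechanism |
|---|---|---|
| strictly stoichiometric | `e_j = Yᵀ ζ` | stoichiometry alone |
| stoichiometric | `e_j = Yᵀ ζ + U ξ` | + linkage structure (`U` = linkage-class indicators, a basis of `ker Aᵀ`) |
| type-I nonstoichiometric | `e_j = Yᵀ ζ₁ + U ξ₁ + θ₁` and `e_j = Yᵀ ζ₂ + U ξ₂ − θ₂` with `A_revᵀ θ_t = 0`, `A_irrᵀ θ_t ≥ 0` | + irreversibility pattern |
| type-II nonstoichiometric | the dual pair `Aᵀ e_j = Aᵀ Yᵀ ζ_t ± (λ_l − λ_u)` with `v_lᵀ λ_l − v_uᵀ λ_u = 0`, `λ ≥ 0` | + explicit bound values |

The solution sets are nested in that order.  Under a canonical flux regime
(irreversible lower bounds exactly zero) the type-I problem captures
*exactly* the balanced complexes; the type-II problem does so in any
regime.  Two structural consequences are exposed and tested: a type-I
complex forces at least two blocked irreversible reactions (so type-I
labels vanish after blocked-reaction removal, re-appearing as
stoichiometric), and a nonstoichiometric complex in a blocked-free network
forces at least three reactions fixated at a nonzero bound.

The first two certificates are decided by exact rational elimination (no
rank tolerances); the last two are LP feasibility problems (HiGHS) whose
witnesses are re-verified by substitution before being reported.  An
independent brute-force oracle (exact elementary-flux-mode enumeration)
cross-checks the LP detector on desk-scale networks.

## Worked example

The built-in `fig4` network (m=6 species, n=9 complexes, r=8 reactions, two
of them irreversible) has exactly one balanced complex:

```sh
balcom fixture fig4 --out fig4.json
balcom classify fig4.json
```

```
# balanced: 1 / 9
# percent_strictly_stoichiometric: 0.0
# percent_stoichiometric: 0.0
# percent_type_I_nonstoichiometric: 100.0
# percent_type_II_nonstoichiometric: 0.0
complex_index	complex_formula	balanced	class	min_net_flux	max_net_flux	certificate
1	A + B	false	not_balanced
2	A + C	false	not_balanced
3	C + D	false	not_balanced
...
9	2 A	true	type_I_nonstoichiometric	0	0	embedded:json
```

Complex `2A` has zero minimum and maximum net flux (balanced) and carries a
type-I certificate: it is balanced because the two irreversible reactions
are blocked at steady state, not because of stoichiometry.  Accordingly,
`balcom classify fig4.json --remove-blocked` reclassifies `2A` as
`stoichiometric` and no type-I complex remains.

Other commands: `balcom detect` (balance testing only), `balcom random
--seed N ...` (seeded random networks, optionally with a planted motif of a
chosen class), `balcom oracle MODEL` (exact elementary-mode verdicts for
small networks).  Models are read from the native JSON/TSV formats or SBML
Level 3 (FBC bounds pass through verbatim).

Library use mirrors the CLI:

```python
from balcom import make_fixture, classify
crn, bounds, _ = make_fixture("fig3", "base")
for r in classify(crn, bounds):
    print(r.formula, r.class_label)
# A + B strictly_stoichiometric, 2 B strictly_stoichiometric,
# 2 C stoichiometric, C + D stoichiometric, the rest not_balanced
```

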