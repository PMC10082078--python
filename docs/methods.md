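# Methods

## Network representation

A reaction network is held at the complex level: an ordered species list, an
ordered list of complexes (multisets of species with nonnegative rational
coefficients), and reactions as ordered pairs of complex indices.  The
stoichiometric map `Y`, incidence matrix `A` and stoichiometry matrix
`N = YA` are kept with exact rational entries; floating-point views exist
only for the LP layer.  Two conventions are enforced at construction time:

- a reversible reaction is a single signed incidence column, never two
  antiparallel columns (the reversibility split lives in the bounds object);
- no two columns of `A` or of `N` may be collinear, and a reaction may not
  have identical substrate and product complexes.  Violations raise rather
  than warn, because downstream statements about blocked reactions and
  nonstoichiometric complexes assume this normal form (the classical
  counterexamples to those statements are exactly the degenerate networks
  this check rejects).

Open networks are supported through one shared explicit empty complex (a
zero column of `Y`).  The component-indicator basis `U` of `ker Aᵀ` is valid
for any incidence graph, including graphs containing the empty complex, so
the linkage-based factorization is applied unconditionally; class labels of
complexes sharing a linkage class with the empty complex are flagged in
reports so a reader can treat them with care.

## Balance detection

Complex `C_j` is balanced iff `min` and `max` of `e_jᵀ A v` over
`F = {v : Nv = 0, v_l ≤ v ≤ v_u}` are both zero.  Both problems are solved
with scipy's HiGHS backend.  Optima are compared to zero at
`tol × max(1, max|Y|)` with `tol = 1e-8` by default: the stoichiometric
scale factor keeps the verdict invariant under rescaling the model's
stoichiometry.  An unbounded optimum means not balanced (a net flux of
arbitrary magnitude exists).  An empty feasible set (possible only with
contradictory non-canonical bounds) raises an explicit error in the
low-level API and produces `not_balanced` + an `infeasible_model` flag per
complex in `classify`: the definition quantifies over `F`, and we refuse to
report vacuous balance silently.

The dual pair of the min/max problems is solved by `dual_balance_check`.  A
dual multiplier attached to an infinite bound is pinned to zero — the dual
feasibility convention for an absent constraint — which keeps the dual
objective finite in unbounded regimes and reduces, in the canonical case, to
the certificate structure used by the type-I/type-II embeddings.  Strong
duality (primal optimum = dual optimum within `10·tol`) is asserted in the
test suite; an infeasible dual corresponds to an unbounded primal direction
and is reported as such, never silently.

Blocked and fixated reactions are found by per-reaction flux variability:
blocked iff both optima are within `tol` of zero, fixated iff
`max − min ≤ tol` (reported value = midpoint, snapped to 0 within `tol`).

## Factorizations and classification

The four certificates are tested in nesting order and the first feasible one
names the class:

1. **strict** (`e_j = Yᵀζ`) and **stoichiometric** (`e_j = Yᵀζ + Uξ`) are
   linear systems over the rationals and are decided by exact Gaussian
   elimination (`fractions.Fraction`).  Deciding these by floating-point
   rank would make the strict/non-strict boundary tolerance-dependent, which
   is the one place the categorization must not wobble.  A float
   least-squares fallback exists behind the CLI flag for very large models.
2. **type-I** and **type-II** are LP feasibility problems with a zero
   objective; any feasible point is a certificate.  Returned witnesses are
   re-verified by direct substitution at residual `1e-9` (relative to the
   witness magnitude) before being reported; a verification failure raises a
   numerical-inconsistency error instead of mislabeling.
3. A balanced complex infeasible even for the type-II problem is a
   numerical contradiction (the type-II problem is equivalent to balance)
   and raises.

The type-I problem's equivalence with balance holds under the canonical
regime.  In non-canonical regimes the test still runs, but a type-I label is
annotated with a regime flag, and the equivalence is asserted in tests only
when canonical.  Strictly stoichiometric complexes are reported under the
most specific label; summary percentages are emitted in both counting
conventions (classes disjoint with strict broken out, and stoichiometric
including its strict subclass), since published per-class percentages are
ambiguous between the two.

## Brute-force oracle

For canonical unbounded regimes the steady-state set is a polyhedral cone
generated by elementary flux modes.  The oracle enumerates them exhaustively
over reaction supports: a support carries a mode iff the restricted kernel
of `N` is one-dimensional with a nowhere-zero generator (support-minimality
is then automatic); sign-feasible orientations are kept, both of them for
supports free of irreversible reactions.  All arithmetic is rational, so the
oracle's verdict (`balanced ⇔ net flux zero on every generator`) is exact
and fully independent of the LP path.  The default cap is r ≤ 14 reactions
— correctness over speed; bounded or non-canonical regimes are out of the
oracle's scope and are instead cross-checked LP-against-LP through the
type-II equivalence.

## Built-in networks and the generator

The four named fixtures are reconstructions of published toy diagrams whose
edge lists are not printed as text.  Each reconstruction was required to
satisfy every printed anchor simultaneously before being frozen: species /
complex / reaction counts and reversible counts; the printed complex
ordering and linkage-indicator matrix; the printed type-I certificate
(verifies with zero residual); the printed counterexample flux vector
(steady and bound-feasible exactly when the text says so); the identity and
blockedness of the two irreversible reactions; and the full expected class
map, including its changes under the two published network variants and
under blocked-reaction removal.  The `fig1b` fixture is a synthetic
reconstruction: only its testable property (complex `B` is the unique
balanced complex, trivially strict) is anchored.

`random_crn` emulates small closed networks: complexes are random multisets
(1–3 species, coefficients 1–2), each linkage class is a random spanning
tree plus a configurable number of chords, and reversibility is i.i.d.
(default p = 0.5).  Defaults (m = 5, 4 complexes per class, 2 classes, one
extra chord) give networks of 8 complexes and ~8 reactions — large enough to
exhibit all structural phenomena the factorizations distinguish, small
enough that hundreds of networks with per-complex LPs run in seconds.
Duplicate complexes/reactions and collinear stoichiometry columns are
removed by rejection sampling, so every emitted network is in normal form.
What the generator does *not* emulate: mass conservation, realistic
biochemistry, genome-scale dimensions, or correlated reversibility patterns.
Passing property campaigns on these networks therefore validates the
mathematics (nesting, equivalences, duality, structural consequences), not
any biological claim about real models.

`plant_motif` grafts a disconnected motif with a known class onto a host,
renaming species until fresh; because certificates decompose over connected
components and over species supports, the planted complex's class is decided
locally and is independent of the host.  The type-II motif is a four-complex
cycle over two species with every flux pinned to its bound value of 1 —
the minimal normal-form configuration in which balance exists only because
of bound values (a three-complex cycle cannot host a nonstoichiometric
complex: its compositions would have to be affinely collinear, which the
normal form forbids).

## Numerical choices and limitations

- LP backend: HiGHS via `scipy.optimize.linprog`; deterministic for a fixed
  scipy build.  Witness vectors may differ across backends; all assertions
  compare values and verdicts, not witnesses.
- Tolerances: `tol = 1e-8` on scaled optima (CLI-configurable); certificate
  re-verification at `1e-9` relative; strong-duality assertions at `10·tol`.
- Ties/degeneracies: exact elimination sets free variables to zero, so
  rational certificates are reproducible; the minimal-index pivot rule makes
  them deterministic.
- Genome-scale SBML models load and classify through the same code path
  (bounds pass through verbatim), but the oracle and the property campaigns
  are desk-scale by design; no genome-scale result is asserted anywhere.
- The equation grammar merges a species repeated on one side with a warning
  rather than rejecting, matching how such models are usually intended.
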