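# Methods

## Model and encoding

A turning machine is a chain `m_0 … m_{n-1}` on the triangular grid.
The model state of the package is the **move-count vector**
`Δs(m_i) ∈ [0, |s0(m_i)|]`: the number of turning rules applied to
monomer `i` since the initial configuration. Everything else is
derived: the current state is `s0 − sign(s0)·Δs`, the direction of
`m_i` is its initial direction rotated by `sign(s0)·Δs` sixths of a
turn, and positions are prefix sums of directions from the origin
(`m_0` never moves). This holds because a rule application at `i`
rotates only `dir(m_i)` and translates all later monomers by
`rotate(dir, ±1) − dir`, which is exactly the head-translation vector
of the rule. Keeping the whole state integral makes configurations
hashable, the reachable space exactly enumerable, and geometry
reproducible to the bit.

Two independent blocking tests coexist deliberately. The *reference*
test translates the head and intersects it with the tail, literally.
The *engine* test observes that a blocked pair is a pair of monomers
at unit distance `t` apart with the tail member ahead of the head
member, so one sorted lookup per unit direction finds all blocking
pairs in `O(n)` vectorised work per configuration. The two are checked
against each other exhaustively on small machines (including
mixed-sign programs) in the test suite; the engine never quietly
replaces the definition.

Conventions at the chain ends: the last monomer points nowhere, so its
rule (if its state is nonzero) has an empty head, is never blocked,
and only changes state. The model definition never exempts it, and
exempting it would make even the canonical machines unable to finish,
so the package allows it. For the same reason the terminal monomer is
excluded from the adjacent-move-count-gap statistic: the `≤ 2` bound
is a consequence of both pair members pointing somewhere.

## Dynamics

Each applicable move fires at rate 1. A configuration with `k`
applicable moves therefore waits `Exp(k)` and picks a move uniformly —
the implementation samples the uniform choice and the holding time
directly, which is distributionally identical to racing `k`
independent unit-rate clocks. Trajectory sampling uses one child RNG
stream per trajectory spawned from a master `SeedSequence`, so results
are reproducible and order-independent.

Because every step removes exactly one remaining move, the reachable
space is a DAG graded by total move count, and all trajectories have
length at most `Σ|s0|`. Exact expected absorption times are computed
by one backward sweep in decreasing total-move order using
`E[c] = (1 + Σ_{c'} E[c'])/k(c)` with `E = 0` at absorbing states
(target or permanently blocked); no linear solver is needed. For
machines that can jam, the same sweep yields the absorption
(blocking) probability, which is reported alongside the expectation —
the time value is then the expected time to absorption, not to the
target.

## Reachability and verdicts

Foldability ("the machine computes its target") is equivalent to: the
all-zero-state vector is reachable and no reachable vector is
permanently blocked. This is sound because trajectories are finite and
every non-terminal configuration has a continuation. The search is a
plain BFS keyed on move-count tuples, so witnesses emerge in
fewest-total-moves order and the first witness is a shortest jammed
configuration. Geometry is recomputed per expansion (an `O(n)` prefix
sum) rather than cached; memory stays proportional to the number of
visited vectors. A state cap (default 5·10^6) turns the verdict into
an explicit *unknown* (`None`) instead of a guess when exceeded.

## Compilers

**Zig-zag paths.** A positive zig-zag path uses steps `{±x, +y, +w}`.
Each monomer's initial state is read off its folded direction:
`+x → 0, +y → 1, +w → 2, −x → 3`, last monomer 0. The mirror class
`{±x, −y, −w}` uses `+x → 0, −w → −1, −y → −2, −x → −3`; the negative
table is the clockwise rotation order, which is forced once the
mirror is taken across the x-axis. Squares are rastered
boustrophedon (row 0 west→east), which is a positive zig-zag path.

**y-monotone shapes.** Rows are concatenated bottom-to-top, even rows
left-to-right, odd rows right-to-left, each row extended sideways by
exactly the points lying directly below/above the turning point of the
neighbouring row. Every added point is grid-adjacent to a perimeter
point of the shape and no perimeter point is charged twice, giving the
perimeter bound on the folding error that the tests check on random
fixtures (perimeter = shape points with at least one of their six
neighbours outside).

**Factor-2 scaled shapes.** For an xy-connected y-monotone shape with
a yw-separator, the doubled shape is cut along the doubled separator
into a left lobe traversed top-to-bottom (negative states, clockwise)
and a right lobe bottom-to-top (positive states), joined by one east
step in the bottom row. A `+y` separator step splits its four doubled
points 2+2; a `+w` step splits 1+3 or 3+1 depending on which side of
the step is in the shape. The package searches separator and split
jointly (a small DP over rows with a two-value "style" flag), because
a chain found in isolation can force a 3+1 split immediately followed
by a 1+3 split, which breaks the cut: there are valid inputs — e.g.
rows `{3}, {1,2,3}, {1}` with its unique separator — for which *no*
cut of this family exists, and the compiler reports that honestly
(`SeparatorCutError`) rather than emitting a broken program. Initial
states are derived from folded directions through the two zig-zag
tables, which reproduces the construction's case table (including
reading its one sign slip as `+3`: the right lobe rotates
anticlockwise through `x → y → w → −x`).

**Spirals.** The k-turn 1-gap spiral is the union of k nested almost-
rectangles; it has `8k² + 6k + 2` points and exactly two degree-1
endpoints, hence exactly two traversals. The canonical turning-number
sequences expand base values `t_0 … t_{4k}` (increments `+1/+2`
inside-out, decrements `−2/−1` outside-in) into arm-length-many
repetitions; the outside-in expansion mirrors the inside-out one
(`[t_0]^{4k+1}, …, [t_{4k}]^1, t_{4k}`), the form the engine verifies
traces the spiral from the outer endpoint. The unfoldability evidence
is executable: for each of the six sign cases of the canonical
sequences (`k = 2`, smallest-magnitude admissible base state per
case), a script plays deterministic line-rotation sweeps that stage
the case's construction (pocket, tight coil, C-shape, pincer) followed
by a greedy fold-toward-the-jam completion; every move is validated
by the engine when played, and the verdict — permanent blockedness of
the final configuration, or of the designated inner-coil monomers
under bounded forward search — is computed, never assumed. A
necessity probe perturbs each directional state of the canonical
sequences by ±1 and classifies the failure (self-intersecting target,
mis-traced point set, or blocking); the last monomer is excluded
because it points nowhere and its state genuinely is free.

## Synthetic fixtures

The fixture generators emulate the shape families the compilers are
specified for, not empirical data: squares, width-1 crosses (the
minimal y-monotone shape with no traversal, hence error ≥ 1), random
y-monotone shapes (random row segments with forced row adjacency),
random separator shapes (a +y/+w chain grown into rows, keeping the
point right of every `+w` step inside the shape so the 3+1 split is
always available), and spirals. All are deterministic given a seed.
Passing tests on them shows the compilers meet their guarantees on
their specified input classes; it says nothing about shapes outside
those classes (non-y-monotone shapes, separators that only admit the
impossible split pattern), which the compilers reject explicitly.

## Problem sizes and numerical choices

Exhaustive suites run at chain length 7 (state ≤ 6), where the
reachable spaces have 10³–10⁴ vectors; the squares explored
exhaustively are n ≤ 4, with the 8×8 square checked on 100 sampled
trajectories; the log-growth probe uses the state-3 line at
n ∈ {16, 64, 256} with 2000 samples per point and accepts a
least-squares `a + b·ln n` fit whose residuals stay within 10%; the
sampling-versus-exact cross-check is a 3σ z-test. Waiting times are
double precision; everything else is exact integer arithmetic, so
there are no tolerances anywhere in the geometry. Tie-breaks are
fixed: enumeration in increasing monomer index, BFS in level order,
script completion by highest- or lowest-index applicable monomer as
documented per case.

## Known limitations

* Mixed-sign programs are fully supported by the engine, but the
  package makes no general foldability claims for them — verdicts are
  per-instance via `explore`.
* The factor-2 compiler covers exactly the separator shapes whose cut
  exists (see above); it does not attempt larger scale factors or
  alternative traversals when the cut family fails.
* The spiral scripts are constructed and validated for `k = 2` (the
  smallest unfoldable turn count); they are parameterised in `k` but
  not proof-checked beyond the scale the tests execute.
* Whether the 1-turn spiral is foldable is left open; `explore` on its
  canonical programs is the provided experiment, and nothing is
  asserted about it in the tests.
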