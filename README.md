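# turnfold

Simulation, verification and compilation for **turning machines** — a
minimal model of algorithmic molecular robotics in which a chain of
monomers folds itself from a straight line into a programmed 2D shape.

## The model

Monomers sit on the triangular grid (axial coordinates with unit
vectors `x = (1,0)`, `y = (0,1)`, `w = (-1,1)`), chained so that each
monomer points at the next. A program is nothing but an integer
*turning number* `s0(m_i)` per monomer: a monomer in state `s > 0`
repeatedly tries to decrement `s` while rotating its direction by
`π/3` anticlockwise (clockwise for `s < 0`), and each rotation rigidly
**translates the whole head** — every monomer after it — by the unit
vector two steps around the hexagonal direction tuple. A move is
**blocked** whenever the translated head would overlap the tail; the
whole difficulty of the model is that blocking can become *permanent*,
freezing the chain short of its target. A target is **foldable** when
every trajectory reaches it. Time is a continuous-time Markov chain:
each applicable move fires at rate 1.

The package implements, in five modules:

* `core` — exact integer geometry: configurations are move-count
  vectors `Δs`, from which states, directions and positions are
  derived; the turning rule, blocking test, turn angles, folding error.
* `dynamics` — trajectory sampling (race semantics), completion-time
  statistics, and exact expected absorption times by a backward sweep
  over the reachable DAG.
* `reachability` — exhaustive BFS over move-count vectors: foldability
  verdicts and permanently blocked witnesses.
* `compilers` / `spirals` — shape-to-program compilers: line rotations
  `L_n^s`, zig-zag paths, `n×n` squares, y-monotone shapes (error
  bounded by perimeter), factor-2 scaled shapes with a yw-separator
  (zero error), and k-turn 1-gap spirals together with the scripted
  trajectories showing spirals are *not* foldable despite having a
  traversal.
* `io` / `render` / `fixtures` / `cli` — plain-text shape and program
  formats, SVG/ASCII rendering, seeded fixture generators, and the
  `turnfold` command-line tool (`simulate`, `verify`, `compile`,
  `shape`, `render`).

## Worked example

The headline phenomenon is the line-rotation boundary: a line of `n`
monomers can be rotated by any angle up to `5π/3` on *every*
trajectory, but a full `2π` rotation inevitably admits a jammed
trajectory.

```python
>>> import turnfold as tf
>>> program, target = tf.line_rotation_program(7, 5)   # rotate 7-chain by 5π/3
>>> report = tf.explore(program)                        # exhaustive reachability
>>> report.reachable_count, report.foldable
(6140, True)

>>> program6, _ = tf.line_rotation_program(7, 6)        # attempt a full turn
>>> report6 = tf.explore(program6)
>>> report6.reachable_count, report6.foldable
(8129, False)
>>> report6.blocked_witnesses[0]                        # a shortest jammed state
(6, 5, 4, 3, 2, 0, 0)
```

The witness is a move-count vector; reconstructing it shows a chain
curled into a tight coil whose every remaining turn is blocked — the
geometric obstruction to `2π` rotation. Dynamics are fast: the
state-1 line completes in expected time equal to a harmonic number,

```python
>>> tf.exact_expected_time(tf.line_rotation_program(9, 1)[0]).expected_time
2.717857142857142      # = H_8 = 1 + 1/2 + ... + 1/8
```

and compiled shapes fold with zero error, e.g. the 8×8 square
(91 moves, mean completion time ≈ 7.6 over 200 sampled trajectories):

```python
>>> program, shape = tf.compile_square(8)
>>> stats = tf.completion_time_stats(program, 200, seed=1)
>>> stats.mean_steps, stats.fraction_reaching_target
(91.0, 1.0)
```

The same checks are available from the shell:

```sh
turnfold compile line --n 7 --s 6 --out l76.tmprog
turnfold verify l76.tmprog --expect-foldable   # exits 3: not foldable
```

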