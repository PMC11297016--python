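"""k-turn 1-gap spirals: shapes, canonical turning numbers, and the
scripted trajectories showing they cannot be folded.

The anticlockwise k-turn 1-gap spiral is a union of nested "almost
rectangles" whose arms keep a unit gap; it has exactly two degree-1
points — the centre ``(0, 0)`` and the outer endpoint ``(2k+1, -2k)`` —
and hence exactly two traversals.  Any machine that folds it must carry
one of the two canonical turning-number sequences (inside-to-outside or
outside-to-inside), and for ``k >= 2`` each sign case of those
sequences admits a constructed trajectory that ends permanently blocked
(or with a permanently blocked inner coil), so the spiral has a
traversal yet is not foldable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .core import (
    Configuration,
    GridPoint,
    Program,
    Shape,
    applicable_mask,
    geometry_arrays,
    is_permanently_blocked,
)
from .errors import BadBaseState, ScriptInapplicable, StateCapExceeded

Orientation = Literal["in_to_out", "out_to_in"]


def spiral_shape(k: int) -> tuple[Shape, tuple[GridPoint, GridPoint]]:
    """The k-turn 1-gap spiral and its (inside, outside) degree-1 endpoints.

    Built as the union over ``k' = 1..k`` of almost-rectangles: the four
    sides of the square ring at radius ``2k'`` (x from ``-2k'`` to
    ``2k'-1``), plus the three joint points ``(2k'-2, -2k'+2)``,
    ``(2k', -2k')``, ``(2k'+1, -2k')``, minus the gap point
    ``(2k'-1, -2k'+1)``.
    """
    if k < 1:
        raise ValueError("k must be positive")
    pts: set[GridPoint] = set()
    removed: set[GridPoint] = set()
    for kk in range(1, k + 1):
        for x in range(-2 * kk, 2 * kk):
            pts.add((x, 2 * kk))
            pts.add((x, -2 * kk))
        for y in range(-2 * kk, 2 * kk + 1):
            pts.add((-2 * kk, y))
            pts.add((2 * kk - 1, y))
        pts.update({(2 * kk - 2, -2 * kk + 2), (2 * kk, -2 * kk), (2 * kk + 1, -2 * kk)})
        removed.add((2 * kk - 1, -2 * kk + 1))
    pts -= removed
    return Shape(pts), ((0, 0), (2 * k + 1, -2 * k))


@dataclass(frozen=True)
class SpiralSpec:
    """Parameters of a canonical spiral turning-number sequence."""

    k: int
    orientation: Orientation
    t0: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.orientation == "in_to_out":
            if self.t0 % 6 != 0:
                raise BadBaseState("inside-to-outside needs t0 = 0 (mod 6)")
        elif self.orientation == "out_to_in":
            if self.t0 % 6 != 3:
                raise BadBaseState("outside-to-inside needs t0 = 3 (mod 6)")
        else:
            raise ValueError(f"unknown orientation {self.orientation!r}")


def _base_values(spec: SpiralSpec) -> list[int]:
    """The 4k+1 base turning numbers t_0 .. t_{4k}."""
    t = [spec.t0]
    for i in range(1, 4 * spec.k + 1):
        if spec.orientation == "in_to_out":
            t.append(t[-1] + (2 if i % 2 == 0 else 1))
        else:
            t.append(t[-1] - (1 if i % 2 == 0 else 2))
    return t


def spiral_turning_numbers(spec: SpiralSpec) -> Program:
    """The canonical state sequence for the spiral, as an east-line program.

    Inside-to-outside: ``[t_0]^1, [t_1]^2, ..., [t_4k]^{4k+1}, t_4k``;
    outside-to-inside: ``[t_0]^{4k+1}, [t_1]^{4k}, ..., [t_4k]^1, t_4k``
    (the mirror of the inside-to-outside form: arm lengths shrink
    walking inwards, and the last monomer — which never points anywhere
    — repeats the final base value).  Either way the length is
    ``8k^2 + 6k + 2``, the point count of the spiral, and the all-zero
    configuration traces the spiral from the corresponding endpoint.
    """
    t = _base_values(spec)
    k = spec.k
    states: list[int] = []
    if spec.orientation == "in_to_out":
        for i, ti in enumerate(t):
            states.extend([ti] * (i + 1))
        states.append(t[-1])
    else:
        for i, ti in enumerate(t):
            states.extend([ti] * (4 * k + 1 - i))
        states.append(t[-1])
    assert len(states) == 8 * k * k + 6 * k + 2
    return Program(states, name=f"spiral-k{k}-{spec.orientation}-t{spec.t0}")


@dataclass(frozen=True)
class Perturbation:
    """Outcome of one single-state perturbation of a canonical sequence."""

    index: int
    delta: int
    mode: str  # "self_intersects" | "mistraces" | "blocks" | "folds"

    @property
    def fails(self) -> bool:
        return self.mode != "folds"


def necessity_probe(spec: SpiralSpec, state_cap: int = 500_000) -> list[Perturbation]:
    """Check that the canonical turning numbers are necessary.

    Perturbs each directional state (all but the last monomer, whose
    direction is undefined) of the canonical sequence by +-1 and
    classifies how the perturbed machine fails to fold the spiral: its
    all-zero configuration self-intersects, or traces a different point
    set (nonzero folding error), or — if it still covers the spiral —
    exhaustive reachability finds permanent blocking.
    """
    from .core import target_configuration
    from .errors import SelfIntersection
    from .reachability import explore

    program = spiral_turning_numbers(spec)
    shape, (inside, outside) = spiral_shape(spec.k)
    origin = inside if spec.orientation == "in_to_out" else outside
    target_pts = {(x - origin[0], y - origin[1]) for x, y in shape.points}
    results: list[Perturbation] = []
    for i in range(program.n - 1):
        for delta in (1, -1):
            states = list(program.states0)
            states[i] += delta
            q = Program(states)
            try:
                tgt = target_configuration(q)
            except SelfIntersection:
                results.append(Perturbation(i, delta, "self_intersects"))
                continue
            if set(tgt.positions) != target_pts:
                results.append(Perturbation(i, delta, "mistraces"))
                continue
            report = explore(q, state_cap)
            mode = "folds" if report.foldable else "blocks"
            results.append(Perturbation(i, delta, mode))
    return results


#: Smallest-magnitude admissible base state for each proof case.
CASE_SPECS = {
    "in_pos": lambda k: SpiralSpec(k, "in_to_out", 0),
    "in_neg": lambda k: SpiralSpec(k, "in_to_out", -6 * k),
    "in_mixed": lambda k: SpiralSpec(k, "in_to_out", -6),
    "out_pos": lambda k: SpiralSpec(k, "out_to_in", 6 * k + 3),
    "out_neg": lambda k: SpiralSpec(k, "out_to_in", -3),
    "out_mixed": lambda k: SpiralSpec(k, "out_to_in", 3),
}


class ScriptRunner:
    """Executes a scripted move sequence, validating every move."""

    def __init__(self, program: Program):
        self.program = program
        self.mc = np.zeros(program.n, dtype=np.int64)
        self.moves: list[int] = []

    def _mask(self) -> np.ndarray:
        pos, dirs, states = geometry_arrays(self.program, self.mc)
        self._states = states
        return applicable_mask(self.program, pos, dirs, states)

    def state(self, i: int) -> int:
        s0 = self.program.states0[i]
        return s0 - (1 if s0 > 0 else -1 if s0 < 0 else 0) * int(self.mc[i])

    def apply(self, i: int) -> None:
        if not self._mask()[i]:
            raise ScriptInapplicable(
                f"scripted move at monomer {i} rejected (step {len(self.moves)})"
            )
        self.mc[i] += 1
        self.moves.append(i)

    def sweep(self, indices: Iterable[int], turns: int = 1) -> None:
        """Apply one move per listed monomer (skipping finished ones),
        repeated ``turns`` times — a rigid sub-line rotation by
        ``turns * pi/3``."""
        idx = list(indices)
        for _ in range(turns):
            for i in idx:
                if self.state(i) != 0:
                    self.apply(i)

    def run_greedy(self, priority: str = "high", limit: int | None = None) -> None:
        """Apply moves until none is applicable, taking the highest-
        (or lowest-) index applicable monomer each time."""
        count = 0
        while limit is None or count < limit:
            mask = self._mask()
            idxs = np.nonzero(mask)[0]
            if idxs.size == 0:
                return
            i = int(idxs[-1] if priority == "high" else idxs[0])
            self.mc[i] += 1
            self.moves.append(i)
            count += 1

    def run_capped(
        self,
        caps: dict[int, int],
        priority: str = "low",
        default: int | None = None,
    ) -> None:
        """Greedy completion under per-monomer move-count caps.

        ``caps[i]`` limits monomer ``i`` to that many total moves;
        monomers not listed get ``default`` (None meaning unlimited).
        Stops when no within-cap move is applicable."""
        big = self.program.total_moves
        while True:
            mask = self._mask()
            idxs = [
                int(i)
                for i in np.nonzero(mask)[0]
                if self.mc[i] < caps.get(int(i), big if default is None else default)
            ]
            if not idxs:
                return
            i = idxs[0] if priority == "low" else idxs[-1]
            self.mc[i] += 1
            self.moves.append(i)

    @property
    def configuration(self) -> Configuration:
        return Configuration(self.program, self.mc.tolist())


@dataclass
class BlockingScriptResult:
    """Outcome of one scripted unfoldability case."""

    case: str
    program: Program
    moves: list[int]
    final: Configuration
    blocked: bool  # final configuration is permanently blocked
    designated: list[int] = field(default_factory=list)
    designated_blocked: bool | None = None  # via bounded forward search

    @property
    def verdict_blocked(self) -> bool:
        return self.blocked or bool(self.designated_blocked)


def _monomers_never_applicable(
    c: Configuration, designated: list[int], cap: int = 200_000
) -> bool:
    """True iff no configuration reachable from ``c`` (within ``cap``
    states) has an applicable rule at any designated monomer."""
    program = c.program
    des = np.zeros(program.n, dtype=bool)
    des[designated] = True
    seen = {c.move_counts}
    stack = [c.move_counts]
    while stack:
        v = stack.pop()
        mc = np.array(v, dtype=np.int64)
        pos, dirs, states = geometry_arrays(program, mc)
        mask = applicable_mask(program, pos, dirs, states)
        if (mask & des).any():
            return False
        for i in np.nonzero(mask)[0]:
            w = list(v)
            w[i] += 1
            w = tuple(w)
            if w not in seen:
                seen.add(w)
                stack.append(w)
        if len(seen) > cap:
            raise StateCapExceeded("forward search cap exceeded")
    return True


def spiral_blocking_trajectory(k: int, case: str) -> BlockingScriptResult:
    """Execute the constructed trajectory for one unfoldability case.

    Every move is validated by the engine as it is played; the verdict
    is computed from the final configuration, not assumed.  Cases
    ``in_neg`` and ``out_pos`` end with a permanently blocked inner
    coil inside a configuration that still has moves elsewhere; there
    the designated monomers are checked by exhaustive forward search.
    """
    if k < 2:
        raise ValueError("the unfoldability construction needs k >= 2")
    if case not in CASE_SPECS:
        raise ValueError(f"unknown case {case!r}")
    spec = CASE_SPECS[case](k)
    program = spiral_turning_numbers(spec)
    runner = ScriptRunner(program)
    designated: list[int] = []
    if case == "in_pos":
        _script_in_pos(runner, k)
    elif case == "in_neg":
        designated = _script_in_neg(runner, k)
    elif case == "in_mixed":
        _script_in_mixed(runner, k)
    elif case == "out_pos":
        designated = _script_out_pos(runner, k)
    elif case == "out_neg":
        _script_out_neg(runner, k)
    else:
        _script_out_mixed(runner, k)
    final = runner.configuration
    blocked = is_permanently_blocked(final)
    des_blocked = None
    if designated and not blocked:
        des_blocked = _monomers_never_applicable(final, designated)
    return BlockingScriptResult(
        case=case,
        program=program,
        moves=runner.moves,
        final=final,
        blocked=blocked,
        designated=designated,
        designated_blocked=des_blocked,
    )


# --- individual case scripts ----------------------------------------------
#
# Each script realises one sign case of the unfoldability argument as an
# explicit trajectory: deterministic line-rotation sweeps set up the
# figure's staging, and a greedy fold-until-jammed completion drives the
# chain into the permanently blocked end configuration.  Every move is
# validated when played; nothing about the outcome is assumed.

#: Move-count pattern of the tight 2-pi coil (the blocked configuration
#: of the state-6 line machine): monomer i makes 0,2,3,4,5,6 moves.
_TIGHT_COIL_CAPS = {0: 0, 1: 2, 2: 3, 3: 4, 4: 5, 5: 6}


def _script_in_pos(r: ScriptRunner, k: int) -> None:
    """All-positive inside-to-outside: fold the inner coil (suffix line
    rotations until the first ring of the spiral is complete, forming
    the pocket), then fold the long straight arm back into the pocket
    from the far end until everything jams."""
    n = r.program.n
    start = 1
    for seg in range(1, 2 * k + 1):
        turns = 1 if seg % 2 == 1 else 2
        r.sweep(range(start, n), turns)
        start += seg + 1
    r.run_greedy("high")


def _script_in_neg(r: ScriptRunner, k: int) -> list[int]:
    """All-negative inside-to-outside: drive the first monomers into the
    clockwise tight coil (the mirror of the 2-pi line-rotation
    impossibility pattern), folding the tail clear as needed."""
    r.run_capped(_TIGHT_COIL_CAPS, "low")
    return list(range(7))


def _script_in_mixed(r: ScriptRunner, k: int) -> None:
    """Mixed-sign inside-to-outside (t0 = -6): fold the state -2 segment
    flat, lift the state 1 segment, advance everything beyond it by
    three turns, then close the two arms into a pincer around the zero
    segment."""
    n = r.program.n
    r.sweep(range(6, 10), 2)  # the [-2]^4 segment reaches 0
    r.sweep(range(15, 21), 1)  # the [1]^6 segment reaches 0
    r.sweep(range(21, n), 3)  # every later segment advances three turns
    r.run_greedy("low")


def _script_out_pos(r: ScriptRunner, k: int) -> list[int]:
    """All-positive outside-to-inside: the x-axis mirror of the negative
    inside-to-outside case — the chain start folds into the
    anticlockwise tight coil before the long arms get out of the way."""
    r.run_capped(_TIGHT_COIL_CAPS, "low")
    return list(range(7))


def _script_out_neg(r: ScriptRunner, k: int) -> None:
    """All-negative outside-to-inside (t0 = -3): three full-line sweeps
    finish the outer arm, two more finish the second arm, one more the
    third (the C shape); the far monomers then turn twice into the
    q-shape and the trapped inner arm wraps clockwise until jammed."""
    n = r.program.n
    r.sweep(range(n), 3)
    r.sweep(range(n), 2)
    r.sweep(range(n), 1)
    r.sweep(range(12 * k + 3, n), 2)
    r.run_greedy("low")


def _script_out_mixed(r: ScriptRunner, k: int) -> None:
    """Mixed-sign outside-to-inside (t0 = 3): advance the state 1
    segment once, the -2 segment twice and the -3 segment three times
    (as far as applicable), then close the pincer around the zero
    segment."""
    caps = {i: 1 for i in range(4 * k + 1, 8 * k + 1)}
    caps.update({i: 2 for i in range(12 * k, 16 * k - 2)})
    caps.update({i: 3 for i in range(16 * k - 2, 20 * k - 5)})
    r.run_capped(caps, "low", default=0)
    r.run_greedy("low")
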