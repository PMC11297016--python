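"""Core turning-machine model on the triangular grid.

The grid uses axial integer coordinates with unit vectors
``x = (1, 0)``, ``y = (0, 1)`` and ``w = (-1, 1)`` (so ``x + w = y``).
A turning machine is a chain of monomers, each with an integer state
(its *turning number*): a monomer in a positive state repeatedly tries
to decrement the state while rotating its direction anticlockwise by
pi/3; a negative state increments and rotates clockwise.  Each rotation
rigidly translates the monomer's *head* (all monomers after it in the
chain) by the direction two steps around the hexagonal direction tuple.
A move is *blocked* when the translated head would overlap the tail.

A configuration of a fixed program is canonically encoded by its
move-count vector ``delta_s`` (number of rule applications per monomer);
states, directions and positions are all derived from it, keeping the
whole state space exactly enumerable with integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    BlockedMove,
    DisconnectedShape,
    RangeError,
    SelfIntersection,
)

GridPoint = tuple[int, int]

#: Unit vectors in anticlockwise order: x, y, w, -x, -y, -w.
DIRECTION_VECTORS: tuple[GridPoint, ...] = (
    (1, 0),
    (0, 1),
    (-1, 1),
    (-1, 0),
    (0, -1),
    (1, -1),
)


class Direction(IntEnum):
    """One of the six unit directions, indexed anticlockwise from east."""

    X = 0
    Y = 1
    W = 2
    NEG_X = 3
    NEG_Y = 4
    NEG_W = 5

    @property
    def vector(self) -> GridPoint:
        return DIRECTION_VECTORS[self.value]


VECTOR_TO_DIRECTION: dict[GridPoint, Direction] = {
    v: Direction(i) for i, v in enumerate(DIRECTION_VECTORS)
}

_DIR_VECS = np.array(DIRECTION_VECTORS, dtype=np.int64)


def rotate_direction(d: Direction, steps: int) -> Direction:
    """Rotate a direction by ``steps`` multiples of pi/3 (anticlockwise)."""
    return Direction((int(d) + steps) % 6)


def grid_neighbors(p: GridPoint) -> Iterator[GridPoint]:
    """The six triangular-grid neighbours of a point."""
    x, y = p
    for dx, dy in DIRECTION_VECTORS:
        yield (x + dx, y + dy)


def _check_connected(points: frozenset[GridPoint]) -> bool:
    if not points:
        return True
    seen = set()
    stack = [next(iter(points))]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        for q in grid_neighbors(p):
            if q in points and q not in seen:
                stack.append(q)
    return len(seen) == len(points)


@dataclass(frozen=True)
class Shape:
    """A finite connected set of triangular-grid points."""

    points: frozenset[GridPoint]

    def __init__(self, points: Iterable[GridPoint]):
        pts = frozenset((int(x), int(y)) for x, y in points)
        if not _check_connected(pts):
            raise DisconnectedShape(
                "point set is not connected under 6-neighbour adjacency"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, p: GridPoint) -> bool:
        return p in self.points

    def __iter__(self) -> Iterator[GridPoint]:
        return iter(self.points)

    def rows(self) -> dict[int, list[int]]:
        """Map each y-coordinate to its sorted list of x-coordinates."""
        rows: dict[int, list[int]] = {}
        for x, y in self.points:
            rows.setdefault(y, []).append(x)
        for xs in rows.values():
            xs.sort()
        return rows

    def is_y_monotone(self) -> bool:
        """True iff every row is a contiguous segment of x-coordinates."""
        for xs in self.rows().values():
            if xs[-1] - xs[0] != len(xs) - 1:
                return False
        return True

    def is_xy_connected(self) -> bool:
        """True iff the shape stays connected after removing w-parallel edges."""
        pts = self.points
        if not pts:
            return True
        seen: set[GridPoint] = set()
        stack = [next(iter(pts))]
        xy_steps = ((1, 0), (-1, 0), (0, 1), (0, -1))
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            for dx, dy in xy_steps:
                q = (p[0] + dx, p[1] + dy)
                if q in pts and q not in seen:
                    stack.append(q)
        return len(seen) == len(pts)

    def translate(self, offset: GridPoint) -> "Shape":
        ox, oy = offset
        return Shape((x + ox, y + oy) for x, y in self.points)


def _validate_path(points: Sequence[GridPoint]) -> tuple[Direction, ...]:
    """Check a point sequence is a self-avoiding unit-step grid path.

    Returns the per-step directions (length ``len(points) - 1``).
    """
    if len(set(points)) != len(points):
        raise SelfIntersection("path repeats a grid point")
    dirs = []
    for a, b in zip(points, points[1:]):
        step = (b[0] - a[0], b[1] - a[1])
        if step not in VECTOR_TO_DIRECTION:
            raise ValueError(f"step {a} -> {b} is not a unit grid step")
        dirs.append(VECTOR_TO_DIRECTION[step])
    return tuple(dirs)


@dataclass(frozen=True)
class Program:
    """A turning-machine instance: initial states plus initial geometry.

    ``states0[i]`` is the initial turning number of monomer ``m_i``; the
    initial positions default to the east-pointing line ``(i, 0)`` with
    ``m_0`` at the origin.
    """

    states0: tuple[int, ...]
    initial_positions: tuple[GridPoint, ...]
    name: str = ""

    def __init__(
        self,
        states0: Sequence[int],
        initial_positions: Sequence[GridPoint] | None = None,
        name: str = "",
    ):
        states = tuple(int(s) for s in states0)
        if not states:
            raise ValueError("a program needs at least one monomer")
        if initial_positions is None:
            positions = tuple((i, 0) for i in range(len(states)))
        else:
            positions = tuple((int(x), int(y)) for x, y in initial_positions)
        if len(positions) != len(states):
            raise ValueError("states and initial positions differ in length")
        if positions[0] != (0, 0):
            raise ValueError("the first monomer must sit at the origin")
        _validate_path(positions)
        object.__setattr__(self, "states0", states)
        object.__setattr__(self, "initial_positions", positions)
        object.__setattr__(self, "name", name)

    @property
    def n(self) -> int:
        return len(self.states0)

    @cached_property
    def move_caps(self) -> tuple[int, ...]:
        """Per-monomer total number of moves, ``|s0(m_i)|``."""
        return tuple(abs(s) for s in self.states0)

    @property
    def total_moves(self) -> int:
        return sum(self.move_caps)

    @cached_property
    def state_set(self) -> range:
        lo = min(min(self.states0), 0)
        hi = max(max(self.states0), 0)
        return range(lo, hi + 1)

    # --- private engine arrays -------------------------------------------

    @cached_property
    def _init_dir_idx(self) -> np.ndarray:
        """Initial direction index per monomer; the last entry is a dummy 0."""
        dirs = _validate_path(self.initial_positions)
        arr = np.zeros(self.n, dtype=np.int64)
        arr[: self.n - 1] = [int(d) for d in dirs]
        return arr

    @cached_property
    def _signs(self) -> np.ndarray:
        return np.sign(np.array(self.states0, dtype=np.int64))

    @cached_property
    def _states0_arr(self) -> np.ndarray:
        return np.array(self.states0, dtype=np.int64)

    @cached_property
    def _caps_arr(self) -> np.ndarray:
        return np.abs(self._states0_arr)

    @cached_property
    def _code_offset(self) -> int:
        ext = max(
            max(abs(x), abs(y)) for x, y in self.initial_positions
        )
        return self.n + ext + 2

    @cached_property
    def _code_stride(self) -> int:
        return 2 * self._code_offset + 1

    @cached_property
    def _delta_codes(self) -> np.ndarray:
        s = self._code_stride
        return np.array([dx * s + dy for dx, dy in DIRECTION_VECTORS], dtype=np.int64)


# ---------------------------------------------------------------------------
# Raw-array engine.  These functions operate on a program plus a move-count
# array and are shared by the object API, the sampler and the reachability
# search.


def geometry_arrays(
    program: Program, move_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive (positions, direction indices, states) from move counts.

    Positions are the prefix sums, from the origin, of each monomer's
    current direction (initial direction rotated by ``sign(s0) * delta_s``).
    The direction entry of the last monomer is a dummy; it has no
    direction.  No simplicity check is performed here.
    """
    dirs = (program._init_dir_idx + program._signs * move_counts) % 6
    states = program._states0_arr - program._signs * move_counts
    n = program.n
    pos = np.empty((n, 2), dtype=np.int64)
    pos[0] = program.initial_positions[0]
    if n > 1:
        np.cumsum(_DIR_VECS[dirs[:-1]], axis=0, out=pos[1:])
    return pos, dirs, states


def applicable_mask(
    program: Program,
    pos: np.ndarray,
    dirs: np.ndarray,
    states: np.ndarray,
) -> np.ndarray:
    """Boolean mask of monomers whose turning rule is applicable.

    A rule at ``m_i`` translates every monomer after ``i`` by the unit
    vector two steps (anticlockwise for positive state, clockwise for
    negative) around the direction tuple from ``m_i``'s direction; it is
    blocked iff the translated head intersects the tail.  Equivalently,
    a head/tail pair ``(a <= i < j)`` with ``pos[a] = pos[j] + t`` blocks
    every monomer ``i`` in ``[a, j)`` whose translation vector is ``t``.
    Unit-vector pairs are found with one sorted lookup per direction.
    """
    n = program.n
    nonzero = states != 0
    if not nonzero.any():
        return nonzero
    stride = program._code_stride
    code = (pos[:, 0] * stride + pos[:, 1]).astype(np.int64)
    order = np.argsort(code, kind="stable")
    sorted_code = code[order]
    sign = np.where(states >= 0, 1, -1)
    trans_idx = (dirs + 2 * sign) % 6
    covered = np.zeros((6, n + 1), dtype=np.int64)
    dcodes = program._delta_codes
    any_pair = False
    for k in range(6):
        target = code + dcodes[k]
        idx = np.searchsorted(sorted_code, target)
        idx_c = np.minimum(idx, n - 1)
        found = sorted_code[idx_c] == target
        j = np.nonzero(found)[0]
        if j.size == 0:
            continue
        a = order[idx_c[j]]
        keep = a < j
        if not keep.any():
            continue
        any_pair = True
        np.add.at(covered[k], a[keep], 1)
        np.add.at(covered[k], j[keep], -1)
    if any_pair:
        blocked = np.cumsum(covered[:, :n], axis=1)[trans_idx, np.arange(n)] > 0
    else:
        blocked = np.zeros(n, dtype=bool)
    mask = nonzero & ~blocked
    mask[n - 1] = nonzero[n - 1]  # empty head: the last monomer never blocks
    return mask


# ---------------------------------------------------------------------------
# Configuration objects.


class Configuration:
    """A reachable chain embedding, encoded by its move-count vector."""

    __slots__ = ("program", "move_counts", "_pos", "_dirs", "_states")

    def __init__(self, program: Program, move_counts: Sequence[int], _arrays=None):
        self.program = program
        self.move_counts = tuple(int(m) for m in move_counts)
        if _arrays is not None:
            self._pos, self._dirs, self._states = _arrays
        else:
            self._pos = None
            self._dirs = None
            self._states = None

    def _ensure(self) -> None:
        if self._pos is None:
            self._pos, self._dirs, self._states = geometry_arrays(
                self.program, np.array(self.move_counts, dtype=np.int64)
            )

    @property
    def n(self) -> int:
        return self.program.n

    @property
    def positions(self) -> tuple[GridPoint, ...]:
        self._ensure()
        return tuple(map(tuple, self._pos.tolist()))

    @property
    def states(self) -> tuple[int, ...]:
        self._ensure()
        return tuple(self._states.tolist())

    def direction(self, i: int) -> Direction:
        """Direction of monomer ``m_i`` (undefined for the last monomer)."""
        if not 0 <= i < self.n - 1:
            raise IndexError("only monomers 0..n-2 point in a direction")
        self._ensure()
        return Direction(int(self._dirs[i]))

    @property
    def is_final(self) -> bool:
        self._ensure()
        return bool((self._states == 0).all())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Configuration)
            and self.program == other.program
            and self.move_counts == other.move_counts
        )

    def __hash__(self) -> int:
        return hash((self.program.states0, self.move_counts))

    def __repr__(self) -> str:
        return f"Configuration(move_counts={self.move_counts})"


def reconstruct_configuration(
    program: Program, move_counts: Sequence[int]
) -> Configuration:
    """Build and validate the configuration with the given move counts.

    Raises ``RangeError`` if a count exceeds ``|s0|`` and
    ``SelfIntersection`` if the derived chain repeats a point.
    """
    mc = np.array([int(m) for m in move_counts], dtype=np.int64)
    if len(mc) != program.n:
        raise ValueError("move-count vector length does not match the program")
    if (mc < 0).any() or (mc > program._caps_arr).any():
        raise RangeError("a move count is negative or exceeds |s0|")
    arrays = geometry_arrays(program, mc)
    pos = arrays[0]
    if len({(int(x), int(y)) for x, y in pos}) != program.n:
        raise SelfIntersection("reconstructed chain repeats a grid point")
    return Configuration(program, mc.tolist(), _arrays=arrays)


def initial_configuration(program: Program) -> Configuration:
    return reconstruct_configuration(program, [0] * program.n)


def target_configuration(program: Program) -> Configuration:
    """The all-states-zero configuration (may raise ``SelfIntersection``)."""
    return reconstruct_configuration(program, program.move_caps)


def rule_applicable(c: Configuration, i: int) -> bool:
    """Direct geometric applicability test for the rule at monomer ``m_i``.

    This is the literal definition — translate the head, intersect with
    the tail — kept independent of the vectorised engine so the two can
    be cross-checked.
    """
    n = c.n
    if not 0 <= i < n:
        raise IndexError(f"monomer index {i} out of range")
    states = c.states
    if states[i] == 0:
        return False
    if i == n - 1:
        return True  # empty head can never collide
    d = c.direction(i)
    shift = rotate_direction(d, 2 if states[i] > 0 else -2).vector
    positions = c.positions
    tail = set(positions[: i + 1])
    for x, y in positions[i + 1 :]:
        if (x + shift[0], y + shift[1]) in tail:
            return False
    return True


def applicable_moves(c: Configuration) -> list[int]:
    """Indices of all monomers with an applicable rule, in increasing order."""
    c._ensure()
    mask = applicable_mask(c.program, c._pos, c._dirs, c._states)
    return [int(i) for i in np.nonzero(mask)[0]]


def apply_rule(c: Configuration, i: int) -> Configuration:
    """Apply the turning rule at monomer ``m_i``; raises ``BlockedMove``."""
    if not 0 <= i < c.n:
        raise IndexError(f"monomer index {i} out of range")
    if not rule_applicable(c, i):
        raise BlockedMove(f"rule not applicable at monomer {i}")
    mc = list(c.move_counts)
    mc[i] += 1
    return Configuration(c.program, mc)


def turn_angle(c: Configuration, i: int) -> int:
    """Signed turn angle at monomer ``m_i`` in units of pi/3.

    Positive iff ``pos(m_{i-1}), pos(m_i), pos(m_{i+1})`` make a left
    (anticlockwise) turn; value is in ``{-2, -1, 0, 1, 2}``.
    """
    if not 0 < i < c.n - 1:
        raise IndexError("turn angle defined for interior monomers only")
    c._ensure()
    d = int(c._dirs[i] - c._dirs[i - 1]) % 6
    if d == 3:
        raise SelfIntersection("straight reversal implies a repeated point")
    return d - 6 if d > 3 else d


def is_permanently_blocked(c: Configuration) -> bool:
    """True iff some state is nonzero yet no monomer has an applicable rule."""
    c._ensure()
    if (c._states == 0).all():
        return False
    mask = applicable_mask(c.program, c._pos, c._dirs, c._states)
    return not mask.any()


def folding_error(c: Configuration, shape: Shape) -> int:
    """Size of the symmetric difference between the chain and the shape."""
    return len(set(c.positions) ^ shape.points)
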