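"""Compilers from target geometry to turning-number programs.

The fundamental primitive is the line rotation machine ``L_n^s`` (a
line of ``n`` monomers, every state ``s``), which folds for ``1 <= s <=
5``.  Zig-zag paths — self-avoiding paths using only ``+-x, +y, +w``
steps (or their mirror ``+-x, -y, -w``) — are compiled monomer-by-
monomer from the target direction of each chain edge; squares and
y-monotone shapes are rastered into zig-zag traversals; xy-connected
y-monotone shapes with a yw-separator are folded at scale factor 2 with
zero error by splitting the doubled shape into a clockwise (negative
state) lobe and an anticlockwise (positive state) lobe that provably
never block each other.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    Configuration,
    Direction,
    GridPoint,
    Program,
    Shape,
    _validate_path,
    grid_neighbors,
    reconstruct_configuration,
)
from .errors import (
    NoSeparator,
    NotAtOrigin,
    NotXYConnected,
    NotYMonotone,
    NotZigZag,
    SeparatorCutError,
)

GridPath = tuple[GridPoint, ...]

#: Positive zig-zag direction-to-state table (anticlockwise rotation order).
POSITIVE_ZIGZAG_STATES: dict[Direction, int] = {
    Direction.X: 0,
    Direction.Y: 1,
    Direction.W: 2,
    Direction.NEG_X: 3,
}

#: Negative mirror: clockwise rotation order, negative turning numbers.
NEGATIVE_ZIGZAG_STATES: dict[Direction, int] = {
    Direction.X: 0,
    Direction.NEG_W: -1,
    Direction.NEG_Y: -2,
    Direction.NEG_X: -3,
}


def line_rotation_program(n: int, s: int) -> tuple[Program, Configuration]:
    """The line rotation machine ``L_n^s`` and its target configuration.

    ``n`` monomers start on the x-axis pointing east; all but the last
    carry state ``s``.  The target is the straight line along the ray at
    angle ``s * pi/3`` from the origin.
    """
    if n < 1:
        raise ValueError("need at least one monomer")
    states = [s] * (n - 1) + [0]
    program = Program(states, name=f"L{n}^{s}")
    target = reconstruct_configuration(program, program.move_caps)
    return program, target


def compile_zigzag(path: GridPath, name: str = "") -> Program:
    """Compile a zig-zag path into the turning machine that folds it.

    The path must start at the origin and use only steps in
    ``{+-x, +y, +w}`` (positive) or ``{+-x, -y, -w}`` (negative).  Each
    monomer's initial state is read off the table for its direction in
    the folded chain; the last monomer gets 0.
    """
    path = tuple((int(x), int(y)) for x, y in path)
    if not path:
        raise ValueError("empty path")
    if path[0] != (0, 0):
        raise NotAtOrigin("zig-zag paths must start at the origin")
    dirs = _validate_path(path)
    used = set(dirs)
    if used <= POSITIVE_ZIGZAG_STATES.keys():
        table = POSITIVE_ZIGZAG_STATES
    elif used <= NEGATIVE_ZIGZAG_STATES.keys():
        table = NEGATIVE_ZIGZAG_STATES
    else:
        raise NotZigZag(f"steps {sorted(d.name for d in used)} mix the two zig-zag classes")
    states = [table[d] for d in dirs] + [0]
    return Program(states, name=name or f"zigzag-{len(path)}")


def square_path(n: int) -> GridPath:
    """Boustrophedon raster of the ``n x n`` square, a positive zig-zag path.

    Row 0 runs west to east, then a ``+y`` step, row 1 east to west, and
    so on; all ``n**2`` points ``0 <= x, y < n`` are covered.
    """
    if n < 1:
        raise ValueError("n must be positive")
    pts: list[GridPoint] = []
    for y in range(n):
        xs = range(n) if y % 2 == 0 else range(n - 1, -1, -1)
        pts.extend((x, y) for x in xs)
    return tuple(pts)


def compile_square(n: int) -> tuple[Program, Shape]:
    """Program folding the ``n x n`` square with zero error."""
    path = square_path(n)
    return compile_zigzag(path, name=f"square-{n}"), Shape(path)


def perimeter(shape: Shape) -> frozenset[GridPoint]:
    """Shape points with at least one of their six neighbours outside."""
    pts = shape.points
    return frozenset(
        p for p in pts if any(q not in pts for q in grid_neighbors(p))
    )


def scale_shape(shape: Shape, k: int) -> Shape:
    """Replace every point ``(i, j)`` by the ``k x k`` block at ``(ki, kj)``."""
    if k < 1:
        raise ValueError("scale factor must be >= 1")
    return Shape(
        (k * i + a, k * j + b)
        for i, j in shape.points
        for a in range(k)
        for b in range(k)
    )


def _row_segments(shape: Shape) -> list[tuple[int, int, int]]:
    """Rows of a y-monotone shape as (y, left, right), bottom to top."""
    segs = []
    for y, xs in sorted(shape.rows().items()):
        if xs[-1] - xs[0] != len(xs) - 1:
            raise NotYMonotone(f"row y={y} is not a contiguous segment")
        segs.append((y, xs[0], xs[-1]))
    return segs


@dataclass
class Traversal:
    """A zig-zag traversal covering a shape, with its error certificate."""

    path: GridPath
    extra_points: frozenset[GridPoint]

    @property
    def error(self) -> int:
        return len(self.extra_points)


def ymonotone_traversal(shape: Shape) -> Traversal:
    """Zig-zag traversal of a connected y-monotone shape.

    Rows are concatenated bottom to top, even rows left-to-right and odd
    rows right-to-left; each row segment is extended sideways by the
    points needed to land directly below/above the turning point of the
    neighbouring row.  Every added point is adjacent to a perimeter
    point of the shape, which bounds the folding error by the perimeter
    length.
    """
    segs = _row_segments(shape)
    ys = [y for y, _, _ in segs]
    if ys != list(range(ys[0], ys[0] + len(ys))):
        raise NotYMonotone("rows are not consecutive in y")
    path: list[GridPoint] = []
    extras: set[GridPoint] = set()
    H = len(segs)
    for i, (y, l, r) in enumerate(segs):
        if i % 2 == 0:
            left = min(l, segs[i - 1][1]) if i > 0 else l
            right = max(r, segs[i + 1][2]) if i + 1 < H else r
            xs = range(left, right + 1)
        else:
            left = min(l, segs[i + 1][1]) if i + 1 < H else l
            right = max(r, segs[i - 1][2]) if i > 0 else r
            xs = range(right, left - 1, -1)
        for x in xs:
            path.append((x, y))
            if not l <= x <= r:
                extras.add((x, y))
    _validate_path(path)
    return Traversal(path=tuple(path), extra_points=frozenset(extras))


def compile_ymonotone(shape: Shape) -> tuple[Program, Traversal, GridPoint]:
    """Compile a y-monotone shape via its zig-zag traversal.

    Returns the program, the traversal (in shape coordinates) and the
    offset that translates the traversal so its first point is the
    origin, where the machine folds it.
    """
    trav = ymonotone_traversal(shape)
    x0, y0 = trav.path[0]
    shifted = tuple((x - x0, y - y0) for x, y in trav.path)
    return compile_zigzag(shifted, name="ymonotone"), trav, (-x0, -y0)


# ---------------------------------------------------------------------------
# Factor-2 scaled folding via yw-separators.


def find_yw_separator(shape: Shape) -> list[GridPoint] | None:
    """A chain from the bottom to the top row using only +y / +w steps.

    Forward row-by-row marking of reachable points followed by leftmost-
    predecessor backtracking; returns None when no chain exists.
    """
    segs = _row_segments(shape)
    pts = shape.points
    marked: list[set[int]] = [set(range(segs[0][1], segs[0][2] + 1))]
    for (y, l, r) in segs[1:]:
        prev = marked[-1]
        cur = set()
        for x in range(l, r + 1):
            # predecessor via +y is (x, y-1); via +w is (x+1, y-1)
            if x in prev or (x + 1) in prev:
                cur.add(x)
        marked.append(cur)
        if not cur:
            return None
    chain: list[GridPoint] = []
    x = min(marked[-1])
    for i in range(len(segs) - 1, -1, -1):
        y = segs[i][0]
        chain.append((x, y))
        if i > 0:
            prev = marked[i - 1]
            if x in prev:
                pass  # +y predecessor, keep x
            elif (x + 1) in prev:
                x = x + 1
            else:  # pragma: no cover - marking guarantees a predecessor
                raise AssertionError("marking invariant violated")
    chain.reverse()
    assert all(p in pts for p in chain)
    return chain


def _find_cuttable_separator(shape: Shape) -> list[GridPoint] | None:
    """A yw-separator whose factor-2 cut is realisable.

    Dynamic programme over (x, last-split-style) per row: a +y step
    always splits 2+2; a +w step needs the 1+3 split (requires
    ``c_i - (1,0)`` in the shape and no preceding 3+1 split) or the 3+1
    split (requires ``c_{i+1} + (1,0)`` in the shape).  Returns None
    when no separator admits a valid cut.
    """
    segs = _row_segments(shape)
    pts = shape.points
    # style "A": boundary sits on the doubled separator column;
    # style "B": one column right (after a 3+1 split).
    layer: dict[tuple[int, str], tuple[int, str] | None] = {
        (x, "A"): None for x in range(segs[0][1], segs[0][2] + 1)
    }
    layers = [layer]
    for (y_prev, _, _), (y, l, r) in zip(segs, segs[1:]):
        nxt: dict[tuple[int, str], tuple[int, str]] = {}
        for (x, st) in layers[-1]:
            if l <= x <= r and (x, "A") not in nxt:
                nxt[(x, "A")] = (x, st)  # +y step, 2+2 split
            xn = x - 1
            if l <= xn <= r:
                if st != "B" and (x - 1, y_prev) in pts and (xn, "A") not in nxt:
                    nxt[(xn, "A")] = (x, st)  # +w step, 1+3 split
                if (x, y) in pts and (xn, "B") not in nxt:
                    nxt[(xn, "B")] = (x, st)  # +w step, 3+1 split
        if not nxt:
            return None
        layers.append(nxt)
    # backtrack, preferring an A-style endpoint
    key = min(layers[-1], key=lambda k: (k[1] != "A", k[0]))
    chain: list[GridPoint] = []
    for (yy, _, _), lay in zip(reversed(segs), reversed(layers)):
        chain.append((key[0], yy))
        prev = lay[key]
        if prev is None:
            break
        key = prev
    chain.reverse()
    return chain


@dataclass
class ScaledCompilation:
    """Result of the factor-2 compiler: program, split and traversal."""

    program: Program
    shape: Shape  # the original (unscaled) shape
    scaled: Shape
    separator: list[GridPoint]
    c_left: list[GridPoint]  # right boundary of the left lobe, bottom to top
    c_right: list[GridPoint]  # left boundary of the right lobe
    traversal: GridPath  # in scaled-shape coordinates
    offset: GridPoint  # traversal[0] maps to the origin

    @property
    def target_shape(self) -> Shape:
        return self.scaled.translate(self.offset)

    @property
    def target(self) -> Configuration:
        return reconstruct_configuration(self.program, self.program.move_caps)


def _split_boundaries(
    shape: Shape, sep: list[GridPoint]
) -> tuple[list[GridPoint], list[GridPoint]]:
    """Cut the doubled shape between the doubled separator points.

    Returns one boundary point per row of the scaled shape for each
    lobe: ``c_left`` (rightmost points of the left lobe) and ``c_right``
    (leftmost points of the right lobe), bottom to top.  Vertical
    separator steps split the four doubled points 2+2; w-parallel steps
    split 1+3 or 3+1 depending on which side of the step belongs to the
    shape (when both do, the 3+1 split is preferred because it keeps the
    next split unconstrained).
    """
    pts = shape.points
    c_left: list[GridPoint] = []
    c_right: list[GridPoint] = []
    (x1, y1) = sep[0]
    c_left.append((2 * x1, 2 * y1))
    c_right.append((2 * x1 + 1, 2 * y1))
    b_style = False  # True when the previous w-step used the 3+1 split
    for (xa, ya), (xb, yb) in zip(sep, sep[1:]):
        if xb == xa:  # +y step
            c_left.append((2 * xa, 2 * ya + 1))
            c_right.append((2 * xa + 1, 2 * ya + 1))
            c_left.append((2 * xb, 2 * yb))
            c_right.append((2 * xb + 1, 2 * yb))
            b_style = False
            continue
        # +w step: xb == xa - 1
        case_a = (xa - 1, ya) in pts and not b_style
        case_b = (xb + 1, yb) in pts
        if case_a:
            c_left.append((2 * xa - 1, 2 * ya + 1))
            c_right.append((2 * xa, 2 * ya + 1))
            c_left.append((2 * xb, 2 * yb))
            c_right.append((2 * xb + 1, 2 * yb))
            b_style = False
        elif case_b:
            c_left.append((2 * xa, 2 * ya + 1))
            c_right.append((2 * xa + 1, 2 * ya + 1))
            c_left.append((2 * xb + 1, 2 * yb))
            c_right.append((2 * xb + 2, 2 * yb))
            b_style = True
        else:
            raise SeparatorCutError(
                f"no valid split at separator step {(xa, ya)} -> {(xb, yb)}"
            )
    (xk, yk) = sep[-1]
    c_left.append((2 * xk, 2 * yk + 1))
    c_right.append((2 * xk + 1, 2 * yk + 1))
    # validate both boundaries are yw-chains
    for chain in (c_left, c_right):
        for (ax, ay), (bx, by) in zip(chain, chain[1:]):
            if by - ay != 1 or bx - ax not in (0, -1):
                raise SeparatorCutError(
                    f"split boundary is not a yw-chain at {(ax, ay)} -> {(bx, by)}"
                )
    return c_left, c_right


def compile_scaled(shape: Shape) -> ScaledCompilation:
    """Fold the factor-2 scaling of a separator shape with zero error.

    The doubled shape is cut along the doubled separator into a left
    lobe (traversed top to bottom by monomers with negative states,
    folding clockwise) and a right lobe (bottom to top, positive
    states); the two halves are joined by a single east step in the
    bottom row.  Initial states are read from the folded direction of
    each monomer through the negative/positive zig-zag tables.
    """
    if not shape.is_y_monotone():
        raise NotYMonotone("scaled compilation needs a y-monotone shape")
    if not shape.is_xy_connected():
        raise NotXYConnected("scaled compilation needs an xy-connected shape")
    if find_yw_separator(shape) is None:
        raise NoSeparator("shape has no yw-separator")
    sep = _find_cuttable_separator(shape)
    if sep is None:
        raise SeparatorCutError(
            "no yw-separator of this shape admits a valid factor-2 cut"
        )
    scaled = scale_shape(shape, 2)
    c_left, c_right = _split_boundaries(shape, sep)
    segs2 = _row_segments(scaled)
    rows = {y: (l, r) for y, l, r in segs2}
    H2 = len(segs2)
    y0 = segs2[0][0]
    assert H2 == len(c_left) == len(c_right)

    path: list[GridPoint] = []
    # left lobe, top to bottom; pairs (top row 2j+1, bottom row 2j)
    for j in range(H2 // 2 - 1, -1, -1):
        ytop, ybot = y0 + 2 * j + 1, y0 + 2 * j
        ltop = rows[ytop][0]
        lbot = rows[ybot][0]
        cx_top = c_left[2 * j + 1][0]
        cx_bot = c_left[2 * j][0]
        path.extend((x, ytop) for x in range(cx_top, ltop - 1, -1))
        path.extend((x, ybot) for x in range(lbot, cx_bot + 1))
    # junction: c_left bottom -> c_right bottom is a +x step
    # right lobe, bottom to top
    for j in range(H2 // 2):
        ybot, ytop = y0 + 2 * j, y0 + 2 * j + 1
        rbot = rows[ybot][1]
        rtop = rows[ytop][1]
        cx_bot = c_right[2 * j][0]
        cx_top = c_right[2 * j + 1][0]
        path.extend((x, ybot) for x in range(cx_bot, rbot + 1))
        path.extend((x, ytop) for x in range(rtop, cx_top - 1, -1))
    if len(path) != len(scaled):
        raise SeparatorCutError("traversal does not cover the scaled shape once")
    dirs = _validate_path(path)

    left_lobe: set[GridPoint] = set()
    for (y, l, r) in segs2:
        cx = c_left[y - y0][0]
        left_lobe.update((x, y) for x in range(l, cx + 1))
    states = []
    for i, d in enumerate(dirs):
        table = (
            NEGATIVE_ZIGZAG_STATES if path[i] in left_lobe else POSITIVE_ZIGZAG_STATES
        )
        if d not in table:
            raise SeparatorCutError(f"traversal step {d.name} outside lobe class")
        states.append(table[d])
    states.append(0)
    program = Program(states, name="scaled2")
    x0, yy0 = path[0]
    return ScaledCompilation(
        program=program,
        shape=shape,
        scaled=scaled,
        separator=sep,
        c_left=c_left,
        c_right=c_right,
        traversal=tuple(path),
        offset=(-x0, -yy0),
    )
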