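"""Synthetic shape generators for tests, experiments and the CLI.

All generators are deterministic given a seed and every output
validates against its own class predicate (y-monotone, xy-connected,
separator existence).
"""

from __future__ import annotations

import numpy as np

from .core import Shape
from .compilers import find_yw_separator
from .errors import BadParams
from .spirals import spiral_shape


def square_shape(n: int) -> Shape:
    if n < 1:
        raise BadParams("square side must be >= 1")
    return Shape((x, y) for x in range(n) for y in range(n))


def cross_shape(arm: int) -> Shape:
    """A plus sign with width-1 arms of the given length (4*arm+1 points).

    y-monotone, but for arm >= 2 it has no traversal (no Hamiltonian
    path), so any folding of it has error > 0.
    """
    if arm < 1:
        raise BadParams("arm length must be >= 1")
    pts = {(x, 0) for x in range(-arm, arm + 1)}
    pts |= {(0, y) for y in range(-arm, arm + 1)}
    return Shape(pts)


def random_ymonotone_shape(
    height: int, max_width: int, seed: int | None = None
) -> Shape:
    """Random y-monotone shape: rows are random segments, consecutive
    rows forced to be adjacent (segments [l,r] and [l',r'] one row up
    are adjacent under +y/+w steps iff l' <= r and r' >= l - 1)."""
    if height < 1 or max_width < 1:
        raise BadParams("height and max_width must be >= 1")
    rng = np.random.default_rng(seed)
    pts = []
    l, r = 0, int(rng.integers(0, max_width))
    for y in range(height):
        pts.extend((x, y) for x in range(l, r + 1))
        if y == height - 1:
            break
        while True:
            nl = int(rng.integers(l - max_width, r + 1))
            nr = int(rng.integers(nl, nl + max_width))
            if nl <= r and nr >= l - 1:
                break
        l, r = nl, nr
    return Shape(pts)


def random_separator_shape(
    height: int, max_margin: int = 3, seed: int | None = None
) -> Shape:
    """Random xy-connected y-monotone shape with a yw-separator.

    A separator chain of +y/+w steps is laid down first and each row is
    grown around it with random margins.  At every +w step the point
    right of the upper chain point is kept in the shape, which (a)
    makes consecutive rows share an x-column (xy-connectivity) and (b)
    guarantees the factor-2 split always has a valid 3+1 cut.
    """
    if height < 1:
        raise BadParams("height must be >= 1")
    rng = np.random.default_rng(seed)
    xs = [0]
    for _ in range(height - 1):
        xs.append(xs[-1] - int(rng.integers(0, 2)))
    pts = []
    for y, cx in enumerate(xs):
        lo = cx - int(rng.integers(0, max_margin + 1))
        hi = cx + int(rng.integers(0, max_margin + 1))
        if y + 1 < height and xs[y + 1] == cx - 1:
            lo = min(lo, cx - 1)  # room for the +w step's right neighbour
        if y > 0 and xs[y - 1] == cx + 1:
            hi = max(hi, cx + 1)  # the point right of c_{i+1} stays in S
        pts.extend((x, y) for x in range(lo, hi + 1))
    shape = Shape(pts)
    assert shape.is_y_monotone() and shape.is_xy_connected()
    assert find_yw_separator(shape) is not None
    return shape


def synthesize_shape(kind: str, params: dict, seed: int | None = None) -> Shape:
    """Dispatcher used by the CLI: square, cross, ymonotone_random,
    separator_random or spiral."""
    try:
        if kind == "square":
            return square_shape(int(params["n"]))
        if kind == "cross":
            return cross_shape(int(params["arm"]))
        if kind == "ymonotone_random":
            return random_ymonotone_shape(
                int(params["height"]), int(params["max_width"]), seed
            )
        if kind == "separator_random":
            return random_separator_shape(
                int(params["height"]), int(params.get("max_margin", 3)), seed
            )
        if kind == "spiral":
            return spiral_shape(int(params["k"]))[0]
    except KeyError as e:
        raise BadParams(f"missing parameter {e} for kind {kind!r}")
    raise BadParams(f"unknown shape kind {kind!r}")
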