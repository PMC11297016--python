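"""Plain-text file formats for shapes, programs and trajectory logs.

Shapes are ``.grid`` files: one ``x y`` axial-integer pair per line,
``#`` comments.  Programs are ``.tmprog`` files with ``key value``
lines (``name``, ``states``, optional ``positions``).  Both round-trip
losslessly; axial integers are used throughout so grid arithmetic stays
exact (Cartesian conversion is confined to rendering).
"""

from __future__ import annotations

import os

from .core import Program, Shape
from .dynamics import Trajectory
from .errors import ParseError


def write_shape(shape: Shape, pathname: str | os.PathLike, comment: str = "") -> None:
    with open(pathname, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for x, y in sorted(shape.points):
            fh.write(f"{x} {y}\n")


def read_shape(pathname: str | os.PathLike) -> Shape:
    points: list[tuple[int, int]] = []
    seen = set()
    with open(pathname) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"expected 'x y', got {line!r}", lineno)
            try:
                p = (int(parts[0]), int(parts[1]))
            except ValueError:
                raise ParseError(f"non-integer coordinate in {line!r}", lineno)
            if p in seen:
                raise ParseError(f"duplicate point {p}", lineno)
            seen.add(p)
            points.append(p)
    if not points:
        raise ParseError("no points in shape file")
    return Shape(points)  # raises DisconnectedShape if disconnected


def write_program(program: Program, pathname: str | os.PathLike) -> None:
    default_line = tuple((i, 0) for i in range(program.n))
    with open(pathname, "w") as fh:
        if program.name:
            fh.write(f"name {program.name}\n")
        fh.write("states " + " ".join(map(str, program.states0)) + "\n")
        if program.initial_positions != default_line:
            flat = " ".join(f"{x} {y}" for x, y in program.initial_positions)
            fh.write("positions " + flat + "\n")


def read_program(pathname: str | os.PathLike) -> Program:
    name = ""
    states: list[int] | None = None
    positions: list[tuple[int, int]] | None = None
    with open(pathname) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, rest = line.partition(" ")
            if key == "name":
                name = rest.strip()
            elif key == "states":
                try:
                    states = [int(t) for t in rest.split()]
                except ValueError:
                    raise ParseError("non-integer state", lineno)
            elif key == "positions":
                toks = rest.split()
                if len(toks) % 2:
                    raise ParseError("odd number of coordinates", lineno)
                try:
                    positions = [
                        (int(toks[i]), int(toks[i + 1]))
                        for i in range(0, len(toks), 2)
                    ]
                except ValueError:
                    raise ParseError("non-integer coordinate", lineno)
            else:
                raise ParseError(f"unknown key {key!r}", lineno)
    if states is None:
        raise ParseError("missing 'states' line")
    return Program(states, positions, name=name)


def write_trajectory_log(trajectory: Trajectory, pathname: str | os.PathLike) -> None:
    """Line-delimited step log: step index, monomer, waiting time, move counts."""
    with open(pathname, "w") as fh:
        fh.write("# step\tmonomer\twait\tmove_counts\n")
        for rec in trajectory.log_records():
            fh.write(rec + "\n")
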