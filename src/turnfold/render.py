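"""Deterministic SVG and ASCII rendering of configurations.

Axial coordinates map to Cartesian as ``(x + y/2, y * sqrt(3)/2)``.
Monomers are drawn as disks joined by chain bonds; a monomer with a
nonzero state but no applicable rule (a blocked monomer) is highlighted
in red, finished monomers (state 0) in gold, active ones in blue.
"""

from __future__ import annotations

import math


from .core import Configuration, applicable_mask

_SQ3_2 = math.sqrt(3) / 2


def _cartesian(p: tuple[int, int]) -> tuple[float, float]:
    x, y = p
    return (x + y / 2, y * _SQ3_2)


def render_configuration(c: Configuration, mode: str = "svg") -> str:
    if mode == "svg":
        return _render_svg(c)
    if mode == "ascii":
        return _render_ascii(c)
    raise ValueError(f"unknown render mode {mode!r}")


def _render_svg(c: Configuration, scale: float = 24.0, radius: float = 8.0) -> str:
    c._ensure()
    mask = applicable_mask(c.program, c._pos, c._dirs, c._states)
    pts = [_cartesian(p) for p in c.positions]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    pad = 1.0
    x0, y0 = min(xs) - pad, min(ys) - pad
    w = (max(xs) - x0 + pad) * scale
    h = (max(ys) - y0 + pad) * scale

    def sx(p):
        return (p[0] - x0) * scale

    def sy(p):
        # flip y so the grid's +y points up on screen
        return h - (p[1] - y0) * scale

    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.1f}" '
        f'height="{h:.1f}" viewBox="0 0 {w:.1f} {h:.1f}">'
    ]
    states = c.states
    for a, b, i in zip(pts, pts[1:], range(c.n - 1)):
        blocked = states[i] != 0 and not mask[i]
        color = "#cc2222" if blocked else "#555555"
        out.append(
            f'<line x1="{sx(a):.1f}" y1="{sy(a):.1f}" x2="{sx(b):.1f}" '
            f'y2="{sy(b):.1f}" stroke="{color}" stroke-width="3"/>'
        )
    for i, p in enumerate(pts):
        if states[i] == 0:
            fill = "#e0b020"
        elif not mask[i]:
            fill = "#cc2222"
        else:
            fill = "#3366bb"
        out.append(
            f'<circle cx="{sx(p):.1f}" cy="{sy(p):.1f}" r="{radius:.1f}" '
            f'fill="{fill}" stroke="#222222"/>'
        )
        out.append(
            f'<text x="{sx(p):.1f}" y="{sy(p) + 3:.1f}" font-size="9" '
            f'text-anchor="middle" fill="#ffffff">{states[i]}</text>'
        )
    out.append("</svg>")
    return "\n".join(out)


def _render_ascii(c: Configuration) -> str:
    """Lossy character sketch: column = 2x + y, row = -y; cells show the
    last decimal digit of the state (``.`` for state 0)."""
    pos = c.positions
    states = c.states
    cells = {}
    for (x, y), s in zip(pos, states):
        cells[(2 * x + y, -y)] = "." if s == 0 else str(abs(s) % 10)
    cols = [cx for cx, _ in cells]
    rows = [ry for _, ry in cells]
    lines = []
    for ry in range(min(rows), max(rows) + 1):
        line = []
        for cx in range(min(cols), max(cols) + 1):
            line.append(cells.get((cx, ry), " "))
        lines.append("".join(line).rstrip())
    return "\n".join(lines)
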