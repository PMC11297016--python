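"""Exhaustive reachability: foldability verdicts and blocked witnesses.

A turning machine *folds* (computes its target configuration) iff every
trajectory from the initial configuration reaches the all-states-zero
configuration.  Because each rule application removes exactly one
remaining move, all trajectories are finite and every non-terminal
configuration has a continuation, so foldability reduces to: the target
is reachable and no reachable configuration is permanently blocked.
The search is a breadth-first enumeration of move-count vectors, so
witnesses are reported in order of total move count (a first witness is
a shortest blocked configuration).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Configuration,
    Program,
    Shape,
    applicable_mask,
    folding_error,
    geometry_arrays,
    reconstruct_configuration,
)

DEFAULT_STATE_CAP = 5_000_000


@dataclass
class ReachabilityReport:
    program: Program
    reachable_count: int
    target_reachable: bool
    blocked_witnesses: list[tuple[int, ...]]
    truncated: bool

    @property
    def foldable(self) -> bool:
        return (
            self.target_reachable
            and not self.blocked_witnesses
            and not self.truncated
        )

    def witness_configurations(self) -> list[Configuration]:
        return [
            reconstruct_configuration(self.program, w)
            for w in self.blocked_witnesses
        ]


def explore(program: Program, state_cap: int = DEFAULT_STATE_CAP) -> ReachabilityReport:
    """Breadth-first enumeration of all reachable move-count vectors.

    Terminal vectors are classified as the target (all states zero) or
    as permanently blocked witnesses.  If the state cap is exceeded the
    report is flagged ``truncated`` and the verdict is withheld.
    """
    start = (0,) * program.n
    target = tuple(program.move_caps)
    seen = {start}
    queue = deque([start])
    witnesses: list[tuple[int, ...]] = []
    truncated = False
    while queue:
        v = queue.popleft()
        mc = np.array(v, dtype=np.int64)
        pos, dirs, states = geometry_arrays(program, mc)
        mask = applicable_mask(program, pos, dirs, states)
        idxs = np.nonzero(mask)[0]
        if idxs.size == 0 and v != target:
            witnesses.append(v)
        for i in idxs:
            w = list(v)
            w[i] += 1
            w = tuple(w)
            if w not in seen:
                seen.add(w)
                queue.append(w)
        if len(seen) > state_cap:
            truncated = True
            break
    return ReachabilityReport(
        program=program,
        reachable_count=len(seen),
        target_reachable=target in seen,
        blocked_witnesses=witnesses,
        truncated=truncated,
    )


@dataclass
class FoldabilityVerdict:
    foldable: bool | None
    error: int | None
    witnesses: list[tuple[int, ...]]
    report: ReachabilityReport = field(repr=False)

    @property
    def truncated(self) -> bool:
        return self.report.truncated


def foldability_verdict(
    program: Program,
    shape: Shape | None = None,
    state_cap: int = DEFAULT_STATE_CAP,
) -> FoldabilityVerdict:
    """Combine exhaustive reachability with the folding error of the target.

    ``foldable`` is None when the state cap truncated the search (an
    explicit "unknown" rather than a guess).  ``error`` is the symmetric
    difference between the unique target configuration and the shape
    (None when no shape is given or the target is not reachable).
    """
    report = explore(program, state_cap)
    error = None
    if shape is not None and report.target_reachable:
        target = reconstruct_configuration(program, program.move_caps)
        error = folding_error(target, shape)
    foldable = None if report.truncated else report.foldable
    return FoldabilityVerdict(
        foldable=foldable, error=error, witnesses=report.blocked_witnesses,
        report=report,
    )
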