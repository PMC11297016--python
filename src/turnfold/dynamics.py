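"""Continuous-time Markov chain semantics for turning machines.

Every applicable rule fires at rate 1, so a configuration with ``k``
applicable moves waits an exponential time with rate ``k`` and then
applies one of the moves uniformly at random (the standard race of
independent unit-rate exponential clocks).  Completion-time statistics
are estimated by sampling; on small instances the expected absorption
time is computed exactly by a backward sweep over the reachable DAG
(the total move count increases by one on every step, so configurations
ordered by total moves are already topologically sorted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core import (
    Configuration,
    Program,
    applicable_mask,
    geometry_arrays,
)
from .errors import StateCapExceeded

TERMINAL_TARGET = "target"
TERMINAL_BLOCKED = "permanently_blocked"
TERMINAL_CAP = "cap_reached"


@dataclass
class Trajectory:
    """One sampled history: ordered rule applications with waiting times."""

    program: Program
    moves: list[int]
    waits: list[float]
    terminal: str
    final_move_counts: tuple[int, ...]

    @property
    def steps(self) -> int:
        return len(self.moves)

    @property
    def total_time(self) -> float:
        return float(sum(self.waits))

    def configurations(self) -> Iterator[Configuration]:
        """Replay the trajectory, yielding every configuration in order."""
        mc = [0] * self.program.n
        yield Configuration(self.program, mc)
        for i in self.moves:
            mc[i] += 1
            yield Configuration(self.program, mc)

    def log_records(self) -> Iterator[str]:
        """Line-per-step text log: step, monomer, waiting time, move counts."""
        mc = [0] * self.program.n
        for t, (i, w) in enumerate(zip(self.moves, self.waits)):
            mc[i] += 1
            yield f"{t}\t{i}\t{w:.9g}\t{','.join(map(str, mc))}"


@dataclass
class CompletionStats:
    samples: int
    mean_time: float
    sd_time: float
    mean_steps: float
    fraction_reaching_target: float


def sample_trajectory(
    program: Program,
    seed: int | None = None,
    step_cap: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Sample one trajectory of the race dynamics from the initial line.

    Identical seeds reproduce identical trajectories.  Terminates at the
    all-zero-state configuration, at a permanently blocked configuration,
    or when ``step_cap`` moves have been applied.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mc = np.zeros(program.n, dtype=np.int64)
    moves: list[int] = []
    waits: list[float] = []
    cap = program.total_moves if step_cap is None else min(step_cap, program.total_moves)
    terminal = TERMINAL_CAP
    while True:
        pos, dirs, states = geometry_arrays(program, mc)
        mask = applicable_mask(program, pos, dirs, states)
        choices = np.nonzero(mask)[0]
        k = len(choices)
        if k == 0:
            terminal = TERMINAL_TARGET if (states == 0).all() else TERMINAL_BLOCKED
            break
        if len(moves) >= cap:
            terminal = TERMINAL_CAP
            break
        i = int(choices[rng.integers(k)])
        waits.append(float(rng.exponential(1.0 / k)))
        moves.append(i)
        mc[i] += 1
    return Trajectory(program, moves, waits, terminal, tuple(mc.tolist()))


def completion_time_stats(
    program: Program,
    n_samples: int,
    seed: int = 0,
    step_cap: int | None = None,
) -> CompletionStats:
    """Aggregate independent trajectory samples with derived child seeds."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    master = np.random.SeedSequence(seed)
    times = np.empty(n_samples)
    steps = np.empty(n_samples)
    hits = 0
    for j, child in enumerate(master.spawn(n_samples)):
        t = sample_trajectory(program, rng=np.random.default_rng(child), step_cap=step_cap)
        times[j] = t.total_time
        steps[j] = t.steps
        hits += t.terminal == TERMINAL_TARGET
    return CompletionStats(
        samples=n_samples,
        mean_time=float(times.mean()),
        sd_time=float(times.std(ddof=1)) if n_samples > 1 else 0.0,
        mean_steps=float(steps.mean()),
        fraction_reaching_target=hits / n_samples,
    )


@dataclass
class ExpectedTimeResult:
    """Exact expected absorption time over the reachable configuration DAG."""

    expected_time: float
    reachable_count: int
    blocking_probability: float

    @property
    def all_reach_target(self) -> bool:
        return self.blocking_probability == 0.0


def exact_expected_time(program: Program, state_cap: int = 1_000_000) -> ExpectedTimeResult:
    """Expected time to absorption (target or permanent block), exactly.

    Enumerates the reachable move-count vectors, then solves
    ``E[c] = (1 + sum_{c'} E[c']) / k(c)`` by a single backward sweep in
    decreasing total-move order (the reachable space is a DAG graded by
    the total move count).  Also returns the probability of absorbing in
    a permanently blocked configuration.
    """
    start = (0,) * program.n
    succs: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    seen = {start}
    frontier = [start]
    while frontier:
        v = frontier.pop()
        mc = np.array(v, dtype=np.int64)
        pos, dirs, states = geometry_arrays(program, mc)
        mask = applicable_mask(program, pos, dirs, states)
        out = []
        for i in np.nonzero(mask)[0]:
            w = list(v)
            w[i] += 1
            w = tuple(w)
            out.append(w)
            if w not in seen:
                seen.add(w)
                frontier.append(w)
        succs[v] = out
        if len(seen) > state_cap:
            raise StateCapExceeded(
                f"more than {state_cap} reachable configurations"
            )
    order = sorted(succs, key=sum, reverse=True)
    target = tuple(program.move_caps)
    etime: dict[tuple[int, ...], float] = {}
    pblock: dict[tuple[int, ...], float] = {}
    for v in order:
        out = succs[v]
        if not out:
            etime[v] = 0.0
            pblock[v] = 0.0 if v == target else 1.0
            continue
        k = len(out)
        etime[v] = (1.0 + math.fsum(etime[w] for w in out)) / k
        pblock[v] = math.fsum(pblock[w] for w in out) / k
    return ExpectedTimeResult(
        expected_time=etime[start],
        reachable_count=len(succs),
        blocking_probability=pblock[start],
    )
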