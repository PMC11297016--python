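import itertools

import pytest

import turnfold as tf


@pytest.fixture(scope="session")
def l76():
    """The 7-monomer state-6 line machine and its exhaustive report."""
    program, _ = tf.line_rotation_program(7, 6)
    return program, tf.explore(program)


def enumerate_valid_configurations(program):
    """Every geometrically valid move-count vector of a program
    (exhaustive over the move-count box, not just the reachable set)."""
    for mc in itertools.product(*(range(c + 1) for c in program.move_caps)):
        try:
            yield tf.reconstruct_configuration(program, mc)
        except (tf.errors.SelfIntersection, tf.errors.RangeError):
            continue


def reachable_configurations(program):
    report = tf.explore(program)
    assert not report.truncated
    seen = set()
    frontier = [(0,) * program.n]
    while frontier:
        v = frontier.pop()
        if v in seen:
            continue
        seen.add(v)
        c = tf.reconstruct_configuration(program, v)
        yield c
        for i in tf.applicable_moves(c):
            w = list(v)
            w[i] += 1
            frontier.append(tuple(w))
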