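"""Exception hierarchy for the turning-machine engine and compilers."""


class TurnfoldError(Exception):
    """Base class for all package-specific errors."""


class SelfIntersection(TurnfoldError):
    """A chain of positions repeats a grid point."""


class RangeError(TurnfoldError):
    """A move count exceeds the magnitude of the initial state."""


class BlockedMove(TurnfoldError):
    """A turning rule was applied to a monomer whose rule is not applicable."""


class StateCapExceeded(TurnfoldError):
    """Reachability exploration exceeded the configured state cap."""


class DisconnectedShape(TurnfoldError):
    """A point set does not induce a connected subgraph of the triangular grid."""


class NotZigZag(TurnfoldError):
    """A path contains a step outside the allowed zig-zag direction set."""


class NotAtOrigin(TurnfoldError):
    """A path or configuration does not start at the origin."""


class NotYMonotone(TurnfoldError):
    """A shape has a row that is not a contiguous segment."""


class NotXYConnected(TurnfoldError):
    """A shape is disconnected once w-parallel edges are removed."""


class NoSeparator(TurnfoldError):
    """A y-monotone shape admits no yw-separator chain."""


class SeparatorCutError(TurnfoldError):
    """The factor-2 split of a shape did not yield yw-chain boundaries."""


class BadBaseState(TurnfoldError):
    """A spiral base turning number violates its congruence condition."""


class ScriptInapplicable(TurnfoldError):
    """A scripted move was rejected by the engine (geometry bug)."""


class ParseError(TurnfoldError):
    """A shape or program file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class BadParams(TurnfoldError):
    """Invalid parameters passed to a fixture generator."""
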