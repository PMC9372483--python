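"""Shared primitives: threshold-crossing detection and error types.

Kept in a leaf module so that both the engine and the system classes can
use them without circular imports.
"""

from __future__ import annotations


class ConfigurationError(ValueError):
    """A model or simulation configuration is invalid (dangling reference,
    negative rate, malformed coupling, ...)."""


class NumericalInstabilityError(RuntimeError):
    """A state variable became non-finite during integration."""

    def __init__(self, system_id: str, time: float):
        self.system_id = system_id
        self.time = time
        super().__init__(
            f"non-finite state in system {system_id!r} at t={time:.6f} s"
        )


class SelectionStateError(RuntimeError):
    """An illegal operation on a competitively selected unit, e.g.
    suppressing a unit that is not currently selected."""


def detect_crossing(x_prev: float, x_curr: float, tau: float) -> bool:
    """Return True iff a state variable crossed threshold ``tau`` on this step.

    The crossing convention is half-open: fires iff ``x_prev < tau <= x_curr``,
    so a trajectory sitting exactly on the threshold fires once and a
    trajectory that is already past it never re-fires.
    """
    return x_prev < tau <= x_curr


def crossing_time(t_prev: float, t_curr: float, x_prev: float, x_curr: float,
                  tau: float) -> float:
    """Linearly interpolated time at which ``x`` reached ``tau``.

    Exact for state variables that grow linearly between the two samples
    (autonomous clocks with constant rate, integrators with constant input).
    """
    if x_curr == x_prev:  # degenerate; crossing only if sitting on tau
        return t_curr
    frac = (tau - x_prev) / (x_curr - x_prev)
    return t_prev + (t_curr - t_prev) * frac
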