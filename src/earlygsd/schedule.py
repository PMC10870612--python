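"""Follow-up schedules and arm-allocation weights.

A two-arm trial observes each participant at a fixed, ordered set of
assessment occasions ``d_1 < d_2 < ... < d_s`` (abstract time units, e.g.
3-month blocks). Occasion ``s`` carries the primary endpoint; occasions
``1..s-1`` are early outcomes that can inform interim analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FollowUpSchedule", "AllocationSpec", "equal_spacing"]


@dataclass(frozen=True)
class FollowUpSchedule:
    """Ordered assessment times ``d_1 < ... < d_s`` with ``s >= 2``.

    Parameters
    ----------
    d : array-like of float
        Strictly increasing, strictly positive assessment times. The last
        entry is the primary-outcome time ``d_s``.
    """

    d: np.ndarray = field()

    def __init__(self, d) -> None:
        arr = np.asarray(d, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("schedule needs at least two assessment times")
        if np.any(arr <= 0):
            raise ValueError("assessment times must be positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("assessment times must be strictly increasing")
        arr.flags.writeable = False
        object.__setattr__(self, "d", arr)

    @property
    def s(self) -> int:
        """Number of assessment occasions."""
        return int(self.d.size)

    @property
    def d_s(self) -> float:
        """Primary endpoint time."""
        return float(self.d[-1])

    @property
    def d_1(self) -> float:
        return float(self.d[0])

    def rescaled(self) -> "FollowUpSchedule":
        """Return a copy rescaled so that ``d_1 = 1``.

        Convenient for the exponential correlation model, whose parameter is
        the correlation at unit time separation: callers working in months can
        divide by the first assessment time to get abstract units.
        """
        return FollowUpSchedule(self.d / self.d[0])

    def __eq__(self, other) -> bool:  # frozen dataclass with ndarray field
        if not isinstance(other, FollowUpSchedule):
            return NotImplemented
        return self.d.shape == other.d.shape and bool(np.all(self.d == other.d))

    def __hash__(self) -> int:
        return hash(self.d.tobytes())


def equal_spacing(s: int, d_1: float = 1.0, d_s: float = 2.0) -> FollowUpSchedule:
    """Equally spaced schedule ``d_r = d_1 + (r-1) (d_s - d_1)/(s-1)``.

    With the defaults this is the ``d_r = 1 + (r-1)/(s-1)`` convention used
    for the planning-table grids.
    """
    if s < 2:
        raise ValueError("s must be at least 2")
    return FollowUpSchedule(np.linspace(d_1, d_s, s))


@dataclass(frozen=True)
class AllocationSpec:
    """Control-arm allocation weight ``phi`` in (0, 1).

    Of ``N_r`` participants with data at occasion ``r``, ``phi * N_r`` are in
    the control arm and ``(1 - phi) * N_r`` in the treatment arm.
    """

    phi: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie strictly between 0 and 1")

    def split(self, n):
        """Split a (possibly fractional) count into (control, treatment)."""
        n = np.asarray(n, dtype=float)
        return self.phi * n, (1.0 - self.phi) * n
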