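"""Uniform orientation grid used for all quadrature.

Orientations are expressed in degrees relative to the reference orientation,
clockwise positive.  All integrals over the stimulus orientation theta and
over internal measurements m share one uniform grid; quadrature is
trapezoidal.  Orientation is treated as a linear variable (all prior support
lies well within +/-60 deg of the reference, so circularity is irrelevant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OrientationGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class OrientationGrid:
    """Uniform grid over orientation (deg) with trapezoidal quadrature weights.

    Parameters
    ----------
    lo, hi : float
        Inclusive bounds in degrees.  Must straddle zero.
    step : float
        Grid spacing in degrees.
    """

    lo: float = -90.0
    hi: float = 90.0
    step: float = 0.2

    theta: np.ndarray = field(init=False, repr=False, compare=False)
    weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if not (self.lo < 0.0 < self.hi):
            raise ValueError("grid must contain 0")
        n = int(round((self.hi - self.lo) / self.step)) + 1
        theta = self.lo + self.step * np.arange(n)
        w = np.full(n, self.step)
        w[0] *= 0.5
        w[-1] *= 0.5
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.theta.size

    def integrate(self, values: np.ndarray) -> float:
        """Trapezoidal integral of ``values`` sampled on the grid."""
        return float(np.dot(self.weights, values))

    def covers(self, lo: float, hi: float) -> bool:
        return self.lo <= lo and hi <= self.hi

    def index_of(self, value: float) -> int:
        """Nearest grid index of ``value``."""
        return int(round((value - self.lo) / self.step))

    def halved(self) -> "OrientationGrid":
        """Same bounds with half the step (convergence checks)."""
        return OrientationGrid(self.lo, self.hi, self.step / 2.0)


DEFAULT_GRID = OrientationGrid()
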