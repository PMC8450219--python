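"""Periodic simulation box: wrapping, minimum image, and box stretch.

The representative volume element (RVE) is a 3D box that is periodic in
all directions.  A point leaving the box through face ``i`` re-enters
through the opposite face; the integer number of box lengths by which a
coordinate was folded back is its *shift*.  Fiber segments that cross a
boundary store the shift triple of their second endpoint relative to the
first, so that the segment vector is always

    d = x_b + shift * (lambda * L) - x_a

where ``lambda`` is the current per-axis box stretch.  Stretching the box
therefore loads every boundary-crossing segment without any explicit
surface degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PeriodicBox:
    """Axis-aligned periodic box with reference lengths and a current stretch.

    Parameters
    ----------
    lengths : (3,) array-like of float
        Reference edge lengths ``L_i`` in μm.
    stretch : (3,) array-like of float, optional
        Current stretch factors ``lambda_i`` per axis (default 1).
    """

    lengths: np.ndarray
    stretch: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if np.any(self.lengths <= 0):
            raise ValueError("box lengths must be positive")
        if self.stretch is None:
            self.stretch = np.ones(3)
        self.stretch = np.asarray(self.stretch, dtype=float).reshape(3)
        if np.any(self.stretch <= 0):
            raise ValueError("box stretch factors must be positive")

    @property
    def current_lengths(self) -> np.ndarray:
        """Deformed edge lengths ``lambda_i * L_i`` (μm)."""
        return self.lengths * self.stretch

    @property
    def volume(self) -> float:
        """Reference volume (μm³)."""
        return float(np.prod(self.lengths))

    def shift_translation(self, shifts: np.ndarray) -> np.ndarray:
        """Translation (μm) carried by integer shift triples in the current box."""
        return np.asarray(shifts, dtype=float) * self.current_lengths

    def wrap(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fold position(s) into ``[0, lambda_i L_i)`` per axis.

        Returns ``(x_in_box, shift)`` with ``x = x_in_box + shift * lambda * L``.
        Idempotent: wrapping a wrapped point returns shift 0.
        """
        x = np.asarray(x, dtype=float)
        L = self.current_lengths
        shift = np.floor(x / L).astype(int)
        x_in = x - shift * L
        # guard against x_in == L from floating-point roundoff
        on_edge = x_in >= L
        x_in = np.where(on_edge, x_in - L, x_in)
        shift = shift + on_edge.astype(int)
        return x_in, shift

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied to difference vector(s)."""
        L = self.current_lengths
        return d - np.round(d / L) * L

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Periodic (minimum-image) distance between points ``a`` and ``b``."""
        d = self.minimum_image(np.asarray(b, float) - np.asarray(a, float))
        return np.linalg.norm(d, axis=-1)


def wrap_position(x: np.ndarray, box: PeriodicBox) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`PeriodicBox.wrap`."""
    return box.wrap(x)
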