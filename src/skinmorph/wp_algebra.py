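"""Weighted-point (ball) algebra.

A weighted point ``b = (z, w)`` is a ball with centre ``z`` in 3-space and
weight ``w`` playing the role of radius squared; ``w`` may be negative
(imaginary ball).  The power distance of a space point ``x`` from ``b`` is
``pi_b(x) = ||x - z||^2 - w``.

Three algebraic operations close the set of balls under affine
combination:

* addition        ``b_i + b_j = (z_i + z_j,  w_i + w_j + 2<z_i, z_j>)``
* scaling         ``g b_i     = (g z_i,      g w_i + (g^2 - g)||z_i||^2)``
* square root     ``sqrt(b)   = (z, w/2)``   (radius divided by sqrt(2))

These are exactly the operations under which the power distance behaves
like a quadratic form: the affine combination ``(1-t) b_i + t b_j`` is
again a ball, with centre interpolated linearly and weight picking up a
``-t(1-t)||z_i - z_j||^2`` deficit relative to the linear weight blend.
The skin surface of a ball set is the boundary of the union of the
square-root-shrunken balls of all its convex combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WeightedPoint",
    "BallSet",
    "wp_add",
    "wp_scale",
    "wp_shrink",
    "wp_interpolate",
    "power_distance",
]


@dataclass(frozen=True)
class WeightedPoint:
    """A ball / weighted point: centre in Angstrom, weight in Angstrom^2."""

    center: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,):
            raise ValueError(f"center must be a 3-vector, got shape {c.shape}")
        if not np.all(np.isfinite(c)) or not np.isfinite(self.weight):
            raise ValueError("center and weight must be finite")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "weight", float(self.weight))

    @property
    def radius(self) -> float:
        """Real radius sqrt(w); raises for negative weight."""
        if self.weight < 0:
            raise ValueError("negative-weight ball has no real radius")
        return float(np.sqrt(self.weight))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedPoint):
            return NotImplemented
        return bool(np.array_equal(self.center, other.center) and self.weight == other.weight)

    def isclose(self, other: "WeightedPoint", tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.center, other.center, atol=tol)
            and abs(self.weight - other.weight) <= tol
        )


def wp_add(a: WeightedPoint, b: WeightedPoint) -> WeightedPoint:
    """Ball addition: (z_i+z_j, w_i+w_j+2<z_i,z_j>)."""
    return WeightedPoint(
        a.center + b.center,
        a.weight + b.weight + 2.0 * float(np.dot(a.center, b.center)),
    )


def wp_scale(g: float, a: WeightedPoint) -> WeightedPoint:
    """Ball scaling: (g z, g w + (g^2 - g) ||z||^2)."""
    g = float(g)
    return WeightedPoint(
        g * a.center,
        g * a.weight + (g * g - g) * float(np.dot(a.center, a.center)),
    )


def wp_shrink(a: WeightedPoint) -> WeightedPoint:
    """Square-root shrink: weight halved, centre unchanged.

    A positive-weight ball keeps its centre and shrinks its radius by
    1/sqrt(2); this is the contraction that defines the skin surface.
    """
    return WeightedPoint(a.center, a.weight / 2.0)


def power_distance(x: np.ndarray, a: WeightedPoint) -> float:
    """Power (weighted) distance ||x - z||^2 - w."""
    d = np.asarray(x, dtype=float) - a.center
    return float(np.dot(d, d)) - a.weight


def wp_interpolate(a: WeightedPoint, b: WeightedPoint, t: float) -> WeightedPoint:
    """Affine ball combination (1-t) a + t b for t in [0, 1].

    Closed form: centre = (1-t) z_a + t z_b, weight = (1-t) w_a + t w_b
    - t(1-t) ||z_a - z_b||^2.  Equals wp_add(wp_scale(1-t, a), wp_scale(t, b)).
    """
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"interpolation parameter t={t} outside [0, 1]")
    dz = a.center - b.center
    return WeightedPoint(
        (1.0 - t) * a.center + t * b.center,
        (1.0 - t) * a.weight + t * b.weight - t * (1.0 - t) * float(np.dot(dz, dz)),
    )


@dataclass
class BallSet:
    """An ordered set of balls; index i is the ball's identity.

    Stored as flat arrays (``centers`` of shape (n, 3), ``weights`` of
    shape (n,)) so geometric kernels can vectorise over the set.
    """

    centers: np.ndarray
    weights: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.centers.shape != (len(self.weights), 3):
            raise ValueError("centers must be (n, 3) matching n weights")
        if len(self.weights) == 0:
            raise ValueError("a ball set must contain at least one ball")
        if not (np.all(np.isfinite(self.centers)) and np.all(np.isfinite(self.weights))):
            raise ValueError("ball coordinates and weights must be finite")
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.weights))]

    @classmethod
    def from_points(cls, points: Iterable[WeightedPoint], labels: Sequence | None = None) -> "BallSet":
        pts = list(points)
        return cls(
            np.array([p.center for p in pts]),
            np.array([p.weight for p in pts]),
            list(labels) if labels is not None else [],
        )

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, i: int) -> WeightedPoint:
        return WeightedPoint(self.centers[i], self.weights[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def power_distances(self, x: np.ndarray) -> np.ndarray:
        """Vector of power distances from x (or (m,3) points) to every ball."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            d = self.centers - x
            return np.einsum("ij,ij->i", d, d) - self.weights
        d = x[:, None, :] - self.centers[None, :, :]
        return np.einsum("mij,mij->mi", d, d) - self.weights[None, :]

    @property
    def max_radius(self) -> float:
        w = self.weights[self.weights > 0]
        return float(np.sqrt(w.max())) if len(w) else 0.0

    def bounding_box(self, inflate: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        lo = self.centers.min(axis=0) - inflate
        hi = self.centers.max(axis=0) + inflate
        return lo, hi
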