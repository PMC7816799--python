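"""Acoustic spreading and planar exposure geometry.

A fixed noise source sits inside a square study region. A whale's daily
ranging area (the convex-hull area of its hourly positions) is idealized as a
circle of equal area placed in the region. Sound level decays from the source
by spherical spreading, so surfaces of equal received level (RL) are circles
around the source; the fraction of the whale's daily circle falling between
two such iso-level circles is the fraction of its day spent in that RL band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "received_level",
    "range_for_level",
    "Circle",
    "circle_overlap",
    "DailyArea",
    "ExposureBins",
    "bin_occupancy",
    "place_daily_area",
]


def received_level(sl_db: float, r_m: float) -> float:
    """Received level (dB re 1 uPa) at range ``r_m`` under spherical spreading.

    RL = SL - 20*log10(r).  The source level is defined at 1 m, so ranges
    below 1 m are clamped to 1 m.
    """
    r = max(float(r_m), 1.0)
    return float(sl_db) - 20.0 * math.log10(r)


def range_for_level(sl_db: float, rl_db: float) -> float:
    """Range in meters at which ``rl_db`` is reached; inverse of received_level.

    Clamped below at 1 m (RL above SL cannot occur under the model).
    """
    return max(10.0 ** ((float(sl_db) - float(rl_db)) / 20.0), 1.0)


@dataclass(frozen=True)
class Circle:
    """A circle in planar km coordinates."""

    x: float
    y: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")

    @property
    def area(self) -> float:
        return math.pi * self.r**2


def circle_overlap(c1: Circle, c2: Circle) -> float:
    """Exact lens area (km^2) of the intersection of two circles.

    Returns 0 when disjoint and the smaller circle's area when nested.
    An infinite radius is treated as covering the whole plane.
    """
    if math.isinf(c1.r):
        return c2.area
    if math.isinf(c2.r):
        return c1.area
    d = math.hypot(c1.x - c2.x, c1.y - c2.y)
    r1, r2 = c1.r, c2.r
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    # standard two-circle lens formula
    a1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    k = 0.5 * math.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - k


@dataclass(frozen=True)
class DailyArea:
    """The area covered by a whale in one day, idealized as a circle."""

    x: float
    y: float
    radius: float

    @classmethod
    def from_area(cls, x: float, y: float, area_km2: float) -> "DailyArea":
        if not area_km2 > 0:
            raise ValueError("daily area must be positive")
        return cls(x=x, y=y, radius=math.sqrt(area_km2 / math.pi))

    @property
    def circle(self) -> Circle:
        return Circle(self.x, self.y, self.radius)

    @property
    def area_km2(self) -> float:
        return math.pi * self.radius**2


@dataclass
class ExposureBins:
    """Partition of a daily circle into distance bands around the source.

    ``edges`` are strictly increasing outer distances in km; bin i covers
    distances [edges[i-1], edges[i]) from the source (with an implicit inner
    edge at 0).  ``proportions[i]`` is the fraction of the daily circle in bin
    i; ``remainder`` is the fraction beyond the outermost edge.
    """

    edges: np.ndarray
    proportions: np.ndarray
    remainder: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.proportions < -1e-12):
            raise ValueError("bin proportions must be non-negative")
        total = float(self.proportions.sum()) + self.remainder
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions + remainder must sum to 1, got {total}")


def bin_occupancy(
    day: DailyArea, source_xy: tuple[float, float], edges_km
) -> ExposureBins:
    """Fractions of the daily circle falling in each distance band.

    Each band is the annulus between consecutive ``edges_km`` around the
    source (innermost band runs from 0 to the first edge).  The fraction for
    a band is the lens-overlap of the daily circle with the outer disc minus
    the overlap with the inner disc, divided by the daily-circle area.
    """
    edges = np.asarray(edges_km, dtype=float)
    if edges.ndim != 1 or edges.size == 0:
        raise ValueError("need at least one distance edge")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    sx, sy = source_xy
    day_circle = day.circle
    cum = np.empty(edges.size)
    for i, e in enumerate(edges):
        cum[i] = circle_overlap(day_circle, Circle(sx, sy, float(e)))
    props = np.diff(np.concatenate(([0.0], cum))) / day_circle.area
    props = np.clip(props, 0.0, None)
    remainder = max(1.0 - float(props.sum()), 0.0)
    return ExposureBins(edges=edges, proportions=props, remainder=remainder)


def place_daily_area(
    area_km2: float, square_km: float, rng: np.random.Generator
) -> DailyArea:
    """Place a circle of the given area with center uniform over the square.

    The circle may extend beyond the square edge; overlap is computed in the
    unbounded plane (the square is a modeling unit, not a barrier).
    """
    x = rng.uniform(0.0, square_km)
    y = rng.uniform(0.0, square_km)
    return DailyArea.from_area(x, y, area_km2)
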