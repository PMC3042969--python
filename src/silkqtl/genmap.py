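"""Genetic maps and map functions.

Positions are centimorgans (cM), 0-based at the first marker of each
chromosome.  The only supported map function is Haldane's (no crossover
interference), under which recombination fractions across adjacent
intervals compose as ``r = r1(1-r2) + r2(1-r1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "haldane_to_recomb",
    "haldane_to_cm",
    "map_to_recomb",
    "Chromosome",
    "GeneticMap",
    "MapError",
]


class MapError(ValueError):
    """Invalid genetic-map structure (ordering, duplicates, bad positions)."""


def haldane_to_recomb(distance_cM):
    """Convert a Haldane map distance in cM to a recombination fraction.

    r = 0.5 * (1 - exp(-2d)) with d in Morgans, i.e. -0.02 * cM in the
    exponent.  Monotone increasing with asymptote 0.5.

    Raises
    ------
    ValueError
        If any distance is negative.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return float(r) if np.isscalar(distance_cM) else r


# canonical name used throughout the package
map_to_recomb = haldane_to_recomb


def haldane_to_cm(r):
    """Inverse Haldane map function: recombination fraction -> cM."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class Chromosome:
    """Ordered markers on one chromosome."""

    name: str
    markers: tuple
    positions: np.ndarray  # cM, strictly increasing, >= 0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(self.markers) != len(pos):
            raise MapError(f"chromosome {self.name}: marker/position length mismatch")
        if np.any(pos < 0):
            raise MapError(f"chromosome {self.name}: negative position")
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise MapError(f"chromosome {self.name}: positions not strictly increasing")

    @property
    def n_markers(self):
        return len(self.markers)

    @property
    def span(self):
        return float(self.positions[0]), float(self.positions[-1])

    def interval_of(self, pos_cM):
        """Index t of the marker interval [pos_t, pos_{t+1}] containing pos_cM."""
        pos = float(pos_cM)
        lo, hi = self.span
        if not (lo <= pos <= hi):
            raise MapError(
                f"position {pos} cM outside chromosome {self.name} span [{lo}, {hi}]"
            )
        t = int(np.searchsorted(self.positions, pos, side="right")) - 1
        return min(max(t, 0), self.n_markers - 2)


@dataclass(frozen=True)
class GeneticMap:
    """A set of chromosomes with ordered marker positions (cM).

    ``map_function`` is a tag; only "haldane" is supported.
    Marker identifiers must be unique genome-wide.
    """

    chromosomes: tuple
    map_function: str = "haldane"
    _marker_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if self.map_function != "haldane":
            raise MapError(f"unsupported map function: {self.map_function!r}")
        index = {}
        for c, chrom in enumerate(self.chromosomes):
            for j, m in enumerate(chrom.markers):
                if m in index:
                    raise MapError(f"duplicate marker id {m!r}")
                index[m] = (c, j)
        object.__setattr__(self, "_marker_index", index)

    @property
    def n_markers(self):
        return sum(c.n_markers for c in self.chromosomes)

    @property
    def marker_ids(self):
        return [m for c in self.chromosomes for m in c.markers]

    def locate(self, marker_id):
        """Return (chromosome index, marker index within chromosome)."""
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise MapError(f"unknown marker id {marker_id!r}") from None

    def chrom(self, name_or_index):
        if isinstance(name_or_index, (int, np.integer)):
            return self.chromosomes[int(name_or_index)]
        for c in self.chromosomes:
            if c.name == name_or_index:
                return c
        raise MapError(f"unknown chromosome {name_or_index!r}")

    def chrom_index(self, name):
        for i, c in enumerate(self.chromosomes):
            if c.name == name:
                return i
        raise MapError(f"unknown chromosome {name!r}")

    def marker_offsets(self):
        """Start column of each chromosome in a genome-wide marker matrix."""
        sizes = [c.n_markers for c in self.chromosomes]
        return np.concatenate([[0], np.cumsum(sizes)])


def uniform_map(n_chrom=5, n_markers=11, spacing_cM=10.0, prefix="M"):
    """Evenly spaced map: ``n_chrom`` chromosomes of ``n_markers`` markers."""
    chroms = []
    for c in range(n_chrom):
        markers = tuple(f"{prefix}{c + 1}_{j + 1}" for j in range(n_markers))
        positions = np.arange(n_markers, dtype=float) * spacing_cM
        chroms.append(Chromosome(name=str(c + 1), markers=markers, positions=positions))
    return GeneticMap(chromosomes=tuple(chroms))
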