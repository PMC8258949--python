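"""Point estimate with confidence bounds, propagated componentwise.

Every quantity in the burden model — allele frequency q, genotype
prevalence q², carrier frequency 2pq, annual incidence, patient counts —
is carried as a ``Triplet`` (point, lo, hi).  Because every transform in
the model chain is monotone in its argument (squaring on [0,1], 2pq on
[0, 0.5], multiplication by positive constants, summation), applying the
transform to each component separately yields valid propagated bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable


@dataclass(frozen=True)
class Triplet:
    """A point estimate bracketed by lower/upper confidence bounds."""

    point: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.point <= self.hi):
            raise ValueError(
                f"invalid triplet ordering: lo={self.lo} point={self.point} hi={self.hi}"
            )

    @classmethod
    def exact(cls, value: float) -> "Triplet":
        """A degenerate triplet with zero-width bounds."""
        return cls(value, value, value)

    def map_monotone(self, f: Callable[[float], float]) -> "Triplet":
        """Apply a monotone non-decreasing transform componentwise."""
        lo, point, hi = f(self.lo), f(self.point), f(self.hi)
        if not (lo <= point <= hi):
            raise ValueError("transform is not monotone non-decreasing on this triplet")
        return Triplet(point, lo, hi)

    def scale(self, c: float) -> "Triplet":
        if c < 0:
            raise ValueError("scale factor must be non-negative")
        return Triplet(self.point * c, self.lo * c, self.hi * c)

    def __add__(self, other: "Triplet") -> "Triplet":
        return Triplet(self.point + other.point, self.lo + other.lo, self.hi + other.hi)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.point, self.lo, self.hi)


def sum_triplets(triplets: Iterable[Triplet]) -> Triplet:
    """Componentwise sum; the sum of an empty iterable is the zero triplet."""
    total = Triplet.exact(0.0)
    for t in triplets:
        total = total + t
    return total
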