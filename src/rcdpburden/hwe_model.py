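"""Hardy–Weinberg conversion of allele frequency into genotype burden.

Under random mating, an aggregate pathogenic allele frequency q in one
gene yields a disease-genotype prevalence of q² (covering homozygotes
and all within-gene compound heterozygotes, since (Σqᵢ)² = Σqᵢ² +
Σ_{i≠j} qᵢqⱼ) and a carrier frequency of 2pq with p = 1 − q.
Cross-gene compound genotypes are treated as negligible.

Confidence bounds propagate componentwise through each transform: both
x ↦ x² on [0, 1] and x ↦ 2x(1−x) on [0, ½] are monotone increasing, so
applying them to (lo, point, hi) yields a valid interval.
"""

from __future__ import annotations

from dataclasses import dataclass

from .allele_stats import GeneAlleleAggregate
from .triplet import Triplet


def genotype_prevalence(q: Triplet) -> Triplet:
    """q² componentwise: probability a conceptus carries a disease genotype."""
    if not (0.0 <= q.lo and q.hi <= 1.0):
        raise ValueError(f"allele frequency triplet outside [0, 1]: {q}")
    return q.map_monotone(lambda v: v * v)


def carrier_frequency(q: Triplet) -> Triplet:
    """2·(1−q)·q componentwise; requires q.hi ≤ 0.5 where 2pq is monotone."""
    if not (0.0 <= q.lo):
        raise ValueError(f"allele frequency triplet below 0: {q}")
    if q.hi > 0.5:
        raise ValueError(
            f"carrier-frequency bounds undefined for q.hi={q.hi} > 0.5: "
            "2pq is non-monotone beyond 0.5"
        )
    return q.map_monotone(lambda v: 2.0 * (1.0 - v) * v)


def carriers_in_population(carrier_freq: Triplet, population_size: float) -> Triplet:
    """Expected carrier count: carrier frequency × population size."""
    if population_size <= 0:
        raise ValueError(f"population_size must be positive, got {population_size}")
    return carrier_freq.scale(population_size)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Genotype and carrier prevalence for one gene in one dataset."""

    gene: str
    dataset: str
    q: Triplet
    genotype_prevalence: Triplet
    carrier_frequency: Triplet

    @classmethod
    def from_aggregate(cls, agg: GeneAlleleAggregate) -> "PrevalenceEstimate":
        q = agg.q
        return cls(
            gene=agg.gene,
            dataset=agg.dataset,
            q=q,
            genotype_prevalence=genotype_prevalence(q),
            carrier_frequency=carrier_frequency(q),
        )
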