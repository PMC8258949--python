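"""Birth incidence: genotype prevalence applied to annual live births.

The expected number of affected births in year y is I_y = q²·B_y, where
B_y is the live-birth count for the region.  The genotype prevalence is
held constant across historic years (allele frequencies are measured
once, in the present-day cohorts) while the birth series varies.

Birth series are read from TSV (columns ``region, year, births``).
Missing historic years are gap-filled from the nearest available year
(ties resolved toward the earlier year); every filled year is flagged so
reports can disclose it.  Old cohorts contribute almost nothing to
prevalence under the mortality model, so the fill rule is low-stakes,
but it is explicit and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .hwe_model import PrevalenceEstimate
from .triplet import Triplet


@dataclass
class BirthSeries:
    """Annual live births for one region."""

    region: str
    births: dict[int, int]
    filled_years: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.births:
            raise ValueError(f"{self.region}: empty birth series")
        for year, b in self.births.items():
            if b < 0:
                raise ValueError(f"{self.region}: negative births in {year}")

    def gap_filled(self, years: Iterable[int]) -> "BirthSeries":
        """Return a series covering ``years``, filling gaps from the nearest year."""
        years = list(years)
        available = sorted(self.births)
        out: dict[int, int] = {}
        filled = set(self.filled_years)
        for y in years:
            if y in self.births:
                out[y] = self.births[y]
            else:
                nearest = min(available, key=lambda a: (abs(a - y), a))
                out[y] = self.births[nearest]
                filled.add(y)
        return BirthSeries(self.region, out, filled)

    def __getitem__(self, year: int) -> int:
        return self.births[year]


def read_birth_series(path: str | Path) -> dict[str, BirthSeries]:
    """Parse a birth-series TSV into one BirthSeries per region."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"region", "year", "births"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    if df.duplicated(["region", "year"]).any():
        dup = df[df.duplicated(["region", "year"])].iloc[0]
        raise ValueError(f"{path}: duplicate year {dup['year']} for region {dup['region']}")
    series = {}
    for region, grp in df.groupby("region"):
        series[str(region)] = BirthSeries(
            str(region), {int(r.year): int(r.births) for r in grp.itertuples()}
        )
    return series


@dataclass
class IncidenceSeries:
    """Expected affected births per year for one gene in one region."""

    gene: str
    region: str
    rows: dict[int, Triplet]

    def years(self) -> list[int]:
        return sorted(self.rows)

    def __getitem__(self, year: int) -> Triplet:
        return self.rows[year]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"year": y, "point": t.point, "lo": t.lo, "hi": t.hi}
                for y, t in sorted(self.rows.items())
            ]
        )


def annual_birth_incidence(
    prev: PrevalenceEstimate,
    births: BirthSeries,
    years: Iterable[int],
    region: str | None = None,
) -> IncidenceSeries:
    """I_y = q² · B_y componentwise over the requested year range."""
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    filled = births.gap_filled(years)
    rows = {y: prev.genotype_prevalence.scale(filled[y]) for y in years}
    return IncidenceSeries(gene=prev.gene, region=region or births.region, rows=rows)


def birth_prevalence_per_100k(incidence: float, births_that_year: float) -> float:
    """Affected births expressed as cases per 100,000 live births."""
    if births_that_year <= 0:
        raise ValueError(f"births_that_year must be positive, got {births_that_year}")
    return 100_000.0 * incidence / births_that_year
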