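"""End-to-end orchestration: variants → q → q² → incidence → prevalence.

For every (gene, region) pair the pipeline pools pathogenic allele
counts into q with its confidence interval, converts to genotype
prevalence q² and carrier frequency 2pq under Hardy–Weinberg, applies
q² to the historic birth series to obtain an incidence series, and ages
each birth cohort through the life table to the reference year:

    patients alive at age a  =  I_{ref_year − a} · S(a),   a = 0..max_age

Confidence bounds travel componentwise through every stage (all
transforms are monotone), so the lower patient bound is the fully
propagated lower allele-frequency bound, and likewise for the upper.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .allele_stats import aggregate_gene_frequency
from .config import RunConfig
from .hwe_model import PrevalenceEstimate, carriers_in_population
from .incidence_model import (
    BirthSeries,
    IncidenceSeries,
    annual_birth_incidence,
    birth_prevalence_per_100k,
    read_birth_series,
)
from .mortality_model import (
    MortalityTable,
    build_default_table,
    read_mortality_csv,
    validate_table,
)
from .triplet import Triplet, sum_triplets
from .variant_catalog import classify_all, read_variant_table

AGE_BINS: tuple[tuple[int, int], ...] = ((0, 4), (5, 9), (10, 14), (15, 19), (20, 24), (25, 29), (30, 34))


def age_structured_prevalence(
    incidence: IncidenceSeries,
    table: MortalityTable,
    reference_year: int,
) -> tuple[Triplet, pd.DataFrame]:
    """Age every birth cohort to the reference year through the life table.

    Returns the total current prevalence (point, lo, hi) and a per-age
    frame with one row per completed year of age 0..max_age.
    """
    s = table.survival_curve()
    rows = []
    for a in range(table.max_age + 1):
        birth_year = reference_year - a
        if birth_year not in incidence.rows:
            raise ValueError(
                f"incidence series for {incidence.gene}/{incidence.region} "
                f"is missing birth year {birth_year}"
            )
        n_a = incidence[birth_year].scale(float(s[a]))
        rows.append({"age": a, "point": n_a.point, "lo": n_a.lo, "hi": n_a.hi})
    per_age = pd.DataFrame(rows)
    total = Triplet(
        float(per_age["point"].sum()), float(per_age["lo"].sum()), float(per_age["hi"].sum())
    )
    return total, per_age


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rounded_total(values: Iterable[float], mode: str = "sum_then_round") -> int:
    """Collapse per-gene values into a printed total.

    ``sum_then_round`` rounds the exact sum to the nearest integer —
    the convention that reproduces published summary rows from their
    per-gene entries.  ``round_then_sum`` rounds each entry first.
    """
    values = list(values)
    if mode == "sum_then_round":
        return round_half_up(sum(values))
    if mode == "round_then_sum":
        return sum(round_half_up(v) for v in values)
    raise ValueError(f"unknown rounding mode: {mode!r}")


def bin_age_distribution(per_age: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-year-of-age counts into 5-year bins."""
    rows = []
    for lo_a, hi_a in AGE_BINS:
        sel = per_age[(per_age["age"] >= lo_a) & (per_age["age"] <= hi_a)]
        rows.append(
            {
                "age_bin": f"{lo_a}-{hi_a}",
                "point": float(sel["point"].sum()),
                "lo": float(sel["lo"].sum()),
                "hi": float(sel["hi"].sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BurdenReport:
    """Machine-readable per-gene, per-region burden summary.

    ``gene_rows`` holds unrounded values; rounding happens only at
    serialisation time so totals can be checked against exact sums.
    Carrier counts are stored in thousands of persons.
    """

    gene_rows: pd.DataFrame
    totals: dict[str, dict[str, Triplet]]        # region -> quantity -> triplet
    age_distribution: pd.DataFrame               # region, age_bin, point, lo, hi
    metadata: dict[str, Any]
    provenance: list[str] = field(default_factory=list)

    QUANTITIES = ("births_per_year", "carriers_thousands", "current_patients")

    def rounded_gene_table(self) -> pd.DataFrame:
        """Display-rounded table: births to 1 decimal, carriers to the
        nearest thousand, patients to the nearest integer."""
        df = self.gene_rows.copy()
        for comp in ("point", "lo", "hi"):
            df[f"births_per_year_{comp}"] = df[f"births_per_year_{comp}"].round(1)
            df[f"carriers_thousands_{comp}"] = [
                round_half_up(v) for v in df[f"carriers_thousands_{comp}"]
            ]
            df[f"current_patients_{comp}"] = [
                round_half_up(v) for v in df[f"current_patients_{comp}"]
            ]
        return df

    def totals_table(self, mode: str | None = None) -> pd.DataFrame:
        mode = mode or self.metadata.get("totals_rounding", "sum_then_round")
        rows = []
        for region in self.totals:
            row: dict[str, Any] = {"region": region}
            sel = self.gene_rows[self.gene_rows["region"] == region]
            for qty in self.QUANTITIES:
                for comp in ("point", "lo", "hi"):
                    row[f"{qty}_{comp}"] = rounded_total(sel[f"{qty}_{comp}"], mode)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        table = self.rounded_gene_table()
        table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metadata": self.metadata,
            "provenance": self.provenance,
            "genes": self.gene_rows.to_dict("records"),
            "totals": {
                region: {qty: list(t.as_tuple()) for qty, t in qtys.items()}
                for region, qtys in self.totals.items()
            },
            "totals_rounded": self.totals_table().to_dict("records"),
            "age_distribution": self.age_distribution.to_dict("records"),
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    def age_distribution_tsv(self, path: str | Path) -> None:
        self.age_distribution.to_csv(path, sep="\t", index=False)


def _resolve_mortality(source: Any, config: RunConfig) -> MortalityTable:
    if isinstance(source, MortalityTable):
        return source
    if source in (None, "default"):
        return build_default_table(max_age=config.max_lifespan)
    if isinstance(source, dict):
        return build_default_table(max_age=config.max_lifespan, **source)
    return read_mortality_csv(source)


def run_full_model(
    variant_path: str | Path,
    births_path: str | Path,
    mortality_source: Any = "default",
    config: RunConfig | None = None,
) -> BurdenReport:
    """Execute the full chain for every (gene, region) in the config."""
    if config is None:
        raise ValueError("a RunConfig is required")

    provenance: list[str] = []
    variants = read_variant_table(
        variant_path,
        dialect="vcf" if str(variant_path).endswith((".vcf", ".vcf.gz")) else "tsv",
        possibly_damaging_is_damaging=config.possibly_damaging_is_damaging,
    )
    unmapped = {v.dataset for v in variants} - set(config.dataset_region)
    if unmapped:
        raise ValueError(
            f"dataset label(s) with no region mapping: {', '.join(sorted(unmapped))}"
        )
    calls = classify_all(variants, config.region_restrictions)
    for v, c in zip(variants, calls):
        if not c.included:
            provenance.append(f"excluded {v.variant_id} ({v.gene}/{v.dataset}): {c.rule_fired.value}")

    table = _resolve_mortality(mortality_source, config)
    problems = validate_table(table)
    if problems:
        raise ValueError("invalid mortality table: " + "; ".join(problems))

    all_series = read_birth_series(births_path)
    years = range(config.reference_year - table.max_age, config.reference_year + 1)

    # fallback AN per dataset: typical allele number when a gene has no
    # included variants at all (its zero-count CI still needs a sample size)
    fallback_an: dict[str, float] = {}
    for ds in config.dataset_region:
        ans = [v.allele_number for v in variants if v.dataset == ds]
        if ans:
            fallback_an[ds] = float(np.mean(ans))

    gene_rows = []
    age_frames: dict[str, list[pd.DataFrame]] = {}
    for dataset, region in config.dataset_region.items():
        if region not in all_series:
            raise ValueError(f"no birth series for region {region!r}")
        births = all_series[region].gap_filled(years)
        for y in sorted(births.filled_years):
            provenance.append(f"birth series {region}: year {y} gap-filled")
        anchor_births = births.gap_filled([config.anchor_year])[config.anchor_year]
        population = config.populations.get(region)
        for gene in config.genes:
            agg = aggregate_gene_frequency(
                variants, calls, gene, dataset,
                conf_level=config.conf_level,
                pooling=config.pooling,
                simplified_z=config.simplified_z,
                fallback_an=fallback_an.get(dataset),
            )
            prev = PrevalenceEstimate.from_aggregate(agg)
            incidence = annual_birth_incidence(prev, births, years, region=region)
            patients, per_age = age_structured_prevalence(incidence, table, config.reference_year)
            births_year = prev.genotype_prevalence.scale(anchor_births)
            if population is not None:
                carriers = carriers_in_population(prev.carrier_frequency, population).scale(1e-3)
            else:
                carriers = Triplet.exact(0.0)
                provenance.append(f"region {region}: no population size; carriers reported as 0")
            row: dict[str, Any] = {
                "gene": gene, "region": region, "dataset": dataset,
                "n_variants": agg.n_variants, "q_hat": agg.q_hat,
                "q_lo": agg.q_lo, "q_hi": agg.q_hi,
            }
            for qty, trip in (
                ("births_per_year", births_year),
                ("carriers_thousands", carriers),
                ("current_patients", patients),
            ):
                row[f"{qty}_point"], row[f"{qty}_lo"], row[f"{qty}_hi"] = (
                    trip.point, trip.lo, trip.hi,
                )
            gene_rows.append(row)
            age_frames.setdefault(region, []).append(per_age)

    gene_df = pd.DataFrame(gene_rows)
    totals: dict[str, dict[str, Triplet]] = {}
    age_rows = []
    per100k: dict[str, dict[str, float]] = {}
    for dataset, region in config.dataset_region.items():
        sel = gene_df[gene_df["region"] == region]
        totals[region] = {
            qty: Triplet(
                float(sel[f"{qty}_point"].sum()),
                float(sel[f"{qty}_lo"].sum()),
                float(sel[f"{qty}_hi"].sum()),
            )
            for qty in BurdenReport.QUANTITIES
        }
        summed = None
        for frame in age_frames[region]:
            summed = frame if summed is None else _add_age_frames(summed, frame)
        binned = bin_age_distribution(summed)
        binned.insert(0, "region", region)
        age_rows.append(binned)
        births = all_series[region].gap_filled([config.anchor_year])
        anchor_births = births[config.anchor_year]
        per100k[region] = {
            comp: birth_prevalence_per_100k(
                getattr(totals[region]["births_per_year"], comp), anchor_births
            )
            for comp in ("point", "lo", "hi")
        }

    metadata = config.metadata()
    metadata["birth_prevalence_per_100k"] = per100k
    return BurdenReport(
        gene_rows=gene_df,
        totals=totals,
        age_distribution=pd.concat(age_rows, ignore_index=True),
        metadata=metadata,
        provenance=provenance,
    )


def _add_age_frames(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    out = a.copy()
    for col in ("point", "lo", "hi"):
        out[col] = a[col].to_numpy() + b[col].to_numpy()
    return out


def combine_regions(reports_or_totals: Sequence[Any]) -> dict[str, Triplet]:
    """Sum regional totals into combined multi-region totals.

    Accepts BurdenReports (whose metadata must agree on confidence level
    and reference year) or bare mappings of quantity → Triplet.  The
    combined confidence range is the componentwise sum of the regional
    bounds.
    """
    pools: dict[str, list[Triplet]] = {}
    meta_seen: set[tuple[Any, Any]] = set()
    for item in reports_or_totals:
        if isinstance(item, BurdenReport):
            meta_seen.add((item.metadata.get("conf_level"), item.metadata.get("reference_year")))
            if len(meta_seen) > 1:
                raise ValueError("reports disagree on confidence level or reference year")
            for region_totals in item.totals.values():
                for qty, trip in region_totals.items():
                    pools.setdefault(qty, []).append(trip)
        else:
            for qty, trip in item.items():
                pools.setdefault(qty, []).append(trip)
    return {qty: sum_triplets(trips) for qty, trips in pools.items()}
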