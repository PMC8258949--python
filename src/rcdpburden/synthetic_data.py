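"""Synthetic inputs with the statistical structure the model assumes.

Generates variant frequency tables (binomial AC draws at known true
allele frequencies across a sequencing cohort), historic birth series,
and natural-history survival cohorts, so every stage of the pipeline —
and the end-to-end chain — can be exercised without any external data.

Variants are simulated as independent sites with no linkage: the burden
model itself assumes independently segregating rare alleles under
Hardy–Weinberg equilibrium, so the generator matches the model's
assumptions by construction.  Each gene's true aggregate frequency
q_true is split across its variants (fixed proportions, or a Dirichlet
draw), and every emitted table also contains decoy variants engineered
to be rejected by each filter rule, to exercise the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mortality_model import MortalityTable

#: consequence classes a simulated "intended pathogenic" variant may take
_INCLUDABLE = ("stop_gained", "frameshift", "splice_donor", "splice_acceptor",
               "start_lost", "missense")

#: gene loci are laid out on a fake chromosome, one 100 kb block per gene
_GENE_BLOCK = 100_000


@dataclass
class GeneSpec:
    symbol: str
    q_true: float
    n_variants: int
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {"stop_gained": 0.5, "missense": 0.5}
    )
    proportions: Optional[Sequence[float]] = None   # fixed split of q_true; else Dirichlet
    restriction_fraction: Optional[float] = None    # if set, only this head fraction of the
                                                    # gene block is "in region"

    def __post_init__(self) -> None:
        if not (0.0 < self.q_true <= 0.01):
            raise ValueError(f"{self.symbol}: q_true must be in (0, 0.01], got {self.q_true}")
        if self.n_variants < 1:
            raise ValueError(f"{self.symbol}: need at least one variant")
        bad = set(self.consequence_mix) - set(_INCLUDABLE)
        if bad:
            raise ValueError(f"{self.symbol}: non-includable consequence(s) in mix: {bad}")
        if self.proportions is not None:
            p = np.asarray(list(self.proportions), dtype=float)
            if len(p) != self.n_variants or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{self.symbol}: proportions must have length n_variants and sum to 1")


@dataclass
class RegionSpec:
    label: str
    population: float
    annual_births: float
    births_noise_sd: float = 0.0    # relative (fraction of the level)
    births_trend: float = 0.0       # additive change in births per year


@dataclass
class SimulationSpec:
    genes: list[GeneSpec]
    regions: list[RegionSpec]
    cohort_size: int = 125_000          # sequenced individuals per dataset
    survival_cohort_size: int = 66      # patients in the simulated natural-history study
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be positive")
        if not self.genes or not self.regions:
            raise ValueError("need at least one gene and one region")


def paper_like_spec(seed: int = 0) -> SimulationSpec:
    """A five-gene preset at realistic ultra-rare-disease frequencies.

    One dominant gene (aggregate q near 1.7×10⁻³, about half of it
    truncating), one intermediate, and three near-zero genes; one gene
    carries a region restriction so the out-of-region decoy path is
    exercised.  Chosen for order-of-magnitude realism of an
    autosomal-recessive ultra-rare disorder, not to reproduce any
    specific published frequency list.
    """
    genes = [
        GeneSpec("GENE_A", 1.7e-3, 10, {"stop_gained": 0.35, "frameshift": 0.15, "missense": 0.5}),
        GeneSpec("GENE_B", 1.1e-3, 8, {"missense": 0.75, "frameshift": 0.25}),
        GeneSpec("GENE_C", 2.6e-4, 4, {"missense": 1.0}),
        GeneSpec("GENE_D", 3.7e-4, 4, {"missense": 0.5, "stop_gained": 0.5}),
        GeneSpec("GENE_E", 2.9e-4, 2, {"splice_acceptor": 1.0}, restriction_fraction=0.5),
    ]
    regions = [
        RegionSpec("US-sim", 328e6, 3.8e6, births_noise_sd=0.01),
        RegionSpec("EU5-sim", 325e6, 3.2e6, births_noise_sd=0.01),
    ]
    return SimulationSpec(genes=genes, regions=regions, seed=seed)


def gene_interval(spec: SimulationSpec, gene: GeneSpec) -> tuple[str, int, int]:
    """The (chrom, start, end) block allocated to a gene, and — when the
    gene has a restriction_fraction — the end of its in-region part."""
    idx = [g.symbol for g in spec.genes].index(gene.symbol)
    start = idx * _GENE_BLOCK + 1
    end = start + _GENE_BLOCK - 1
    return "1", start, end


def restriction_interval(spec: SimulationSpec, gene: GeneSpec) -> Optional[tuple[str, int, int]]:
    if gene.restriction_fraction is None:
        return None
    chrom, start, end = gene_interval(spec, gene)
    span = int((end - start + 1) * gene.restriction_fraction)
    return chrom, start, start + span - 1


def _split_q(gene: GeneSpec, rng: np.random.Generator) -> np.ndarray:
    if gene.proportions is not None:
        p = np.asarray(list(gene.proportions), dtype=float)
    else:
        p = rng.dirichlet(np.ones(gene.n_variants))
    return gene.q_true * p


def _assign_consequences(gene: GeneSpec) -> list[str]:
    """Deterministic largest-remainder allocation of the consequence mix."""
    classes = sorted(gene.consequence_mix)
    weights = np.array([gene.consequence_mix[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    raw = weights * gene.n_variants
    counts = np.floor(raw).astype(int)
    remainder = gene.n_variants - counts.sum()
    for i in np.argsort(-(raw - counts))[:remainder]:
        counts[i] += 1
    out: list[str] = []
    for c, k in zip(classes, counts):
        out.extend([c] * k)
    return out


def simulate_variant_table(
    spec: SimulationSpec,
    deterministic: bool = False,
    decoys: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a variant table plus a truth sidecar.

    Per region, each variant's allele count is drawn Binomial(2·N, qᵢ)
    with N the cohort size (``deterministic=True`` instead sets AC to
    the rounded expectation, for exact-recovery checks).  Annotation
    fields are set so that exactly the intended variants pass the
    pathogenicity filter; decoy variants engineered to be rejected by
    each exclusion rule are appended when ``decoys`` is True.

    Returns the table (TSV dialect columns) and a truth dict with
    q_true per gene, the seed, and the per-variant frequency splits.
    """
    rng = np.random.default_rng(spec.seed)
    an = 2 * spec.cohort_size
    rows: list[dict] = []
    truth: dict = {"seed": spec.seed, "allele_number": an, "genes": {}, "splits": {}}

    for gene in spec.genes:
        chrom, start, _ = gene_interval(spec, gene)
        restr = restriction_interval(spec, gene)
        in_region_end = restr[2] if restr else None
        q_split = _split_q(gene, rng)
        consequences = _assign_consequences(gene)
        truth["genes"][gene.symbol] = gene.q_true
        truth["splits"][gene.symbol] = [float(q) for q in q_split]
        for i, (q_i, csq) in enumerate(zip(q_split, consequences)):
            pos = start + 10 * i  # inside the restriction when one applies
            if in_region_end is not None and pos > in_region_end:
                pos = start + i
            is_missense = csq == "missense"
            for region in spec.regions:
                ac = int(round(q_i * an)) if deterministic else int(rng.binomial(an, q_i))
                rows.append({
                    "variant_id": f"{gene.symbol}_v{i}",
                    "gene": gene.symbol, "chrom": chrom, "pos": pos,
                    "ref": "A", "alt": "T", "consequence": csq,
                    "sift": "deleterious" if is_missense else "unknown",
                    "polyphen": "probably_damaging" if is_missense else "unknown",
                    "clinical": "reported_pathogenic" if i == 0 else "unreported",
                    "AC": ac, "AN": an, "dataset": region.label,
                })
        if decoys:
            rows.extend(_decoy_rows(spec, gene, rng, an))

    df = pd.DataFrame(rows)
    return df, truth


def _decoy_rows(spec: SimulationSpec, gene: GeneSpec, rng: np.random.Generator, an: int) -> list[dict]:
    """One decoy per exclusion rule, per region, at a visible frequency."""
    chrom, start, end = gene_interval(spec, gene)
    restr = restriction_interval(spec, gene)
    decoy_q = 1e-4
    base = {
        "gene": gene.symbol, "chrom": chrom, "ref": "G", "alt": "C", "AN": an,
    }
    specs = [
        # clinically benign despite concordant damaging predictions
        dict(variant_id=f"{gene.symbol}_decoy_benign", pos=start + 5_001,
             consequence="missense", sift="deleterious", polyphen="probably_damaging",
             clinical="reported_benign"),
        # discordant in-silico predictions
        dict(variant_id=f"{gene.symbol}_decoy_discordant", pos=start + 5_002,
             consequence="missense", sift="deleterious", polyphen="benign",
             clinical="unreported"),
        # non-missense, non-LoF consequence
        dict(variant_id=f"{gene.symbol}_decoy_other", pos=start + 5_003,
             consequence="splice_region", sift="unknown", polyphen="unknown",
             clinical="unreported"),
    ]
    if restr is not None:
        specs.append(
            dict(variant_id=f"{gene.symbol}_decoy_region", pos=end,  # outside the head interval
                 consequence="stop_gained", sift="unknown", polyphen="unknown",
                 clinical="unreported")
        )
    rows = []
    for d in specs:
        for region in spec.regions:
            rows.append({**base, **d, "AC": int(rng.binomial(an, decoy_q)),
                         "dataset": region.label})
    return rows


def simulate_birth_series(
    spec: SimulationSpec,
    years: Sequence[int],
) -> pd.DataFrame:
    """Level + optional linear trend + bounded Gaussian noise, per region."""
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for region in spec.regions:
        y0 = years[0]
        for y in years:
            level = region.annual_births + region.births_trend * (y - y0)
            noise = rng.normal(0.0, region.births_noise_sd * region.annual_births) \
                if region.births_noise_sd > 0 else 0.0
            noise = float(np.clip(noise, -0.5 * level, 0.5 * level))
            rows.append({"region": region.label, "year": y,
                         "births": max(0, int(round(level + noise)))})
    return pd.DataFrame(rows)


def simulate_survival_cohort(
    table: MortalityTable,
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw per-patient age at death from the life table's distribution.

    A patient dies during the year of age a with probability m_a,
    conditional on reaching a; survivors through age max_age die during
    that final year (the hard lifespan cutoff).  The returned array
    holds completed years attained, so the empirical survival at age a
    is ``mean(lifetimes >= a)``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    m = np.asarray(table.rates, dtype=float)
    u = rng.random((n, table.max_age + 1))
    dies = u < m[None, :]
    lifetimes = np.where(dies.any(axis=1), dies.argmax(axis=1), table.max_age)
    return lifetimes.astype(int)


def write_fixture_bundle(
    spec: SimulationSpec,
    out_dir: str | Path,
    years: Optional[Sequence[int]] = None,
    deterministic: bool = False,
) -> dict[str, Path]:
    """Emit variants.tsv, births.tsv and truth.json, ready for the pipeline."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if years is None:
        years = range(1970, 2021)
    variants, truth = simulate_variant_table(spec, deterministic=deterministic)
    births = simulate_birth_series(spec, list(years))
    paths = {
        "variants": out_dir / "variants.tsv",
        "births": out_dir / "births.tsv",
        "truth": out_dir / "truth.json",
    }
    header = "# synthetic data: independent sites, no linkage; seed = %d\n" % spec.seed
    with open(paths["variants"], "w") as fh:
        fh.write(header)
        variants.to_csv(fh, sep="\t", index=False)
    with open(paths["births"], "w") as fh:
        fh.write(header)
        births.to_csv(fh, sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
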