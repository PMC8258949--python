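"""Run configuration: the model's fixed constants and strategy flags.

Defaults mirror the study design this package implements: 95%
confidence level, birth incidence anchored to 2018 births, historic
births aged from 1970, maximum lifespan 34, 8%/yr adult hazard.  All of
them are explicit so every run is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .variant_catalog import GenomicInterval


@dataclass
class RunConfig:
    genes: list[str]
    dataset_region: dict[str, str]                 # dataset label -> region label
    populations: dict[str, float] = field(default_factory=dict)  # region -> persons
    region_restrictions: dict[str, GenomicInterval] = field(default_factory=dict)
    conf_level: float = 0.95
    reference_year: int = 2020
    anchor_year: int = 2018                        # year whose births define headline incidence
    max_lifespan: int = 34
    mortality: Any = "default"                     # "default" | CSV path | segment-param mapping
    pooling: str = "mean_an"
    simplified_z: bool = False
    totals_rounding: str = "sum_then_round"        # or "round_then_sum"
    possibly_damaging_is_damaging: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.conf_level < 1.0):
            raise ValueError(f"conf_level must be in (0, 1), got {self.conf_level}")
        if self.max_lifespan < 0:
            raise ValueError("max_lifespan must be >= 0")
        if self.totals_rounding not in ("sum_then_round", "round_then_sum"):
            raise ValueError(f"unknown totals_rounding: {self.totals_rounding!r}")

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for r in self.dataset_region.values():
            if r not in seen:
                seen.append(r)
        return seen

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        restrictions = {}
        for gene, iv in (data.pop("region_restrictions", None) or {}).items():
            restrictions[gene] = GenomicInterval(
                chrom=str(iv["chrom"]), start=int(iv["start"]), end=int(iv["end"])
            )
        return cls(
            genes=list(data.pop("genes")),
            dataset_region={str(k): str(v) for k, v in data.pop("dataset_region").items()},
            populations={str(k): float(v) for k, v in (data.pop("populations", None) or {}).items()},
            region_restrictions=restrictions,
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_mapping(data)

    def metadata(self) -> dict[str, Any]:
        """The constants and strategy flags in effect, for report provenance."""
        return {
            "genes": list(self.genes),
            "dataset_region": dict(self.dataset_region),
            "conf_level": self.conf_level,
            "reference_year": self.reference_year,
            "anchor_year": self.anchor_year,
            "max_lifespan": self.max_lifespan,
            "mortality": str(self.mortality),
            "pooling": self.pooling,
            "simplified_z": self.simplified_z,
            "totals_rounding": self.totals_rounding,
            "possibly_damaging_is_damaging": self.possibly_damaging_is_damaging,
        }
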