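"""Fiber-content phenotypes and extreme-bulk selection.

Bulked segregant analysis pools the phenotypic extremes of a segregating
population.  Here the trait is bast fiber content, computed from fresh stem
and bast weights as ``bast / stem x 100``; the high and low bulks are the
top and bottom ``bulk_size`` plants by fiber content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


def fiber_content(stem_weight: float, bast_weight: float) -> float:
    """Bast fiber content as a percentage of stem weight.

    Rejects non-positive stem weight and bast weight exceeding stem weight
    (the bast is peeled from the stem, so it cannot outweigh it).
    """
    if stem_weight <= 0:
        raise ValueError("stem_weight must be > 0")
    if bast_weight < 0 or bast_weight > stem_weight:
        raise ValueError("bast_weight must lie in [0, stem_weight]")
    return bast_weight / stem_weight * 100.0


@dataclass(frozen=True)
class PlantPhenotype:
    plant_id: str
    stem_weight: float
    bast_weight: float

    @property
    def fiber_content(self) -> float:
        return fiber_content(self.stem_weight, self.bast_weight)


@dataclass(frozen=True)
class BulkAssignment:
    """Disjoint id lists for the high- and low-trait bulks."""

    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    bulk_size: int

    def __post_init__(self) -> None:
        if len(self.high_ids) != self.bulk_size or len(self.low_ids) != self.bulk_size:
            raise ValueError("bulk id lists must each have length bulk_size")
        if set(self.high_ids) & set(self.low_ids):
            raise ValueError("high and low bulks must be disjoint")


def select_bulks(
    phenotypes: Sequence[PlantPhenotype], bulk_size: int = 30
) -> BulkAssignment:
    """Top/bottom ``bulk_size`` plants by fiber content.

    Ties are broken by plant_id lexicographic order — ascending for the
    high bulk and descending for the low bulk — so the assignment is
    invariant to input row order and the bulks stay disjoint even under
    complete ties.
    """
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    if len(phenotypes) < 2 * bulk_size:
        raise ValueError(
            f"need at least {2 * bulk_size} plants, got {len(phenotypes)}"
        )
    ids = {p.plant_id for p in phenotypes}
    if len(ids) != len(phenotypes):
        raise ValueError("duplicate plant ids")
    by_id = sorted(phenotypes, key=lambda p: p.plant_id)
    by_high = sorted(by_id, key=lambda p: p.fiber_content, reverse=True)
    by_low = sorted(by_id[::-1], key=lambda p: p.fiber_content)
    high = tuple(p.plant_id for p in by_high[:bulk_size])
    low = tuple(p.plant_id for p in by_low[:bulk_size])
    if set(high) & set(low):
        raise ValueError("bulks overlap; population too small for bulk_size")
    return BulkAssignment(high, low, bulk_size)


def read_phenotypes(path: str | Path) -> list[PlantPhenotype]:
    """Headered TSV with columns plant_id, stem_weight_g, bast_weight_g."""
    df = pd.read_csv(path, sep="\t", dtype={"plant_id": str})
    required = {"plant_id", "stem_weight_g", "bast_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return [
        PlantPhenotype(r.plant_id, float(r.stem_weight_g), float(r.bast_weight_g))
        for r in df.itertuples()
    ]


def write_assignment(assignment: BulkAssignment, path: str | Path) -> None:
    rows = [{"plant_id": i, "bulk": "high"} for i in assignment.high_ids]
    rows += [{"plant_id": i, "bulk": "low"} for i in assignment.low_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def phenotype_frame(phenotypes: Sequence[PlantPhenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plant_id": [p.plant_id for p in phenotypes],
            "stem_weight_g": [p.stem_weight for p in phenotypes],
            "bast_weight_g": [p.bast_weight for p in phenotypes],
            "fiber_content_pct": [p.fiber_content for p in phenotypes],
        }
    )
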