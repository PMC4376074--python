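"""Experimental-design bookkeeping: condition, data-point, and test counts.

The screening study's headline denominators follow from its factorial
design: conditions = organs x endocrine disruptors x SNPs; data points =
individuals per group x treatment groups (vehicle included) x organs x
SNPs; level-1 differential-methylation tests = platforms x the per-cell-
type (generations x disruptors tested) sum x directions per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["DesignSpec", "design_counts"]


@dataclass
class DesignSpec:
    """Factor levels of the screening design; unused fields may stay None."""

    organs: int | None = None
    eds: int | None = None
    snps: int | None = None
    individuals_per_group: int | None = None
    treatment_groups: int | None = None  # including the vehicle group
    platforms: int | None = None
    directions_per_comparison: int | None = None
    # cell type -> (generations assayed, disruptors tested on that cell type)
    cell_type_tests: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def _require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None or (name == "cell_type_tests" and not value):
                raise ValueError(f"DesignSpec field {name!r} required for this quantity")
            if isinstance(value, int) and value < 1:
                raise ValueError(f"DesignSpec field {name!r} must be >= 1")


def design_counts(spec: DesignSpec, quantity: str) -> int:
    """Count experimental conditions, data points, or level-1 tests."""
    if quantity == "conditions":
        spec._require("organs", "eds", "snps")
        return spec.organs * spec.eds * spec.snps
    if quantity == "data_points":
        spec._require("individuals_per_group", "treatment_groups", "organs", "snps")
        return (
            spec.individuals_per_group * spec.treatment_groups * spec.organs * spec.snps
        )
    if quantity == "level1_tests":
        spec._require("platforms", "directions_per_comparison", "cell_type_tests")
        per_platform = sum(g * e for g, e in spec.cell_type_tests.values())
        return spec.platforms * per_platform * spec.directions_per_comparison
    raise ValueError(
        f"unknown quantity {quantity!r}; choose conditions, data_points, or level1_tests"
    )
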