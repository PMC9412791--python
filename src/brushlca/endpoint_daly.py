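"""Human-health endpoint conversion to disability-adjusted life years.

Endpoint (damage-level) LCIA expresses human-health impacts in DALYs —
years of healthy life lost — via damage factors per unit of the relevant
midpoint pressure (ReCiPe 2016 hierarchist human-health pathways).  Eight
human-health endpoint categories are modelled: global warming,
stratospheric ozone depletion, ionising radiation, particulate matter
formation, photochemical ozone formation, cancer and non-cancer effects,
and water consumption.

Because a DALY is an inconveniently large unit for a per-child-year
intervention, totals are also expressed in DALY-seconds using a 365-day
year (31,536,000 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "ENDPOINT_CATEGORIES",
    "MIDPOINT_TO_ENDPOINT",
    "SECONDS_PER_YEAR",
    "EndpointFactorSet",
    "DALYResult",
    "endpoint_convert",
    "total_dalys",
    "daly_seconds",
]

ENDPOINT_CATEGORIES = (
    "global_warming",
    "stratospheric_ozone_depletion",
    "ionising_radiation",
    "particulate_matter_formation",
    "photochemical_ozone_formation",
    "cancer_effects",
    "non_cancer_effects",
    "water_consumption",
)

# Which midpoint category feeds each human-health endpoint pathway.
MIDPOINT_TO_ENDPOINT: Dict[str, str] = {
    "CC": "global_warming",
    "HOD": "stratospheric_ozone_depletion",
    "HIR": "ionising_radiation",
    "HRI": "particulate_matter_formation",
    "HOF": "photochemical_ozone_formation",
    "HCE": "cancer_effects",
    "HNC": "non_cancer_effects",
    "RDW": "water_consumption",
}

SECONDS_PER_YEAR = 31_536_000  # 365-day year


@dataclass(frozen=True)
class EndpointFactorSet:
    """DALY damage factors, one per endpoint human-health category."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(ENDPOINT_CATEGORIES) - set(self.factors)
        if missing:
            raise ValidationError(
                f"endpoint factor set missing categories: {sorted(missing)}"
            )
        for cat, value in self.factors.items():
            if value < 0:
                raise DomainError(
                    f"endpoint factor for {cat!r} must be >= 0, got {value}"
                )


def endpoint_convert(
    inputs: Mapping[str, float], factors: EndpointFactorSet
) -> Dict[str, float]:
    """Elementwise DALYs: input quantity times damage factor, per category."""
    missing = set(inputs) - set(factors.factors)
    if missing:
        raise ValidationError(f"no endpoint factor for: {sorted(missing)}")
    return {cat: inputs[cat] * factors.factors[cat] for cat in inputs}


def total_dalys(per_category: Mapping[str, float]) -> float:
    """Sum DALYs over the 8 endpoint categories; all must be present.

    A missing category must be given as an explicit zero so that absent
    data cannot silently masquerade as zero impact.
    """
    missing = set(ENDPOINT_CATEGORIES) - set(per_category)
    if missing:
        raise ValidationError(
            f"per-category DALYs missing entries for: {sorted(missing)}"
        )
    values = [float(per_category[c]) for c in ENDPOINT_CATEGORIES]
    if not all(v == v and abs(v) != float("inf") for v in values):
        raise ValidationError("per-category DALYs must be finite")
    return sum(values)


def daly_seconds(total: float) -> float:
    """Express total DALYs in seconds of healthy life lost."""
    if total < 0:
        raise DomainError(f"total DALYs must be >= 0, got {total}")
    return total * SECONDS_PER_YEAR


@dataclass
class DALYResult:
    """Per-category DALYs with derived total and seconds."""

    programme: str
    per_category: Dict[str, float]
    total: float
    seconds: float

    @classmethod
    def from_per_category(
        cls, programme: str, per_category: Mapping[str, float]
    ) -> "DALYResult":
        total = total_dalys(per_category)
        return cls(
            programme=programme,
            per_category=dict(per_category),
            total=total,
            seconds=daly_seconds(total),
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [(c, self.per_category[c]) for c in ENDPOINT_CATEGORIES]
        rows.append(("total_dalys", self.total))
        rows.append(("daly_seconds", self.seconds))
        return pd.DataFrame(rows, columns=["category", self.programme])


def read_endpoint_factors(path) -> EndpointFactorSet:
    """Load an endpoint factor CSV with columns (category, factor, unit)."""
    frame = pd.read_csv(path)
    missing = {"category", "factor"} - set(frame.columns)
    if missing:
        raise ValidationError(
            f"endpoint factor table missing columns: {sorted(missing)}"
        )
    return EndpointFactorSet(
        {str(r.category): float(r.factor) for r in frame.itertuples(index=False)}
    )


def write_endpoint_factors(factors: EndpointFactorSet, path) -> None:
    pd.DataFrame(
        [(c, factors.factors[c], "DALY/unit") for c in ENDPOINT_CATEGORIES],
        columns=["category", "factor", "unit"],
    ).to_csv(path, index=False)
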