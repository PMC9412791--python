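"""Impact-category registry for the 16 PEF midpoint categories.

The European Product Environmental Footprint (PEF) framework scores a
product system against 16 midpoint impact categories (climate change,
acidification, three eutrophication pathways, toxicity, radiation,
particulate matter, ozone formation and depletion, land/water/resource
use).  Each category carries the LCIA method it is computed with and the
unit its score is expressed in.

PEF guidance currently recommends excluding the three toxicity-related
categories (freshwater ecotoxicity, cancer and non-cancer effects) from
normalized comparisons while the robustness of those methods is under
review; :func:`pef_excluded_toxicity_ids` returns that set.

Normalization references (annual per-person footprints) are a
user-supplied table; :func:`default_normalization_references` provides a
unit (1.0 per category) synthetic default so normalized pipelines stay
runnable and testable without asserting any external reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Mapping

import pandas as pd

from .errors import RegistryError, ValidationError

__all__ = [
    "ImpactCategory",
    "CategoryRegistry",
    "register_default_categories",
    "pef_excluded_toxicity_ids",
    "default_normalization_references",
    "read_normalization_references",
    "write_normalization_references",
]


@dataclass(frozen=True)
class ImpactCategory:
    """One midpoint impact category.

    Parameters
    ----------
    id : str
        Short code, e.g. ``"CC"`` for climate change.
    name : str
        Human-readable category name.
    lcia_method_name : str
        Name of the LCIA method the scores are computed with.
    unit : str
        Unit of the category score, e.g. ``"kg CO2 eq"``.
    """

    id: str
    name: str
    lcia_method_name: str
    unit: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("category id must be non-empty")
        if not self.unit:
            raise ValidationError(f"category {self.id!r}: unit must be non-empty")


# The 16 PEF midpoint categories with their methods and units.
_DEFAULT_ROWS = [
    ("CC", "Climate change", "IPCC 2013 GWP 100a", "kg CO2 eq"),
    ("EAC", "Freshwater and terrestrial acidification", "ILCD 2011 Midpoint+", "Mol H+ eq"),
    ("ECF", "Ecotoxicity freshwater", "ILCD 2011 Midpoint+", "CTUe"),
    ("EUF", "Eutrophication freshwater", "ILCD 2011 Midpoint+", "kg P eq"),
    ("EUM", "Eutrophication marine", "ILCD 2011 Midpoint+", "kg N eq"),
    ("EUT", "Eutrophication terrestrial", "ILCD 2011 Midpoint+", "Molc N eq"),
    ("HCE", "Cancer effects", "ILCD 2011 Midpoint+", "CTUh"),
    ("HIR", "Ionising radiation", "ILCD 2011 Midpoint+", "kBq U-235 eq"),
    ("HNC", "Non-cancer effects", "ILCD 2011 Midpoint+", "CTUh"),
    ("HRI", "Respiratory inorganics", "PM method", "Disease inc."),
    ("HOF", "Photochemical ozone formation", "ILCD 2011 Midpoint+", "kg NMVOC eq"),
    ("RLU", "Land use", "Soil quality index based on LANCA", "Pt"),
    ("HOD", "Ozone depletion", "ILCD 2011 Midpoint+", "kg CFC11 eq"),
    ("RFF", "Resource use, fossils", "CML-IA baseline", "MJ"),
    ("RMM", "Resource use, minerals and metals", "CML-IA baseline", "kg Sb eq"),
    ("RDW", "Resource use, dissipated water", "AWARE", "m3 depriv"),
]


class CategoryRegistry:
    """Ordered collection of :class:`ImpactCategory` with unique ids."""

    def __init__(self, categories: Iterator[ImpactCategory] = ()) -> None:
        self._categories: Dict[str, ImpactCategory] = {}
        for cat in categories:
            self.register(cat)

    def register(self, category: ImpactCategory) -> None:
        if category.id in self._categories:
            raise RegistryError(f"duplicate category id {category.id!r}")
        self._categories[category.id] = category

    def lookup(self, category_id: str) -> ImpactCategory:
        try:
            return self._categories[category_id]
        except KeyError:
            raise RegistryError(f"unknown category id {category_id!r}") from None

    def ids(self) -> list[str]:
        return list(self._categories)

    def __contains__(self, category_id: str) -> bool:
        return category_id in self._categories

    def __len__(self) -> int:
        return len(self._categories)

    def __iter__(self) -> Iterator[ImpactCategory]:
        return iter(self._categories.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoryRegistry):
            return NotImplemented
        return list(self) == list(other)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.id, c.name, c.lcia_method_name, c.unit) for c in self],
            columns=["id", "name", "method", "unit"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryRegistry":
        required = {"id", "name", "method", "unit"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"registry table missing columns: {sorted(missing)}")
        return cls(
            ImpactCategory(row.id, row.name, row.method, row.unit)
            for row in frame.itertuples(index=False)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CategoryRegistry":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def register_default_categories() -> CategoryRegistry:
    """Return a registry holding the 16 default PEF midpoint categories."""
    return CategoryRegistry(
        ImpactCategory(*row) for row in _DEFAULT_ROWS
    )


def pef_excluded_toxicity_ids() -> frozenset[str]:
    """The three toxicity categories excluded from PEF normalization.

    Freshwater ecotoxicity (ECF), cancer effects (HCE) and non-cancer
    effects (HNC) are left out of normalized comparisons per PEF
    recommendations while their methods are under review.
    """
    return frozenset({"ECF", "HCE", "HNC"})


def default_normalization_references(
    registry: CategoryRegistry,
) -> Dict[str, float]:
    """Synthetic unit references: 1.0 per category in the category's unit.

    Real per-capita reference values are a user-supplied table; this
    default keeps normalization exercisable without asserting any
    particular reference set.
    """
    return {cat.id: 1.0 for cat in registry}


def read_normalization_references(path) -> Dict[str, float]:
    """Load a (category_id, reference_value) CSV; values must be > 0."""
    frame = pd.read_csv(path)
    required = {"category_id", "reference_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(
            f"normalization table missing columns: {sorted(missing)}"
        )
    refs: Dict[str, float] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        value = float(row.reference_value)
        if not value > 0:
            raise ValidationError(
                f"normalization reference for {row.category_id!r} at line {i} "
                f"must be > 0, got {value}"
            )
        refs[str(row.category_id)] = value
    return refs


def write_normalization_references(refs: Mapping[str, float], path) -> None:
    pd.DataFrame(
        sorted(refs.items()), columns=["category_id", "reference_value"]
    ).to_csv(path, index=False)
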