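"""Matrix-based life cycle inventory and impact assessment.

Standard computational LCA structure: a technology matrix ``A`` (product
flows x processes; reference products positive, consumed products
negative), an intervention matrix ``B`` (elementary flows x processes),
and a demand vector ``f``.  Solving ``A s = f`` gives the scaling vector
``s``; the inventory is ``g = B s``; midpoint scores are ``Q g`` with
``Q`` the characterization-factor matrix.  Foreground systems here are
tiny (tens of processes), so a direct dense solve is used.

Sign convention: emissions and resource draws are positive, which keeps
all category scores positive for ordinary (credit-free) systems.
Normalization divides included category scores by annual per-person
references; PEF's three toxicity categories are carried as explicitly
excluded, never silently zeroed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import (
    CoverageError,
    InventorySolveError,
    MissingFactorError,
    ValidationError,
)
from .foreground_inventory import ForegroundSystem
from .impact_schema import CategoryRegistry, pef_excluded_toxicity_ids

logger = logging.getLogger(__name__)

__all__ = [
    "CharacterizationTable",
    "LCIAResult",
    "NormalizedResult",
    "ContributionBreakdown",
    "build_technology_matrix",
    "build_intervention_matrix",
    "solve_scaling",
    "aggregate_inventory",
    "characterize",
    "compute_lcia",
    "normalize",
    "contribution_by_group",
    "contribution_summary",
]


class CharacterizationTable:
    """Factors per (impact category, elementary flow).

    Thin wrapper over a long-form DataFrame with columns
    ``(category_id, flow_id, factor, unit)``; the pivoted matrix is built
    on demand for characterization.
    """

    COLUMNS = ("category_id", "flow_id", "factor", "unit")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(
                f"characterization table missing columns: {sorted(missing)}"
            )
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["factor"] = frame["factor"].astype(float)
        if not np.isfinite(frame["factor"]).all():
            raise ValidationError("characterization factors must be finite")
        dup = frame.duplicated(subset=["category_id", "flow_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate (category, flow) factor rows: "
                f"{frame.loc[dup, ['category_id', 'flow_id']].values.tolist()}"
            )
        self.frame = frame.reset_index(drop=True)

    def matrix(self) -> pd.DataFrame:
        """Pivot to categories x flows, absent pairs as 0."""
        return self.frame.pivot(
            index="category_id", columns="flow_id", values="factor"
        ).fillna(0.0)

    def factor(self, category_id: str, flow_id: str) -> float:
        sel = self.frame[
            (self.frame.category_id == category_id)
            & (self.frame.flow_id == flow_id)
        ]
        return float(sel.factor.iloc[0]) if len(sel) else 0.0

    def flow_ids(self) -> Set[str]:
        return set(self.frame.flow_id)

    def category_ids(self) -> Set[str]:
        return set(self.frame.category_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterizationTable):
            return NotImplemented
        a = self.frame.sort_values(["category_id", "flow_id"]).reset_index(drop=True)
        b = other.frame.sort_values(["category_id", "flow_id"]).reset_index(drop=True)
        return a.equals(b)


@dataclass
class LCIAResult:
    """Per-category midpoint scores for one programme/scenario run."""

    programme: str
    scenario: str
    scores: Dict[str, float]
    units: Dict[str, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, name=f"{self.programme}/{self.scenario}")


@dataclass
class NormalizedResult:
    """Dimensionless normalized scores; excluded categories carried as such."""

    programme: str
    scenario: str
    values: Dict[str, float]
    excluded: Set[str]


@dataclass
class ContributionBreakdown:
    """Per-category group scores and percentage shares.

    ``scores`` and ``shares`` are DataFrames indexed by category with one
    column per group.  Shares are NaN where undefined (negative group
    scores or zero total).
    """

    scores: pd.DataFrame
    shares: pd.DataFrame


# --------------------------------------------------------------------------
# Matrix assembly and inventory solve
# --------------------------------------------------------------------------

def build_technology_matrix(system: ForegroundSystem) -> pd.DataFrame:
    """Square technology matrix: product flows x processes."""
    system.validate()
    producers = system.producers()
    products = list(producers)
    processes = list(system.processes)
    A = pd.DataFrame(0.0, index=products, columns=processes)
    for proc in system.processes.values():
        fid, amount = proc.reference_product
        A.loc[fid, proc.id] += amount
        for in_fid, in_amount in proc.product_inputs:
            A.loc[in_fid, proc.id] -= in_amount
    return A


def build_intervention_matrix(system: ForegroundSystem) -> pd.DataFrame:
    """Intervention matrix: elementary flows x processes."""
    elem = system.elementary_flow_ids()
    processes = list(system.processes)
    B = pd.DataFrame(0.0, index=elem, columns=processes)
    for proc in system.processes.values():
        for fid, amount in proc.elementary_exchanges:
            B.loc[fid, proc.id] += amount
    return B


_COND_WARN = 1e12


def solve_scaling(A: pd.DataFrame, demand: Mapping[str, float]) -> pd.Series:
    """Solve ``A s = f`` for the process scaling vector ``s``."""
    if A.shape[0] != A.shape[1]:
        raise InventorySolveError(
            f"technology matrix is not square: {A.shape}"
        )
    unknown = set(demand) - set(A.index)
    if unknown:
        raise CoverageError(
            f"demand references unproduced flows: {sorted(unknown)}"
        )
    f = pd.Series(0.0, index=A.index)
    for fid, amount in demand.items():
        f[fid] = amount
    mat = A.to_numpy()
    if not np.isfinite(mat).all():
        raise InventorySolveError("technology matrix has non-finite entries")
    try:
        s = scipy.linalg.solve(mat, f.to_numpy())
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise InventorySolveError(f"singular technology matrix: {exc}") from exc
    if not np.isfinite(s).all():
        raise InventorySolveError("scaling solve produced non-finite values")
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > _COND_WARN:
        raise InventorySolveError(
            f"technology matrix is singular or ill-conditioned (cond={cond:.3g})"
        )
    return pd.Series(s, index=A.columns, name="scaling")


def aggregate_inventory(B: pd.DataFrame, s: pd.Series) -> pd.Series:
    """Elementary-flow totals ``g = B s``."""
    if set(B.columns) != set(s.index):
        raise ValidationError(
            "intervention matrix columns do not match scaling index"
        )
    g = B.to_numpy() @ s.reindex(B.columns).to_numpy()
    return pd.Series(g, index=B.index, name="inventory")


def characterize(
    g: Mapping[str, float] | pd.Series,
    cf: CharacterizationTable,
    registry: CategoryRegistry,
    programme: str = "",
    scenario: str = "baseline",
    strict: bool = True,
) -> LCIAResult:
    """Midpoint scores per category: ``score[c] = sum_f cf[c,f] * g[f]``.

    In strict mode a nonzero inventory flow with no factor row in any
    category raises :class:`MissingFactorError`; in lenient mode it is
    treated as zero and logged.
    """
    g = pd.Series(dict(g), dtype=float)
    known = cf.flow_ids()
    uncovered = [fid for fid, amt in g.items() if amt != 0 and fid not in known]
    if uncovered:
        if strict:
            raise MissingFactorError(
                f"no characterization factors for nonzero flows: "
                f"{sorted(uncovered)}"
            )
        logger.warning(
            "treating %d uncovered flows as zero impact: %s",
            len(uncovered), sorted(uncovered),
        )
    Q = cf.matrix()
    common = [f for f in g.index if f in Q.columns]
    raw = Q.loc[:, common].to_numpy() @ g.loc[common].to_numpy() if common else None
    scores = {c.id: 0.0 for c in registry}
    if raw is not None:
        for cid, val in zip(Q.index, raw):
            if cid in scores:
                scores[cid] = float(val)
    units = {c.id: c.unit for c in registry}
    return LCIAResult(programme, scenario, scores, units)


def compute_lcia(
    system: ForegroundSystem,
    cf: CharacterizationTable,
    registry: CategoryRegistry,
    programme: str = "",
    scenario: str = "baseline",
    strict: bool = True,
) -> LCIAResult:
    """Full chain: build matrices, solve, aggregate, characterize."""
    A = build_technology_matrix(system)
    B = build_intervention_matrix(system)
    s = solve_scaling(A, system.demand)
    g = aggregate_inventory(B, s)
    return characterize(g, cf, registry, programme, scenario, strict=strict)


# --------------------------------------------------------------------------
# Normalization and contribution analysis
# --------------------------------------------------------------------------

def normalize(
    result: LCIAResult,
    refs: Mapping[str, float],
    exclusions: Optional[Iterable[str]] = None,
) -> NormalizedResult:
    """Divide included scores by per-person annual references.

    Excluded categories (by default the PEF toxicity trio) are reported
    as excluded rather than zero, so a downstream reader cannot mistake
    "not assessed" for "no impact".
    """
    excluded = set(
        pef_excluded_toxicity_ids() if exclusions is None else exclusions
    )
    values: Dict[str, float] = {}
    for cid, score in result.scores.items():
        if cid in excluded:
            continue
        if cid not in refs:
            raise ValidationError(
                f"no normalization reference for included category {cid!r}"
            )
        ref = float(refs[cid])
        if ref <= 0:
            raise ValidationError(
                f"normalization reference for {cid!r} must be > 0, got {ref}"
            )
        values[cid] = score / ref
    return NormalizedResult(result.programme, result.scenario, values, excluded)


def contribution_by_group(
    system: ForegroundSystem,
    demand: Mapping[str, float],
    cf: CharacterizationTable,
    grouping: Mapping[str, str],
    registry: CategoryRegistry,
) -> ContributionBreakdown:
    """Decompose each category score into labelled process-group shares.

    Each process column of the scaled inventory is attributed to its
    group; group scores therefore sum exactly to the total score.
    """
    unlabelled = set(system.processes) - set(grouping)
    if unlabelled:
        raise ValidationError(
            f"processes without a contribution label: {sorted(unlabelled)}"
        )
    A = build_technology_matrix(system)
    B = build_intervention_matrix(system)
    s = solve_scaling(A, demand)
    groups = sorted(set(grouping[p] for p in system.processes))
    cats = registry.ids()
    scores = pd.DataFrame(0.0, index=cats, columns=groups)
    for group in groups:
        members = [p for p in system.processes if grouping[p] == group]
        g_group = B.loc[:, members].to_numpy() @ s.loc[members].to_numpy()
        part = characterize(
            pd.Series(g_group, index=B.index), cf, registry, strict=False
        )
        for cid, val in part.scores.items():
            scores.loc[cid, group] = val
    totals = scores.sum(axis=1)
    shares = pd.DataFrame(np.nan, index=cats, columns=groups)
    for cid in cats:
        row = scores.loc[cid]
        if (row < 0).any() or totals[cid] <= 0:
            if (row < 0).any():
                warnings.warn(
                    f"negative group scores in category {cid}; percentage "
                    "shares undefined, reporting absolute scores only",
                    stacklevel=2,
                )
            continue
        shares.loc[cid] = 100.0 * row / totals[cid]
    return ContributionBreakdown(scores=scores, shares=shares)


def contribution_summary(breakdown: ContributionBreakdown) -> pd.DataFrame:
    """Mean/min/max percentage share per group across categories."""
    shares = breakdown.shares.dropna(how="all")
    if shares.empty:
        raise ValidationError("breakdown has no defined percentage shares")
    return pd.DataFrame(
        {
            "mean_share_pct": shares.mean(axis=0),
            "min_share_pct": shares.min(axis=0),
            "max_share_pct": shares.max(axis=0),
        }
    )
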