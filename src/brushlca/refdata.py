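"""Published reference results shipped as benchmark fixtures.

The study these programmes come from reports full-database midpoint
scores (16 categories, baseline plus sensitivity scenarios, for both
programmes) and a human-health DALY breakdown.  Those absolute scores
depend on a proprietary background database and are not recomputed here;
they are shipped verbatim as inputs for the arithmetic the package *can*
reproduce exactly — percent changes between scenario columns, DALY
totals and DALY-second conversions — and as fixtures for benchmark
tests.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd

__all__ = [
    "reference_lcia_scores",
    "reference_daly_breakdown",
    "reference_daly_reported_totals",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("brushlca.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def reference_lcia_scores() -> pd.DataFrame:
    """Long-form reported midpoint scores.

    Columns: programme, scenario, category_id, score.  Scenarios are
    ``baseline``, ``bamboo_brush``, ``double_paste`` (supervised) and
    ``baseline``, ``bamboo_brush``, ``paper_bag``, ``bamboo_and_paper``,
    ``exclude_water`` (provision).
    """
    frame = _read("reference_lcia_scores.csv")
    frame["score"] = frame["score"].astype(float)
    return frame


def reference_score(programme: str, scenario: str, category_id: str) -> float:
    frame = reference_lcia_scores()
    sel = frame[
        (frame.programme == programme)
        & (frame.scenario == scenario)
        & (frame.category_id == category_id)
    ]
    if sel.empty:
        raise KeyError((programme, scenario, category_id))
    return float(sel.score.iloc[0])


def reference_daly_breakdown() -> Dict[str, Dict[str, float]]:
    """Reported per-category endpoint DALYs, keyed by programme."""
    frame = _read("reference_dalys.csv")
    out: Dict[str, Dict[str, float]] = {}
    for row in frame.itertuples(index=False):
        if row.category in ("total_dalys", "daly_seconds"):
            continue
        out.setdefault(row.programme, {})[row.category] = float(row.dalys)
    return out


def reference_daly_reported_totals() -> Dict[str, Tuple[float, float]]:
    """Reported (total DALYs, DALY seconds) per programme."""
    frame = _read("reference_dalys.csv")
    totals: Dict[str, float] = {}
    seconds: Dict[str, float] = {}
    for row in frame.itertuples(index=False):
        if row.category == "total_dalys":
            totals[row.programme] = float(row.dalys)
        elif row.category == "daly_seconds":
            seconds[row.programme] = float(row.dalys)
    return {p: (totals[p], seconds[p]) for p in totals}
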