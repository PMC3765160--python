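"""Docking-score / activity comparisons.

Docking itself is out of scope (the scores were produced by a proprietary
engine against the mosquito odorant binding protein OBP1); the published
score tables ship as fixtures and user-supplied score CSVs from any engine
are accepted.  The analyses are deliberately simple: Pearson correlation of
raw observed MEDs with docking scores over a most-active subset (the
published observation is r = 0.922 over the seven most active compounds),
and a joint rank report that flags score/activity concordance.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DockingScoreRecord",
    "CorrelationResult",
    "load_score_table",
    "read_scores_csv",
    "most_active_subset",
    "correlate",
    "rank_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DockingScoreRecord:
    """One compound's docking score and observed MED (more negative = better score)."""

    id: str
    score: float
    med_obs: Optional[float]
    units: str = ""
    source: str = ""


def _parse_scores(text: str, source: Optional[str]) -> List[DockingScoreRecord]:
    out = []
    for row in csv.DictReader(io.StringIO(text)):
        if source is not None and row.get("source", "") != source:
            continue
        med = row.get("med_obs", "").strip()
        out.append(
            DockingScoreRecord(
                id=row["id"].strip(),
                score=float(row["score"]),
                med_obs=float(med) if med else None,
                units=row.get("units", "").strip(),
                source=row.get("source", "").strip(),
            )
        )
    return out


def load_score_table(source: str = "table4") -> List[DockingScoreRecord]:
    """Packaged docking-score fixtures (``"table4"`` or ``"table5"``)."""
    text = (
        resources.files("repelqsar.data")
        .joinpath("glide_scores.csv")
        .read_text(encoding="utf-8")
    )
    recs = _parse_scores(text, source)
    if not recs:
        raise ValueError(f"no score records with source {source!r}")
    return recs


def read_scores_csv(path: str) -> List[DockingScoreRecord]:
    """User-supplied scores: CSV with columns id, score[, med_obs, units, source]."""
    with open(path, encoding="utf-8") as fh:
        return _parse_scores(fh.read(), None)


def most_active_subset(records: Sequence[DockingScoreRecord], k: int) -> List[str]:
    """Ids of the ``k`` lowest-MED records; ties broken by id (logged)."""
    if k <= 0:
        raise ValueError("k must be positive")
    scored = [r for r in records if r.med_obs is not None]
    if k > len(scored):
        raise ValueError(f"k={k} exceeds the {len(scored)} records with MEDs")
    ordered = sorted(scored, key=lambda r: (r.med_obs, r.id))
    meds = [r.med_obs for r in ordered]
    if len(set(meds[: k + 1])) <= k and len(meds) > k and meds[k - 1] == meds[k]:
        log.info("MED tie at the subset boundary broken by id order")
    return [r.id for r in ordered[:k]]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between raw MED and docking score over a subset."""

    subset_ids: tuple
    r: float
    n: int
    p_value: float


def correlate(
    records: Sequence[DockingScoreRecord], subset: Optional[Sequence[str]] = None
) -> CorrelationResult:
    """Pearson r between raw observed MED and docking score.

    Uses raw (untransformed) MEDs: the published 0.922 arises from the raw
    values of the most-active subset, not from log MEDs.
    """
    by_id = {r.id: r for r in records}
    ids = list(subset) if subset is not None else [
        r.id for r in records if r.med_obs is not None
    ]
    missing = [i for i in ids if i not in by_id or by_id[i].med_obs is None]
    if missing:
        raise ValueError(f"subset ids without MED/score data: {missing}")
    if len(ids) < 3:
        raise ValueError("correlation needs at least 3 records")
    med = np.array([by_id[i].med_obs for i in ids])
    sc = np.array([by_id[i].score for i in ids])
    if med.std() == 0 or sc.std() == 0:
        raise ValueError("correlation undefined: zero variance in MED or score")
    r, p = stats.pearsonr(med, sc)
    return CorrelationResult(subset_ids=tuple(ids), r=float(r), n=len(ids),
                             p_value=float(p))


def rank_report(records: Sequence[DockingScoreRecord]) -> pd.DataFrame:
    """Joint ranking by docking score and by activity.

    Rank 1 is the best docking score (most negative) respectively the
    strongest activity (lowest MED); ``concordant`` flags compounds whose
    two ranks differ by at most 2.  Row order of the input is irrelevant;
    ties are broken by id for stability.
    """
    scored = [r for r in records if r.med_obs is not None]
    if len(scored) < 2:
        raise ValueError("rank report needs at least 2 records with MEDs")
    df = pd.DataFrame(
        {
            "id": [r.id for r in scored],
            "score": [r.score for r in scored],
            "med_obs": [r.med_obs for r in scored],
        }
    )
    df = df.sort_values("id", kind="stable")
    df["score_rank"] = (
        df.sort_values(["score", "id"], kind="stable")["id"]
        .reset_index(drop=True)
        .reset_index()
        .set_index("id")["index"]
        .reindex(df["id"])
        .to_numpy()
        + 1
    )
    df["activity_rank"] = (
        df.sort_values(["med_obs", "id"], kind="stable")["id"]
        .reset_index(drop=True)
        .reset_index()
        .set_index("id")["index"]
        .reindex(df["id"])
        .to_numpy()
        + 1
    )
    df["concordant"] = (df["score_rank"] - df["activity_rank"]).abs() <= 2
    return df.sort_values("activity_rank").reset_index(drop=True)
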