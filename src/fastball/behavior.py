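"""Scoring of the behavioural instruments.

Covers the psychomotor vigilance task (PVT), the post-task 2AFC
recognition check, the DMS-48 visual recognition test, and norm-based
amnestic classification from the ACE-III memory subscale. All scorers
are pure functions of their input rows and invariant to row order.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PVTScore",
    "DMS48Score",
    "score_pvt",
    "score_2afc",
    "score_dms48",
    "cutoff_from_norms",
    "classify_mci",
    "score_cohort",
]


class PVTScore(NamedTuple):
    median_rt_s: float
    n_lapses: int
    n_discarded: int


class DMS48Score(NamedTuple):
    total_acc: float
    unique_acc: float
    paired_acc: float
    abstract_acc: float


def score_pvt(
    rts_s,
    discard_below_s: float = 0.100,
    lapse_above_s: float = 0.500,
    lapses_in_median: bool = True,
) -> PVTScore:
    """Apply the PVT filtering and lapse rules.

    Responses faster than 100 ms are discarded from all statistics;
    responses slower than 500 ms count as lapses. Lapse trials stay in
    the median by default (only sub-100 ms responses are discarded);
    set ``lapses_in_median=False`` to drop them from the median too.
    """
    rts = np.asarray(list(rts_s), dtype=float)
    kept = rts[rts >= discard_below_s]
    n_discarded = len(rts) - len(kept)
    n_lapses = int(np.sum(kept > lapse_above_s))
    pool = kept if lapses_in_median else kept[kept <= lapse_above_s]
    if len(pool) == 0:
        raise ValueError("no valid PVT responses after filtering")
    return PVTScore(float(np.median(pool)), n_lapses, n_discarded)


def score_2afc(rows: pd.DataFrame) -> pd.DataFrame:
    """Accuracy and median RT per item class (oddball vs standard).

    Returns one row per class present in the input; a class with no
    rows is simply absent.
    """
    out = []
    for cls, sub in rows.groupby("item_class", sort=True):
        out.append(
            {
                "item_class": cls,
                "n": len(sub),
                "accuracy": float(sub["correct"].mean()),
                "median_rt_s": float(sub["rt_s"].median()) if sub["rt_s"].notna().any() else np.nan,
            }
        )
    return pd.DataFrame(out)


def score_dms48(rows: pd.DataFrame) -> DMS48Score:
    """Overall and per-subset accuracy over the 48 DMS-48 trials.

    Subsets are the three 16-item groups: unique images, paired
    pictures and abstract items.
    """
    acc = {}
    for cls in ("unique", "paired", "abstract"):
        sub = rows[rows["item_class"] == cls]
        if len(sub) == 0:
            raise ValueError(f"no DMS-48 rows for subset '{cls}'")
        acc[cls] = float(sub["correct"].mean())
    total = float(rows[rows["item_class"].isin(("unique", "paired", "abstract"))]["correct"].mean())
    return DMS48Score(total, acc["unique"], acc["paired"], acc["abstract"])


def cutoff_from_norms(control_scores, k: float = 2.0) -> int:
    """Impairment cutoff: floor(mean - k * SD) of the control scores.

    Applied as "score <= cutoff -> amnestic". With control memory
    scores of mean 25 and SD 2 the cutoff is 21.
    """
    x = np.asarray(list(control_scores), dtype=float)
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return int(math.floor(x.mean() - k * sd))


def classify_mci(ace_memory: float, cutoff: int = 21) -> str:
    """Split MCI into amnestic (score <= cutoff) vs non-amnestic."""
    return "aMCI" if ace_memory <= cutoff else "naMCI"


def score_cohort(responses: pd.DataFrame, ace: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject behavioural summary over a long response table.

    Combines 2AFC accuracy/speed, PVT median and lapses, and DMS-48
    subset accuracies into one row per subject; ACE-III subscale
    totals are merged in when provided.
    """
    rows = []
    for sid, sub in responses.groupby("subject_id", sort=True):
        rec: dict = {"subject_id": sid}
        afc = sub[sub["task"].str.startswith("fastball_2afc")]
        if len(afc):
            for r in score_2afc(afc).itertuples():
                rec[f"acc_2afc_{r.item_class}"] = r.accuracy
                rec[f"rt_2afc_{r.item_class}_s"] = r.median_rt_s
        pvt = sub[sub["task"] == "pvt"]
        if len(pvt):
            try:
                s = score_pvt(pvt["rt_s"])
                rec["pvt_median_rt_s"] = s.median_rt_s
                rec["pvt_lapses"] = s.n_lapses
                rec["pvt_discarded"] = s.n_discarded
            except ValueError:
                rec["pvt_median_rt_s"] = np.nan
        dms = sub[sub["task"] == "dms48"]
        if len(dms):
            d = score_dms48(dms)
            rec["dms48_total"] = d.total_acc
            rec["dms48_unique"] = d.unique_acc
            rec["dms48_paired"] = d.paired_acc
            rec["dms48_abstract"] = d.abstract_acc
        rows.append(rec)
    out = pd.DataFrame(rows)
    if ace is not None:
        out = out.merge(ace, on="subject_id", how="left")
    return out
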