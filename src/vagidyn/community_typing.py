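"""Dominance-group community typing and longitudinal shift statistics.

Each vaginal sample is assigned one of five community types based on its
relative abundance profile at the *Lactobacillus* sub-genus-group level:

* ``CRISPATUS_DOM`` — *L. crispatus* group dominated,
* ``INERS_DOM`` — *L. iners* group dominated,
* ``CRISP_INERS_CODOM`` — both groups each above 10% and jointly above 50%,
* ``OTHER_LACTO_DOM`` — dominated by the *L. gasseri*, *L. jensenii* or
  *L. pasteurii* group,
* ``NON_LACTO`` — everything else (a non-*Lactobacillus* taxon on top, or no
  taxon above the dominance threshold).

A taxon "dominates" when it is the most abundant taxon in the sample and its
relative abundance exceeds 40%.  Codominance is checked before single
dominance, so a profile such as {crispatus 0.45, iners 0.12} is codominant.
Thresholds are strict inequalities by default; ``inclusive_thresholds=True``
switches to >= comparisons.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    TIMEPOINTS,
    LACTOBACILLUS_GROUPS,
    AbundanceTable,
    StudyDesign,
)
from .errors import ValidationError


class DominanceGroup(str, Enum):
    CRISPATUS_DOM = "CRISPATUS_DOM"
    INERS_DOM = "INERS_DOM"
    CRISP_INERS_CODOM = "CRISP_INERS_CODOM"
    OTHER_LACTO_DOM = "OTHER_LACTO_DOM"
    NON_LACTO = "NON_LACTO"


_OTHER_LACTO = ("L_gasseri_group", "L_jensenii_group", "L_pasteurii_group")

DOMINANCE_THRESHOLD = 0.40
CODOMINANCE_EACH = 0.10
CODOMINANCE_COMBINED = 0.50


def classify_sample(
    composition: Mapping[str, float] | pd.Series,
    inclusive_thresholds: bool = False,
) -> DominanceGroup:
    """Assign a dominance group to one relative abundance profile.

    ``composition`` maps aggregated taxon labels (sub-genus groups for
    lactobacilli, genera otherwise) to relative abundances summing to 1.
    """
    comp = pd.Series(composition, dtype=float)
    total = float(comp.sum())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValidationError(f"composition sums to {total:.6g}, not 1")
    gt = operator.ge if inclusive_thresholds else operator.gt
    crisp = float(comp.get("L_crispatus_group", 0.0))
    iners = float(comp.get("L_iners_group", 0.0))
    if (
        gt(crisp, CODOMINANCE_EACH)
        and gt(iners, CODOMINANCE_EACH)
        and gt(crisp + iners, CODOMINANCE_COMBINED)
    ):
        return DominanceGroup.CRISP_INERS_CODOM
    # top taxon; equal maxima broken alphabetically for determinism
    top_value = float(comp.max())
    candidates = sorted(comp.index[comp.to_numpy() == top_value])
    top = candidates[0]
    if gt(top_value, DOMINANCE_THRESHOLD):
        if top == "L_crispatus_group":
            return DominanceGroup.CRISPATUS_DOM
        if top == "L_iners_group":
            return DominanceGroup.INERS_DOM
        if top in _OTHER_LACTO:
            return DominanceGroup.OTHER_LACTO_DOM
        return DominanceGroup.NON_LACTO
    return DominanceGroup.NON_LACTO


def classify_cohort(
    table: AbundanceTable,
    design: StudyDesign,
    inclusive_thresholds: bool = False,
) -> pd.Series:
    """Label every sample of a relative, sub-genus-aggregated table.

    Returns a Series of :class:`DominanceGroup` indexed by sample id, ordered
    by (participant, chronological time point).
    """
    if table.mode != "relative":
        raise ValidationError("classification requires a relative table")
    missing = [s for s in table.sample_ids if s not in design.samples.index]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} absent from study design")
    ordered: list[str] = []
    for pid in design.participants:
        for sid in design.samples_of(pid).index:
            if sid in table.values.columns:
                ordered.append(sid)
    labels = {
        sid: classify_sample(table.sample(sid), inclusive_thresholds)
        for sid in ordered
    }
    return pd.Series([labels[s] for s in ordered], index=pd.Index(ordered, name="sample_id"))


@dataclass
class ShiftSummary:
    """Per-participant account of dominant-community shifts over time."""

    participant_id: str
    labels_in_time_order: list[DominanceGroup]
    n_transitions: int
    n_deviations_from_majority: int
    stable: bool


def shift_summary(
    labels: Sequence[DominanceGroup], participant_id: str = ""
) -> ShiftSummary:
    """Summarize shifts for one participant's chronologically ordered labels.

    ``n_transitions`` counts adjacent unequal pairs; missing time points must
    already be skipped by the caller.  ``n_deviations_from_majority`` counts
    labels differing from the modal label, ties broken toward the
    earliest-occurring modal label.
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("empty label sequence")
    transitions = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
    counts: dict[DominanceGroup, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top_count = max(counts.values())
    modal = next(lab for lab in labels if counts[lab] == top_count)
    deviations = sum(1 for lab in labels if lab != modal)
    return ShiftSummary(
        participant_id=participant_id,
        labels_in_time_order=labels,
        n_transitions=transitions,
        n_deviations_from_majority=deviations,
        stable=transitions == 0,
    )


def cohort_shift_summaries(
    labels: pd.Series, design: StudyDesign
) -> list[ShiftSummary]:
    """Shift summaries for every participant with at least one labeled sample."""
    out = []
    for pid in design.participants:
        seq = [
            labels[sid]
            for sid in design.samples_of(pid).index
            if sid in labels.index
        ]
        if seq:
            out.append(shift_summary(seq, participant_id=pid))
    return out


def percent_rounded(count: float, total: float) -> int:
    """100*count/total rounded half away from zero, as reported in text."""
    if total == 0:
        raise ValidationError("percentage of an empty stratum")
    frac = 100.0 * count / total
    return int(Decimal(repr(frac)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def dominance_prevalence(
    labels: pd.Series,
    design: StudyDesign,
    stratify_by_arm: bool = False,
) -> pd.DataFrame:
    """Counts and percentages of each dominance group, optionally per arm.

    Percentages are rounded half away from zero to integers for reporting;
    the raw fraction is retained in the ``fraction`` column.
    """
    missing = [s for s in labels.index if s not in design.samples.index]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} absent from study design")
    df = pd.DataFrame(
        {
            "group": [lab.value for lab in labels],
            "arm": design.samples.loc[labels.index, "arm"].to_numpy(),
        },
        index=labels.index,
    )
    strata = [("all", df)] if not stratify_by_arm else [
        (arm, df[df["arm"] == arm]) for arm in ("placebo", "treatment")
    ]
    rows = []
    for stratum, sub in strata:
        total = len(sub)
        for group in DominanceGroup:
            n = int((sub["group"] == group.value).sum())
            rows.append(
                {
                    "stratum": stratum,
                    "group": group.value,
                    "count": n,
                    "total": total,
                    "fraction": n / total if total else float("nan"),
                    "percent": percent_rounded(n, total) if total else 0,
                }
            )
    return pd.DataFrame(rows)
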