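"""Dominant-taxon prediction from the species-specific qPCR panel.

The panel quantifies L. crispatus, L. iners, L. gasseri and L. jensenii
(CFU/mL).  A sample is called crispatus/iners codominant when those two
species carry the two largest concentrations and differ by less than
two-fold; otherwise the single most abundant species names the predicted
group.  The panel contains only lactobacilli, so a non-*Lactobacillus*
community can never be predicted; agreement with 16S-based typing is
therefore scored over *Lactobacillus*-typed samples by default, with
non-*Lactobacillus* 16S samples tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_typing import DominanceGroup
from .core_io import QPCR_SPECIES, QpcrPanel
from .errors import ValidationError

CODOMINANCE_FOLD = 2.0

_SPECIES_TO_GROUP = {
    "L_crispatus": DominanceGroup.CRISPATUS_DOM,
    "L_iners": DominanceGroup.INERS_DOM,
    "L_gasseri": DominanceGroup.OTHER_LACTO_DOM,
    "L_jensenii": DominanceGroup.OTHER_LACTO_DOM,
}


def predict_group_from_qpcr(panel_entry) -> DominanceGroup | None:
    """Predict the dominance group from one sample's four concentrations.

    Returns ``None`` (a no-call) when no species has a positive
    concentration.  Absent (NaN) measurements are treated as unavailable,
    not zero.  Scale-invariant: only concentration ranks and the
    crispatus/iners fold ratio matter.
    """
    entry = pd.Series(panel_entry, dtype=float).reindex(list(QPCR_SPECIES))
    present = entry.dropna()
    positive = present[present > 0]
    if positive.empty:
        return None
    # sort by concentration, species name breaking exact ties deterministically
    ranked = sorted(positive.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) >= 2:
        (sp1, c1), (sp2, c2) = ranked[0], ranked[1]
        if {sp1, sp2} == {"L_crispatus", "L_iners"} and c1 / c2 < CODOMINANCE_FOLD:
            return DominanceGroup.CRISP_INERS_CODOM
    return _SPECIES_TO_GROUP[ranked[0][0]]


def predict_cohort(panel: QpcrPanel) -> pd.Series:
    """Per-sample qPCR predictions (None = no-call)."""
    return pd.Series(
        {sid: predict_group_from_qpcr(panel.sample(sid)) for sid in panel.sample_ids},
        name="qpcr_group",
    )


@dataclass
class ConcordanceReport:
    """Agreement between 16S dominance typing and qPCR prediction.

    ``confusion`` is a 5x5 count table (16S group rows, qPCR-predicted
    columns) over the scored samples.  ``n_non_lacto_16s`` counts samples
    whose 16S label was NON_LACTO; these are excluded from the agreement
    denominator unless ``include_non_lacto`` was set, in which case they are
    automatic disagreements.  ``defined`` is False when no sample could be
    scored.
    """

    n_samples: int
    n_agree: int
    agreement_fraction: float
    confusion: pd.DataFrame
    n_no_call: int
    n_non_lacto_16s: int
    include_non_lacto: bool
    defined: bool = True


def concordance(
    labels_16s: pd.Series,
    labels_qpcr: pd.Series,
    include_non_lacto: bool = False,
) -> ConcordanceReport:
    """Score qPCR predictions against 16S dominance labels.

    Both series must cover the same sample set.  No-call predictions are
    excluded from scoring and counted separately.
    """
    idx_16s = set(labels_16s.index)
    idx_q = set(labels_qpcr.index)
    if not idx_16s & idx_q:
        raise ValidationError("label sets share no samples")
    if idx_16s != idx_q:
        raise ValidationError("16S and qPCR label sets differ")
    samples = list(labels_16s.index)

    groups = [g.value for g in DominanceGroup]
    confusion = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    n_agree = 0
    n_scored = 0
    n_no_call = 0
    n_non_lacto = 0
    for sid in samples:
        pred = labels_qpcr[sid]
        obs = labels_16s[sid]
        if pred is None:
            n_no_call += 1
            continue
        if obs == DominanceGroup.NON_LACTO:
            n_non_lacto += 1
            if not include_non_lacto:
                continue
        confusion.loc[obs.value, pred.value] += 1
        n_scored += 1
        if obs == pred:
            n_agree += 1
    defined = n_scored > 0
    return ConcordanceReport(
        n_samples=n_scored,
        n_agree=n_agree,
        agreement_fraction=n_agree / n_scored if defined else float("nan"),
        confusion=confusion,
        n_no_call=n_no_call,
        n_non_lacto_16s=n_non_lacto,
        include_non_lacto=include_non_lacto,
        defined=defined,
    )
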