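"""Relative abundance difference (RAD) statistics for paired longitudinal data.

For one taxon and a pair of time points, the RAD of a participant is the
taxon's relative abundance at the later time point minus that at the earlier
one (positive = the taxon increased).  Per time-point pair the framework
reports the median RAD across pairwise-complete participants with a two-sided
Wilcoxon signed-rank test; the 15 pairwise p values over six time points are
corrected with the Benjamini-Yekutieli step-up procedure, which controls the
false discovery rate under arbitrary dependence.

Between-arm contrasts use the Hodges-Lehmann estimator (median of all
pairwise differences of RAD values between a treatment and a placebo
participant) with a two-sided Wilcoxon rank-sum test, again BY-corrected
over the tested cells.  Cross-sectional arm comparisons at a single time
point use the Kruskal-Wallis test.

Zero differences are dropped from the signed-rank statistic (Wilcoxon's
original convention; ``zero_method="pratt"`` is available).  Exact null
distributions are used for small samples without ties (signed-rank n <= 25;
rank-sum min arm size <= 10), otherwise a normal approximation with
continuity and tie corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TIMEPOINTS, AbundanceTable, StudyDesign
from .errors import UsageError, ValidationError

SIGNED_RANK_EXACT_MAX_N = 25
RANK_SUM_EXACT_MAX_N = 10

CONVENTIONS = ("treatment_minus_placebo", "placebo_minus_treatment")


def _chronological(t1: str, t2: str) -> None:
    if t1 not in TIMEPOINTS or t2 not in TIMEPOINTS:
        raise UsageError(f"unknown timepoint in ({t1!r}, {t2!r})")
    if t1 == t2:
        raise UsageError("timepoints must differ")
    if TIMEPOINTS.index(t1) > TIMEPOINTS.index(t2):
        raise UsageError(f"{t1!r} is not chronologically before {t2!r}")


def _sample_values(
    table: AbundanceTable | None,
    taxon: str | None,
    values: pd.Series | None,
) -> pd.Series:
    """Per-sample scalar series: a taxon row of a relative table, or a
    caller-supplied metric (e.g. log10 qPCR concentrations)."""
    if values is not None:
        return values
    assert table is not None and taxon is not None
    if table.mode != "relative":
        raise ValidationError("RAD statistics require a relative table")
    if taxon not in table.values.index:
        raise ValidationError(f"taxon {taxon!r} not present in table")
    return table.values.loc[taxon]


def compute_rads(
    table: AbundanceTable | None,
    design: StudyDesign,
    taxon: str | None,
    t1: str,
    t2: str,
    arm: str | None = None,
    values: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-participant RAD between two time points (pairwise-complete).

    Returns a DataFrame with columns ``participant_id``, ``arm``, ``rad``;
    one row per participant having samples at both time points (and in
    ``arm``, if given).  A taxon absent from both samples yields rad 0 and is
    retained: zero change is informative.
    """
    _chronological(t1, t2)
    series = _sample_values(table, taxon, values)
    pairs = design.paired_samples(t1, t2)
    if arm is not None:
        pairs = pairs[pairs["arm"] == arm]
    rows = []
    for _, row in pairs.iterrows():
        if row["sample1"] not in series.index or row["sample2"] not in series.index:
            continue
        rad = float(series[row["sample2"]] - series[row["sample1"]])
        rows.append((row["participant_id"], row["arm"], rad))
    return pd.DataFrame(rows, columns=["participant_id", "arm", "rad"])


def signed_rank_test(diffs, zero_method: str = "wilcox") -> float:
    """Two-sided Wilcoxon signed-rank p value for paired differences.

    Exact when n <= 25 with no ties or zeros; otherwise a normal
    approximation with continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValidationError("no differences to test")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 1.0
    no_ties = len(np.unique(np.abs(nonzero))) == len(nonzero)
    exact = (d == 0).sum() == 0 and no_ties and d.size <= SIGNED_RANK_EXACT_MAX_N
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(
        d, zero_method=zero_method, alternative="two-sided",
        correction=not exact, method=method,
    )
    return float(res.pvalue)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact when the smaller group has <= 10 observations and there are no
    ties; otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([xa, ya])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and min(xa.size, ya.size) <= RANK_SUM_EXACT_MAX_N
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return float(res.pvalue)


def hodges_lehmann(x, y) -> float:
    """Median of all pairwise differences x_i - y_j.

    A robust estimate of the location shift between two samples; for an even
    number of pairs the mean of the two central order statistics is returned.
    Translation-equivariant: shifting x by delta shifts the estimate by delta.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValidationError("Hodges-Lehmann estimator needs nonempty inputs")
    return float(np.median(np.subtract.outer(xa, ya)))


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment.

    Adjusted p_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) the m-th harmonic number, mapped back to the input order.  Valid
    under arbitrary dependence among the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class RadMatrix:
    """Median RADs over all ordered time-point pairs for one taxon.

    ``cells`` is a long-format DataFrame with one row per ordered pair
    (t1 before t2): columns ``t1``, ``t2``, ``n``, ``median_rad``, ``p_raw``,
    ``p_adj``, ``tested``.  Positive median_rad means higher abundance at the
    later time point.  BY adjustment spans exactly the tested cells.
    """

    taxon: str
    cells: pd.DataFrame
    arm: str | None = None

    def cell(self, t1: str, t2: str) -> pd.Series:
        sel = self.cells[(self.cells["t1"] == t1) & (self.cells["t2"] == t2)]
        if sel.empty:
            raise UsageError(f"no cell for pair ({t1!r}, {t2!r})")
        return sel.iloc[0]

    def matrix(self, column: str = "median_rad") -> pd.DataFrame:
        """Pivot a column to a time point x time point matrix (upper triangle)."""
        out = pd.DataFrame(np.nan, index=list(TIMEPOINTS), columns=list(TIMEPOINTS))
        for _, row in self.cells.iterrows():
            out.loc[row["t1"], row["t2"]] = row[column]
        return out


def _pair_iter(timepoints=TIMEPOINTS):
    for i, j in itertools.combinations(range(len(timepoints)), 2):
        yield timepoints[i], timepoints[j]


def median_rad_matrix(
    table: AbundanceTable | None,
    design: StudyDesign,
    taxon: str | None,
    arm: str | None = None,
    values: pd.Series | None = None,
    min_pairs: int = 2,
    zero_method: str = "wilcox",
) -> RadMatrix:
    """Median RAD and paired test for each of the 15 ordered time-point pairs.

    Cells with fewer than ``min_pairs`` pairwise-complete participants are
    marked untested (NaN p values) and excluded from the BY family.
    """
    rows = []
    for t1, t2 in _pair_iter():
        rads = compute_rads(table, design, taxon, t1, t2, arm=arm, values=values)
        n = len(rads)
        if n >= min_pairs:
            med = float(np.median(rads["rad"]))
            p = signed_rank_test(rads["rad"].to_numpy(), zero_method=zero_method)
            rows.append((t1, t2, n, med, p, True))
        else:
            rows.append((t1, t2, n, np.nan, np.nan, False))
    cells = pd.DataFrame(
        rows, columns=["t1", "t2", "n", "median_rad", "p_raw", "tested"]
    )
    cells["p_adj"] = np.nan
    tested = cells["tested"].to_numpy()
    if tested.any():
        cells.loc[tested, "p_adj"] = by_adjust(cells.loc[tested, "p_raw"].to_numpy())
    else:
        import logging

        logging.getLogger(__name__).warning(
            "all cells untested for taxon %r", taxon
        )
    return RadMatrix(taxon=taxon or "metric", cells=cells, arm=arm)


@dataclass
class DifferentialRadMatrix:
    """Between-arm RAD contrasts (Hodges-Lehmann) over time-point pairs.

    Swapping ``sign_convention`` negates ``hl_estimate`` and leaves p values
    unchanged.
    """

    taxon: str
    sign_convention: str
    cells: pd.DataFrame

    def cell(self, t1: str, t2: str) -> pd.Series:
        sel = self.cells[(self.cells["t1"] == t1) & (self.cells["t2"] == t2)]
        if sel.empty:
            raise UsageError(f"no cell for pair ({t1!r}, {t2!r})")
        return sel.iloc[0]


def differential_rad_matrix(
    table: AbundanceTable | None,
    design: StudyDesign,
    taxon: str | None,
    convention: str = "treatment_minus_placebo",
    values: pd.Series | None = None,
    min_per_arm: int = 1,
) -> DifferentialRadMatrix:
    """Hodges-Lehmann between-arm RAD difference with rank-sum tests.

    Per cell the estimate is the median over all (treatment, placebo)
    participant pairs of the difference of their RADs, signed per
    ``convention``; significance is a two-sided Wilcoxon rank-sum test of
    the two arms' RAD distributions, BY-corrected over tested cells.
    """
    if convention not in CONVENTIONS:
        raise UsageError(f"unknown sign convention {convention!r}")
    rows = []
    for t1, t2 in _pair_iter():
        rads = compute_rads(table, design, taxon, t1, t2, values=values)
        rt = rads.loc[rads["arm"] == "treatment", "rad"].to_numpy()
        rp = rads.loc[rads["arm"] == "placebo", "rad"].to_numpy()
        if len(rt) >= min_per_arm and len(rp) >= min_per_arm:
            hl = hodges_lehmann(rt, rp)
            if convention == "placebo_minus_treatment":
                hl = -hl
            p = rank_sum_test(rt, rp)
            rows.append((t1, t2, len(rt), len(rp), hl, p, True))
        else:
            rows.append((t1, t2, len(rt), len(rp), np.nan, np.nan, False))
    cells = pd.DataFrame(
        rows,
        columns=["t1", "t2", "n_treatment", "n_placebo", "hl_estimate", "p_raw", "tested"],
    )
    cells["p_adj"] = np.nan
    tested = cells["tested"].to_numpy()
    if tested.any():
        cells.loc[tested, "p_adj"] = by_adjust(cells.loc[tested, "p_raw"].to_numpy())
    return DifferentialRadMatrix(
        taxon=taxon or "metric", sign_convention=convention, cells=cells
    )


def cross_sectional_test(
    table: AbundanceTable | None,
    design: StudyDesign,
    taxon: str | None,
    timepoint: str,
    values: pd.Series | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis comparison of the arms at one time point.

    Returns (H, p) using the tie-corrected chi-square approximation.
    """
    if timepoint not in TIMEPOINTS:
        raise UsageError(f"unknown timepoint {timepoint!r}")
    series = _sample_values(table, taxon, values)
    groups = []
    for arm in ("placebo", "treatment"):
        sel = design.samples[
            (design.samples["arm"] == arm)
            & (design.samples["timepoint"] == timepoint)
        ].index
        vals = [float(series[s]) for s in sel if s in series.index]
        if not vals:
            raise ValidationError(f"no {arm} samples at {timepoint}")
        groups.append(vals)
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
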