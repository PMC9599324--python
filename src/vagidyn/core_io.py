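"""Core containers and TSV I/O for longitudinal microbiome profiling data.

A cohort is represented by three aligned objects: an :class:`AbundanceTable`
(taxon x sample matrix of counts or relative abundances plus taxonomy
annotation), a :class:`StudyDesign` mapping each sample to a participant,
study arm and menstrual-cycle-anchored time point, and an optional
:class:`QpcrPanel` holding species-specific absolute abundance estimates
(CFU/mL) for the four diagnostic vaginal lactobacilli.  All on-disk formats
are plain tab-separated text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, UsageError, ValidationError

#: Canonical time points in chronological order (days 0, 7, 14, 21, 28, 42).
#: V1 and V2 fall just after menstruation.
TIMEPOINTS: tuple[str, ...] = ("V1", "D7", "D14", "D21", "V2", "V3")

TIMEPOINT_DAYS: dict[str, int] = {
    "V1": 0, "D7": 7, "D14": 14, "D21": 21, "V2": 28, "V3": 42,
}

ARMS: tuple[str, str] = ("placebo", "treatment")

#: Sub-genus group labels used for Lactobacillus ASVs.
LACTOBACILLUS_GROUPS: tuple[str, ...] = (
    "L_crispatus_group",
    "L_iners_group",
    "L_gasseri_group",
    "L_jensenii_group",
    "L_pasteurii_group",
)

#: Species quantified by the qPCR panel, keyed as in qpcr.tsv.
QPCR_SPECIES: tuple[str, ...] = ("L_crispatus", "L_iners", "L_gasseri", "L_jensenii")

#: Maps each qPCR species to the 16S sub-genus group it estimates.
QPCR_SPECIES_TO_GROUP: dict[str, str] = {
    "L_crispatus": "L_crispatus_group",
    "L_iners": "L_iners_group",
    "L_gasseri": "L_gasseri_group",
    "L_jensenii": "L_jensenii_group",
}

_REL_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix.

    Parameters
    ----------
    values
        DataFrame indexed by taxon id with one column per sample.  In
        ``counts`` mode entries are nonnegative integers and every sample
        column sum is positive; in ``relative`` mode every column sums to 1
        within 1e-9.
    mode
        Either ``"counts"`` or ``"relative"``.
    taxonomy
        Optional DataFrame indexed by ``asv_id`` with columns ``genus`` and
        ``subgenus_group`` (the latter set only for *Lactobacillus*).
    """

    values: pd.DataFrame
    mode: str = "counts"
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate taxon id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance for taxon {self.values.index[i]!r} in "
                f"sample {self.values.columns[j]!r}"
            )
        if self.mode == "counts":
            if arr.size and not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count for taxon {self.values.index[i]!r} in "
                    f"sample {self.values.columns[j]!r}"
                )
            sums = arr.sum(axis=0)
            if arr.size and (sums <= 0).any():
                bad = self.values.columns[int(np.argmax(sums <= 0))]
                raise ValidationError(f"sample {bad!r} has zero total count")
            self.values = self.values.astype(np.int64)
        else:
            sums = arr.sum(axis=0)
            if arr.size and (np.abs(sums - 1.0) > 1e-6).any():
                bad = self.values.columns[int(np.argmax(np.abs(sums - 1.0) > 1e-6))]
                raise ValidationError(
                    f"sample {bad!r} does not sum to 1 in relative mode"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    def sample(self, sample_id: str) -> pd.Series:
        """Return one sample's abundance vector."""
        return self.values[sample_id]

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.values.copy(),
            self.mode,
            None if self.taxonomy is None else self.taxonomy.copy(),
        )


def _validate_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    if tax.index.has_duplicates:
        dup = tax.index[tax.index.duplicated()][0]
        raise FormatError(f"duplicate asv_id {dup!r} in taxonomy")
    for asv, row in tax.iterrows():
        has_group = isinstance(row["subgenus_group"], str) and row["subgenus_group"]
        if row["genus"] == "Lactobacillus" and not has_group:
            raise ValidationError(f"Lactobacillus ASV {asv!r} lacks a subgenus_group")
        if row["genus"] != "Lactobacillus" and has_group:
            raise ValidationError(
                f"non-Lactobacillus ASV {asv!r} carries subgenus_group "
                f"{row['subgenus_group']!r}"
            )
    return tax


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV with columns asv_id, genus, subgenus_group."""
    tax = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"asv_id", "genus", "subgenus_group"}
    if not required.issubset(tax.columns):
        raise FormatError(f"taxonomy file {path} must have columns {sorted(required)}")
    tax = tax.set_index("asv_id")
    tax["subgenus_group"] = tax["subgenus_group"].replace("", None)
    return _validate_taxonomy(tax)


def read_count_table(
    path: str | Path, taxonomy_path: str | Path | None = None
) -> AbundanceTable:
    """Read a taxon x sample TSV, first column ``taxon_id``, one column per sample.

    An optional leading comment line ``#mode=relative`` declares a
    pre-normalized table; otherwise entries are validated as nonnegative
    integer counts.  Taxa present in the counts but absent from the taxonomy
    are annotated with genus ``"unclassified"``.
    """
    path = Path(path)
    mode = "counts"
    with open(path) as fh:
        first = fh.readline()
        skip = 0
        while first.startswith("#"):
            if first.strip().replace(" ", "") == "#mode=relative":
                mode = "relative"
            skip += 1
            first = fh.readline()
    raw = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    if raw.columns[0] != "taxon_id":
        raise FormatError(f"{path}: first column must be 'taxon_id'")
    raw = raw.set_index("taxon_id")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for taxon, cell in raw[col].items():
            try:
                x = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric entry {cell!r} at taxon {taxon!r}, "
                    f"sample {col!r}"
                ) from None
            if x < 0:
                raise ParseError(
                    f"{path}: negative entry {cell!r} at taxon {taxon!r}, "
                    f"sample {col!r}"
                )
            values.at[taxon, col] = x
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"{path}: taxon id {dup!r} appears on more than one row")
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
        missing = [t for t in values.index if t not in taxonomy.index]
        if missing:
            extra = pd.DataFrame(
                {"genus": "unclassified", "subgenus_group": None}, index=missing
            )
            taxonomy = pd.concat([taxonomy, extra])
    return AbundanceTable(values, mode=mode, taxonomy=taxonomy)


def write_count_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as TSV; relative tables get a ``#mode=relative`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        if table.mode == "relative":
            fh.write("#mode=relative\n")
        out = table.values.copy()
        out.index.name = "taxon_id"
        out.to_csv(fh, sep="\t", float_format="%.17g")


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    out = taxonomy.copy()
    out.index.name = "asv_id"
    out = out.fillna("")
    out.to_csv(path, sep="\t")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to sum to 1.

    Raises
    ------
    UsageError
        If the table is already in relative mode.
    ValidationError
        If any column sums to zero.
    """
    if table.mode == "relative":
        raise UsageError("table already relative")
    sums = table.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total count")
    values = table.values.astype(float) / sums
    return AbundanceTable(values, mode="relative", taxonomy=table.taxonomy)


def aggregate_taxa(table: AbundanceTable, level: str) -> AbundanceTable:
    """Sum ASV rows to ``genus`` or ``subgenus_group`` level.

    *Lactobacillus* ASVs aggregate to their sub-genus group at
    ``subgenus_group`` level and to a single ``"Lactobacillus"`` row at
    ``genus`` level; all other ASVs aggregate to their genus at both levels.
    Column sums are preserved exactly.
    """
    if level not in ("genus", "subgenus_group"):
        raise UsageError(f"unknown aggregation level {level!r}")
    if table.taxonomy is None:
        raise ValidationError("table has no taxonomy annotation")
    labels = []
    for taxon in table.values.index:
        if taxon not in table.taxonomy.index:
            labels.append("unclassified")
            continue
        row = table.taxonomy.loc[taxon]
        if row["genus"] == "Lactobacillus":
            labels.append(row["subgenus_group"] if level == "subgenus_group" else "Lactobacillus")
        else:
            labels.append(row["genus"])
    values = table.values.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    before = table.values.sum(axis=0)
    after = values.sum(axis=0)
    if not np.allclose(before, after, rtol=0, atol=1e-9 * max(1.0, float(before.max()))):
        raise ValidationError("aggregation changed sample totals")  # pragma: no cover
    return AbundanceTable(values, mode=table.mode, taxonomy=None)


@dataclass
class StudyDesign:
    """Sample -> (participant, arm, time point) mapping for the cohort.

    ``samples`` is indexed by sample_id with columns ``participant_id``,
    ``arm``, ``timepoint`` and ``day``.  At most one sample exists per
    participant and time point, and each participant belongs to a single arm.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples
        required = {"participant_id", "arm", "timepoint"}
        if not required.issubset(df.columns):
            raise FormatError(f"metadata must have columns {sorted(required)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        bad_arm = set(df["arm"]) - set(ARMS)
        if bad_arm:
            raise ParseError(f"unknown arm token(s) {sorted(bad_arm)}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ParseError(f"unknown timepoint token(s) {sorted(bad_tp)}")
        dup_pairs = df.duplicated(subset=["participant_id", "timepoint"])
        if dup_pairs.any():
            p, t = df.loc[dup_pairs, ["participant_id", "timepoint"]].iloc[0]
            raise ValidationError(f"participant {p!r} has two samples at {t!r}")
        arms_per = df.groupby("participant_id")["arm"].nunique()
        multi = arms_per[arms_per > 1]
        if len(multi):
            raise ValidationError(
                f"participant {multi.index[0]!r} is assigned to more than one arm"
            )
        if "day" not in df.columns:
            df = df.copy()
            df["day"] = df["timepoint"].map(TIMEPOINT_DAYS)
            self.samples = df
        # lookup caches; samples is treated as immutable after construction
        df = self.samples
        self._arm: dict[str, str] = {}
        self._by_pt: dict[tuple[str, str], str] = {}
        self._participants: list[str] = []
        for sid, row in zip(df.index, df.itertuples(index=False)):
            pid = row.participant_id
            if pid not in self._arm:
                self._arm[pid] = row.arm
                self._participants.append(pid)
            self._by_pt[(pid, row.timepoint)] = sid

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def participants(self) -> list[str]:
        return list(self._participants)

    def arm_of(self, participant_id: str) -> str:
        if participant_id not in self._arm:
            raise ValidationError(f"unknown participant {participant_id!r}")
        return self._arm[participant_id]

    def sample_for(self, participant_id: str, timepoint: str) -> str | None:
        return self._by_pt.get((participant_id, timepoint))

    def samples_of(self, participant_id: str) -> pd.DataFrame:
        """Participant's samples in chronological order."""
        rows = self.samples[self.samples["participant_id"] == participant_id]
        order = {t: i for i, t in enumerate(TIMEPOINTS)}
        return rows.iloc[np.argsort([order[t] for t in rows["timepoint"]], kind="stable")]

    def paired_samples(self, t1: str, t2: str) -> pd.DataFrame:
        """Participants with samples at both time points (pairwise-complete).

        Returns a DataFrame with columns ``participant_id``, ``arm``,
        ``sample1`` and ``sample2``.
        """
        for t in (t1, t2):
            if t not in TIMEPOINTS:
                raise UsageError(f"unknown timepoint {t!r}")
        rows = []
        for pid in self.participants:
            s1 = self.sample_for(pid, t1)
            s2 = self.sample_for(pid, t2)
            if s1 is not None and s2 is not None:
                rows.append((pid, self.arm_of(pid), s1, s2))
        return pd.DataFrame(
            rows, columns=["participant_id", "arm", "sample1", "sample2"]
        )


def read_metadata(path: str | Path) -> StudyDesign:
    """Read a sample metadata TSV (sample_id, participant_id, arm, timepoint, day)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    return StudyDesign(df.set_index("sample_id"))


def write_metadata(design: StudyDesign, path: str | Path) -> None:
    out = design.samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


@dataclass
class QpcrPanel:
    """Per-sample CFU/mL estimates for the four diagnostic lactobacilli.

    ``concentrations`` is indexed by sample_id with one column per species in
    :data:`QPCR_SPECIES`; missing measurements are NaN (explicitly absent,
    never coerced to zero).
    """

    concentrations: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.concentrations
        missing = set(QPCR_SPECIES) - set(df.columns)
        if missing:
            raise FormatError(f"qPCR panel missing species columns {sorted(missing)}")
        arr = df[list(QPCR_SPECIES)].to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("negative qPCR concentration")
        self.concentrations = df[list(QPCR_SPECIES)].astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    def sample(self, sample_id: str) -> pd.Series:
        return self.concentrations.loc[sample_id]


def read_qpcr(path: str | Path) -> QpcrPanel:
    """Read a long-format qPCR TSV (sample_id, taxon, cfu_per_ml).

    ``NA`` or empty concentrations are recorded as absent (NaN), not zero.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "taxon": str},
        na_values=["NA", ""], keep_default_na=True,
    )
    required = {"sample_id", "taxon", "cfu_per_ml"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: qpcr file must have columns {sorted(required)}")
    bad = set(df["taxon"]) - set(QPCR_SPECIES)
    if bad:
        raise ParseError(f"{path}: unknown qPCR taxon token(s) {sorted(bad)}")
    wide = df.pivot(index="sample_id", columns="taxon", values="cfu_per_ml")
    for sp in QPCR_SPECIES:
        if sp not in wide.columns:
            wide[sp] = np.nan
    return QpcrPanel(wide)


def write_qpcr(panel: QpcrPanel, path: str | Path) -> None:
    long = (
        panel.concentrations.reset_index(names="sample_id")
        .melt(id_vars="sample_id", var_name="taxon", value_name="cfu_per_ml")
        .sort_values(["sample_id", "taxon"], kind="stable")
    )
    long.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
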