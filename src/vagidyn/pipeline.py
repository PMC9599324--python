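"""End-to-end orchestration: simulate or load a cohort, type communities,
compute diversity, run the RAD statistics and qPCR concordance, and write a
consolidated report.

Every stage is a pure function of (inputs, config, seed); re-running with
the same configuration reproduces the output bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_typing, diversity_metrics, qpcr_concordance, rad_stats
from .core_io import (
    LACTOBACILLUS_GROUPS,
    AbundanceTable,
    QpcrPanel,
    StudyDesign,
    aggregate_taxa,
    read_count_table,
    read_metadata,
    read_qpcr,
    to_relative,
)
from .errors import ValidationError
from .synthetic_cohort import CohortConfig, CohortResult, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

DEFAULT_RAD_TAXA = (
    "Lactobacillus",
    "L_crispatus_group",
    "L_iners_group",
    "Gardnerella",
    "Prevotella",
    "Streptococcus",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` holds a :class:`CohortConfig`, or the four input
    paths point to existing TSV files.  ``rad_taxa`` may mix genus names and
    *Lactobacillus* sub-genus group labels; each is analysed at the matching
    aggregation level.
    """

    outdir: str | Path = "vagidyn_out"
    simulate: CohortConfig | None = None
    counts_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    metadata_path: str | Path | None = None
    qpcr_path: str | Path | None = None
    rad_taxa: tuple[str, ...] = DEFAULT_RAD_TAXA
    differential_convention: str = "treatment_minus_placebo"
    inclusive_thresholds: bool = False
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.rad_taxa:
            raise ValidationError("rad_taxa must be nonempty")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.simulate is None and (
            self.counts_path is None
            or self.taxonomy_path is None
            or self.metadata_path is None
        ):
            raise ValidationError(
                "either a simulation config or counts/taxonomy/metadata paths are required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "rad_taxa"})
        if "rad_taxa" in raw:
            cfg.rad_taxa = tuple(raw["rad_taxa"])
        if sim is not None:
            cfg.simulate = CohortConfig(**(sim or {}))
        return cfg


def _load_inputs(config: RunConfig) -> tuple[AbundanceTable, StudyDesign, QpcrPanel | None, CohortResult | None]:
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed != config.seed:
            from dataclasses import replace

            sim_cfg = replace(sim_cfg, seed=config.seed)
        result = generate_cohort(sim_cfg)
        return result.counts, result.design, result.qpcr, result
    counts = read_count_table(config.counts_path, config.taxonomy_path)
    design = read_metadata(config.metadata_path)
    qpcr = read_qpcr(config.qpcr_path) if config.qpcr_path else None
    return counts, design, qpcr, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the output bundle; returns the report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    counts, design, qpcr, sim_result = _load_inputs(config)
    if sim_result is not None:
        write_cohort(sim_result, outdir / "simulated")
    logger.info("inputs ready: %d samples (%.2fs)", len(counts.sample_ids), time.perf_counter() - t0)

    rel = to_relative(counts)
    rel_sub = aggregate_taxa(rel, "subgenus_group")
    rel_gen = aggregate_taxa(rel, "genus")

    # --- community typing -------------------------------------------------
    labels = community_typing.classify_cohort(
        rel_sub, design, inclusive_thresholds=config.inclusive_thresholds
    )
    labels_df = pd.DataFrame(
        {
            "sample_id": labels.index,
            "participant_id": design.samples.loc[labels.index, "participant_id"].to_numpy(),
            "timepoint": design.samples.loc[labels.index, "timepoint"].to_numpy(),
            "group": [lab.value for lab in labels],
        }
    )
    labels_df.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    shifts = community_typing.cohort_shift_summaries(labels, design)
    shifts_df = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in shifts],
            "n_transitions": [s.n_transitions for s in shifts],
            "n_deviations_from_majority": [s.n_deviations_from_majority for s in shifts],
            "stable": [s.stable for s in shifts],
        }
    )
    shifts_df.to_csv(outdir / "shifts.tsv", sep="\t", index=False)

    prevalence = community_typing.dominance_prevalence(labels, design, stratify_by_arm=True)
    prevalence_all = community_typing.dominance_prevalence(labels, design, stratify_by_arm=False)
    pd.concat([prevalence_all, prevalence]).to_csv(
        outdir / "prevalence.tsv", sep="\t", index=False
    )

    # --- diversity ---------------------------------------------------------
    alpha_df = diversity_metrics.alpha_diversity(counts)
    alpha_df["bc_to_baseline"] = diversity_metrics.distance_to_baseline(rel, design)
    alpha_df.to_csv(outdir / "diversity.tsv", sep="\t", float_format="%.10g")

    # --- RAD matrices ------------------------------------------------------
    rad_frames = []
    diff_frames = []
    n_sig_rad: dict[str, int] = {}
    n_sig_diff: dict[str, int] = {}
    for taxon in config.rad_taxa:
        table = rel_sub if taxon in LACTOBACILLUS_GROUPS else rel_gen
        if taxon not in table.values.index:
            logger.warning("taxon %r absent; skipped", taxon)
            continue
        rad = rad_stats.median_rad_matrix(table, design, taxon)
        cells = rad.cells.copy()
        cells.insert(0, "taxon", taxon)
        rad_frames.append(cells)
        n_sig_rad[taxon] = int(
            (cells["tested"] & (cells["p_adj"] < config.alpha)).sum()
        )
        diff = rad_stats.differential_rad_matrix(
            table, design, taxon, convention=config.differential_convention
        )
        dcells = diff.cells.copy()
        dcells.insert(0, "taxon", taxon)
        diff_frames.append(dcells)
        n_sig_diff[taxon] = int(
            (dcells["tested"] & (dcells["p_adj"] < config.alpha)).sum()
        )
    if rad_frames:
        pd.concat(rad_frames).to_csv(
            outdir / "rad_matrices.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.concat(diff_frames).to_csv(
            outdir / "rad_differential.tsv", sep="\t", index=False, float_format="%.10g"
        )

    # --- qPCR concordance --------------------------------------------------
    concordance_report = None
    if qpcr is not None:
        shared = [s for s in labels.index if s in qpcr.sample_ids]
        preds = qpcr_concordance.predict_cohort(
            QpcrPanel(qpcr.concentrations.loc[shared])
        )
        concordance_report = qpcr_concordance.concordance(labels.loc[shared], preds)
        conf = concordance_report.confusion.copy()
        conf.index.name = "group_16s"
        conf.to_csv(outdir / "concordance.tsv", sep="\t")

    # --- report ------------------------------------------------------------
    pct = community_typing.percent_rounded
    n_participants = len(shifts)
    n_stable = sum(1 for s in shifts if s.stable)
    transition_counts = {
        "0": sum(1 for s in shifts if s.n_transitions == 0),
        "1": sum(1 for s in shifts if s.n_transitions == 1),
        "2": sum(1 for s in shifts if s.n_transitions == 2),
        "3+": sum(1 for s in shifts if s.n_transitions >= 3),
    }
    deviation_counts = {
        "0": sum(1 for s in shifts if s.n_deviations_from_majority == 0),
        "1": sum(1 for s in shifts if s.n_deviations_from_majority == 1),
        "2": sum(1 for s in shifts if s.n_deviations_from_majority == 2),
        "3+": sum(1 for s in shifts if s.n_deviations_from_majority >= 3),
    }
    report = {
        "n_samples": int(len(labels)),
        "n_participants": n_participants,
        "stable_fraction": n_stable / n_participants,
        "stable_percent": pct(n_stable, n_participants),
        "shift_transition_counts": transition_counts,
        "shift_transition_percent": {
            k: pct(v, n_participants) for k, v in transition_counts.items()
        },
        "shift_deviation_counts": deviation_counts,
        "dominance_prevalence_percent_by_arm": {
            arm: {
                row["group"]: row["percent"]
                for _, row in prevalence[prevalence["stratum"] == arm].iterrows()
            }
            for arm in ("placebo", "treatment")
        },
        "significant_rad_cells": n_sig_rad,
        "significant_differential_cells": n_sig_diff,
        "alpha": config.alpha,
        "seed": config.seed,
    }
    if concordance_report is not None and concordance_report.defined:
        report["qpcr_concordance"] = {
            "n_samples": concordance_report.n_samples,
            "n_agree": concordance_report.n_agree,
            "agreement_percent": pct(
                concordance_report.n_agree, concordance_report.n_samples
            ),
            "n_no_call": concordance_report.n_no_call,
            "n_non_lacto_16s": concordance_report.n_non_lacto_16s,
        }
    if sim_result is not None:
        truth_labels = sim_result.truth.dominance_labels(config.inclusive_thresholds)
        truth_shifts = community_typing.cohort_shift_summaries(truth_labels, design)
        n_truth_stable = sum(1 for s in truth_shifts if s.stable)
        report["truth_stable_fraction"] = n_truth_stable / len(truth_shifts)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return report
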