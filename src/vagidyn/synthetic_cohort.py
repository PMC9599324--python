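"""Synthetic longitudinal vaginal-microbiome cohorts.

Generates counts, metadata and qPCR tables with the statistical structure the
downstream analyses assume: a two-arm cohort (18 placebo / 34 treatment by
default) sampled at six menstrual-cycle-anchored time points (V1, D7, D14,
D21, V2, V3; V1 and V2 just after menstruation), participants drawn from
five community archetypes (crispatus-dominated, iners-dominated,
crispatus+iners codominant, other-*Lactobacillus* dominated, and a diverse
non-*Lactobacillus* profile), Dirichlet within-participant compositional
noise, additive logit-scale perturbations (a post-menstrual *L. crispatus*
drop with a pathobiont rise at V1/V2, and optional treatment effects),
multinomial read sampling, independent sample missingness, and lognormal
qPCR concentrations proportional to the latent species abundances.

Each participant owns an RNG stream derived from (seed, participant index),
so changing the cohort size or deleting a participant never perturbs the
draws of the others.  The latent compositions and archetypes are returned as
ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import community_typing
from .core_io import (
    ARMS,
    LACTOBACILLUS_GROUPS,
    QPCR_SPECIES,
    QPCR_SPECIES_TO_GROUP,
    TIMEPOINT_DAYS,
    TIMEPOINTS,
    AbundanceTable,
    QpcrPanel,
    StudyDesign,
)
from .errors import ValidationError

#: Group-level taxa of the synthetic community (sub-genus groups for
#: lactobacilli, genera otherwise, plus an unclassified residual).
GROUP_TAXA: tuple[str, ...] = LACTOBACILLUS_GROUPS + (
    "Gardnerella",
    "Prevotella",
    "Streptococcus",
    "Bifidobacterium",
    "unclassified",
)

_PATHOBIONT_TAXA = ("Gardnerella", "Streptococcus")

#: ASV registry: (asv_id, genus, subgenus_group, weight within its group).
ASV_DEFS: tuple[tuple[str, str, str | None, float], ...] = (
    ("Lactobacillus_ASV_2", "Lactobacillus", "L_crispatus_group", 0.6),
    ("Lactobacillus_ASV_4", "Lactobacillus", "L_crispatus_group", 0.3),
    ("Lactobacillus_ASV_6", "Lactobacillus", "L_crispatus_group", 0.1),
    ("Lactobacillus_ASV_1", "Lactobacillus", "L_iners_group", 1.0),
    ("Lactobacillus_ASV_3", "Lactobacillus", "L_gasseri_group", 1.0),
    ("Lactobacillus_ASV_5", "Lactobacillus", "L_jensenii_group", 1.0),
    ("Lactobacillus_ASV_7", "Lactobacillus", "L_pasteurii_group", 1.0),
    ("Gardnerella_ASV_1", "Gardnerella", None, 0.7),
    ("Gardnerella_ASV_2", "Gardnerella", None, 0.3),
    ("Prevotella_ASV_1", "Prevotella", None, 0.6),
    ("Prevotella_ASV_2", "Prevotella", None, 0.4),
    ("Streptococcus_ASV_1", "Streptococcus", None, 1.0),
    ("Bifidobacterium_ASV_1", "Bifidobacterium", None, 1.0),
    ("residual_ASV_1", "unclassified", None, 1.0),
)


def default_taxonomy() -> pd.DataFrame:
    """Taxonomy annotation table for the synthetic ASV universe."""
    return pd.DataFrame(
        {
            "genus": [g for _, g, _, _ in ASV_DEFS],
            "subgenus_group": [sg for _, _, sg, _ in ASV_DEFS],
        },
        index=pd.Index([a for a, _, _, _ in ASV_DEFS], name="asv_id"),
    )


@dataclass(frozen=True)
class ArchetypeSpec:
    """A community archetype: mean composition plus Dirichlet tightness."""

    name: str
    base_composition: dict[str, float]
    dirichlet_concentration: float

    def __post_init__(self) -> None:
        vals = np.array(list(self.base_composition.values()), dtype=float)
        if (vals < 0).any() or not math.isclose(float(vals.sum()), 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"archetype {self.name!r}: composition must be nonnegative and sum to 1"
            )
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be positive")


def _comp(**kw: float) -> dict[str, float]:
    base = {t: 0.0 for t in GROUP_TAXA}
    base.update(kw)
    return base


DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "crispatus_dominated": ArchetypeSpec(
        "crispatus_dominated",
        _comp(
            L_crispatus_group=0.78, L_iners_group=0.04, L_gasseri_group=0.01,
            L_jensenii_group=0.01, L_pasteurii_group=0.005, Gardnerella=0.02,
            Prevotella=0.02, Streptococcus=0.02, Bifidobacterium=0.02,
            unclassified=0.075,
        ),
        150.0,
    ),
    "iners_dominated": ArchetypeSpec(
        "iners_dominated",
        _comp(
            L_iners_group=0.78, L_crispatus_group=0.04, L_gasseri_group=0.01,
            L_jensenii_group=0.01, L_pasteurii_group=0.005, Gardnerella=0.02,
            Prevotella=0.02, Streptococcus=0.02, Bifidobacterium=0.02,
            unclassified=0.075,
        ),
        150.0,
    ),
    "crispatus_iners_codominant": ArchetypeSpec(
        "crispatus_iners_codominant",
        _comp(
            L_crispatus_group=0.37, L_iners_group=0.40, L_gasseri_group=0.01,
            L_jensenii_group=0.01, L_pasteurii_group=0.005, Gardnerella=0.035,
            Prevotella=0.04, Streptococcus=0.04, Bifidobacterium=0.04,
            unclassified=0.05,
        ),
        120.0,
    ),
    "other_lactobacillus_dominated": ArchetypeSpec(
        "other_lactobacillus_dominated",
        _comp(
            L_gasseri_group=0.60, L_jensenii_group=0.08, L_pasteurii_group=0.02,
            L_crispatus_group=0.08, L_iners_group=0.08, Gardnerella=0.03,
            Prevotella=0.03, Streptococcus=0.03, Bifidobacterium=0.03,
            unclassified=0.02,
        ),
        150.0,
    ),
    "non_lactobacillus_diverse": ArchetypeSpec(
        "non_lactobacillus_diverse",
        _comp(
            L_crispatus_group=0.05, L_iners_group=0.10, L_gasseri_group=0.02,
            L_jensenii_group=0.01, L_pasteurii_group=0.005, Gardnerella=0.22,
            Prevotella=0.22, Streptococcus=0.14, Bifidobacterium=0.14,
            unclassified=0.095,
        ),
        60.0,
    ),
}

#: Baseline archetype frequencies: 15 crispatus-only, 15 iners-only,
#: 12 codominant, 3 other-Lactobacillus, 7 non-Lactobacillus out of 52.
DEFAULT_ARCHETYPE_PROBABILITIES: dict[str, float] = {
    "crispatus_dominated": 15 / 52,
    "iners_dominated": 15 / 52,
    "crispatus_iners_codominant": 12 / 52,
    "other_lactobacillus_dominated": 3 / 52,
    "non_lactobacillus_diverse": 7 / 52,
}


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Effects act on the logit scale so perturbed compositions stay in the
    simplex: the menses effects apply at V1 and V2 only (a negative shift to
    the *L. crispatus* group, a positive shift to Gardnerella and
    Streptococcus), the treatment effects apply in the treatment arm at every
    post-baseline time point (D7 onward).  qPCR concentrations are
    total load x latent species abundance x lognormal noise.
    """

    n_placebo: int = 18
    n_treatment: int = 34
    timepoints: tuple[str, ...] = TIMEPOINTS
    archetypes: dict[str, ArchetypeSpec] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    archetype_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_PROBABILITIES)
    )
    menses_effect_crispatus: float = -0.6
    menses_effect_pathobiont: float = 0.5
    treatment_effect_lactobacillus: float = 0.0
    treatment_effect_prevotella: float = 0.0
    arm_archetype_bias: float = 0.0
    read_depth: int = 10_000
    missing_rate: float = 11 / 312
    total_load_log10_mean: float = 9.8
    total_load_log10_sd: float = 0.4
    qpcr_noise_log10_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_placebo + self.n_treatment < 2:
            raise ValidationError("cohort needs at least two participants")
        if self.read_depth < 100:
            raise ValidationError("read_depth must be >= 100")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.menses_effect_crispatus > 0:
            raise ValidationError("menses_effect_crispatus must be <= 0")
        if self.menses_effect_pathobiont < 0:
            raise ValidationError("menses_effect_pathobiont must be >= 0")
        probs = np.array(list(self.archetype_probabilities.values()), dtype=float)
        if (probs < 0).any() or not math.isclose(float(probs.sum()), 1.0, abs_tol=1e-9):
            raise ValidationError("archetype probabilities must sum to 1")
        unknown = set(self.archetype_probabilities) - set(self.archetypes)
        if unknown:
            raise ValidationError(f"unknown archetype(s) {sorted(unknown)}")
        for t in self.timepoints:
            if t not in TIMEPOINTS:
                raise ValidationError(f"unknown timepoint {t!r}")


@dataclass
class CohortTruth:
    """Latent per-sample compositions and per-participant archetypes."""

    latent_compositions: pd.DataFrame  # group taxa x retained samples
    archetypes: pd.Series  # participant -> archetype name

    def dominance_labels(self, inclusive_thresholds: bool = False) -> pd.Series:
        """Classify the latent (noise-free of sequencing) compositions."""
        labels = {
            sid: community_typing.classify_sample(
                self.latent_compositions[sid], inclusive_thresholds
            )
            for sid in self.latent_compositions.columns
        }
        return pd.Series(labels, name="group")


@dataclass
class CohortResult:
    counts: AbundanceTable
    design: StudyDesign
    qpcr: QpcrPanel
    truth: CohortTruth


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _shift_mass_arr(comp: np.ndarray, idx: np.ndarray, delta: float) -> np.ndarray:
    """Logit-shift the combined mass of the taxa at ``idx``; rescale the rest."""
    p = float(comp[idx].sum())
    if not 0.0 < p < 1.0:
        raise ValidationError("target mass must lie strictly in (0, 1)")
    p_new = _logistic(_logit(p) + delta)
    out = comp * ((1.0 - p_new) / (1.0 - p))
    out[idx] = comp[idx] * (p_new / p)
    return out


def _shift_mass(comp: pd.Series, taxa: list[str], delta: float) -> pd.Series:
    """Logit-shift the combined mass of ``taxa``; rescale the rest to fill."""
    idx = np.array([comp.index.get_loc(t) for t in taxa], dtype=int)
    return pd.Series(
        _shift_mass_arr(comp.to_numpy(dtype=float), idx, delta), index=comp.index
    )


def apply_logit_shift(composition: pd.Series, taxon: str, delta: float) -> pd.Series:
    """Shift one taxon's abundance p to logistic(logit(p) + delta).

    The remaining taxa are rescaled proportionally so the output sums to 1.
    """
    if taxon not in composition.index:
        raise ValidationError(f"taxon {taxon!r} absent from composition")
    if not math.isclose(float(composition.sum()), 1.0, abs_tol=1e-6):
        raise ValidationError("composition must sum to 1")
    return _shift_mass(composition, [taxon], delta)


def _arm_biased_probs(
    probs: dict[str, float], arm: str, bias: float
) -> dict[str, float]:
    """Move probability mass between the crispatus and iners archetypes.

    Positive bias makes crispatus dominance more likely in the placebo arm
    and iners dominance more likely in the treatment arm, emulating an
    imbalanced randomization.
    """
    if bias == 0.0:
        return probs
    out = dict(probs)
    shift = bias if arm == "placebo" else -bias
    c = out.get("crispatus_dominated", 0.0)
    i = out.get("iners_dominated", 0.0)
    shift = max(-c, min(i, shift))
    out["crispatus_dominated"] = c + shift
    out["iners_dominated"] = i - shift
    return out


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Draw one synthetic cohort; same config and seed give identical output."""
    config.validate()
    names = sorted(config.archetype_probabilities)
    asv_ids = [a for a, _, _, _ in ASV_DEFS]
    asv_groups = [(sg if sg is not None else g) for _, g, sg, _ in ASV_DEFS]
    asv_weights = np.array([w for _, _, _, w in ASV_DEFS], dtype=float)
    group_index = {g: i for i, g in enumerate(GROUP_TAXA)}
    asv_group_idx = np.array([group_index[g] for g in asv_groups], dtype=int)
    crisp_idx = np.array([group_index["L_crispatus_group"]])
    patho_idx = [np.array([group_index[t]]) for t in _PATHOBIONT_TAXA]
    lacto_idx = np.array([group_index[t] for t in LACTOBACILLUS_GROUPS])
    prevotella_idx = np.array([group_index["Prevotella"]])
    qpcr_group_idx = {
        sp: group_index[g] for sp, g in QPCR_SPECIES_TO_GROUP.items()
    }

    n_total = config.n_placebo + config.n_treatment

    count_cols: dict[str, np.ndarray] = {}
    latent_cols: dict[str, pd.Series] = {}
    meta_rows: list[tuple[str, str, str, str, int]] = []
    qpcr_rows: dict[str, dict[str, float]] = {}
    archetypes: dict[str, str] = {}

    for idx in range(n_total):
        pid = f"P{idx + 1:03d}"
        arm = "placebo" if idx < config.n_placebo else "treatment"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx]))

        probs = _arm_biased_probs(
            config.archetype_probabilities, arm, config.arm_archetype_bias
        )
        pvec = np.array([probs[n] for n in names], dtype=float)
        arch_name = names[int(rng.choice(len(names), p=pvec / pvec.sum()))]
        arch = config.archetypes[arch_name]
        archetypes[pid] = arch_name

        base = np.array([arch.base_composition[t] for t in GROUP_TAXA], dtype=float)
        conc = arch.dirichlet_concentration
        participant_base = rng.dirichlet(conc * base + 1e-3)

        samples: dict[str, tuple[np.ndarray, np.ndarray, dict[str, float]]] = {}
        for tp in config.timepoints:
            comp = rng.dirichlet(conc * participant_base + 1e-3)
            # at very low concentrations a draw can underflow to exactly 0,
            # which the logit-scale effects cannot handle
            comp = np.maximum(comp, 1e-12)
            comp /= comp.sum()
            if tp in ("V1", "V2"):
                if config.menses_effect_crispatus != 0.0:
                    comp = _shift_mass_arr(
                        comp, crisp_idx, config.menses_effect_crispatus
                    )
                if config.menses_effect_pathobiont != 0.0:
                    for idx_arr in patho_idx:
                        comp = _shift_mass_arr(
                            comp, idx_arr, config.menses_effect_pathobiont
                        )
            if arm == "treatment" and tp != "V1":
                if config.treatment_effect_lactobacillus != 0.0:
                    comp = _shift_mass_arr(
                        comp, lacto_idx, config.treatment_effect_lactobacillus
                    )
                if config.treatment_effect_prevotella != 0.0:
                    comp = _shift_mass_arr(
                        comp, prevotella_idx, config.treatment_effect_prevotella
                    )
            comp = comp / comp.sum()

            asv_probs = comp[asv_group_idx] * asv_weights
            asv_probs /= asv_probs.sum()
            counts = rng.multinomial(config.read_depth, asv_probs)

            load = 10.0 ** rng.normal(
                config.total_load_log10_mean, config.total_load_log10_sd
            )
            qpcr = {
                sp: float(
                    load
                    * comp[qpcr_group_idx[sp]]
                    * 10.0 ** rng.normal(0.0, config.qpcr_noise_log10_sd)
                )
                for sp in QPCR_SPECIES
            }
            samples[tp] = (comp, counts, qpcr)

        # Independent missingness; a participant never loses their whole series.
        n_tp = len(config.timepoints)
        missing = rng.random(n_tp) < config.missing_rate
        while missing.all():
            missing = rng.random(n_tp) < config.missing_rate
        for tp, drop in zip(config.timepoints, missing):
            if drop:
                continue
            sid = f"{pid}_{tp}"
            comp, counts, qpcr = samples[tp]
            count_cols[sid] = counts
            latent_cols[sid] = comp
            qpcr_rows[sid] = qpcr
            meta_rows.append((sid, pid, arm, tp, TIMEPOINT_DAYS[tp]))

    counts_df = pd.DataFrame(
        count_cols, index=pd.Index(asv_ids, name="taxon_id")
    )
    table = AbundanceTable(counts_df, mode="counts", taxonomy=default_taxonomy())
    design = StudyDesign(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "participant_id", "arm", "timepoint", "day"],
        ).set_index("sample_id")
    )
    qpcr_panel = QpcrPanel(pd.DataFrame(qpcr_rows).T.rename_axis("sample_id"))
    truth = CohortTruth(
        latent_compositions=pd.DataFrame(latent_cols, index=list(GROUP_TAXA)),
        archetypes=pd.Series(archetypes, name="archetype"),
    )
    return CohortResult(counts=table, design=design, qpcr=qpcr_panel, truth=truth)


def write_cohort(result: CohortResult, outdir) -> None:
    """Write counts.tsv, taxonomy.tsv, metadata.tsv, qpcr.tsv and truth.tsv."""
    from pathlib import Path

    from .core_io import write_count_table, write_metadata, write_qpcr, write_taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(result.counts, outdir / "counts.tsv")
    write_taxonomy(result.counts.taxonomy, outdir / "taxonomy.tsv")
    write_metadata(result.design, outdir / "metadata.tsv")
    write_qpcr(result.qpcr, outdir / "qpcr.tsv")
    truth_long = (
        result.truth.latent_compositions.rename_axis("taxon")
        .reset_index()
        .melt(id_vars="taxon", var_name="sample_id", value_name="latent_abundance")
    )
    truth_long["archetype"] = truth_long["sample_id"].map(
        lambda s: result.truth.archetypes[s.rsplit("_", 1)[0]]
    )
    truth_long.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.17g")
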