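"""Synthetic multi-site cohort generator.

Emulates a genetic-FTD family cohort: non-carrier controls and C9orf72 / GRN
/ MAPT mutation carriers staged presymptomatic (CDR®+NACC-FTLD global 0 or
0.5) or fully symptomatic (global >= 1), scanned on five 3T scanner types.
Regional measures follow a per-ROI linear model in age, sex, TIV and scanner
with Gaussian residual noise; carrier abnormality is injected as a shift in
control-residual SD units, so the mean w-score of a generated group is known
by construction. Follow-up clinical scores move by an additive Gaussian
change whose mean depends on (gene, scale, baseline abnormality status),
which is the structure the progression analysis is designed to detect.

The generator draws ROI residuals independently given the shared covariates;
real regional measures are spatially correlated beyond that, which this
module does not attempt to model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rois import (FA, MD, MODALITIES, REGISTRY, VOLUME, _SUBFIELDS,
                   validate_roi_modality)

logger = logging.getLogger(__name__)

GENES = ("C9orf72", "GRN", "MAPT")
STAGES = ("presymptomatic", "symptomatic")
SCANNERS = ("SiemensTrio", "SiemensSkyra", "SiemensPrisma",
            "PhilipsAchieva", "GEDiscoveryMR750")
SCALES = ("cdr_sb", "cbir")
CBIR_MAX = 180.0

PARTICIPANT_COLUMNS = ["participant_id", "group", "stage", "age_years", "sex",
                       "tiv_mm3", "scanner", "visit", "cdr_global", "cdr_sb",
                       "cbir"]
MEASURE_COLUMNS = ["participant_id", "roi", "modality", "value"]


class SpecValidationError(ValueError):
    """A cohort/progression spec field failed validation."""


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Demographics of one cohort cell (controls or a gene x stage group)."""

    n: int
    age_mean: float
    age_sd: float
    prop_male: float

    def validate(self, name: str) -> None:
        if self.n < 0:
            raise SpecValidationError(f"{name}.n must be >= 0, got {self.n}")
        if self.age_sd <= 0:
            raise SpecValidationError(f"{name}.age_sd must be > 0, got {self.age_sd}")
        if not 0.0 <= self.prop_male <= 1.0:
            raise SpecValidationError(
                f"{name}.prop_male must be in [0, 1], got {self.prop_male}")


@dataclass(frozen=True)
class CohortSpec:
    """Sample sizes and covariate distributions for a full synthetic cohort.

    ``carriers`` maps (gene, stage) to a :class:`GroupSpec`. TIV is shared
    across groups; scanners are assigned i.i.d. from ``scanner_probs``.
    """

    controls: GroupSpec
    carriers: dict[tuple[str, str], GroupSpec]
    tiv_mean: float = 1_450_000.0
    tiv_sd: float = 130_000.0
    scanner_probs: tuple[float, ...] = (0.25, 0.20, 0.20, 0.20, 0.15)
    seed: int = 0

    def validate(self) -> None:
        self.controls.validate("controls")
        for (gene, stage), grp in self.carriers.items():
            if gene not in GENES:
                raise SpecValidationError(f"carriers: unknown gene {gene!r}")
            if stage not in STAGES:
                raise SpecValidationError(f"carriers: unknown stage {stage!r}")
            grp.validate(f"carriers[{gene},{stage}]")
        if self.tiv_sd <= 0:
            raise SpecValidationError(f"tiv_sd must be > 0, got {self.tiv_sd}")
        if len(self.scanner_probs) != len(SCANNERS):
            raise SpecValidationError(
                f"scanner_probs needs {len(SCANNERS)} entries, got {len(self.scanner_probs)}")
        if any(p < 0 for p in self.scanner_probs):
            raise SpecValidationError("scanner_probs must be non-negative")
        if abs(sum(self.scanner_probs) - 1.0) > 1e-9:
            raise SpecValidationError(
                f"scanner_probs must sum to 1, got {sum(self.scanner_probs)}")


def default_genfi_spec() -> CohortSpec:
    """Cohort spec matching the published GENFI demographics.

    240 controls (age 44.8 +/- 12.2 y, 42.9% male) and per-gene
    presymptomatic/symptomatic carrier groups with their printed sample sizes
    and age/sex distributions.
    """
    return CohortSpec(
        controls=GroupSpec(240, 44.8, 12.2, 0.429),
        carriers={
            ("C9orf72", "presymptomatic"): GroupSpec(113, 45.0, 11.5, 0.425),
            ("C9orf72", "symptomatic"): GroupSpec(47, 63.5, 7.4, 0.660),
            ("MAPT", "presymptomatic"): GroupSpec(52, 41.1, 10.6, 0.404),
            ("MAPT", "symptomatic"): GroupSpec(15, 59.2, 9.3, 0.600),
            ("GRN", "presymptomatic"): GroupSpec(130, 46.5, 12.2, 0.369),
            ("GRN", "symptomatic"): GroupSpec(30, 63.3, 8.1, 0.467),
        },
    )


# ---------------------------------------------------------------------------
# Regional generative model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIParams:
    """Control generative model for one (ROI, modality) series.

    value = intercept + beta_age*age + beta_sex*male + beta_tiv*tiv
            + scanner_offset + N(0, sigma).
    """

    intercept: float
    beta_age: float        # measure units per year
    beta_sex: float        # male minus female offset
    beta_tiv: float        # measure units per mm^3 of TIV
    scanner_offsets: tuple[float, ...]  # one per scanner category
    sigma: float           # residual SD, >= 0

    def validate(self, key: tuple[str, str]) -> None:
        if self.sigma < 0:
            raise SpecValidationError(f"sigma for {key} must be >= 0")
        if len(self.scanner_offsets) != len(SCANNERS):
            raise SpecValidationError(
                f"{key}: need {len(SCANNERS)} scanner offsets")


ROIModel = dict[tuple[str, str], ROIParams]

# Field-plausible bilateral whole-structure volumes (mm^3) used as the
# default intercepts; cortical values are composite-region GM volumes.
_PLAUSIBLE_VOLUMES = {
    "orbitofrontal": 26_000.0, "dlpfc": 48_000.0, "vmpfc": 14_000.0,
    "motor": 40_000.0, "insula": 14_000.0, "temporal_pole": 15_000.0,
    "dorsolateral_temporal": 45_000.0, "medial_temporal": 22_000.0,
    "cingulate": 26_000.0, "sensory": 30_000.0, "medial_parietal": 24_000.0,
    "lateral_parietal": 44_000.0, "occipital": 44_000.0,
    "nucleus_accumbens": 900.0, "caudate": 7_000.0, "putamen": 9_500.0,
    "globus_pallidus": 3_300.0, "basal_forebrain": 800.0,
    "amygdala": 3_200.0, "hippocampus": 7_400.0, "thalamus": 14_500.0,
    "hypothalamus": 1_100.0, "whole_brain": 1_100_000.0,
}
# Small nonzero per-scanner additive offsets, as fractions of sigma, so the
# scanner adjustment is actually exercised by default.
_SCANNER_OFFSET_FRACTIONS = (0.0, 0.15, -0.10, 0.20, -0.15)


def _volume_params(intercept: float) -> ROIParams:
    sigma = 0.07 * intercept
    return ROIParams(
        intercept=intercept,
        beta_age=-0.003 * intercept,          # ~0.3%/year ageing atrophy
        beta_sex=0.02 * intercept,
        beta_tiv=0.6 * intercept / 1_450_000.0,
        scanner_offsets=tuple(f * sigma for f in _SCANNER_OFFSET_FRACTIONS),
        sigma=sigma,
    )


def default_roi_model() -> ROIModel:
    """Control generative parameters for every registered (ROI, modality).

    Volumes scale with plausible structure sizes and decline with age; FA
    declines and MD rises slowly with age (MD in mm^2/s, so coefficients are
    tiny in absolute units).
    """
    model: ROIModel = {}
    for name, vol in _PLAUSIBLE_VOLUMES.items():
        model[(name, VOLUME)] = _volume_params(vol)
    for parent, subs in _SUBFIELDS.items():
        per_sub = _PLAUSIBLE_VOLUMES[parent] / len(subs)
        for sub in subs:
            model[(f"{parent}_{sub}", VOLUME)] = _volume_params(per_sub)
    for (name, roi) in REGISTRY.items():
        if FA in roi.modalities:
            sigma = 0.025
            model[(name, FA)] = ROIParams(
                intercept=0.48, beta_age=-8e-4, beta_sex=0.004, beta_tiv=0.0,
                scanner_offsets=tuple(f * sigma for f in _SCANNER_OFFSET_FRACTIONS),
                sigma=sigma)
        if MD in roi.modalities:
            sigma = 3.0e-5  # mm^2/s
            model[(name, MD)] = ROIParams(
                intercept=7.8e-4, beta_age=1.5e-6, beta_sex=-2.0e-6,
                beta_tiv=0.0,
                scanner_offsets=tuple(f * sigma for f in _SCANNER_OFFSET_FRACTIONS),
                sigma=sigma)
    return model


# ---------------------------------------------------------------------------
# Effect maps (gene x stage regional abnormality, in sigma units)
# ---------------------------------------------------------------------------

#: map (ROI, modality) -> signed effect in control-residual SD units
ROIEffectMap = dict[tuple[str, str], float]


def validate_effect_map(effects: ROIEffectMap) -> None:
    """Reject effect maps that reference unregistered (ROI, modality) pairs."""
    offenders = []
    for (roi, modality) in effects:
        try:
            validate_roi_modality(roi, modality)
        except (KeyError, ValueError):
            offenders.append((roi, modality))
    if offenders:
        raise SpecValidationError(
            f"effect map references unknown (ROI, modality) pairs: {offenders}")


def default_effect_maps() -> dict[tuple[str, str], ROIEffectMap]:
    """Qualitative gene x stage abnormality patterns for demonstration runs.

    Signs follow the disease direction (volume and FA shifted down, MD up);
    presymptomatic magnitudes sit around the 10th-percentile cut, symptomatic
    ones well beyond it. These are illustrative defaults for end-to-end runs,
    not estimates of the real cohort's effect sizes.
    """
    maps: dict[tuple[str, str], ROIEffectMap] = {}
    maps[("C9orf72", "presymptomatic")] = {
        ("thalamus", VOLUME): -1.4, ("thalamus_pulvinar", VOLUME): -1.5,
        ("dlpfc", VOLUME): -0.9, ("insula", VOLUME): -0.8,
        ("whole_brain", VOLUME): -0.9,
        ("ss", FA): -0.8, ("ss", MD): 0.8, ("gcc", FA): -0.7,
        ("gcc", MD): 0.7, ("bcc", MD): 0.7, ("ptr", MD): 0.8,
        ("acr", MD): 0.7, ("ec", FA): -0.7,
    }
    maps[("C9orf72", "symptomatic")] = {
        ("thalamus", VOLUME): -2.5, ("dlpfc", VOLUME): -2.2,
        ("insula", VOLUME): -2.2, ("whole_brain", VOLUME): -2.2,
        ("gcc", FA): -2.2, ("acr", FA): -2.0, ("ss", MD): 2.3,
        ("gcc", MD): 2.3, ("bcc", MD): 2.2, ("acr", MD): 2.2,
        ("scr", MD): 2.0, ("cingulum", MD): 2.0, ("ptr", MD): 2.1,
        ("aic", MD): 2.0,
    }
    maps[("MAPT", "presymptomatic")] = {
        ("dorsolateral_temporal", VOLUME): -1.3, ("amygdala", VOLUME): -1.1,
        ("hippocampus", VOLUME): -1.1, ("thalamus", VOLUME): -0.9,
        ("whole_brain", VOLUME): -0.7, ("aic", FA): -0.9,
    }
    maps[("MAPT", "symptomatic")] = {
        ("dorsolateral_temporal", VOLUME): -2.6, ("temporal_pole", VOLUME): -2.6,
        ("medial_temporal", VOLUME): -2.5, ("amygdala", VOLUME): -2.6,
        ("hippocampus", VOLUME): -2.5, ("insula", VOLUME): -2.2,
        ("whole_brain", VOLUME): -1.8,
        ("uf", FA): -2.3, ("uf", MD): 2.3, ("ss", MD): 2.2,
    }
    maps[("GRN", "presymptomatic")] = {
        ("temporal_pole", VOLUME): -1.0,
        ("hippocampus_presubiculum", VOLUME): -1.0,
        ("whole_brain", VOLUME): -0.8,
        ("scr", FA): -0.9, ("uf", MD): 0.9, ("acr", MD): 0.9,
    }
    maps[("GRN", "symptomatic")] = {
        ("dlpfc", VOLUME): -2.6, ("insula", VOLUME): -2.5,
        ("motor", VOLUME): -2.4, ("whole_brain", VOLUME): -2.2,
        ("gcc", FA): -2.3, ("bcc", FA): -2.2, ("cingulum", FA): -2.1,
        ("aic", FA): -2.1, ("acr", FA): -2.2,
        ("gcc", MD): 2.5, ("ec", MD): 2.4, ("acr", MD): 2.3,
        ("slf", MD): 2.2, ("uf", MD): 2.2,
    }
    for m in maps.values():
        validate_effect_map(m)
    return maps


# ---------------------------------------------------------------------------
# Participant & measure generation
# ---------------------------------------------------------------------------

def _draw_covariates(rng: np.random.Generator, grp: GroupSpec,
                     spec: CohortSpec) -> dict[str, np.ndarray]:
    n = grp.n
    return {
        "age_years": rng.normal(grp.age_mean, grp.age_sd, n),
        "sex": np.where(rng.random(n) < grp.prop_male, "male", "female"),
        "tiv_mm3": rng.normal(spec.tiv_mean, spec.tiv_sd, n),
        "scanner": rng.choice(SCANNERS, size=n, p=np.asarray(spec.scanner_probs)),
    }


def _clamp(values: np.ndarray, modality: str, roi: str) -> np.ndarray:
    """Enforce physical ranges; clamping is logged, never silent."""
    if modality == VOLUME:
        lo, hi = 0.0, np.inf
    elif modality == FA:
        lo, hi = 0.0, 1.0
    else:  # MD strictly positive
        lo, hi = np.finfo(float).tiny, np.inf
    n_clamped = int(np.sum((values < lo) | (values > hi)))
    if n_clamped:
        logger.warning("clamped %d %s/%s values to [%g, %g]",
                       n_clamped, roi, modality, lo, hi)
    return np.clip(values, lo, hi)


def _generate_measures(rng: np.random.Generator, ids: np.ndarray,
                       cov: dict[str, np.ndarray], roi_model: ROIModel,
                       effects: ROIEffectMap | None) -> pd.DataFrame:
    male = (cov["sex"] == "male").astype(float)
    idx_map = {s: i for i, s in enumerate(SCANNERS)}
    scanner_idx = np.array([idx_map[s] for s in cov["scanner"]])
    frames = []
    for (roi, modality), p in sorted(roi_model.items()):
        offsets = np.asarray(p.scanner_offsets)[scanner_idx]
        mean = (p.intercept + p.beta_age * cov["age_years"]
                + p.beta_sex * male + p.beta_tiv * cov["tiv_mm3"] + offsets)
        if effects:
            mean = mean + effects.get((roi, modality), 0.0) * p.sigma
        values = mean + rng.normal(0.0, p.sigma, len(ids)) if p.sigma > 0 else mean
        frames.append(pd.DataFrame({
            "participant_id": ids, "roi": roi, "modality": modality,
            "value": _clamp(values, modality, roi)}))
    return pd.concat(frames, ignore_index=True)


def _clinical_baseline(rng: np.random.Generator, n: int, gene: str | None,
                       stage: str | None) -> dict[str, np.ndarray]:
    """Baseline CDR global / sum-of-boxes / CBI-R by group membership."""
    if gene is None:  # controls
        return {"cdr_global": np.zeros(n),
                "cdr_sb": np.zeros(n),
                "cbir": np.maximum(rng.normal(1.0, 2.0, n), 0.0)}
    if stage == "presymptomatic":
        cdr_global = rng.choice([0.0, 0.5], size=n, p=[0.7, 0.3])
        cdr_sb = np.maximum(rng.normal(0.2, 0.5, n), 0.0)
        cdr_sb = np.where(cdr_global == 0.0, 0.0, np.maximum(cdr_sb, 0.5))
        cbir_mean = {"C9orf72": 9.0, "MAPT": 6.8, "GRN": 5.2}[gene]
        cbir_sd = {"C9orf72": 9.5, "MAPT": 7.8, "GRN": 8.5}[gene]
        cbir = np.clip(rng.normal(cbir_mean, cbir_sd, n), 0.0, CBIR_MAX)
    else:
        cdr_global = rng.choice([1.0, 2.0, 3.0], size=n, p=[0.6, 0.3, 0.1])
        cdr_sb = np.maximum(rng.normal(6.0, 3.0, n), cdr_global)
        cbir = np.clip(rng.normal(50.0, 25.0, n), 0.0, CBIR_MAX)
    return {"cdr_global": cdr_global, "cdr_sb": cdr_sb, "cbir": cbir}


def _assemble_participants(ids, group, stage, cov, clin) -> pd.DataFrame:
    return pd.DataFrame({
        "participant_id": ids, "group": group, "stage": stage,
        "age_years": cov["age_years"], "sex": cov["sex"],
        "tiv_mm3": cov["tiv_mm3"], "scanner": cov["scanner"],
        "visit": "baseline", "cdr_global": clin["cdr_global"],
        "cdr_sb": clin["cdr_sb"], "cbir": clin["cbir"],
    })[PARTICIPANT_COLUMNS]


def generate_controls(spec: CohortSpec, roi_model: ROIModel | None = None,
                      seed: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the control participant and measure tables.

    Deterministic given (spec, seed); ``seed`` defaults to ``spec.seed``.
    Returns (participants, measures) in the documented long CSV schemas.
    """
    spec.validate()
    roi_model = roi_model if roi_model is not None else default_roi_model()
    for key, params in roi_model.items():
        params.validate(key)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.controls.n
    ids = np.array([f"CTRL{i:04d}" for i in range(1, n + 1)])
    cov = _draw_covariates(rng, spec.controls, spec)
    clin = _clinical_baseline(rng, n, None, None)
    participants = _assemble_participants(ids, "control", "control", cov, clin)
    measures = _generate_measures(rng, ids, cov, roi_model, None)
    return participants, measures


def generate_carriers(spec: CohortSpec, roi_model: ROIModel | None = None,
                      effects: dict[tuple[str, str], ROIEffectMap] | None = None,
                      seed: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate carrier tables for every (gene, stage) cell in the spec.

    ``effects`` maps (gene, stage) to an ROI effect map in control-residual
    SD units; a generated effect of -1.5 in an ROI yields a population mean
    w-score of -1.5 there by construction. Missing cells mean no shift.
    """
    spec.validate()
    roi_model = roi_model if roi_model is not None else default_roi_model()
    for key, params in roi_model.items():
        params.validate(key)
    effects = effects or {}
    for m in effects.values():
        validate_effect_map(m)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    part_frames, meas_frames = [], []
    for (gene, stage) in sorted(spec.carriers):
        grp = spec.carriers[(gene, stage)]
        if grp.n == 0:
            continue
        tag = "P" if stage == "presymptomatic" else "S"
        ids = np.array([f"{gene}_{tag}{i:04d}" for i in range(1, grp.n + 1)])
        cov = _draw_covariates(rng, grp, spec)
        clin = _clinical_baseline(rng, grp.n, gene, stage)
        part_frames.append(_assemble_participants(ids, gene, stage, cov, clin))
        meas_frames.append(_generate_measures(rng, ids, cov, roi_model,
                                              effects.get((gene, stage))))
    if not part_frames:
        return (pd.DataFrame(columns=PARTICIPANT_COLUMNS),
                pd.DataFrame(columns=MEASURE_COLUMNS))
    return (pd.concat(part_frames, ignore_index=True),
            pd.concat(meas_frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Longitudinal follow-up
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgressionSpec:
    """Generative model for 12-month clinical change.

    ``cells`` maps (gene, scale, abnormality status) to (mean change, noise
    SD) in scale points; ``availability`` is the probability a baseline
    participant returns for the month-12 visit.
    """

    cells: dict[tuple[str, str, str], tuple[float, float]]
    availability: float = 0.8

    def validate(self) -> None:
        if not 0.0 <= self.availability <= 1.0:
            raise SpecValidationError(
                f"availability must be in [0, 1], got {self.availability}")
        for key, (mean, sd) in self.cells.items():
            gene, scale, status = key
            if gene not in GENES:
                raise SpecValidationError(f"cells: unknown gene {gene!r}")
            if scale not in SCALES:
                raise SpecValidationError(f"cells: unknown scale {scale!r}")
            if status not in ("normal", "abnormal"):
                raise SpecValidationError(f"cells: unknown status {status!r}")
            if sd < 0:
                raise SpecValidationError(f"cells[{key}]: noise SD must be >= 0")


def default_progression_spec() -> ProgressionSpec:
    """Follow-up change model with magnitudes typical of reported findings.

    Abnormal-at-baseline strata progress by a few CDR-SB points and ~10
    CBI-R points over 12 months; normal strata move little. 80% of baseline
    participants have a usable month-12 visit.
    """
    cells: dict[tuple[str, str, str], tuple[float, float]] = {}
    cdr_abn = {"C9orf72": 3.0, "GRN": 3.0, "MAPT": 2.0}
    cbir_abn = {"C9orf72": 8.0, "GRN": 10.0, "MAPT": 11.0}
    for gene in GENES:
        cells[(gene, "cdr_sb", "abnormal")] = (cdr_abn[gene], 1.5)
        cells[(gene, "cdr_sb", "normal")] = (0.3, 0.5)
        cells[(gene, "cbir", "abnormal")] = (cbir_abn[gene], 4.0)
        cells[(gene, "cbir", "normal")] = (0.5, 2.0)
    return ProgressionSpec(cells=cells, availability=0.8)


def generate_followup(participants: pd.DataFrame, prog: ProgressionSpec,
                      abnormality: pd.Series, seed: int = 0) -> pd.DataFrame:
    """Generate month-12 clinical records for retained baseline carriers.

    ``abnormality`` maps participant_id -> {'normal', 'abnormal'} from the
    baseline measure chosen for stratification. Returns the baseline rows
    plus one month-12 row per retained participant; sum-of-boxes and CBI-R
    are floored at 0 (CBI-R also capped at its 180-point maximum).
    """
    prog.validate()
    baseline = participants[participants["visit"] == "baseline"]
    missing = set(baseline["participant_id"]) - set(abnormality.index)
    if missing:
        raise SpecValidationError(
            f"missing abnormality label for participants: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else ""))
    rng = np.random.default_rng(seed)
    retained = baseline[rng.random(len(baseline)) < prog.availability]
    rows = []
    for rec in retained.itertuples(index=False):
        status = abnormality.loc[rec.participant_id]
        fu = rec._asdict()
        fu["visit"] = "month12"
        for scale, cap in (("cdr_sb", np.inf), ("cbir", CBIR_MAX)):
            mean, sd = prog.cells[(rec.group, scale, status)]
            delta = rng.normal(mean, sd) if sd > 0 else mean
            fu[scale] = float(np.clip(getattr(rec, scale) + delta, 0.0, cap))
        rows.append(fu)
    followup = pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)
    return pd.concat([baseline, followup], ignore_index=True)
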