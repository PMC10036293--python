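"""End-to-end orchestration: simulate -> fit -> w-score -> classify -> map
-> progression, with input validation and a reproducibility manifest.

Every run emits its stage outputs as UTF-8 CSV (header row, '.' decimal,
missing values as empty fields) plus a JSON manifest recording the tool
version, a hash of the configuration, the seeds used, row counts at every
stage and any warnings (degenerate models, skipped ROIs, excluded strata),
so that identical config + seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abnormality import classify_wscores, group_abnormality_map
from .cohort import (GENES, MEASURE_COLUMNS, PARTICIPANT_COLUMNS, SCALES,
                     SCANNERS, default_effect_maps, default_genfi_spec,
                     default_progression_spec, default_roi_model,
                     generate_carriers, generate_controls, generate_followup)
from .normative import compute_wscores, fit_normative_models
from .progression import pair_visits, progression_by_roi
from .rois import FA, MD, REGISTRY, VOLUME, default_progression_rois

logger = logging.getLogger(__name__)

CSV_KWARGS = dict(index=False, na_rep="")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``participants_csv``/``measures_csv``/``clinical_csv`` unset the
    run simulates a cohort from the built-in defaults; otherwise the tables
    are read from those paths. ``stratify_roi`` picks the (ROI, modality)
    whose baseline abnormality call drives the simulated follow-up change.
    """

    out_dir: str = "ftdnorm_run"
    seed: int = 0
    cut_percentile: float = 10.0
    bootstrap_B: int = 1000
    bootstrap_level: float = 0.95
    sigma_df: str = "n-p"
    participants_csv: str | None = None
    measures_csv: str | None = None
    clinical_csv: str | None = None
    roi_subset: list[list[str]] | None = None
    stratify_roi: tuple[str, str] = ("whole_brain", VOLUME)
    genes: tuple[str, ...] = GENES
    scales: tuple[str, ...] = SCALES

    def validate(self) -> None:
        if not 0.0 < self.cut_percentile < 50.0:
            raise ValueError(
                f"cut_percentile must be in (0, 50), got {self.cut_percentile}")
        if self.bootstrap_B < 1:
            raise ValueError(f"bootstrap_B must be >= 1, got {self.bootstrap_B}")
        if not 0.0 < self.bootstrap_level < 1.0:
            raise ValueError("bootstrap_level must be in (0, 1)")
        if self.sigma_df not in ("n-p", "n-1"):
            raise ValueError(f"sigma_df must be 'n-p' or 'n-1', got {self.sigma_df}")
        for path in (self.participants_csv, self.measures_csv, self.clinical_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "stratify_roi" in raw:
            raw["stratify_roi"] = tuple(raw["stratify_roi"])
        for key in ("genes", "scales"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(participants: pd.DataFrame,
                    measures: pd.DataFrame) -> list[str]:
    """Schema, range and referential checks; returns ALL violations found."""
    violations: list[str] = []
    for col in PARTICIPANT_COLUMNS:
        if col not in participants.columns:
            violations.append(f"participants: missing column {col!r}")
    for col in MEASURE_COLUMNS:
        if col not in measures.columns:
            violations.append(f"measures: missing column {col!r}")
    if violations:
        return violations

    base = participants[participants["visit"] == "baseline"]
    dup = base["participant_id"].duplicated()
    if dup.any():
        violations.append(
            f"participants: duplicate baseline ids {sorted(base['participant_id'][dup].unique())[:5]}")
    bad_sex = ~participants["sex"].isin(["male", "female"])
    if bad_sex.any():
        violations.append(f"participants: invalid sex values "
                          f"{sorted(participants['sex'][bad_sex].unique())}")
    bad_visit = ~participants["visit"].isin(["baseline", "month12"])
    if bad_visit.any():
        violations.append(f"participants: invalid visit labels "
                          f"{sorted(participants['visit'][bad_visit].unique())}")
    bad_scanner = ~participants["scanner"].isin(SCANNERS)
    if bad_scanner.any():
        violations.append(f"participants: unknown scanner types "
                          f"{sorted(participants['scanner'][bad_scanner].unique())}")
    for col in ("age_years", "tiv_mm3"):
        vals = pd.to_numeric(participants[col], errors="coerce")
        if not np.isfinite(vals).all():
            violations.append(f"participants: non-finite {col}")
    g = pd.to_numeric(base["cdr_global"], errors="coerce")
    bad_g = ~g.isin([0.0, 0.5, 1.0, 2.0, 3.0])
    if bad_g.any():
        violations.append(
            f"participants: invalid cdr_global values {sorted(g[bad_g].dropna().unique())}")
    if (pd.to_numeric(participants["cdr_sb"], errors="coerce") < 0).any():
        violations.append("participants: negative cdr_sb values")
    cbir = pd.to_numeric(participants["cbir"], errors="coerce")
    if ((cbir < 0) | (cbir > 180)).any():
        violations.append("participants: cbir values outside [0, 180]")

    unknown_pid = ~measures["participant_id"].isin(participants["participant_id"])
    if unknown_pid.any():
        violations.append(
            f"measures: rows reference unknown participant_ids "
            f"{sorted(measures['participant_id'][unknown_pid].unique())[:5]}")
    unknown_roi = ~measures["roi"].isin(REGISTRY.keys())
    if unknown_roi.any():
        violations.append(f"measures: unknown ROIs "
                          f"{sorted(measures['roi'][unknown_roi].unique())[:5]}")
    vals = pd.to_numeric(measures["value"], errors="coerce")
    fa = measures["modality"] == FA
    if ((vals[fa] < 0) | (vals[fa] > 1)).any():
        violations.append("measures: FA values outside [0, 1]")
    if (vals[measures["modality"] == MD] <= 0).any():
        violations.append("measures: non-positive MD values")
    if (vals[measures["modality"] == VOLUME] < 0).any():
        violations.append("measures: negative volumes")
    return violations


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record emitted with every pipeline run."""

    version: str
    config_hash: str
    seed: int
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _simulate_cohort(config: RunConfig, rng: np.random.Generator):
    spec = default_genfi_spec()
    roi_model = default_roi_model()
    controls, control_measures = generate_controls(
        spec, roi_model, seed=int(rng.integers(2 ** 31)))
    carriers, carrier_measures = generate_carriers(
        spec, roi_model, default_effect_maps(), seed=int(rng.integers(2 ** 31)))
    participants = pd.concat([controls, carriers], ignore_index=True)
    measures = pd.concat([control_measures, carrier_measures], ignore_index=True)
    return participants, measures, controls, control_measures, carriers, carrier_measures


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis and write all stage outputs to disk.

    Stages: (1) simulate or load tables; (2) validate; (3) fit normative
    models in controls; (4) w-score carriers; (5) abnormality calls;
    (6) group percentile-band map; (7) stratified progression per gene and
    scale. Deterministic given config + seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(version=__version__,
                           config_hash=config.config_hash(), seed=config.seed)

    simulated = config.participants_csv is None
    if simulated:
        (participants, measures, controls, control_measures,
         carriers, carrier_measures) = _simulate_cohort(config, rng)
    else:
        participants = pd.read_csv(config.participants_csv)
        measures = pd.read_csv(config.measures_csv)
        is_control = participants["group"] == "control"
        controls = participants[is_control & (participants["visit"] == "baseline")]
        carriers = participants[~is_control & (participants["visit"] == "baseline")]
        control_measures = measures[measures["participant_id"].isin(controls["participant_id"])]
        carrier_measures = measures[measures["participant_id"].isin(carriers["participant_id"])]

    violations = validate_inputs(participants, measures)
    if violations:
        raise ValueError("input validation failed:\n  " + "\n  ".join(violations))

    participants.to_csv(out / "participants.csv", **CSV_KWARGS)
    measures.to_csv(out / "measures.csv", **CSV_KWARGS)
    manifest.row_counts["participants"] = len(participants)
    manifest.row_counts["measures"] = len(measures)

    models = fit_normative_models(controls, control_measures,
                                  sigma_df=config.sigma_df)
    models.to_json(out / "models.json")
    manifest.row_counts["models"] = len(models)
    for key in models.skipped:
        manifest.warnings.append(f"model skipped (no data): {key}")
    for key, m in models.models.items():
        if m.degenerate:
            manifest.warnings.append(f"degenerate model (sigma=0): {key}")

    wscores = compute_wscores(models, carriers, carrier_measures)
    wscores.to_csv(out / "wscores.csv", **CSV_KWARGS)
    manifest.row_counts["wscores"] = len(wscores)

    calls = classify_wscores(wscores, cut_percentile=config.cut_percentile)
    calls.to_csv(out / "calls.csv", **CSV_KWARGS)
    manifest.row_counts["calls"] = len(calls)

    groupmap = group_abnormality_map(
        wscores, participants, B=config.bootstrap_B,
        level=config.bootstrap_level, seed=int(rng.integers(2 ** 31)))
    groupmap.to_csv(out / "groupmap.csv", **CSV_KWARGS)
    manifest.row_counts["groupmap"] = len(groupmap)

    # follow-up clinical table: simulated from the stratification ROI's
    # baseline abnormality call, or taken from the provided clinical CSV
    if simulated:
        roi, modality = config.stratify_roi
        strat = calls[(calls["roi"] == roi) & (calls["modality"] == modality)]
        labels = strat.set_index("participant_id")["label"]
        clinical = generate_followup(carriers, default_progression_spec(),
                                     labels, seed=int(rng.integers(2 ** 31)))
    elif config.clinical_csv is not None:
        clinical = pd.read_csv(config.clinical_csv)
    else:
        clinical = participants
    clinical.to_csv(out / "clinical.csv", **CSV_KWARGS)
    manifest.row_counts["clinical"] = len(clinical)

    roi_pairs = ([tuple(p) for p in config.roi_subset]
                 if config.roi_subset else default_progression_rois())
    prog_frames = []
    for scale in config.scales:
        pairs = pair_visits(clinical, scale)
        manifest.row_counts[f"pairs_{scale}"] = len(pairs)
        for gene in config.genes:
            prog = progression_by_roi(
                calls, pairs, participants, gene, roi_pairs, scale,
                B=config.bootstrap_B, seed=int(rng.integers(2 ** 31)))
            prog.insert(0, "scale", scale)
            prog_frames.append(prog)
    progression = pd.concat(prog_frames, ignore_index=True)
    progression.to_csv(out / "progression.csv", **CSV_KWARGS)
    manifest.row_counts["progression"] = len(progression)
    n_excluded = int((progression["flag"] == "excluded_lt3").sum())
    n_caution = int((progression["flag"] == "caution_lt6").sum())
    if n_excluded:
        manifest.warnings.append(f"{n_excluded} progression strata excluded (n<3)")
    if n_caution:
        manifest.warnings.append(f"{n_caution} progression strata flagged caution (n<6)")

    manifest.to_json(out / "manifest.json")
    return manifest
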