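"""Abnormality classification and group-level percentile-band maps.

A carrier's measure is called 'abnormal' when its w-score lies beyond the
cut corresponding to a control percentile (default the 10th, w = -1.282) in
the disease direction: below the cut for volumes and FA, above +the cut for
MD, where diffusivity rises with degeneration. Group-level maps summarise
each (gene x stage, ROI, modality) cell by the mean w-score, a seeded
non-parametric percentile bootstrap 95% CI of that mean (1000 replicates),
a one-sample t-test against 0, and a percentile band (<2.5th, <5th, <10th,
<25th, not-abnormal) derived from the disease-tail probability of the mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .normative import percentile_cutpoint
from .rois import LOWER_TAIL_MODALITIES, MODALITIES, UPPER_TAIL_MODALITIES

logger = logging.getLogger(__name__)

NORMAL = "normal"
ABNORMAL = "abnormal"

BAND_THRESHOLDS = ((0.025, "<2.5th"), (0.05, "<5th"),
                   (0.10, "<10th"), (0.25, "<25th"))
NOT_ABNORMAL = "not-abnormal"

CALL_COLUMNS = ["participant_id", "roi", "modality", "wscore",
                "cut_percentile", "cut_w", "label"]
GROUPMAP_COLUMNS = ["group", "stage", "roi", "modality", "n", "mean_wscore",
                    "ci_lo", "ci_hi", "t_pvalue", "band", "significant"]


def classify_wscore(w: float, modality: str, cut_percentile: float = 10.0):
    """Label one w-score normal/abnormal with the modality's direction.

    ``cut_percentile`` is on the 0-100 scale (default 10 -> |w| cut 1.282).
    A w-score exactly at the cut is normal (strictly beyond is required).
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if not np.isfinite(w):
        raise ValueError(f"w-score must be finite, got {w}")
    cut = abs(percentile_cutpoint(cut_percentile / 100.0))
    if modality in UPPER_TAIL_MODALITIES:
        return ABNORMAL if w > cut else NORMAL
    return ABNORMAL if w < -cut else NORMAL


def classify_wscores(wscores: pd.DataFrame,
                     cut_percentile: float = 10.0) -> pd.DataFrame:
    """Vectorised abnormality calls for a WScoreTable."""
    cut = abs(percentile_cutpoint(cut_percentile / 100.0))
    w = wscores["wscore"].to_numpy()
    upper = wscores["modality"].isin(UPPER_TAIL_MODALITIES).to_numpy()
    abnormal = np.where(upper, w > cut, w < -cut)
    out = wscores[["participant_id", "roi", "modality", "wscore"]].copy()
    out["cut_percentile"] = cut_percentile
    out["cut_w"] = np.where(upper, cut, -cut)
    out["label"] = np.where(abnormal, ABNORMAL, NORMAL)
    return out[CALL_COLUMNS]


def bootstrap_percentile_ci(values: np.ndarray, B: int = 1000,
                            level: float = 0.95,
                            seed: int | None = 0) -> tuple[float, float]:
    """Non-parametric percentile bootstrap CI for the mean.

    Draws ``B`` resamples with replacement, takes each mean, and returns the
    ((1-level)/2, 1-(1-level)/2) percentiles of the replicate means.
    Seeded and reproducible.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError(f"bootstrap CI needs at least 2 values, got {n}")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    return float(lo), float(hi)


def disease_tail_probability(mean_w: float, modality: str) -> float:
    """Control-tail probability of a mean w-score in the disease direction."""
    if modality in UPPER_TAIL_MODALITIES:
        return float(stats.norm.sf(mean_w))
    return float(stats.norm.cdf(mean_w))


def percentile_band(mean_w: float, modality: str) -> str:
    """Map a group mean w-score to its percentile colour band."""
    tail = disease_tail_probability(mean_w, modality)
    for threshold, band in BAND_THRESHOLDS:
        if tail < threshold:
            return band
    return NOT_ABNORMAL


def group_abnormality_map(wscores: pd.DataFrame, participants: pd.DataFrame,
                          B: int = 1000, level: float = 0.95,
                          seed: int = 0,
                          fdr: bool = False) -> pd.DataFrame:
    """Group-level abnormality map over (gene x stage, ROI, modality).

    For each cell: n, mean w-score, seeded bootstrap percentile CI of the
    mean, two-sided one-sample t-test against 0, percentile band from the
    disease-tail probability of the mean, and a significance flag. The flag
    is primary on the bootstrap CI excluding 0; the t p-value is reported
    alongside. Cells with n < 2 are emitted with CI and test set to NA and
    ``significant`` False. ``fdr=True`` adds a Benjamini-Hochberg adjusted
    q-value column (no correction is applied by default).
    """
    base = participants[participants["visit"] == "baseline"] \
        if "visit" in participants.columns else participants
    labels = base.set_index("participant_id")[["group", "stage"]]
    merged = wscores.merge(labels, left_on="participant_id", right_index=True,
                           how="inner")
    rows = []
    rng = np.random.default_rng(seed)
    for (group, stage, roi, modality), grp in merged.groupby(
            ["group", "stage", "roi", "modality"], sort=True):
        w = grp["wscore"].to_numpy(dtype=float)
        n = len(w)
        mean_w = float(np.mean(w))
        if n < 2:
            logger.warning("group map cell %s/%s %s/%s has n=%d < 2: "
                           "CI and test unavailable", group, stage, roi, modality, n)
            rows.append({"group": group, "stage": stage, "roi": roi,
                         "modality": modality, "n": n, "mean_wscore": mean_w,
                         "ci_lo": np.nan, "ci_hi": np.nan, "t_pvalue": np.nan,
                         "band": percentile_band(mean_w, modality),
                         "significant": False})
            continue
        lo, hi = bootstrap_percentile_ci(
            w, B=B, level=level, seed=int(rng.integers(2 ** 31)))
        t_p = float(stats.ttest_1samp(w, 0.0).pvalue)
        rows.append({"group": group, "stage": stage, "roi": roi,
                     "modality": modality, "n": n, "mean_wscore": mean_w,
                     "ci_lo": lo, "ci_hi": hi, "t_pvalue": t_p,
                     "band": percentile_band(mean_w, modality),
                     "significant": bool(lo > 0.0 or hi < 0.0)})
    result = pd.DataFrame(rows, columns=GROUPMAP_COLUMNS)
    if fdr and len(result):
        from statsmodels.stats.multitest import multipletests
        mask = result["t_pvalue"].notna()
        q = np.full(len(result), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                result.loc[mask, "t_pvalue"], method="fdr_bh")[1]
        result["t_qvalue"] = q
    return result
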