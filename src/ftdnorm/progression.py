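"""Clinical-progression analysis stratified by baseline regional abnormality.

Presymptomatic mutation carriers (CDR®+NACC-FTLD global 0 or 0.5) are split,
per ROI, into those with normal versus abnormal baseline w-scores, and the
change in clinical severity (CDR®+NACC-FTLD sum-of-boxes, CBI-R total) from
baseline to the 12-month visit is tested within each stratum with an exact
two-sided Wilcoxon signed-rank test.

The exact test enumerates the null distribution of the positive-rank sum
over all 2^n sign assignments of the observed (midranked, possibly tied)
absolute differences, so its p-values are valid at the very small n these
strata produce. Small-sample rules mirror clinical practice with such
strata: strata with fewer than 3 pairs are excluded outright, and
non-significant results with fewer than 6 pairs are flagged for caution —
with n < 6 the smallest attainable two-sided p is 2/2^n > 0.05, so
significance is impossible by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abnormality import ABNORMAL, NORMAL, bootstrap_percentile_ci

logger = logging.getLogger(__name__)

PRESYMPTOMATIC = "presymptomatic"
SYMPTOMATIC = "symptomatic"

FLAG_OK = "ok"
FLAG_CAUTION = "caution_lt6"
FLAG_EXCLUDED = "excluded_lt3"

#: largest n for which the exact null distribution is enumerated
EXACT_ENUMERATION_CUTOFF = 20

PROGRESSION_COLUMNS = ["gene", "roi", "modality", "stratum", "n_pairs",
                       "mean_baseline", "mean_followup", "mean_delta",
                       "ci_lo", "ci_hi", "statistic", "pvalue", "method",
                       "flag"]


# ---------------------------------------------------------------------------
# Staging and visit pairing
# ---------------------------------------------------------------------------

VALID_GLOBAL_SCORES = (0.0, 0.5, 1.0, 2.0, 3.0)


def stage_participants(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive disease stage from the CDR®+NACC-FTLD global score.

    Global 0 or 0.5 -> presymptomatic; 1, 2 or 3 -> symptomatic. Rows with
    any other global value raise, listing the offenders. Uses baseline rows
    when a ``visit`` column is present.
    """
    rows = clinical[clinical["visit"] == "baseline"] \
        if "visit" in clinical.columns else clinical
    g = rows["cdr_global"].astype(float)
    bad = rows.loc[~g.isin(VALID_GLOBAL_SCORES) | g.isna(), "participant_id"]
    if len(bad):
        raise ValueError(
            f"invalid CDR global scores for participants: {sorted(bad)[:10]}"
            + ("..." if len(bad) > 10 else ""))
    return pd.DataFrame({
        "participant_id": rows["participant_id"].to_numpy(),
        "stage": np.where(g <= 0.5, PRESYMPTOMATIC, SYMPTOMATIC),
    })


def pair_visits(clinical: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Build the paired baseline / month-12 change table for one scale.

    Returns one row per participant with both visits: participant_id,
    scale, baseline, month12, delta (= month12 - baseline). Participants
    with a single visit are logged as unpaired; duplicate visit labels per
    participant are an error.
    """
    if scale not in clinical.columns:
        raise ValueError(f"clinical table has no column {scale!r}")
    dup = clinical.duplicated(subset=["participant_id", "visit"])
    if dup.any():
        offenders = clinical.loc[dup, "participant_id"].unique()
        raise ValueError(f"duplicate visit labels for participants: "
                         f"{sorted(offenders)[:10]}")
    wide = clinical.pivot(index="participant_id", columns="visit", values=scale)
    for col in ("baseline", "month12"):
        if col not in wide.columns:
            wide[col] = np.nan
    paired = wide.dropna(subset=["baseline", "month12"])
    n_unpaired = len(wide) - len(paired)
    if n_unpaired:
        logger.info("%s: %d participants without both visits dropped",
                    scale, n_unpaired)
    return pd.DataFrame({
        "participant_id": paired.index.to_numpy(),
        "scale": scale,
        "baseline": paired["baseline"].to_numpy(dtype=float),
        "month12": paired["month12"].to_numpy(dtype=float),
        "delta": (paired["month12"] - paired["baseline"]).to_numpy(dtype=float),
    })


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of the signed-rank test on one set of paired differences."""

    statistic: float       # positive-rank sum W+
    pvalue: float          # two-sided; NaN when unavailable
    n_used: int            # non-zero differences entering the test
    method: str            # 'exact' | 'normal-approx' | 'unavailable'
    reason: str | None = None


def _exact_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null counts of the doubled positive-rank sum over all 2^n sign flips.

    Iterative convolution: each rank contributes 0 or its (doubled, hence
    integer even with midranks) value. counts[s] is the number of sign
    assignments with doubled rank-sum s; identical to brute-force 2^n
    enumeration.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upper = 0
    for r in doubled_ranks:
        r = int(r)
        counts[r:upper + r + 1] += counts[0:upper + 1]
        upper += r
    return counts


def exact_wilcoxon_signed_rank(
        deltas: np.ndarray,
        enumeration_cutoff: int = EXACT_ENUMERATION_CUTOFF) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (``n_used`` reports how
    many remain); ties in |delta| get midranks. For ``n_used`` at or below
    ``enumeration_cutoff`` the p-value is exact, from the full null
    distribution of the positive-rank sum over all sign assignments of the
    observed rank vector (ties handled exactly); beyond the cutoff a
    tie-corrected normal approximation is used. The two-sided p doubles the
    smaller tail, capped at 1.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0 or not np.all(np.isfinite(deltas)):
        raise ValueError("deltas must be a non-empty finite array")
    nonzero = deltas[deltas != 0.0]
    n = len(nonzero)
    if n == 0:
        return WilcoxonResult(np.nan, np.nan, 0, "unavailable",
                              reason="all paired differences are zero")
    ranks = stats.rankdata(np.abs(nonzero))          # midranks
    w_pos = float(np.sum(ranks[nonzero > 0.0]))
    if n <= enumeration_cutoff:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_null_counts(doubled)
        total = 2.0 ** n
        w2 = int(np.rint(2.0 * w_pos))
        p_ge = counts[w2:].sum() / total
        p_le = counts[:w2 + 1].sum() / total
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w_pos, p, n, "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - np.sum(tie_counts ** 3 - tie_counts) / 48.0
    z = (w_pos - mean) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return WilcoxonResult(w_pos, p, n, "normal-approx")


def min_attainable_p(n: int) -> float:
    """Smallest two-sided exact p reachable with ``n`` untied differences.

    Enumerated from the exact null distribution of ranks 1..n; equals
    2/2^n, strictly decreasing in n, and first drops to 0.05 or below at
    n = 6 — the basis for treating smaller strata with caution.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    counts = _exact_null_counts(2 * np.arange(1, n + 1, dtype=np.int64))
    total = 2.0 ** n
    cum = np.cumsum(counts)
    best = 1.0
    for w2 in np.flatnonzero(counts):
        p_le = cum[w2] / total
        p_ge = (total - (cum[w2 - 1] if w2 > 0 else 0.0)) / total
        best = min(best, min(1.0, 2.0 * min(p_le, p_ge)))
    return best


# ---------------------------------------------------------------------------
# Stratified progression
# ---------------------------------------------------------------------------

def progression_by_roi(calls: pd.DataFrame, pairs: pd.DataFrame,
                       participants: pd.DataFrame, gene: str,
                       roi_pairs: list[tuple[str, str]], scale: str,
                       B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Normal/abnormal stratified 12-month progression per ROI.

    ``calls`` are baseline abnormality calls; ``pairs`` the paired change
    table for ``scale``; ``participants`` supplies gene and stage labels.
    Only presymptomatic carriers of ``gene`` enter. Per (ROI, modality) and
    stratum: pair count, baseline/follow-up/delta means, bootstrap CI of
    the mean delta, and the exact signed-rank p — except that strata with
    n < 3 are excluded (no test) and 3 <= n < 6 results are flagged
    ``caution_lt6``.
    """
    if not roi_pairs:
        raise ValueError("roi_pairs must be non-empty")
    base = participants[participants["visit"] == "baseline"] \
        if "visit" in participants.columns else participants
    if "cdr_global" in base.columns:
        # stage from the clinical instrument itself, not the cohort label
        staged = stage_participants(base).set_index("participant_id")["stage"]
        stage = base["participant_id"].map(staged)
    else:
        stage = base["stage"]
    eligible = base.loc[(base["group"] == gene)
                        & (stage.to_numpy() == PRESYMPTOMATIC), "participant_id"]
    pairs = pairs[pairs["participant_id"].isin(eligible)]
    rng = np.random.default_rng(seed)
    rows = []
    for roi, modality in roi_pairs:
        roi_calls = calls[(calls["roi"] == roi) & (calls["modality"] == modality)]
        merged = pairs.merge(roi_calls[["participant_id", "label"]],
                             on="participant_id", how="inner")
        for stratum in (NORMAL, ABNORMAL):
            sub = merged[merged["label"] == stratum]
            n = len(sub)
            row = {"gene": gene, "roi": roi, "modality": modality,
                   "stratum": stratum, "n_pairs": n,
                   "mean_baseline": sub["baseline"].mean() if n else np.nan,
                   "mean_followup": sub["month12"].mean() if n else np.nan,
                   "mean_delta": sub["delta"].mean() if n else np.nan,
                   "ci_lo": np.nan, "ci_hi": np.nan,
                   "statistic": np.nan, "pvalue": np.nan, "method": "",
                   "flag": FLAG_OK}
            if n < 3:
                row["flag"] = FLAG_EXCLUDED
                rows.append(row)
                continue
            if n < 6:
                row["flag"] = FLAG_CAUTION
            res = exact_wilcoxon_signed_rank(sub["delta"].to_numpy())
            row["statistic"], row["pvalue"] = res.statistic, res.pvalue
            row["method"] = res.method
            lo, hi = bootstrap_percentile_ci(
                sub["delta"].to_numpy(), B=B, seed=int(rng.integers(2 ** 31)))
            row["ci_lo"], row["ci_hi"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows, columns=PROGRESSION_COLUMNS)
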