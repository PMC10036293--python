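"""Normative modelling: per-ROI control regressions and w-scores.

For each (ROI, modality) an ordinary least-squares model is fitted in
controls relating the measure to age, sex, TIV and scanner type. A mutation
carrier's w-score is the covariate-adjusted standardized residual

    w_i = (x_i - x_hat_i) / sigma,

where x_hat_i is the control-model prediction at the carrier's covariates
and sigma is the control residual SD. In controls, w has mean 0 and SD ~1,
so w maps onto control percentiles through the standard normal CDF: -1.960
is the 2.5th percentile, -1.645 the 5th, -1.282 the 10th, -0.675 the 25th.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age_years", "sex", "tiv_mm3", "scanner")

WSCORE_COLUMNS = ["participant_id", "roi", "modality", "value", "predicted",
                  "wscore", "percentile"]


class NormativeFitError(ValueError):
    """Control regression could not be fitted (rank deficiency etc.)."""


class UnseenScannerError(KeyError):
    """A participant's scanner category was absent from the control fit."""


# ---------------------------------------------------------------------------
# Percentile <-> w conversions
# ---------------------------------------------------------------------------

def percentile_cutpoint(p: float) -> float:
    """w value at control percentile ``p`` (probability in (0, 1)).

    Inverse standard normal CDF: ``percentile_cutpoint(0.10)`` ~ -1.282.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"percentile probability must be in (0, 1), got {p}")
    return float(stats.norm.ppf(p))


def wscore_percentile(w: float | np.ndarray) -> float | np.ndarray:
    """Control percentile (0-100) implied by a w-score: 100 * Phi(w)."""
    return 100.0 * stats.norm.cdf(w)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class NormativeModel:
    """Fitted control regression for one (ROI, modality) series.

    ``coefficients`` is keyed by design-column name: ``intercept``,
    ``age_years``, ``sex_male``, ``tiv_mm3`` and one ``scanner_<name>``
    offset per non-reference scanner category.
    """

    roi: str
    modality: str
    coefficients: dict[str, float]
    sigma: float
    n_controls: int
    df_resid: int
    reference_scanner: str
    scanner_categories: tuple[str, ...]
    sigma_df: str = "n-p"  # residual-SD convention used at fit time
    degenerate: bool = False

    def design_row(self, age: float, sex: str, tiv: float,
                   scanner: str) -> dict[str, float]:
        if scanner not in self.scanner_categories:
            raise UnseenScannerError(
                f"scanner {scanner!r} not seen in controls for "
                f"{self.roi}/{self.modality} (known: {self.scanner_categories})")
        row = {"intercept": 1.0, "age_years": age,
               "sex_male": 1.0 if sex == "male" else 0.0, "tiv_mm3": tiv}
        for cat in self.scanner_categories:
            if cat != self.reference_scanner:
                row[f"scanner_{cat}"] = 1.0 if scanner == cat else 0.0
        return row

    def predict(self, age: float, sex: str, tiv: float, scanner: str) -> float:
        """Linear predictor at one participant's covariates."""
        row = self.design_row(age, sex, tiv, scanner)
        return float(sum(self.coefficients[k] * v for k, v in row.items()))


@dataclass
class NormativeModelSet:
    """All fitted per-(ROI, modality) models plus fit-level metadata."""

    models: dict[tuple[str, str], NormativeModel]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, key: tuple[str, str]) -> NormativeModel:
        return self.models[key]

    def __len__(self) -> int:
        return len(self.models)

    def to_json(self, path) -> None:
        payload = {
            "models": [asdict(m) for m in self.models.values()],
            "skipped": [list(k) for k in self.skipped],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormativeModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        models = {}
        for rec in payload["models"]:
            rec["scanner_categories"] = tuple(rec["scanner_categories"])
            m = NormativeModel(**rec)
            models[(m.roi, m.modality)] = m
        return cls(models=models,
                   skipped=[tuple(k) for k in payload.get("skipped", [])])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _build_design(cov: pd.DataFrame, reference_scanner: str,
                  scanner_categories: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({
        "intercept": 1.0,
        "age_years": cov["age_years"].astype(float),
        "sex_male": (cov["sex"] == "male").astype(float),
        "tiv_mm3": cov["tiv_mm3"].astype(float),
    }, index=cov.index)
    for cat in scanner_categories:
        if cat != reference_scanner:
            X[f"scanner_{cat}"] = (cov["scanner"] == cat).astype(float)
    return X


def _reference_scanner(scanners: pd.Series) -> str:
    # most frequent category; ties broken lexicographically
    counts = scanners.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def fit_normative_models(controls: pd.DataFrame, measures: pd.DataFrame,
                         sigma_df: str = "n-p") -> NormativeModelSet:
    """Fit per-(ROI, modality) OLS control regressions.

    ``controls`` holds one baseline row per control with the covariate
    columns (age_years, sex, tiv_mm3, scanner); ``measures`` is the long
    (participant_id, roi, modality, value) table. Residual SD uses
    ``sigma_df`` degrees of freedom: ``"n-p"`` (regression convention,
    default) or ``"n-1"``.

    ROIs whose values are all missing are skipped with a log entry; a model
    whose residual SD is 0 is flagged degenerate (its w-scores are
    undefined). Complete-case analysis per ROI, no imputation.
    """
    if sigma_df not in ("n-p", "n-1"):
        raise ValueError(f"sigma_df must be 'n-p' or 'n-1', got {sigma_df!r}")
    cov = controls.set_index("participant_id")
    missing_cov = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing_cov:
        raise NormativeFitError(f"controls table lacks covariates: {missing_cov}")

    models: dict[tuple[str, str], NormativeModel] = {}
    skipped: list[tuple[str, str]] = []
    for (roi, modality), grp in measures.groupby(["roi", "modality"], sort=True):
        grp = grp.dropna(subset=["value"])
        grp = grp[grp["participant_id"].isin(cov.index)]
        if grp.empty:
            logger.warning("skipping %s/%s: no usable control values", roi, modality)
            skipped.append((roi, modality))
            continue
        c = cov.loc[grp["participant_id"]]
        complete = c[list(COVARIATE_COLUMNS)].notna().all(axis=1).to_numpy()
        if not complete.all():
            logger.warning("%s/%s: dropping %d controls with incomplete covariates",
                           roi, modality, int((~complete).sum()))
        c, grp = c[complete], grp[complete]
        if c.empty:
            skipped.append((roi, modality))
            continue
        ref = _reference_scanner(c["scanner"])
        cats = tuple(sorted(c["scanner"].unique()))
        X = _build_design(c, ref, cats)
        y = grp["value"].astype(float).to_numpy()
        n, p = X.shape
        if n <= p:
            raise NormativeFitError(
                f"{roi}/{modality}: {n} controls cannot identify {p} parameters")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < p:
            collinear = _collinear_columns(X)
            raise NormativeFitError(
                f"{roi}/{modality}: rank-deficient design (rank {rank} < {p}); "
                f"collinear columns: {collinear}")
        fit = sm.OLS(y, X.to_numpy()).fit()
        resid = y - fit.fittedvalues
        dof = n - p if sigma_df == "n-p" else n - 1
        sigma = float(np.sqrt(np.sum(resid ** 2) / dof))
        # relative floor: a perfect in-sample fit leaves only rounding noise
        degenerate = (not np.isfinite(sigma)
                      or sigma <= 1e-10 * max(1.0, float(np.mean(np.abs(y)))))
        if degenerate:
            logger.warning("%s/%s: zero residual variance, model flagged degenerate",
                           roi, modality)
        models[(roi, modality)] = NormativeModel(
            roi=roi, modality=modality,
            coefficients=dict(zip(X.columns, (float(b) for b in fit.params))),
            sigma=sigma, n_controls=n, df_resid=n - p,
            reference_scanner=ref, scanner_categories=cats,
            sigma_df=sigma_df, degenerate=degenerate)
    return NormativeModelSet(models=models, skipped=skipped)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns involved in exact linear dependence, via QR pivoting."""
    arr = X.to_numpy()
    kept: list[int] = []
    for j in range(arr.shape[1]):
        cand = arr[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
    return [X.columns[j] for j in range(arr.shape[1]) if j not in kept]


def predict_expected(model: NormativeModel, age: float, sex: str, tiv: float,
                     scanner: str) -> float:
    """Control-model expected value at one participant's covariates.

    Raises :class:`UnseenScannerError` for a scanner category absent from
    the control fit — there is no defensible silent fallback.
    """
    return model.predict(age, sex, tiv, scanner)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def compute_wscores(models: NormativeModelSet, participants: pd.DataFrame,
                    measures: pd.DataFrame) -> pd.DataFrame:
    """Compute w-scores for every measure row with a usable model.

    Returns the WScoreTable with columns participant_id, roi, modality,
    value, predicted, wscore, percentile. Rows whose (ROI, modality) has no
    fitted or non-degenerate model, or whose participant lacks complete
    covariates, are skipped with a log entry.
    """
    cov = participants[participants["visit"] == "baseline"] \
        if "visit" in participants.columns else participants
    cov = cov.set_index("participant_id")
    out_frames = []
    for (roi, modality), grp in measures.groupby(["roi", "modality"], sort=True):
        model = models.models.get((roi, modality))
        if model is None:
            logger.warning("no model for %s/%s: %d rows skipped",
                           roi, modality, len(grp))
            continue
        if model.degenerate:
            logger.warning("degenerate model for %s/%s: %d rows skipped",
                           roi, modality, len(grp))
            continue
        grp = grp.dropna(subset=["value"])
        known = grp["participant_id"].isin(cov.index)
        if not known.all():
            logger.warning("%s/%s: %d measure rows without covariates skipped",
                           roi, modality, int((~known).sum()))
            grp = grp[known]
        if grp.empty:
            continue
        c = cov.loc[grp["participant_id"]]
        complete = c[list(COVARIATE_COLUMNS)].notna().all(axis=1).to_numpy()
        if not complete.all():
            logger.warning("%s/%s: %d participants with incomplete covariates skipped",
                           roi, modality, int((~complete).sum()))
            c, grp = c[complete], grp[complete]
        X = _build_design(c, model.reference_scanner, model.scanner_categories)
        unseen = ~c["scanner"].isin(model.scanner_categories)
        if unseen.any():
            raise UnseenScannerError(
                f"{roi}/{modality}: scanner categories not in control fit: "
                f"{sorted(c['scanner'][unseen].unique())}")
        beta = np.array([model.coefficients[col] for col in X.columns])
        predicted = X.to_numpy() @ beta
        w = (grp["value"].astype(float).to_numpy() - predicted) / model.sigma
        out_frames.append(pd.DataFrame({
            "participant_id": grp["participant_id"].to_numpy(),
            "roi": roi, "modality": modality,
            "value": grp["value"].astype(float).to_numpy(),
            "predicted": predicted, "wscore": w,
            "percentile": wscore_percentile(w)}))
    if not out_frames:
        return pd.DataFrame(columns=WSCORE_COLUMNS)
    return pd.concat(out_frames, ignore_index=True)[WSCORE_COLUMNS]
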