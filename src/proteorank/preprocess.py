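"""Normalization, blood-contamination correction, outlier QC and PCA.

Biofluid proteomes are confounded by erythrocyte/blood carry-over: a
contaminated sample shows elevated hemoglobin-like marker proteins and a
correlated lift across much of the proteome. The correction here scores
each sample by its mean log2 level over a marker panel, flags gross
outlier samples on that score, and residualizes every protein on the score
with a robust (Huber) linear fit so that downstream group contrasts are
not driven by contamination. Residuals keep each protein's intercept, so
the abundance scale (and hence abundance ranking) survives correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, ProteomeDataset

HUBER_C = 1.345  # 95% Gaussian efficiency tuning constant
MAD_TO_SD = 1.4826


def log2_median_normalize(dataset_or_matrix) -> pd.DataFrame:
    """log2-transform and median-center each sample column.

    Missing cells stay missing. A column with no observed value is an
    error — an empty sample cannot be normalized.
    """
    if isinstance(dataset_or_matrix, ProteomeDataset):
        mat = dataset_or_matrix.intensities
    else:
        mat = dataset_or_matrix
    vals = mat.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if np.any(obs & (vals <= 0)):
        raise DataError("nonpositive intensity encountered in normalization")
    empty = ~obs.any(axis=0)
    if empty.any():
        bad = list(mat.columns[empty])
        raise DataError(f"empty sample column(s): {bad}")
    logv = np.where(obs, np.log2(np.where(obs, vals, 1.0)), np.nan)
    med = np.nanmedian(logv, axis=0)
    return pd.DataFrame(logv - med[None, :], index=mat.index, columns=mat.columns)


def log2_reference_normalize(dataset_or_matrix) -> pd.DataFrame:
    """log2-transform and center each sample on a row-median reference.

    Column offsets are estimated as the median of per-protein differences
    to the across-sample median profile (size-factor estimation on the log
    scale). Unlike plain column-median centering, the difference density
    is concentrated at zero, so the estimate is precise and nearly
    unaffected by an asymmetrically regulated protein block; loading
    differences between samples are still removed exactly.
    """
    if isinstance(dataset_or_matrix, ProteomeDataset):
        mat = dataset_or_matrix.intensities
    else:
        mat = dataset_or_matrix
    vals = mat.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if np.any(obs & (vals <= 0)):
        raise DataError("nonpositive intensity encountered in normalization")
    empty = ~obs.any(axis=0)
    if empty.any():
        raise DataError(f"empty sample column(s): {list(mat.columns[empty])}")
    logv = np.where(obs, np.log2(np.where(obs, vals, 1.0)), np.nan)
    # geometric-mean reference profile; per-column offset = median log-ratio
    ref = np.nanmean(logv, axis=1)
    offsets = np.nanmedian(logv - ref[:, None], axis=0)
    return pd.DataFrame(logv - offsets[None, :], index=mat.index, columns=mat.columns)


def contamination_score(log2_matrix: pd.DataFrame, marker_panel) -> pd.Series:
    """Per-sample contamination score: mean log2 level over observed panel proteins."""
    panel = [p for p in marker_panel if p in log2_matrix.index]
    if not panel:
        raise DataError("no marker-panel protein present in the matrix")
    sub = log2_matrix.loc[panel].to_numpy(dtype=float)
    n_obs = (~np.isnan(sub)).sum(axis=0)
    missing = n_obs == 0
    if missing.any():
        bad = list(log2_matrix.columns[missing])
        raise DataError(f"no panel protein observed in sample(s): {bad}")
    with np.errstate(invalid="ignore"):
        score = np.nanmean(sub, axis=0)
    return pd.Series(score, index=log2_matrix.columns, name="contamination_score")


@dataclass
class ContaminationModel:
    """Result of residualizing a log2 matrix on a contamination score."""

    marker_panel: list
    scores: pd.Series
    coefficients: pd.Series  # per-protein slope on the score (NaN if unfitted)
    intercepts: pd.Series
    robust_weights: pd.DataFrame  # per-observation Huber weights in [0, 1]
    residual_matrix: pd.DataFrame  # corrected log2 values, intercept re-added
    unfitted: list  # proteins passed through (fewer than 3 observations)


def huber_regress_matrix(
    vals: np.ndarray,
    s: np.ndarray,
    c: float = HUBER_C,
    tol: float = 1e-8,
    max_iter: int = 100,
    min_obs: int = 3,
):
    """Row-wise Huber simple regression y ~ 1 + s, vectorized over rows.

    IRLS with Huber weights (tuning ``c``) and MAD-about-zero residual
    scale, run simultaneously for every row of ``vals`` (NaN = missing).
    After convergence the coefficients come from one weighted LS solve
    with the converged weights, so weighted residuals are orthogonal to
    the design to machine precision. Rows with an exactly-fitting line
    (zero residual scale) fall back to OLS with unit weights. Rows with
    fewer than ``min_obs`` observations are left unfitted (NaN coefs).

    Returns (intercepts, slopes, weights) with weights NaN at missing
    cells and for unfitted rows.
    """
    vals = np.asarray(vals, dtype=float)
    s = np.asarray(s, dtype=float)
    obs = np.isfinite(vals)
    n_obs = obs.sum(axis=1)
    fit_rows = n_obs >= min_obs

    y = np.where(obs, vals, 0.0)
    sm_ = np.where(obs, s[None, :], 0.0)

    def _solve(w):
        # weighted normal equations per row, closed form for 2 parameters
        sw = w.sum(axis=1)
        sws = (w * sm_).sum(axis=1)
        swss = (w * sm_ * sm_).sum(axis=1)
        swy = (w * y).sum(axis=1)
        swsy = (w * sm_ * y).sum(axis=1)
        det = sw * swss - sws * sws
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        b1 = (sw * swsy - sws * swy) / det
        b0 = (swy - b1 * sws) / sw
        return b0, b1

    w = obs.astype(float)
    b0, b1 = _solve(w)
    exact = np.zeros(vals.shape[0], dtype=bool)
    for _ in range(max_iter):
        r = np.where(obs, y - b0[:, None] - b1[:, None] * sm_, np.nan)
        with np.errstate(invalid="ignore"):
            scale = np.nanmedian(np.abs(r), axis=1) / 0.6745
        exact = scale <= 1e-10 * np.maximum(1.0, np.nanstd(np.where(obs, vals, np.nan), axis=1))
        scale_safe = np.where(scale > 0, scale, 1.0)
        u = np.abs(np.where(obs, r, 0.0)) / scale_safe[:, None]
        w_new = np.where(u <= c, 1.0, c / np.maximum(u, 1e-300))
        w_new = np.where(obs, w_new, 0.0)
        w_new[exact] = obs[exact].astype(float)
        b0n, b1n = _solve(w_new)
        delta = np.nanmax(
            np.abs(np.array([b0n - b0, b1n - b1]))
            / np.maximum(1.0, np.abs(np.array([b0, b1])))
        )
        w, b0, b1 = w_new, b0n, b1n
        if not np.isfinite(delta) or delta < tol:
            break
    # final solve already used w; weights reported are those of that solve
    b0 = np.where(fit_rows, b0, np.nan)
    b1 = np.where(fit_rows, b1, np.nan)
    weights = np.where(obs & fit_rows[:, None], w, np.nan)
    return b0, b1, weights


def regress_out_contamination(
    log2_matrix: pd.DataFrame, scores: pd.Series, min_obs: int = 3
) -> ContaminationModel:
    """Residualize each protein on the contamination score (robust fit).

    Per protein a Huber simple regression of log2 value on score; the
    returned matrix holds residuals with the intercept re-added so the
    abundance scale is preserved. Proteins observed in fewer than
    ``min_obs`` samples pass through unchanged and are flagged.
    """
    s_all = scores.reindex(log2_matrix.columns).to_numpy(dtype=float)
    if not np.all(np.isfinite(s_all)):
        raise DataError("non-finite contamination score")
    if np.ptp(s_all) == 0:
        raise DataError("degenerate covariate: contamination scores are constant")

    vals = log2_matrix.to_numpy(dtype=float)
    # center the covariate so the intercept is the protein's level at the
    # average contamination — re-adding it then preserves abundance scale
    s_centered = s_all - float(np.mean(s_all))
    intercepts, slopes, weights = huber_regress_matrix(vals, s_centered, min_obs=min_obs)
    fitted = np.isfinite(slopes)
    resid = vals.copy()
    fitted_part = intercepts[:, None] + slopes[:, None] * s_centered[None, :]
    resid[fitted] = vals[fitted] - fitted_part[fitted] + intercepts[fitted, None]
    unfitted = list(log2_matrix.index[~fitted])
    idx = log2_matrix.index
    return ContaminationModel(
        marker_panel=[],
        scores=pd.Series(s_all, index=log2_matrix.columns, name="contamination_score"),
        coefficients=pd.Series(slopes, index=idx, name="slope"),
        intercepts=pd.Series(intercepts, index=idx, name="intercept"),
        robust_weights=pd.DataFrame(weights, index=idx, columns=log2_matrix.columns),
        residual_matrix=pd.DataFrame(resid, index=idx, columns=log2_matrix.columns),
        unfitted=unfitted,
    )


def detect_outlier_samples(scores: pd.Series, k: float = 3.0) -> list:
    """Flag samples whose score exceeds median + k * robust SD.

    Robust SD is 1.4826*MAD; when MAD is zero (heavily tied scores) the
    ordinary sample SD is used instead. Only the upper tail is flagged —
    contamination inflates, never deflates, marker levels.
    """
    x = scores.to_numpy(dtype=float)
    if x.size < 4:
        raise DataError("need at least 4 samples for outlier detection")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    spread = MAD_TO_SD * mad if mad > 0 else float(np.std(x, ddof=1))
    if spread == 0:
        return []
    return list(scores.index[x > med + k * spread])


def score_group_confounded(
    scores: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sample t of contamination score against AD/Ctl membership.

    In small cohorts a blood covariate can itself differ between groups;
    residualizing on it would then absorb disease signal. Returns
    (confounded?, p-value).
    """
    g = groups.reindex(scores.index)
    ad = scores[g == "AD"].to_numpy(float)
    ctl = scores[g == "Ctl"].to_numpy(float)
    if ad.size < 2 or ctl.size < 2:
        return False, 1.0
    t, p = stats.ttest_ind(ad, ctl, equal_var=True)
    return bool(p < alpha), float(p)


def pca_qc(log2_matrix: pd.DataFrame, n_components: int = 2):
    """Sample coordinates on the first two principal components.

    Uses complete-case proteins only (observed in every sample), centers
    each protein, and takes the SVD. Sign convention: within each
    component the largest-magnitude protein loading is positive.

    Returns (scores DataFrame: samples × PC1/PC2, variance fractions).
    """
    if log2_matrix.shape[1] < 2:
        raise DataError("PCA needs at least 2 samples")
    vals = log2_matrix.to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    if not complete.any():
        raise DataError("no complete-case protein for PCA")
    X = vals[complete]
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    for j in range(k):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] *= -1.0
            Vt[j, :] *= -1.0
    total = float((S**2).sum())
    var_frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = pd.DataFrame(
        (S[:k, None] * Vt[:k, :]).T,
        index=log2_matrix.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return scores, var_frac


@dataclass
class PreprocessResult:
    corrected: pd.DataFrame  # log2, contamination-residualized, outliers dropped
    groups: pd.Series
    model: ContaminationModel | None
    outliers: list
    confounded: bool
    confound_p: float


def preprocess_dataset(
    dataset: ProteomeDataset,
    marker_panel,
    outlier_k: float = 3.0,
    skip_correction_if_confounded: bool = False,
) -> PreprocessResult:
    """Full per-cohort preprocessing: normalize, flag outliers, residualize.

    When ``skip_correction_if_confounded`` is set and the contamination
    score is itself associated with disease group (two-sample t, α=0.05),
    only outlier removal is applied and the matrix is left unresidualized.
    """
    logm = log2_reference_normalize(dataset)
    if not marker_panel:
        # no panel: normalization only (no score, no outlier call, no fit)
        return PreprocessResult(
            corrected=logm, groups=dataset.sample_groups.copy(), model=None,
            outliers=[], confounded=False, confound_p=1.0,
        )
    scores = contamination_score(logm, marker_panel)
    outliers = detect_outlier_samples(scores, k=outlier_k) if len(scores) >= 4 else []
    keep = [s for s in logm.columns if s not in set(outliers)]
    logm = logm[keep]
    scores = scores[keep]
    groups = dataset.sample_groups[keep]

    confounded, confound_p = score_group_confounded(scores, groups)
    model = None
    corrected = logm
    if not (skip_correction_if_confounded and confounded) and np.ptp(scores.to_numpy()) > 0:
        model = regress_out_contamination(logm, scores)
        model.marker_panel = list(marker_panel)
        corrected = model.residual_matrix
    return PreprocessResult(
        corrected=corrected,
        groups=groups,
        model=model,
        outliers=outliers,
        confounded=confounded,
        confound_p=confound_p,
    )
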