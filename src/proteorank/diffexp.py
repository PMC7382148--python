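"""Per-dataset differential expression with an empirical-Bayes moderated t.

The AD-vs-Ctl contrast on each protein is a two-sample comparison on the
corrected log2 scale. With cohorts of ~10 per group, per-protein variance
estimates are noisy; the moderated t shrinks them toward a proteome-wide
prior variance s0² with prior degrees of freedom d0:

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)
    t̃_g  = log2FC_g / (s̃_g · sqrt(1/n_AD + 1/n_Ctl)),   df = d_g + d0

d0 and s0² are estimated by moment matching on log s²: if s² ~ s0²·F(d, d0)
then E[log s²] and Var[log s²] involve digamma/trigamma of d/2 and d0/2;
inverting the trigamma relation (monotone bisection) yields d0. When the
observed spread of log s² is no larger than its sampling noise the prior
dominates (d0 = ∞, full shrinkage to s0²).

Fold changes are additionally standardized across proteins (the "Z-scored
log2 fold change"), and DE calls combine a |Z| threshold with a BH-FDR or
nominal-p ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataError, DECallSpec


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection (trigamma is decreasing)."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-12, 1e12
    # expand is unnecessary: trigamma(1e-12) ~ 1e24, trigamma(1e12) ~ 1e-12
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0²) from per-protein variances.

    Returns d0 = inf (full shrinkage) when the excess spread of log s² is
    nonpositive.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        raise DataError("too few usable variances to estimate the prior")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.mean(n / (n - 1) * (e - emean) ** 2 - special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


# ---------------------------------------------------------------------------
# DE fit


@dataclass
class DEResult:
    """Per-protein DE statistics for one dataset's AD-vs-Ctl contrast."""

    dataset_id: str
    tissue: str
    table: pd.DataFrame  # log2fc, z, p_raw, fdr, mean_abund, n_ad, n_ctl, s2, t
    d0: float
    s0sq: float

    def de_set(self, spec: DECallSpec) -> set:
        return call_de(self, spec)


def fit_moderated_t(
    corrected_matrix: pd.DataFrame,
    groups: pd.Series,
    d0: float | None = None,
    dataset_id: str = "",
    tissue: str = "",
) -> DEResult:
    """Moderated two-sample t of AD vs Ctl per protein.

    ``groups`` labels each sample column; MCI samples are carried in the
    matrix but excluded from the contrast. ``d0`` overrides the estimated
    prior df (0 = ordinary pooled t, inf = full shrinkage). Proteins with
    fewer than 2 usable samples in either group get missing statistics and
    do not enter the Z standardization.
    """
    g = groups.reindex(corrected_matrix.columns)
    ad_cols = g.index[g == "AD"]
    ctl_cols = g.index[g == "Ctl"]
    if len(ad_cols) == 0 or len(ctl_cols) == 0:
        raise DataError("contrast needs at least one AD and one Ctl sample")

    vals = corrected_matrix.to_numpy(dtype=float)
    a = corrected_matrix[ad_cols].to_numpy(dtype=float)
    c = corrected_matrix[ctl_cols].to_numpy(dtype=float)
    na = np.isfinite(a).sum(axis=1)
    nc = np.isfinite(c).sum(axis=1)
    usable = (na >= 2) & (nc >= 2)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
        mean_c = np.nanmean(np.where(np.isfinite(c), c, np.nan), axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_c = np.nanvar(c, axis=1, ddof=1)
        mean_abund = np.nanmean(vals, axis=1)

    lfc = np.where(usable, mean_a - mean_c, np.nan)
    df_resid = np.where(usable, na + nc - 2.0, np.nan)
    s2 = np.where(
        usable,
        ((na - 1) * var_a + (nc - 1) * var_c) / np.maximum(na + nc - 2, 1),
        np.nan,
    )

    if d0 is None:
        d0_hat, s0sq = estimate_variance_prior(s2[usable], df_resid[usable])
    else:
        d0_hat = float(d0)
        # s0² only matters when shrinkage is active
        s0sq = (
            float(np.exp(np.mean(np.log(s2[usable & (s2 > 0)]))))
            if d0_hat > 0
            else float("nan")
        )
        if d0_hat > 0 and np.isinf(d0_hat):
            _, s0sq = estimate_variance_prior(s2[usable], df_resid[usable])

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0_hat):
            s2_post = np.full_like(s2, s0sq)
            df_total = np.full_like(s2, np.inf)
        elif d0_hat == 0:
            s2_post = s2
            df_total = df_resid
        else:
            s2_post = (d0_hat * s0sq + df_resid * s2) / (d0_hat + df_resid)
            df_total = df_resid + d0_hat
        se = np.sqrt(s2_post * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nc, 1)))
        tstat = lfc / se

    p = np.full(tstat.shape, np.nan)
    fin = usable & np.isfinite(tstat)
    if fin.any():
        dfv = df_total[fin]
        tv = np.abs(tstat[fin])
        pv = np.where(np.isinf(dfv), 2.0 * stats.norm.sf(tv), 2.0 * stats.t.sf(tv, np.where(np.isinf(dfv), 1.0, dfv)))
        p[fin] = np.minimum(pv, 1.0)

    z = np.full(lfc.shape, np.nan)
    if fin.sum() >= 2:
        z[fin] = z_transform_logfc(lfc[fin])
    fdr = bh_adjust(p)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "z": z,
            "t": tstat,
            "p_raw": p,
            "fdr": fdr,
            "mean_abund": mean_abund,
            "n_ad": na,
            "n_ctl": nc,
            "s2": s2,
        },
        index=corrected_matrix.index,
    )
    return DEResult(dataset_id=dataset_id, tissue=tissue, table=table, d0=d0_hat, s0sq=s0sq)


def z_transform_logfc(log2fc) -> np.ndarray:
    """Standardize fold changes across proteins: (x − mean) / SD (ddof=1)."""
    x = np.asarray(log2fc, dtype=float)
    fin = np.isfinite(x)
    if fin.sum() < 2:
        raise DataError("need at least 2 finite fold changes to standardize")
    sd = np.std(x[fin], ddof=1)
    if sd == 0:
        raise DataError("degenerate fold-change vector (zero SD)")
    out = np.full(x.shape, np.nan)
    out[fin] = (x[fin] - np.mean(x[fin])) / sd
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values; NaN entries stay NaN."""
    x = np.asarray(p, dtype=float)
    fin = np.isfinite(x)
    if np.any((x[fin] < 0) | (x[fin] > 1)):
        raise DataError("p-values must lie in [0, 1]")
    out = np.full(x.shape, np.nan)
    if fin.any():
        out[fin] = multipletests(x[fin], method="fdr_bh")[1]
    return out


def call_de(de: DEResult, spec: DECallSpec) -> set:
    """Protein ids passing |Z| > z_min and the FDR or nominal-p ceiling."""
    t = de.table
    keep = np.isfinite(t["z"]) & (np.abs(t["z"]) > spec.z_min)
    if spec.fdr_max is not None:
        keep &= np.isfinite(t["fdr"]) & (t["fdr"] < spec.fdr_max)
    else:
        keep &= np.isfinite(t["p_raw"]) & (t["p_raw"] < spec.p_max)
    if spec.direction == "up":
        keep &= t["z"] > 0
    elif spec.direction == "down":
        keep &= t["z"] < 0
    return set(t.index[keep])


# ---------------------------------------------------------------------------
# abundance / depth analysis


def abundance_rank(matrix: pd.DataFrame) -> pd.Series:
    """Rank proteins by mean log2 level, 1 = most abundant; ties by id."""
    if matrix.shape[0] == 0:
        raise DataError("empty matrix")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(matrix.to_numpy(dtype=float), axis=1)
    order = sorted(range(len(means)), key=lambda i: (-means[i], str(matrix.index[i])))
    ranks = np.empty(len(means), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return pd.Series(ranks, index=matrix.index, name="abundance_rank")


@dataclass
class DepthCurve:
    """Detectability of a protein set as profiling depth grows."""

    depth_grid: list
    detected_counts: list
    median_rank: float
    set_size: int

    @property
    def detected_fractions(self) -> list:
        return [c / self.set_size for c in self.detected_counts]


def depth_detection_curve(query_set, abundance_ranks: pd.Series, depth_grid) -> DepthCurve:
    """How many query proteins fall within the top-d most abundant, per depth d."""
    missing = [p for p in query_set if p not in abundance_ranks.index]
    if missing:
        raise DataError(f"query protein(s) absent from ranking: {sorted(missing)[:5]}")
    ranks = abundance_ranks.loc[sorted(query_set)].to_numpy(dtype=float)
    grid = list(depth_grid)
    counts = [int(np.sum(ranks <= d)) for d in grid]
    return DepthCurve(
        depth_grid=grid,
        detected_counts=counts,
        median_rank=float(np.median(ranks)),
        set_size=len(ranks),
    )


def validation_correlation(quant_a, quant_b) -> float:
    """Pearson r between two quantifications of the same proteins/samples."""
    a = np.asarray(quant_a, dtype=float)
    b = np.asarray(quant_b, dtype=float)
    fin = np.isfinite(a) & np.isfinite(b)
    if fin.sum() < 3:
        raise DataError("need at least 3 paired finite values")
    a, b = a[fin], b[fin]
    if np.std(a) == 0 or np.std(b) == 0:
        raise DataError("zero variance in one of the quantifications")
    return float(stats.pearsonr(a, b)[0])
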