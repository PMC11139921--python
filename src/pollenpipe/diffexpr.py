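"""Negative-binomial differential abundance with median-of-ratios
normalization, Wald tests, BH FDR, and VST + PCA.

This is a compact re-implementation of the standard NB differential-
expression core for a two-group design: per-sample size factors by the
median-of-ratios method, a per-feature (or pooled) method-of-moments
dispersion estimate, a log-link NB GLM fitted by IRLS with size-factor
offsets, a Wald test on the group coefficient against the normal reference,
and Benjamini-Hochberg adjustment at FDR 0.05.  It deliberately omits the
full shrinkage machinery of larger DE frameworks; the contract is "NB
differential abundance at a stated FDR", not bit-compatibility with any one
of them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DeConfig

LN2 = float(np.log(2.0))


def size_factors_median_of_ratios(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-feature geometric mean across samples, computed
    only on features with all counts positive; each sample's factor is the
    median of count/reference over those features.
    """
    counts = matrix.to_numpy(dtype=float)
    counts = counts[~np.all(counts == 0, axis=1)]
    all_pos = np.all(counts > 0, axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; median-of-ratios "
            "undefined (consider a pseudo-reference fallback)"
        )
    pos = counts[all_pos]
    log_ref = np.mean(np.log(pos), axis=1)
    ratios = np.log(pos) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize_counts(matrix: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(matrix)
    return matrix.astype(float).div(size_factors, axis=1)


def estimate_dispersion(
    normalized: pd.DataFrame,
    groups: list[str],
    cfg: DeConfig | None = None,
) -> pd.Series:
    """Method-of-moments NB dispersion from within-group statistics.

    Per feature, alpha-hat = max(0, (s2 - m) / m^2) using the pooled
    within-group sample variance; in shrinkage mode estimates are pulled
    toward a rolling-median trend over the mean-ranked features.  In common
    mode every feature receives one across-feature estimate from the
    Cox-Reid-adjusted profile likelihood (group means profiled out, half
    log-determinant penalty), which stays precise at the 2-replicate
    designs where per-feature moments are degenerate.  Estimates are
    floored at a small positive constant.
    """
    cfg = cfg or DeConfig()
    cfg.validate()
    y = normalized.to_numpy(dtype=float)
    garr = np.asarray(groups)
    labels = pd.unique(garr)
    n = y.shape[1]
    resid_df = n - len(labels)
    if resid_df < 1:
        raise ValueError("need at least one residual degree of freedom")
    min_group = min(int((garr == g).sum()) for g in labels)
    if min_group < 2 and cfg.dispersion_mode != "common":
        raise ValueError(
            "one replicate per group: per-feature dispersion is degenerate; "
            "force common-dispersion mode"
        )

    ss = np.zeros(y.shape[0])
    for g in labels:
        sub = y[:, garr == g]
        ss += np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1)
    s2 = ss / resid_df
    m = y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(m > 0, np.maximum(0.0, (s2 - m) / np.maximum(m, 1e-300) ** 2), 0.0)

    informative = m > 0
    floor = cfg.dispersion_floor
    if not informative.any():
        return pd.Series(np.full(y.shape[0], floor), index=normalized.index, name="dispersion")

    if cfg.dispersion_mode == "common":
        common = _common_dispersion_cr(y[informative], garr)
        out = np.full(y.shape[0], max(common, floor))
    else:
        # rolling-median trend over features ordered by mean expression
        order = np.argsort(m)
        window = max(11, (informative.sum() // 10) | 1)
        trend_sorted = (
            pd.Series(alpha[order]).rolling(window, center=True, min_periods=1).median().to_numpy()
        )
        trend = np.empty_like(trend_sorted)
        trend[order] = trend_sorted
        # shrink on the log scale, halfway to the trend
        out = np.exp(0.5 * np.log(np.maximum(alpha, floor)) + 0.5 * np.log(np.maximum(trend, floor)))
        out = np.maximum(out, floor)
    return pd.Series(out, index=normalized.index, name="dispersion")


def _common_dispersion_cr(y: np.ndarray, groups: np.ndarray) -> float:
    """Cox-Reid-adjusted profile likelihood estimate of one shared NB
    dispersion across all features.

    Group means are profiled out with plug-in sample means; the adjustment
    subtracts half the log-determinant of the per-feature information,
    countering the downward bias of profiling means from tiny samples.
    Accepts (size-factor-)normalized counts; the NB log-likelihood is
    evaluated as a quasi-likelihood at non-integer values.
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import gammaln

    labels = pd.unique(groups)
    masks = [groups == g for g in labels]
    mu = np.empty_like(y, dtype=float)
    for mask in masks:
        mu[:, mask] = y[:, mask].mean(axis=1, keepdims=True)
    mu = np.maximum(mu, 1e-8)

    def neg_adj_profile_ll(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        r = 1.0 / a
        ll = float(
            np.sum(gammaln(y + r) - gammaln(r) + y * np.log(a * mu) - (y + r) * np.log1p(a * mu))
        )
        w = mu / (1.0 + a * mu)
        cr = 0.5 * float(sum(np.sum(np.log(w[:, mask].sum(axis=1))) for mask in masks))
        return -(ll - cr)

    res = minimize_scalar(
        neg_adj_profile_ll, bounds=(np.log(1e-8), np.log(100.0)), method="bounded"
    )
    return float(np.exp(res.x))


def _nb_irls_two_group(
    y: np.ndarray,
    offset: np.ndarray,
    is_b: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for the saturated two-group log-link NB GLM.

    Model: log mu_ij = offset_j + b0_i + b1_i * [j in group B].  Returns
    (b0, b1, se_b1) per feature; the Wald SE comes from the Fisher
    information with GLM weights w = mu / (1 + alpha mu).
    """
    eps = 1e-8
    sf = np.exp(offset)
    a_mask, b_mask = ~is_b, is_b
    mu_a = np.maximum((y[:, a_mask] / sf[a_mask]).mean(axis=1), eps)
    mu_b = np.maximum((y[:, b_mask] / sf[b_mask]).mean(axis=1), eps)
    b0 = np.log(mu_a)
    b1 = np.log(mu_b) - np.log(mu_a)
    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * is_b[None, :]
        mu = np.exp(np.clip(eta, -500, 500))
        mu = np.maximum(mu, 1e-300)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        wa = w[:, a_mask].sum(axis=1)
        wb = w[:, b_mask].sum(axis=1)
        za = (w[:, a_mask] * z[:, a_mask]).sum(axis=1) / np.maximum(wa, 1e-300)
        zb = (w[:, b_mask] * z[:, b_mask]).sum(axis=1) / np.maximum(wb, 1e-300)
        new_b0, new_b1 = za, zb - za
        delta = np.max(np.abs(new_b0 - b0) + np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break
    eta = offset[None, :] + b0[:, None] + b1[:, None] * is_b[None, :]
    mu = np.maximum(np.exp(np.clip(eta, -500, 500)), 1e-300)
    w = mu / (1.0 + alpha[:, None] * mu)
    wa = w[:, ~is_b].sum(axis=1)
    wb = w[:, is_b].sum(axis=1)
    se_b1 = np.sqrt(1.0 / np.maximum(wa, 1e-300) + 1.0 / np.maximum(wb, 1e-300))
    return b0, b1, se_b1


def nb_wald_test(
    matrix: pd.DataFrame,
    groups: list[str],
    cfg: DeConfig | None = None,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential-abundance test on a raw count matrix.

    Returns one row per feature: base_mean (mean of normalized counts),
    log2_fold_change (B vs A), lfc_se (log2 scale), wald_p, adjusted_p
    (Benjamini-Hochberg), significant (adjusted_p < alpha_fdr), direction.
    All-zero features are reported with NA statistics and excluded from the
    FDR adjustment.
    """
    cfg = cfg or DeConfig()
    cfg.validate()
    garr = np.asarray(groups)
    labels = list(pd.unique(garr))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(matrix)
    normalized = normalize_counts(matrix, size_factors)
    if dispersions is None:
        dispersions = estimate_dispersion(normalized, groups, cfg)

    y = matrix.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    is_b = garr == labels[1]
    offset = np.log(size_factors.to_numpy(dtype=float))
    alpha = dispersions.to_numpy(dtype=float)

    n_feat = y.shape[0]
    l2fc = np.full(n_feat, np.nan)
    se = np.full(n_feat, np.nan)
    pvals = np.full(n_feat, np.nan)
    if nonzero.any():
        b0, b1, se_b1 = _nb_irls_two_group(y[nonzero], offset, is_b, alpha[nonzero])
        z = np.where(se_b1 > 0, b1 / se_b1, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        l2fc[nonzero] = b1 / LN2
        se[nonzero] = se_b1 / LN2
        pvals[nonzero] = p

    padj = bh_adjust(pd.Series(pvals, index=matrix.index)).to_numpy()
    significant = padj < cfg.alpha_fdr
    direction = np.where(
        np.isnan(l2fc), "na", np.where(l2fc < 0, "down", np.where(l2fc > 0, "up", "none"))
    )
    return pd.DataFrame(
        {
            "base_mean": normalized.mean(axis=1),
            "log2_fold_change": l2fc,
            "lfc_se": se,
            "wald_p": pvals,
            "adjusted_p": padj,
            "significant": np.where(np.isnan(padj), False, significant),
            "direction": direction,
        },
        index=matrix.index,
    )


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaN entries pass through."""
    s = pd.Series(np.asarray(pvalues, dtype=float)) if not isinstance(pvalues, pd.Series) else pvalues.astype(float)
    out = pd.Series(np.nan, index=s.index, dtype=float)
    mask = s.notna()
    if mask.any():
        vals = s[mask].to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def vst_and_pca(
    normalized: pd.DataFrame, cfg: DeConfig | None = None, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """log2(x + pseudo_count) transform, feature centering, PCA of samples.

    Returns (sample coordinates on the principal axes, variance explained
    per axis).  The log2 transform is a pragmatic variance-stabilizer for
    visualization; a closed-form NB VST is an extension hook.
    """
    cfg = cfg or DeConfig()
    if normalized.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    x = np.log2(normalized.to_numpy(dtype=float) + cfg.pseudo_count)
    x = x - x.mean(axis=1, keepdims=True)  # center each feature
    # samples as observations
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    k = min(normalized.shape[1] - 1, x.shape[0])
    if n_components is not None:
        k = min(k, n_components)
    coords = u[:, :k] * s[:k]
    total = float(np.sum(s**2))
    var_explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=normalized.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, var_explained
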