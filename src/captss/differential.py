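"""Two-condition differential TSS-usage testing on the cluster count matrix.

Model: per cluster, a negative-binomial GLM with log link, a single
condition coefficient, and log size factors as offsets,

    K_cs ~ NB(mu_cs, alpha_c),   log mu_cs = beta0_c + beta1_c * x_s + log f_s,

where x_s is the condition indicator and f_s the per-sample size factor
(median-of-ratios).  Variance is mu + alpha * mu^2.  The condition
coefficient is tested by a Wald statistic.  Dispersion is estimated per
cluster by a method-of-moments fit on size-factor-scaled counts solving the
NB variance relation with per-condition means,

    alpha_hat = max(0, (s2_pooled - mean_g m_g) / mean_g m_g^2),

floored at 1e-8 (the Poisson limit); s2_pooled is the within-condition
pooled variance.  Because the dispersion is estimated with very few residual
degrees of freedom, the Wald statistic is referred to a t distribution with
the residual df (n_samples - 2); with a *fixed* dispersion the statistic is
asymptotically normal and a normal reference is used.  There is no
information sharing across clusters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
DEFAULT_ALPHA = 0.05


@dataclass
class CountMatrix:
    """Integer cluster x sample count matrix with a two-level condition factor."""

    counts: pd.DataFrame  # index: cluster_id, columns: sample labels
    condition: pd.Series  # sample label -> condition name

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integers")
        self.condition = self.condition.reindex(counts.columns)
        if self.condition.isna().any():
            missing = list(counts.columns[self.condition.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        levels = self.condition.unique()
        for lv in levels:
            if (self.condition == lv).sum() < 1:
                raise ValueError(f"condition {lv!r} has no samples")

    @property
    def levels(self) -> list[str]:
        return list(pd.unique(self.condition))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over clusters (nonzero in all samples) of
    counts[c, s] / geometric mean over samples of counts[c, .].  If no
    cluster is nonzero in every sample, falls back to total-count ratios
    (normalized to geometric mean 1) with a warning.
    """
    mat = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_pos = np.isfinite(logs).all(axis=1)
    if all_pos.sum() == 0:
        warnings.warn(
            "no cluster has nonzero counts in all samples; "
            "falling back to total-count size factors"
        )
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        loggeo = logs[all_pos].mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs[all_pos] - loggeo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def moments_dispersion(
    counts: pd.DataFrame, factors: pd.Series, condition: pd.Series
) -> np.ndarray:
    """Per-cluster method-of-moments NB dispersion on scaled counts."""
    z = counts.values / factors.values[None, :]
    groups = [np.where((condition == lv).values)[0] for lv in pd.unique(condition)]
    ss = np.zeros(z.shape[0])
    df = 0
    means = []
    for idx in groups:
        zg = z[:, idx]
        m = zg.mean(axis=1)
        means.append(m)
        ss += ((zg - m[:, None]) ** 2).sum(axis=1)
        df += len(idx) - 1
    if df == 0:
        # no replication: Poisson limit
        return np.full(z.shape[0], DISPERSION_FLOOR)
    s2 = ss / df
    means = np.array(means)  # groups x clusters
    mbar = means.mean(axis=0)
    m2bar = (means**2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (s2 - mbar) / m2bar
    return np.maximum(np.nan_to_num(a, nan=0.0), DISPERSION_FLOOR)


def _irls_nb(
    y: np.ndarray, offset: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fisher scoring for per-cluster NB GLMs with design [1, x].

    Returns (beta, se_beta1).  ``y`` is clusters x samples, ``alpha`` per
    cluster.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    g0 = x == 0
    g1 = x == 1
    z = y / np.exp(offset)[None, :]
    m0 = np.maximum(z[:, g0].mean(axis=1), 1e-8)
    m1 = np.maximum(z[:, g1].mean(axis=1), 1e-8)
    beta = np.column_stack([np.log(m0), np.log(m1) - np.log(m0)])
    a = alpha[:, None]
    for _ in range(100):
        eta = beta @ X.T + offset[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + a * mu)
        r = (y - mu) / (1.0 + a * mu)
        u = np.einsum("cs,sk->ck", r, X)
        info = np.einsum("cs,sj,sk->cjk", w, X, X)
        det = info[:, 0, 0] * info[:, 1, 1] - info[:, 0, 1] ** 2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        db0 = (info[:, 1, 1] * u[:, 0] - info[:, 0, 1] * u[:, 1]) / det
        db1 = (-info[:, 0, 1] * u[:, 0] + info[:, 0, 0] * u[:, 1]) / det
        step = np.column_stack([db0, db1])
        beta = beta + step
        if np.nanmax(np.abs(step)) < 1e-10:
            break
    eta = beta @ X.T + offset[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + a * mu)
    info = np.einsum("cs,sj,sk->cjk", w, X, X)
    det = info[:, 0, 0] * info[:, 1, 1] - info[:, 0, 1] ** 2
    var_b1 = info[:, 0, 0] / np.where(np.abs(det) < 1e-12, 1e-12, det)
    return beta, np.sqrt(np.maximum(var_b1, 0.0))


def nb_test(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    dispersion: str | float = "moments",
    reference_level: str | None = None,
) -> pd.DataFrame:
    """Per-cluster NB Wald test of the condition effect.

    ``dispersion`` is either the string ``"moments"`` (per-cluster moment
    estimate; Wald statistic referred to t with residual df) or a fixed
    numeric dispersion (normal reference).  The log2 fold change is
    test-level vs reference level; by default the reference is the first
    condition level in sample order.  All-zero clusters get NaN p-values.
    """
    levels = matrix.levels
    if len(levels) != 2:
        raise ValueError(f"exactly two condition levels required, got {levels}")
    if reference_level is None:
        reference_level = levels[0]
    test_level = next(lv for lv in levels if lv != reference_level)
    if factors is None:
        factors = size_factors(matrix.counts)
    factors = factors.reindex(matrix.counts.columns)

    y = matrix.counts.values.astype(float)
    x = (matrix.condition == test_level).values.astype(int)
    offset = np.log(factors.values)

    if dispersion == "moments":
        alpha = moments_dispersion(matrix.counts, factors, matrix.condition)
        resid_df = len(x) - 2
        ref_dist = stats.t(resid_df) if resid_df >= 1 else stats.norm
    else:
        alpha = np.full(y.shape[0], max(float(dispersion), DISPERSION_FLOOR))
        ref_dist = stats.norm

    beta, se = _irls_nb(y, offset, x, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta[:, 1] / se
    p = 2.0 * ref_dist.sf(np.abs(wald))

    all_zero = (y == 0).all(axis=1)
    log2fc = beta[:, 1] / np.log(2.0)
    log2fc[all_zero] = np.nan
    p = np.asarray(p, dtype=float)
    p[all_zero | ~np.isfinite(wald)] = np.nan

    base_mean = (y / factors.values[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "cluster_id": matrix.counts.index,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "stat": wald,
            "p": p,
            "dispersion": alpha,
        }
    ).set_index("cluster_id")


def adjust_and_classify(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    classify_on: str = "p",
) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment and up/down/ns classification.

    ``classify_on`` chooses the significance column ("p" reproduces a raw
    p < alpha rule; "padj" is the safer FDR-controlling default for new
    analyses).  Direction is the sign of log2FC among significant clusters.
    """
    if classify_on not in ("p", "padj"):
        raise ValueError("classify_on must be 'p' or 'padj'")
    out = results.copy()
    padj = np.full(len(out), np.nan)
    ok = out["p"].notna().values
    if ok.any():
        padj[ok] = multipletests(out["p"].values[ok], method="fdr_bh")[1]
    out["padj"] = padj
    crit = out[classify_on].values
    sig = np.where(np.isnan(crit), False, crit < alpha)
    out["direction"] = np.where(
        sig & (out["log2FC"] > 0), "up", np.where(sig & (out["log2FC"] < 0), "down", "ns")
    )
    return out
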