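"""Inference primitives: NB Wald test, BH adjustment, rank-sum, Cohen's d.

The differential test is a negative-binomial Wald test with fixed size
factors, approximating the DESeq2 procedure used on pre-scaled coverage
summaries: per-feature method-of-moments dispersion with a floor of 1e-4,
shrunk toward a mean-dispersion trend (bin-pooled moment regression over 10
log-mean bins) with an empirical-Bayes moderation weight; group means fitted
by maximum likelihood under the NB GLM with log link; two-sided normal p
values on the Wald statistic log2FC / SE, with the SE carrying a small-sample
adjustment for dispersion-estimation uncertainty.  It is a documented
approximation, not a re-implementation of DESeq2's Cox-Reid dispersion
estimation or apeglm shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

LOG2 = np.log(2.0)
DISPERSION_FLOOR = 1e-4
DISPERSION_CEIL = 10.0
MEAN_PSEUDOCOUNT = 0.1  # added to group means before the ratio when one is 0


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are propagated."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise DataError("p values outside [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


#: prior degrees of freedom of the dispersion trend in the moderation weight
DISPERSION_PRIOR_DF = 20.0
_TREND_BINS = 10


def _moderated_dispersion(norm: np.ndarray, groups: list[np.ndarray]):
    """Moderated per-feature NB dispersion and the Wald SE adjustment.

    Per-feature method-of-moments estimates alpha_i = (var - mu)/mu^2
    (pooled within-group moments, floored at 1e-4) are shrunk toward a
    mean-dispersion trend fitted by bin-pooled moment regression in 10
    quantile bins of log mean.  The shrinkage weight follows an
    empirical-Bayes moderation scheme, w = d / (d + d0) on the per-feature
    estimate with residual df d and prior df d0 = 20; the accompanying SE
    multiplier t(d + d0, 0.975) / z(0.975) propagates the remaining
    dispersion-estimation uncertainty into the normal Wald test, which keeps
    its size close to nominal at small n.
    """
    resid_var = np.zeros(norm.shape[0])
    mean_term = np.zeros(norm.shape[0])
    mean_sq = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        n = sub.shape[1]
        mu = sub.mean(axis=1)
        w = n - 1
        resid_var += w * sub.var(axis=1, ddof=1)
        mean_term += w * mu
        mean_sq += w * mu**2
        den += w
    resid_var /= den
    mean_term /= den
    mean_sq /= den
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_i = (resid_var - mean_term) / mean_sq
    alpha_i = np.where(np.isfinite(alpha_i), alpha_i, DISPERSION_FLOOR)
    alpha_i = np.clip(alpha_i, DISPERSION_FLOOR, DISPERSION_CEIL)

    base_mean = norm.mean(axis=1)
    trend = np.full(norm.shape[0], max(np.median(alpha_i), DISPERSION_FLOOR))
    ok = base_mean > 0
    if ok.sum() >= 2:
        logmu = np.log(base_mean[ok])
        edges = np.unique(np.quantile(logmu, np.linspace(0, 1, _TREND_BINS + 1)))
        if len(edges) >= 2:
            which = np.clip(
                np.searchsorted(edges, logmu, side="right") - 1, 0, len(edges) - 2
            )
            centers, vals = [], []
            for b in range(len(edges) - 1):
                sel = which == b
                if sel.any():
                    centers.append(logmu[sel].mean())
                    # bin-pooled moment regression through the origin
                    vals.append(
                        max(
                            (resid_var[ok][sel] - mean_term[ok][sel]).sum()
                            / max(mean_sq[ok][sel].sum(), 1e-12),
                            DISPERSION_FLOOR,
                        )
                    )
            if len(centers) >= 2:
                trend[ok] = np.interp(logmu, centers, vals)
            elif centers:
                trend[ok] = vals[0]
    trend = np.clip(trend, DISPERSION_FLOOR, DISPERSION_CEIL)

    d = float(sum(len(idx) for idx in groups) - len(groups))
    w = d / (d + DISPERSION_PRIOR_DF)
    alpha = np.clip(w * alpha_i + (1 - w) * trend, DISPERSION_FLOOR, DISPERSION_CEIL)
    se_mult = float(
        stats.t.ppf(0.975, d + DISPERSION_PRIOR_DF) / stats.norm.ppf(0.975)
    )
    return alpha, se_mult


def _nb_group_fit(y: np.ndarray, s: np.ndarray, alpha: np.ndarray):
    """Vectorized NB MLE of the group mean (log link, known dispersion).

    Solves sum_j (y_j - mu s_j) / (1 + alpha mu s_j) = 0 per feature by
    Newton iteration on log mu; returns (mu, fisher information of log mu).
    """
    mu = np.maximum(y.mean(axis=1) / s.mean(), 1e-8)
    eta = np.log(mu)
    for _ in range(50):
        mus = np.exp(eta)[:, None] * s[None, :]
        denom = 1.0 + alpha[:, None] * mus
        score = ((y - mus) / denom).sum(axis=1)
        info = (mus * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(eta)
    # information evaluated at the pseudocount floor for near-zero means, so
    # an all-zero group yields a large but finite SE rather than 0/0
    mu_eff = np.maximum(mu, MEAN_PSEUDOCOUNT)[:, None] * s[None, :]
    fisher = (mu_eff / (1.0 + alpha[:, None] * mu_eff)).sum(axis=1)
    return mu, fisher


def nb_wald_test(
    counts: pd.DataFrame,
    conditions: pd.Series | dict,
    condition_a: str,
    condition_b: str,
    size_factors: pd.Series | None = None,
    shrink_log2fc: bool = False,
    prior_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-feature NB Wald test of condition B over condition A.

    ``counts`` is a feature x sample frame of non-negative integers (or
    integer pseudo-counts derived from scaled coverage); ``conditions``
    maps sample column names to condition labels; ``size_factors`` default
    to 1 (fixed size factors for pre-scaled data).  Returns base_mean,
    log2fc, se, wald_p and BH-adjusted padj (features with all-zero counts
    in both conditions get log2fc 0 and p NaN, excluded from BH).  With
    ``shrink_log2fc`` the estimate is shrunk with a normal prior on the
    log2 fold change (ridge posterior mean, prior SD ``prior_sd``).
    """
    conditions = pd.Series(conditions)
    cols_a = [c for c in counts.columns if conditions.get(c) == condition_a]
    cols_b = [c for c in counts.columns if conditions.get(c) == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ConfigurationError(
            f"need >=2 replicates per condition, got {len(cols_a)} vs {len(cols_b)}"
        )
    cols = cols_a + cols_b
    if size_factors is None:
        sf = np.ones(len(cols))
    else:
        sf = pd.Series(size_factors).reindex(cols).to_numpy(float)
        if np.any(~(sf > 0)):
            raise ConfigurationError("size factors must be > 0")
    y = counts[cols].to_numpy(float)
    if (y < 0).any():
        raise DataError("negative counts")
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols))
    norm = y / sf[None, :]
    base_mean = norm.mean(axis=1)

    alpha, se_mult = _moderated_dispersion(norm, [ia, ib])

    nonzero = y.sum(axis=1) > 0
    mu_a = np.zeros(len(y))
    mu_b = np.zeros(len(y))
    info_a = np.full(len(y), np.nan)
    info_b = np.full(len(y), np.nan)
    if nonzero.any():
        mu_a[nonzero], info_a[nonzero] = _nb_group_fit(
            y[nonzero][:, ia], sf[ia], alpha[nonzero]
        )
        mu_b[nonzero], info_b[nonzero] = _nb_group_fit(
            y[nonzero][:, ib], sf[ib], alpha[nonzero]
        )

    pc = np.where((mu_a == 0) | (mu_b == 0), MEAN_PSEUDOCOUNT, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_b + pc) - np.log2(mu_a + pc)
        se = np.sqrt(1.0 / info_a + 1.0 / info_b) * se_mult / LOG2
    if shrink_log2fc:
        lfc = lfc / (1.0 + (se / prior_sd) ** 2)
    lfc = np.where(nonzero, lfc, 0.0)
    with np.errstate(invalid="ignore"):
        z = lfc / se
    p = np.where(nonzero, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "se": se,
            "wald_p": p,
            "dispersion": alpha,
        },
        index=counts.index,
    )
    out["padj"] = bh_adjust(out["wald_p"].to_numpy())
    return out


def call_significant(
    diff: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 1.5
):
    """Significant up/down feature sets at adjusted p < alpha, |FC| > threshold.

    Returns ``(up, down)`` sets of feature ids; ``diff`` must carry
    ``padj`` and ``log2fc``.
    """
    thr = np.log2(fc_threshold)
    sig = diff["padj"] < alpha
    up = set(diff.index[sig & (diff["log2fc"] > thr)])
    down = set(diff.index[sig & (diff["log2fc"] < -thr)])
    return up, down


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration (ties handled by midranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    e_w = n1 * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - e_w)
    total = comb(len(pooled), n1)
    hits = 0
    for idx in combinations(range(len(pooled)), n1):
        if abs(ranks[list(idx)].sum() - e_w) >= dev - 1e-9:
            hits += 1
    return hits / total


@dataclass
class ClassResponse:
    """Response of one gene class relative to all genes."""

    label: str
    n_class: int
    wilcoxon_p: float
    cohens_d: float
    median_log2fc: float


def cohens_d(x, y) -> float:
    """(mean(x) - mean(y)) / pooled SD; NaN when the pooled variance is 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1) if n1 > 1 else 0.0
    v2 = y.var(ddof=1) if n2 > 1 else 0.0
    df = n1 + n2 - 2
    if df <= 0:
        return float("nan")
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def class_response(
    lfc_all: pd.Series, class_members, label: str = ""
) -> ClassResponse:
    """Wilcoxon rank-sum and Cohen's d of a gene class against all genes.

    The background is the full gene set (class included), mirroring a
    class-vs-all comparison; p values use the normal approximation with tie
    correction, or exact enumeration when both groups have <= 10 members.
    """
    members = [g for g in class_members if g in lfc_all.index]
    if not members:
        raise ConfigurationError(f"class {label!r} has no members in the data")
    x = lfc_all.loc[members].to_numpy(float)
    y = lfc_all.to_numpy(float)
    if len(x) <= 10 and len(y) <= 10:
        p = _exact_ranksum_p(x, y)
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    return ClassResponse(
        label=label,
        n_class=len(x),
        wilcoxon_p=p,
        cohens_d=cohens_d(x, y),
        median_log2fc=float(np.median(x)),
    )
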