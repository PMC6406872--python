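"""Beta-binomial differential tests on protein spectral counts.

Spectral counts are overdispersed relative to a binomial draw from the
per-sample library size: biological replicates share a protein-level
sampling probability that itself varies between replicates. The
beta-binomial model captures this with a mean proportion pi and an
overdispersion theta in (0, 1):

    k_j ~ BetaBinomial(t_j, alpha, beta),
    alpha = pi (1 - theta) / theta,  beta = (1 - pi)(1 - theta) / theta

so that Var(k/t) -> pi(1-pi) theta as t grows; theta -> 0 recovers the
binomial. Group differences are assessed by likelihood-ratio tests:

* multi-group (batch) test: H0 a common (pi, theta) across groups, H1
  group-specific pi_g with shared theta; LRT ~ chi2 with G-1 df.
* paired ("inverted") test: conditional on the pair sum s_r = k_Ar +
  k_Br, k_Ar ~ BetaBinomial(s_r, pi_r, theta) where logit(pi_r) =
  logit(t_Ar / (t_Ar + t_Br)) + delta; H0: delta = 0; LRT ~ chi2, 1 df.

A protein is called differential when the Holm-adjusted p-value is
below alpha AND the largest pairwise fold change of group mean
proportions exceeds the fold-change threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, expit, gammaln, logit

from .compare import holm_adjust

logger = logging.getLogger(__name__)

_EPS = 1e-8
_BOUND = (_EPS, 1.0 - _EPS)


def min_spectra_filter(counts: pd.DataFrame, threshold: int = 4) -> pd.Index:
    """Retain proteins with at least ``threshold`` protein-specific
    spectra in at least one sample."""
    counts = counts.fillna(0)
    return counts.index[counts.max(axis=1) >= threshold]


def _bb_loglik(k: np.ndarray, t: np.ndarray, pi: float, theta: float) -> float:
    """Beta-binomial log-likelihood; theta below 1e-10 falls back to binomial."""
    pi = min(max(pi, _EPS), 1.0 - _EPS)
    theta = min(max(theta, 0.0), 1.0 - _EPS)
    if theta < 1e-10:
        return float(np.sum(
            gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
            + k * np.log(pi) + (t - k) * np.log1p(-pi)
        ))
    a = pi * (1.0 - theta) / theta
    b = (1.0 - pi) * (1.0 - theta) / theta
    return float(np.sum(
        gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
        + betaln(k + a, t - k + b) - betaln(a, b)
    ))


def _moment_start(k: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Moment estimates of (pi, theta) used as optimizer starts."""
    pi0 = float(np.sum(k) / np.sum(t))
    pi0 = min(max(pi0, _EPS), 1.0 - _EPS)
    prop = k / t
    v = float(np.var(prop, ddof=1)) if prop.size > 1 else 0.0
    binom_v = pi0 * (1 - pi0) / float(np.mean(t))
    excess = max(v - binom_v, 0.0)
    denom = pi0 * (1 - pi0)
    theta0 = excess / denom if denom > 0 else 0.0
    theta0 = min(max(theta0, 1e-4), 0.5)
    return pi0, theta0


_THETA_STARTS = (0.001, 0.05, 0.3)


def _fit_common(k: np.ndarray, t: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Maximize the common-(pi, theta) likelihood; returns (loglik, params)."""
    pi0, theta0 = _moment_start(k, t)
    best = (-np.inf, (pi0, theta0))
    for th in (theta0, *_THETA_STARTS):
        res = optimize.minimize(
            lambda x: -_bb_loglik(k, t, x[0], x[1]),
            x0=[pi0, th], method="L-BFGS-B", bounds=[_BOUND, _BOUND],
        )
        if -res.fun > best[0]:
            best = (-res.fun, (float(res.x[0]), float(res.x[1])))
    return best


def _fit_groups(k: np.ndarray, t: np.ndarray, g: np.ndarray,
                theta_per_group: bool = False) -> float:
    """Maximize the group-specific-pi likelihood (shared theta by default)."""
    labels = np.unique(g)
    starts = []
    pis0 = []
    for lab in labels:
        m = g == lab
        pis0.append(_moment_start(k[m], t[m])[0])
    _, theta0 = _moment_start(k, t)
    if theta_per_group:
        def neg(x):
            ll = 0.0
            for i, lab in enumerate(labels):
                m = g == lab
                ll += _bb_loglik(k[m], t[m], x[2 * i], x[2 * i + 1])
            return -ll
        for th in (theta0, *_THETA_STARTS):
            x0 = []
            for p in pis0:
                x0 += [p, th]
            starts.append(x0)
        bounds = [_BOUND] * (2 * len(labels))
    else:
        def neg(x):
            theta = x[-1]
            ll = 0.0
            for i, lab in enumerate(labels):
                m = g == lab
                ll += _bb_loglik(k[m], t[m], x[i], theta)
            return -ll
        for th in (theta0, *_THETA_STARTS):
            starts.append(list(pis0) + [th])
        bounds = [_BOUND] * (len(labels) + 1)
    best = -np.inf
    for x0 in starts:
        res = optimize.minimize(neg, x0=x0, method="L-BFGS-B", bounds=bounds)
        best = max(best, -res.fun)
    return best


def beta_binomial_test(
    k, t, groups, theta_per_group: bool = False
) -> float:
    """Multi-group beta-binomial likelihood-ratio test for one protein.

    Parameters
    ----------
    k : spectral counts per sample.
    t : per-sample library sizes (totals), same length.
    groups : group (batch) label per sample; G >= 2 groups.

    Returns the chi-square (G-1 df) upper-tail p-value of the LRT.
    All-zero counts give p = 1.
    """
    k = np.asarray(k, dtype=float)
    t = np.asarray(t, dtype=float)
    g = np.asarray(groups)
    if not (k.shape == t.shape == g.shape):
        raise ValueError("k, t and groups must have equal length")
    if np.any(k > t):
        raise ValueError("counts exceed library sizes")
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if k.sum() == 0:
        return 1.0
    ll0, _ = _fit_common(k, t)
    ll1 = _fit_groups(k, t, g, theta_per_group=theta_per_group)
    lam = max(2.0 * (ll1 - ll0), 0.0)
    df = (labels.size - 1) * (2 if theta_per_group else 1)
    return float(stats.chi2.sf(lam, df))


def inverted_beta_binomial_test(k_a, k_b, t_a, t_b) -> float:
    """Paired beta-binomial ("inverted") test for one protein.

    Conditions each pair on its count sum s_r = k_Ar + k_Br; under the
    null, k_Ar follows a beta-binomial whose mean proportion is the
    library-size share t_Ar / (t_Ar + t_Br). The alternative shifts all
    pairs by a common log-odds offset. Pairs with s_r = 0 carry no
    information; all-zero data give p = 1.
    """
    k_a = np.asarray(k_a, dtype=float)
    k_b = np.asarray(k_b, dtype=float)
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if not (k_a.shape == k_b.shape == t_a.shape == t_b.shape):
        raise ValueError("paired arrays must have equal length")
    if k_a.size < 2:
        raise ValueError("need at least two pairs")
    s = k_a + k_b
    keep = s > 0
    if not keep.any():
        return 1.0
    k = k_a[keep]
    n = s[keep]
    base = logit(np.clip(t_a[keep] / (t_a[keep] + t_b[keep]), _EPS, 1 - _EPS))

    def loglik(delta: float, theta: float) -> float:
        pi = expit(base + delta)
        pi = np.clip(pi, _EPS, 1 - _EPS)
        theta = min(max(theta, 0.0), 1.0 - _EPS)
        if theta < 1e-10:
            return float(np.sum(
                gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                + k * np.log(pi) + (n - k) * np.log1p(-pi)
            ))
        a = pi * (1 - theta) / theta
        b = (1 - pi) * (1 - theta) / theta
        return float(np.sum(
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + betaln(k + a, n - k + b) - betaln(a, b)
        ))

    # maximize over (delta, theta); the fitted theta is then plugged into
    # the null (delta = 0) likelihood. Leaving theta free under the null
    # would let overdispersion absorb a consistent paired shift.
    best = (-np.inf, 0.05)
    p_hat = np.clip(k.sum() / n.sum(), _EPS, 1 - _EPS)
    d0 = float(logit(p_hat) - np.mean(base))
    for th in _THETA_STARTS:
        res = optimize.minimize(
            lambda x: -loglik(x[0], x[1]), x0=[d0, th],
            method="L-BFGS-B", bounds=[(-50, 50), _BOUND],
        )
        if -res.fun > best[0]:
            best = (-res.fun, float(res.x[1]))
    ll1, theta_hat = best
    ll0 = loglik(0.0, theta_hat)
    lam = max(2.0 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lam, 1))


def pairwise_fold_changes(
    counts: pd.DataFrame, totals: pd.Series, groups: pd.Series
) -> pd.Series:
    """Max pairwise fold change of group mean count proportions.

    A group mean of zero is floored at half the smallest positive group
    mean observed anywhere in the table (logged), so ratios stay finite.
    """
    prop = counts.div(totals, axis=1)
    group_means = prop.T.groupby(groups).mean().T
    arr = group_means.to_numpy()
    positive = arr[arr > 0]
    floor = positive.min() / 2.0 if positive.size else 1.0
    if (arr <= 0).any():
        logger.info("floored %d zero group-mean proportion(s) at %.3g",
                    int((arr <= 0).sum()), floor)
    arr = np.maximum(arr, floor)
    fc = arr.max(axis=1) / arr.min(axis=1)
    return pd.Series(fc, index=counts.index, name="max_pairwise_fc")


def call_differential(
    raw_p: pd.Series,
    fold_changes: pd.Series,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Holm-correct raw p-values and call differential proteins.

    ``is_different`` requires both a Holm-adjusted p below ``alpha``
    and a max pairwise fold change above ``fc_threshold``.
    """
    holm = pd.Series(holm_adjust(raw_p.to_numpy()), index=raw_p.index)
    fc = fold_changes.reindex(raw_p.index)
    out = pd.DataFrame({
        "raw_p": raw_p,
        "holm_p": holm,
        "max_pairwise_fc": fc,
        "is_different": (holm < alpha) & (fc > fc_threshold),
    })
    return out


def batch_stability(
    counts: pd.DataFrame,
    groups: pd.Series,
    min_spectra: int = 4,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    theta_per_group: bool = False,
) -> pd.DataFrame:
    """Batch-to-batch stability screen over a spectral-count matrix.

    Filters to proteins with >= ``min_spectra`` specific spectra in
    some sample, takes library sizes as the column sums of the retained
    counts, tests each protein with the multi-group beta-binomial LRT,
    and calls differential proteins per ``call_differential``.
    """
    counts = counts.fillna(0)
    retained = min_spectra_filter(counts, threshold=min_spectra)
    sub = counts.loc[retained]
    totals = sub.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample has zero total retained spectra")
    g = groups.loc[sub.columns].to_numpy()
    t = totals.to_numpy(dtype=float)
    pvals = pd.Series(
        [beta_binomial_test(sub.loc[acc].to_numpy(dtype=float), t, g,
                            theta_per_group=theta_per_group)
         for acc in sub.index],
        index=sub.index, name="raw_p",
    )
    fc = pairwise_fold_changes(sub, totals, groups.loc[sub.columns])
    return call_differential(pvals, fc, alpha=alpha, fc_threshold=fc_threshold)
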