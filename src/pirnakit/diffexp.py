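"""Per-tag expression quantification and two-group differential expression.

Expression is reported as TPM (count / library size x 1e6 over quantified
tags). Differential expression between two phases uses an in-package
negative-binomial exact-style test: median-of-ratios size factors,
moment-based dispersion pooled across tags of similar mean, and a
two-sided p-value from the NB probability of the observed split of each
tag's total count between the two groups. The screening thresholds are
raw p-value < 0.05, fold change > 2.0 (two-sided) and read counts > 10,
applied simultaneously; a Benjamini-Hochberg column is emitted in
addition but does not enter the screen.

The 2^-ddCt helper for qPCR relative quantification lives here too.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from pirnakit.io import ValidationError

_MIN_DISPERSION = 1e-8


def tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Transcripts-per-million per sample over the quantified tags.

    ``TPM_ij = count_ij / libsize_j * 1e6`` with ``libsize_j`` the column
    sum; every column of the result sums to 1e6.
    """
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValidationError(f"samples with zero library size: {bad}")
    return counts.div(libsize, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    factor_j = median over tags of count_ij / geometric_mean_i, computed
    over tags with all-positive counts, then rescaled so the median factor
    is 1 (a pure scale choice: downstream statistics are invariant to it,
    and an unperturbed sample keeps factor 1).
    """
    logc = np.log(counts.where(counts > 0))
    all_positive = logc.notna().all(axis=1)
    if not all_positive.any():
        raise ValidationError("no tag has positive counts in every sample")
    logc = logc[all_positive]
    log_ratios = logc.sub(logc.mean(axis=1), axis=0)
    sf = np.exp(log_ratios.median(axis=0))
    return sf / sf.median()


def _dispersion_trend(mean: np.ndarray, raw_alpha: np.ndarray) -> np.ndarray:
    """Local (rolling-median) smoothing of per-tag moment dispersions
    across tags ordered by mean, floored at a small positive value."""
    n = len(mean)
    order = np.argsort(mean, kind="stable")
    sorted_alpha = raw_alpha[order]
    window = max(25, n // 20)
    smoothed = (
        pd.Series(sorted_alpha)
        .rolling(window=2 * window + 1, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    out = np.empty(n)
    out[order] = smoothed
    out = np.where(np.isfinite(out), out, _MIN_DISPERSION)
    return np.maximum(out, _MIN_DISPERSION)


def estimate_dispersions(
    norm_counts: pd.DataFrame, groups: pd.Series
) -> pd.Series:
    """Per-tag NB dispersion alpha (variance = mu + alpha mu^2).

    Method of moments on normalized counts with within-group pooling,
    then a local-median trend across tags of similar mean. The counting-
    noise term uses the mean reciprocal size-adjustment implicitly equal
    to 1 on normalized counts.
    """
    labels = groups.unique()
    mean = norm_counts.mean(axis=1).to_numpy()
    pooled_num = np.zeros(len(norm_counts))
    pooled_df = 0
    for g in labels:
        cols = groups.index[groups == g]
        sub = norm_counts[cols]
        if len(cols) >= 2:
            pooled_num += sub.var(axis=1, ddof=1).to_numpy() * (len(cols) - 1)
            pooled_df += len(cols) - 1
    var = pooled_num / max(pooled_df, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_alpha = (var - mean) / np.square(mean)
    trend = _dispersion_trend(mean, raw_alpha)
    return pd.Series(trend, index=norm_counts.index)


def _nb_logpmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def _split_pvalue(ka: int, kb: int, mu_a: float, mu_b: float, alpha_a: float, alpha_b: float) -> float:
    """Two-sided exact-style p-value of the (ka, kb) split of S = ka + kb.

    Sums the probabilities of all splits no more likely than the observed
    one under independent NB models for the two group sums, normalized by
    the total probability of the splits (conditioning on S).
    """
    S = ka + kb
    if S == 0:
        return 1.0
    ks = np.arange(S + 1)
    lp = _nb_logpmf(ks, mu_a, alpha_a) + _nb_logpmf(S - ks, mu_b, alpha_b)
    lp_obs = lp[ka]
    selected = lp <= lp_obs + 1e-10
    return float(np.exp(logsumexp(lp[selected]) - logsumexp(lp)))


def nb_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    numerator: str | None = None,
    denominator: str | None = None,
    dispersion: float | pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial test for differential expression between two groups.

    Parameters
    ----------
    counts
        Raw integer counts, tags x samples.
    groups
        Sample -> group label (exactly two labels, each with >= 2 samples).
    numerator, denominator
        Which group is the fold-change numerator (defaults to the two
        labels in sorted order).
    dispersion
        Override the moment/trend dispersion estimate (useful for the
        Poisson limit ``dispersion=0``).

    Returns a DataFrame indexed like ``counts`` with normalized group
    means, raw-count group means, log2 fold change (pseudocount 0.5),
    p-value and BH-adjusted p-value.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[counts.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    if numerator is None or denominator is None:
        numerator, denominator = labels
    if {numerator, denominator} != set(labels):
        raise ValidationError("numerator/denominator must be the two group labels")
    cols_a = list(groups.index[groups == numerator])
    cols_b = list(groups.index[groups == denominator])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("each group needs at least two samples")

    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    q0 = norm.mean(axis=1).to_numpy()

    if dispersion is None:
        alpha = estimate_dispersions(norm, groups).to_numpy()
    elif np.isscalar(dispersion):
        alpha = np.full(len(counts), max(float(dispersion), _MIN_DISPERSION))
    else:
        alpha = np.maximum(pd.Series(dispersion).loc[counts.index].to_numpy(), _MIN_DISPERSION)

    sa = sf[cols_a].to_numpy()
    sb = sf[cols_b].to_numpy()
    Sa, Sb = sa.sum(), sb.sum()
    # Group sums are modelled as NB with moment-matched dispersion:
    # Var(sum) = q0*S + alpha*q0^2*sum(s_j^2)  =>  alpha_sum = alpha*sum(s^2)/S^2.
    ka = counts[cols_a].sum(axis=1).round().astype(int).to_numpy()
    kb = counts[cols_b].sum(axis=1).round().astype(int).to_numpy()
    mu_a = q0 * Sa
    mu_b = q0 * Sb
    alpha_a = alpha * (sa**2).sum() / Sa**2
    alpha_b = alpha * (sb**2).sum() / Sb**2

    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if q0[i] <= 0:
            continue
        pvals[i] = _split_pvalue(ka[i], kb[i], mu_a[i], mu_b[i], alpha_a[i], alpha_b[i])

    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    padj = multipletests(pvals, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "base_mean": q0,
            f"mean_{numerator}": mean_a,
            f"mean_{denominator}": mean_b,
            f"mean_count_{numerator}": counts[cols_a].mean(axis=1),
            f"mean_count_{denominator}": counts[cols_b].mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
        },
        index=counts.index,
    )
    df.attrs["groups"] = (numerator, denominator)
    return df


def call_de(
    results: pd.DataFrame,
    p_max: float = 0.05,
    fc_min: float = 2.0,
    count_min: float = 10.0,
) -> pd.DataFrame:
    """Flag differentially expressed tags at the joint screen.

    A tag is called when simultaneously p < ``p_max``, fold change > ``fc_min``
    in either direction (strict), and the larger of the two group mean raw
    counts exceeds ``count_min`` (strict). Direction is reported as
    ``up_in_<group>`` from the sign of the log2 fold change.
    """
    numerator, denominator = results.attrs.get("groups", ("A", "B"))
    ca, cb = f"mean_count_{numerator}", f"mean_count_{denominator}"
    fold = np.power(2.0, results["log2fc"])
    eligible = np.maximum(results[ca], results[cb]) > count_min
    sig = (results["pvalue"] < p_max) & ((fold > fc_min) | (fold < 1.0 / fc_min)) & eligible
    direction = np.where(
        ~sig, "ns", np.where(results["log2fc"] > 0, f"up_in_{numerator}", f"up_in_{denominator}")
    )
    out = results.copy()
    out["eligible"] = eligible
    out["direction"] = direction
    out.attrs["groups"] = (numerator, denominator)
    return out


def ddct(records: pd.DataFrame, calibrator_group: str) -> pd.Series:
    """Relative expression per group by the 2^-ddCt method.

    ``records`` needs columns sample, group, ct_target, ct_reference.
    dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt(group) -
    mean dCt(calibrator); relative expression = 2^-ddCt (calibrator = 1).
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValidationError("missing Ct values in qPCR table")
    if calibrator_group not in set(records["group"]):
        raise ValidationError(f"calibrator group {calibrator_group!r} absent from table")
    dct = records["ct_target"] - records["ct_reference"]
    mean_dct = dct.groupby(records["group"]).mean()
    ddct_values = mean_dct - mean_dct[calibrator_group]
    return np.power(2.0, -ddct_values).rename("relative_expression")
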