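"""Empirical-Bayes moderated one-sample t-test, BH FDR, and bait-enrichment z.

The moderated test shrinks each site's sample variance s2 (from n replicate
log2 ratios, d = n - 1 residual df) toward a pooled prior variance s0^2 with
prior df d0, both estimated from all sites in a condition by fitting a
scaled inverse-chi-square distribution to the observed variances:

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d)
    t_mod   = mean / sqrt(s2_post / n),   df_total = d0 + d

The hyperparameters are obtained by the method of moments on log variances
(digamma/trigamma matching). With d0 = 0 the test reduces to the ordinary
one-sample t; with d0 = infinity it becomes a z-test against s0^2.

Everything here is implemented from the closed-form equations; no external
statistics package is called.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from . import quant

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


class DegenerateInputError(ValueError):
    """Variance pool carries no usable information for prior estimation."""


@dataclass
class PriorEstimate:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float          # prior degrees of freedom; may be math.inf
    s0_squared: float  # prior variance


@dataclass
class ModeratedTestResult:
    site_id: str
    condition: str
    n: int
    mean_log2FC: float
    s2: float
    s2_post: float
    t_mod: float
    df_total: float
    p: float
    fdr: float = math.nan


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma).

    Monotone decreasing target; the iteration below converges for any y > 0.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(variances, df) -> PriorEstimate:
    """Fit (d0, s0^2) to observed sample variances by moment matching.

    ``df`` is the residual df of each variance (scalar or array). Variances
    that are zero or non-finite carry no scale information on the log scale
    and are excluded; at least two positive variances are required.

    When the spread of log variances does not exceed what sampling noise
    alone predicts, the prior is degenerate at a point: d0 = infinity and
    s0^2 = the mean observed variance.
    """
    v = np.asarray(variances, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), v.shape)
    ok = np.isfinite(v) & (v > 0) & np.isfinite(d) & (d > 0)
    if v.size and not ok.all():
        logger.debug("excluding %d non-positive variances from prior fit",
                     int((~ok).sum()))
    v, d = v[ok], d[ok]
    if v.size < 2:
        raise DegenerateInputError(
            "need at least two positive finite variances to estimate the prior"
        )
    # E[log s2] = log s0^2 + digamma(d/2) - log(d/2) + [digamma(d0/2) terms];
    # matching mean and excess variance of e identifies (d0, s0^2).
    e = np.log(v) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_squared = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_squared = float(np.mean(v))
    return PriorEstimate(d0=d0, s0_squared=s0_squared)


def _moderated_arrays(means, s2, n, d0, s0_squared):
    """Vectorized core: returns (s2_post, t, df_total, p) arrays."""
    means = np.asarray(means, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), means.shape)
    d = n - 1.0
    if math.isinf(d0):
        s2_post = np.full_like(means, s0_squared)
        df_total = np.full_like(means, np.inf)
    else:
        s2_post = (d0 * s0_squared + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, means / se,
                     np.where(means == 0, 0.0, np.sign(means) * np.inf))
    if math.isinf(d0):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    # extreme t underflows sf to 0; clamp to keep p in (0, 1]
    p = np.clip(p, _TINY_P, 1.0)
    return s2_post, t, df_total, p


def moderated_t(values, d0: float, s0_squared: float,
                site_id: str = "", condition: str = "") -> ModeratedTestResult:
    """Moderated one-sample t-test of mean zero on replicate log2FC values.

    Missing values (NaN) are dropped; fewer than two remaining replicates
    yields an NA result rather than an error, mirroring how sparsely
    quantified sites are reported.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < 2:
        return ModeratedTestResult(site_id, condition, n, math.nan, math.nan,
                                   math.nan, math.nan, math.nan, math.nan)
    mean = float(np.mean(arr))
    s2 = float(np.var(arr, ddof=1))
    s2_post, t, df_total, p = _moderated_arrays(
        np.array([mean]), np.array([s2]), np.array([n]), d0, s0_squared
    )
    return ModeratedTestResult(site_id, condition, n, mean, s2,
                               float(s2_post[0]), float(t[0]),
                               float(df_total[0]), float(p[0]))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1).

    adj_(i) = min over j >= i of p_(j) * m / j, for p sorted ascending.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def bait_enrichment_z(bait_intensities, control_intensities,
                      floor: float | None = None) -> float:
    """AP-MS bait-enrichment z-score: (mean(bait) - mean(control)) / sd(control).

    Missing control intensities are imputed with ``floor`` (default: half the
    smallest observed nonzero intensity across bait and controls). A control
    spread of zero after imputation yields +inf with a warning, signalling
    enrichment beyond what the controls can scale.
    """
    bait = np.asarray(bait_intensities, dtype=float)
    control = np.asarray(control_intensities, dtype=float)
    bait = bait[np.isfinite(bait)]
    if bait.size == 0:
        raise ValueError("no finite bait intensities")
    if control.size < 2:
        raise ValueError("need at least two control intensities")
    if not np.isfinite(control).any():
        raise ValueError("all control intensities missing")
    if floor is None:
        observed = np.concatenate([bait, control[np.isfinite(control)]])
        positive = observed[observed > 0]
        if positive.size == 0:
            raise ValueError("cannot derive imputation floor: no positive intensities")
        floor = float(positive.min()) / 2.0
    control = np.where(np.isfinite(control), control, floor)
    sd = float(np.std(control, ddof=1))
    diff = float(np.mean(bait) - np.mean(control))
    if sd == 0:
        warnings.warn("control spread is zero after imputation; z-score is infinite",
                      RuntimeWarning, stacklevel=2)
        return math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
    return diff / sd


# ---------------------------------------------------------------------------
# table-level driver


def test_condition(norm_table: pd.DataFrame, condition: str,
                   min_replicates: int = 2,
                   prior: PriorEstimate | None = None) -> pd.DataFrame:
    """Moderated test of every site in one condition against zero log2FC.

    Sites quantified in fewer than ``min_replicates`` replicates get NA
    statistics and are excluded from FDR correction. The variance prior is
    pooled across all testable sites within the condition unless one is
    supplied.
    """
    sub = norm_table[norm_table["condition"] == condition]
    rep_cols = quant.replicate_columns(norm_table)
    values = sub[rep_cols].to_numpy(dtype=float)
    n = np.isfinite(values).sum(axis=1)
    testable = n >= max(2, min_replicates)

    means = np.full(len(sub), np.nan)
    s2 = np.full(len(sub), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means[testable] = np.nanmean(values[testable], axis=1)
        s2[testable] = np.nanvar(values[testable], axis=1, ddof=1)

    if prior is None:
        try:
            prior = estimate_prior(s2[testable], n[testable] - 1)
        except DegenerateInputError:
            # all testable variances are zero (noise-free data): a point
            # prior at zero variance; the t statistic guard handles se = 0
            logger.info("condition %s: variance pool degenerate; using point "
                        "prior at zero", condition)
            prior = PriorEstimate(d0=math.inf, s0_squared=0.0)

    out = pd.DataFrame({
        "site_id": sub["site_id"].to_numpy(),
        "condition": condition,
        "n_replicates": n,
        "mean_log2FC": means,
        "summary_log2FC": sub["summary_log2FC"].to_numpy(dtype=float),
        "s2": s2,
        "s2_post": np.nan,
        "t_mod": np.nan,
        "df_total": np.nan,
        "p": np.nan,
        "fdr": np.nan,
        "d0": prior.d0,
        "s0_squared": prior.s0_squared,
    })
    if testable.any():
        s2_post, t, df_total, p = _moderated_arrays(
            means[testable], s2[testable], n[testable],
            prior.d0, prior.s0_squared,
        )
        out.loc[testable, "s2_post"] = s2_post
        out.loc[testable, "t_mod"] = t
        out.loc[testable, "df_total"] = df_total
        out.loc[testable, "p"] = p
        out.loc[testable, "fdr"] = bh_fdr(p)
    return out


def test_all_conditions(norm_table: pd.DataFrame, min_replicates: int = 2,
                        global_fdr: bool = False) -> pd.DataFrame:
    """Run the moderated test per condition; FDR per condition by default.

    ``global_fdr=True`` re-adjusts all p-values jointly across conditions
    instead (a stricter, study-wide correction).
    """
    conditions = list(dict.fromkeys(norm_table["condition"]))
    parts = [test_condition(norm_table, c, min_replicates) for c in conditions]
    results = pd.concat(parts, ignore_index=True)
    if global_fdr:
        tested = results["p"].notna()
        results.loc[tested, "fdr"] = bh_fdr(results.loc[tested, "p"].to_numpy())
    return results
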