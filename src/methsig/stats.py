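"""Statistical primitives shared by every pipeline stage.

Tail probabilities are accumulated in log space via log-gamma so that
enrichment p-values remain exact far below the smallest positive float
(methylation enrichment results routinely reach p < 1e-200).  Every test
returns a :class:`TailTestResult` carrying both ``p_value`` (possibly
underflowed to 0.0) and ``log10_p`` (always finite for nonzero tails).

Sign conventions: effects are "invasive minus non-invasive" throughout the
package, so a DiffScore of -30 means hypomethylated (or downregulated) in
the invasive group at p = 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

_LN10 = math.log(10.0)

__all__ = [
    "TailTestResult",
    "hypergeometric_tail",
    "log10_binomial_tail",
    "bh_fdr",
    "welch_t_test",
    "pooled_t_from_summary",
    "moderated_t_table",
    "diff_score",
    "ihc_total_score",
]


@dataclass(frozen=True)
class TailTestResult:
    """Outcome of a tail test.

    ``p_value`` is ``10**log10_p`` whenever that is representable; for
    deeper tails ``p_value`` is 0.0 and ``log10_p`` carries the value.
    """

    statistic: float
    p_value: float
    log10_p: float
    df: float | None = None
    method: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.log10_p <= 0.0 or math.isnan(self.log10_p)):
            raise ParameterError(f"log10_p must be <= 0, got {self.log10_p}")


def _result_from_log10(statistic: float, log10_p: float, **kw) -> TailTestResult:
    p = 10.0 ** log10_p if log10_p > -320 else 0.0
    return TailTestResult(statistic=statistic, p_value=min(p, 1.0), log10_p=min(log10_p, 0.0), **kw)


def _log_comb(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeometric_tail(universe_size: int, category_size: int, draw_size: int,
                        observed: int) -> TailTestResult:
    """Upper tail P(X >= observed) for X ~ Hypergeometric(N, K, n).

    ``observed <= 0`` gives p = 1; ``observed > min(K, n)`` gives p = 0.
    Computed by log-gamma accumulation, so the tail is exact in log space.
    """
    N, K, n, k = (int(universe_size), int(category_size), int(draw_size), int(observed))
    if N < 0 or K < 0 or n < 0:
        raise ParameterError("counts must be non-negative")
    if K > N or n > N:
        raise ParameterError(f"category_size ({K}) and draw_size ({n}) must not exceed universe_size ({N})")
    kmax = min(K, n)
    kmin = max(0, n + K - N)
    if k <= kmin or k <= 0:
        return TailTestResult(float(k), 1.0, 0.0, method="hypergeometric")
    if k > kmax:
        return TailTestResult(float(k), 0.0, -math.inf, method="hypergeometric")
    j = np.arange(k, kmax + 1)
    logpmf = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    log10_p = float(special.logsumexp(logpmf)) / _LN10
    return _result_from_log10(float(k), log10_p, method="hypergeometric")


def log10_binomial_tail(n: int, k: int, p0: float) -> TailTestResult:
    """Upper tail P(X >= k) for X ~ Binomial(n, p0), stable in log space.

    Used for enrichment of a subset against a background *fraction* (e.g.
    the 21% of array CpGs that fall in enhancers) when no finite universe
    count is available.
    """
    n, k = int(n), int(k)
    if not (0.0 < p0 < 1.0):
        raise ParameterError(f"background probability must lie in (0,1), got {p0}")
    if not (0 <= k <= n):
        raise ParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k <= 0:
        return TailTestResult(float(k), 1.0, 0.0, method="binomial")
    j = np.arange(k, n + 1)
    logpmf = _log_comb(n, j) + j * math.log(p0) + (n - j) * math.log1p(-p0)
    log10_p = float(special.logsumexp(logpmf)) / _LN10
    return _result_from_log10(float(k), log10_p, method="binomial")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_VAR_FLOOR = 1e-12


def welch_t_test(group_a, group_b) -> TailTestResult:
    """Two-sided Welch t test with Welch-Satterthwaite degrees of freedom.

    A variance floor of 1e-12 is added to each group variance so that
    constant groups do not divide by zero; such results are flagged
    ``degenerate``.  Identical constant groups give t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    va = float(np.var(a, ddof=1)) + _VAR_FLOOR
    vb = float(np.var(b, ddof=1)) + _VAR_FLOOR
    degenerate = np.var(a, ddof=1) < _VAR_FLOOR and np.var(b, ddof=1) < _VAR_FLOOR
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (float(a.mean()) - float(b.mean())) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if t == 0.0:
        return TailTestResult(0.0, 1.0, 0.0, df=df, method="welch", degenerate=degenerate)
    log10_p = (math.log(2.0) + sps.t.logsf(abs(t), df)) / _LN10
    return _result_from_log10(t, log10_p, df=df, method="welch", degenerate=degenerate)


def pooled_t_from_summary(n1: int, mean1: float, sd1: float,
                          n2: int, mean2: float, sd2: float) -> TailTestResult:
    """Student two-sample pooled-variance t from summary statistics.

    Accepts printed (n, mean, SD) triplets, e.g. from immunohistochemistry
    score tables; df = n1 + n2 - 2, two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    degenerate = sp2 < _VAR_FLOOR
    sp2 += _VAR_FLOOR
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if degenerate and mean1 == mean2:
        return TailTestResult(0.0, 1.0, 0.0, df=df, method="pooled_t", degenerate=True)
    log10_p = (math.log(2.0) + sps.t.logsf(abs(t), df)) / _LN10
    return _result_from_log10(t, log10_p, df=float(df), method="pooled_t", degenerate=degenerate)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on the log scale (monotone, convex); matches the
    # standard empirical-Bayes variance-moderation literature.
    if y <= 0:
        raise ParameterError("trigamma inverse needs y > 0")
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


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit a scaled F prior to observed variances by moments of log(s2).

    Returns (prior_df d0, prior_variance s0^2); d0 = inf when the observed
    spread of log-variances is no larger than expected from chi-square
    sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return math.inf, float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else _VAR_FLOOR
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_t_table(mean_diff: np.ndarray, s2_pooled: np.ndarray, df_resid: np.ndarray,
                      n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated pooled t over a table of features.

    Shrinks each feature's pooled variance toward a prior fitted across
    all features (scaled-F / inverse-chi-square model), adding the prior
    degrees of freedom to the residual df.  Returns (t, p_two_sided, df).
    With only a handful of samples per group this is the standard way to
    make array-scale differential testing well powered; with thousands of
    features behaving homoscedastically it approaches a z test.
    """
    mean_diff = np.asarray(mean_diff, dtype=float)
    s2 = np.asarray(s2_pooled, dtype=float)
    df_resid = np.asarray(df_resid, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    d0, s0_sq = fit_f_dist(s2, df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df_resid, 1e6)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return t, np.clip(p, 0.0, 1.0), df_total


def diff_score(delta: float, p_value: float) -> float:
    """Illumina-convention signed score 10*sign(delta)*(-log10 p).

    |13| corresponds to p ~ 0.05 and |30| to p = 0.001, preserving the
    familiar DiffScore thresholds; delta = 0 maps to 0.
    """
    if p_value <= 0 or p_value > 1:
        raise ParameterError(f"p_value must lie in (0, 1], got {p_value}")
    if delta == 0:
        return 0.0
    return 10.0 * math.copysign(1.0, delta) * (-math.log10(p_value))


def diff_score_array(delta: np.ndarray, p: np.ndarray, p_floor: float = 1e-300) -> np.ndarray:
    """Vectorised :func:`diff_score`; p is floored to keep scores finite."""
    delta = np.asarray(delta, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), p_floor, 1.0)
    return np.where(delta == 0, 0.0, 10.0 * np.sign(delta) * (-np.log10(p)))


def ihc_total_score(intensity: int, proportion: int) -> int:
    """Total immunostaining score: intensity (0-3) plus proportion (0-7)."""
    if intensity not in range(0, 4):
        raise ParameterError(f"intensity score must be 0..3, got {intensity}")
    if proportion not in range(0, 8):
        raise ParameterError(f"proportion score must be 0..7, got {proportion}")
    return intensity + proportion
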