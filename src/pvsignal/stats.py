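"""Disproportionality statistics on 2x2 drug-event contingency tables.

Every measure is built from the same report-level table::

                    target ADE   other ADEs
    target drug         a            b
    other drugs         c            d

with N = a + b + c + d.  Four families are implemented:

* ROR  - reporting odds ratio ``ad/bc`` with a lognormal Wald interval,
* PRR  - proportional reporting ratio ``a(c+d)/(c(a+b))`` paired with the
  uncorrected Pearson chi-squared statistic,
* BCPNN information component ``IC = log2(a*N / ((a+c)(a+b)))`` with a
  credibility bound from the Bayesian posterior-variance approximation,
* EBGM - the relative reporting ratio ``a*N / ((a+c)(a+b))`` (identical to
  ``2**IC``) with a lognormal interval; an optional empirical-Bayes
  gamma-Poisson shrinkage variant is available separately.

Zero cells make a statistic undefined; undefined values are reported as NaN
(never silently as 0) so that screening criteria fail them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats as sps

__all__ = [
    "ContingencyTable",
    "Thresholds",
    "SignalDecision",
    "ror_stat",
    "prr_stat",
    "ic_stat",
    "ebgm_stat",
    "classify_signal",
    "bonferroni",
    "metrics_frame",
    "mgps_ebgm",
]

_LN2 = math.log(2.0)
_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug-event pair over the full case universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty contingency table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class StatResult:
    """A point estimate with its 95% interval; NaN fields mean undefined."""

    estimate: float
    lower: float
    upper: float
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    def __iter__(self):
        return iter((self.estimate, self.lower, self.upper))


def _undefined(reason: str) -> StatResult:
    return StatResult(math.nan, math.nan, math.nan, reason)


def ror_stat(t: ContingencyTable) -> StatResult:
    """Reporting odds ratio ``ad/bc`` with lognormal 95% CI.

    Undefined (NaN) whenever any cell is zero, since both the estimate and
    the Woolf standard error ``sqrt(1/a+1/b+1/c+1/d)`` require positive cells.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return _undefined("zero cell")
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return StatResult(ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se))


def prr_stat(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and uncorrected Pearson chi-squared.

    ``PRR = a(c+d) / (c(a+b))``;  the chi-squared statistic is the classic
    ``(ad-bc)^2 N / ((a+b)(c+d)(a+c)(b+d))`` without continuity correction.
    Returns ``(nan, nan)`` when a margin in either denominator is zero.
    """
    if t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return (math.nan, math.nan)
    prr = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom == 0:
        return (prr, math.nan)
    chi2 = (t.a * t.d - t.b * t.c) ** 2 * t.n / denom
    return (prr, chi2)


def _bate_ic_variance(a: float, ab: float, ac: float, n: float) -> float:
    """Posterior variance of the information component (Bate-style BCPNN).

    Uses the standard non-informative priors alpha1 = beta1 = 1,
    alpha = beta = 2, gamma11 = 1 with
    ``gamma = gamma11 (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1))``.
    """
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
    v = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
        + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
    )
    return v / (_LN2 ** 2)


def ic_stat(t: ContingencyTable, variance: str = "bate") -> tuple[float, float]:
    """Information component ``log2(a N / ((a+c)(a+b)))`` and its lower bound.

    The point estimate is the observed/expected log2 ratio.  The 95% lower
    credibility bound is ``IC - 2 sqrt(V(IC))`` where ``V(IC)`` is the
    Bayesian posterior-variance approximation (``variance="bate"``, default)
    or the large-count profile approximation ``IC025 ~ IC - 3.3 a^-1/2 -
    2 a^-3/2`` (``variance="approx"``).
    """
    if t.a == 0:
        return (math.nan, math.nan)
    ic = math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))
    if variance == "bate":
        v = _bate_ic_variance(t.a, t.a + t.b, t.a + t.c, t.n)
        return (ic, ic - 2.0 * math.sqrt(v))
    if variance == "approx":
        return (ic, ic - 3.3 * t.a ** -0.5 - 2.0 * t.a ** -1.5)
    raise ValueError(f"unknown IC variance method {variance!r}")


def ebgm_stat(t: ContingencyTable) -> StatResult:
    """Relative reporting ratio ``a N / ((a+c)(a+b))`` with lognormal 95% CI.

    This is the unshrunk observed/expected ratio (equal to ``2**IC``); the
    interval reuses the Woolf standard error and therefore needs all four
    cells positive.  The point estimate only needs ``a > 0`` and nonzero
    margins.
    """
    if t.a == 0 or (t.a + t.c) == 0 or (t.a + t.b) == 0:
        return _undefined("zero target cell")
    ebgm = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    if min(t.a, t.b, t.c, t.d) == 0:
        return StatResult(ebgm, math.nan, math.nan, "zero cell: no interval")
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return StatResult(ebgm, ebgm * math.exp(-_Z95 * se), ebgm * math.exp(_Z95 * se))


@dataclass(frozen=True)
class Thresholds:
    """Positivity criteria for the four algorithms.

    Defaults are the standard screening thresholds: ROR 95% CI lower bound
    above 1 with at least 3 reports; PRR >= 2 with chi-squared >= 4 and at
    least 3 reports; IC025 > 0; EBGM05 > 2.
    """

    ror_ci_low: float = 1.0
    min_n: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class SignalDecision:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool

    @property
    def consensus(self) -> bool:
        return self.pass_ror and self.pass_prr and self.pass_bcpnn and self.pass_mgps


def classify_signal(
    n: int,
    ror_lo: float,
    prr: float,
    chi2: float,
    ic025: float,
    ebgm05: float,
    thresholds: Thresholds = Thresholds(),
) -> SignalDecision:
    """Apply the four positivity criteria; NaN statistics fail theirs."""

    def ok(x: float) -> bool:
        return isinstance(x, (int, float)) and not math.isnan(x)

    t = thresholds
    return SignalDecision(
        pass_ror=ok(ror_lo) and ror_lo > t.ror_ci_low and n >= t.min_n,
        pass_prr=ok(prr) and ok(chi2) and prr >= t.prr_min and chi2 >= t.chi2_min and n >= t.min_n,
        pass_bcpnn=ok(ic025) and ic025 > t.ic025_min,
        pass_mgps=ok(ebgm05) and ebgm05 > t.ebgm05_min,
    )


def bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni adjustment: ``p_i * n`` capped at 1, threshold ``alpha/n``."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0), alpha / p.size


# ---------------------------------------------------------------------------
# vectorised metrics for screening


def metrics_frame(a, b, c, d, ic_variance: str = "bate"):
    """All four statistics for parallel arrays of cell counts.

    Returns a dict of float arrays (NaN where undefined):
    ``ror, ror_lo, ror_hi, prr, chi2, ic, ic025, ebgm, ebgm05``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    d = np.asarray(d, float)
    n = a + b + c + d
    ab, ac, bd, cd = a + b, a + c, b + d, c + d

    with np.errstate(divide="ignore", invalid="ignore"):
        allpos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        se = np.where(allpos, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), np.nan)

        ror = np.where(allpos, (a * d) / (b * c), np.nan)
        ror_lo = ror * np.exp(-_Z95 * se)
        ror_hi = ror * np.exp(_Z95 * se)

        prr_ok = (c > 0) & (ab > 0) & (cd > 0)
        prr = np.where(prr_ok, (a * cd) / (c * ab), np.nan)
        chi_den = ab * cd * ac * bd
        chi2 = np.where(prr_ok & (chi_den > 0), (a * d - b * c) ** 2 * n / chi_den, np.nan)

        obs_exp_ok = (a > 0) & (ac > 0) & (ab > 0)
        ebgm = np.where(obs_exp_ok, a * n / (ac * ab), np.nan)
        ic = np.log2(ebgm)
        if ic_variance == "bate":
            a1 = b1 = 1.0
            al = be = 2.0
            g11 = 1.0
            g = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
            v = (
                (n - a + g - g11) / ((a + g11) * (1 + n + g))
                + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
                + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
            ) / (_LN2 ** 2)
            ic025 = ic - 2.0 * np.sqrt(v)
        elif ic_variance == "approx":
            ic025 = ic - 3.3 * a ** -0.5 - 2.0 * a ** -1.5
        else:
            raise ValueError(f"unknown IC variance method {ic_variance!r}")
        ebgm05 = np.where(allpos, ebgm * np.exp(-_Z95 * se), np.nan)

    return {
        "ror": ror, "ror_lo": ror_lo, "ror_hi": ror_hi,
        "prr": prr, "chi2": chi2,
        "ic": ic, "ic025": ic025,
        "ebgm": ebgm, "ebgm05": ebgm05,
    }


# ---------------------------------------------------------------------------
# optional gamma-Poisson shrinkage (empirical-Bayes EBGM)


def _nb_mix_nll(params, a, e):
    """Negative log-likelihood of the two-gamma mixture for counts a with
    baseline expectations e (DuMouchel's marginal negative binomial)."""
    la1, lb1, la2, lb2, logit_w = params
    a1, b1v, a2, b2v = np.exp([la1, lb1, la2, lb2])
    w = 1.0 / (1.0 + np.exp(-logit_w))

    def nb_logpmf(alpha, beta):
        # success prob p = beta/(beta+e); written in log form (e > 0 always)
        return (
            special.gammaln(alpha + a)
            - special.gammaln(alpha)
            - special.gammaln(a + 1)
            + alpha * (np.log(beta) - np.log(beta + e))
            + a * (np.log(e) - np.log(beta + e))
        )

    l1 = nb_logpmf(a1, b1v) + np.log(w)
    l2 = nb_logpmf(a2, b2v) + np.log1p(-w)
    return -np.sum(np.logaddexp(l1, l2))


def mgps_ebgm(a, e, q: float = 0.05):
    """Empirical-Bayes gamma-Poisson shrinkage (MGPS-style EBGM / EB05).

    Fits a two-component gamma mixture prior on the relative reporting rate
    ``lambda = mu / E`` by maximum marginal likelihood over all supplied
    (count, expectation) pairs, then reports per pair the posterior geometric
    mean ``EBGM = exp(E[log lambda])`` and the posterior ``q`` quantile.

    This is the shrinkage alternative to the unshrunk observed/expected
    ratio; it pulls small-count signals toward the database background.
    """
    a = np.asarray(a, float)
    e = np.asarray(e, float)
    if a.shape != e.shape or a.size == 0:
        raise ValueError("a and e must be equal-length nonempty arrays")
    x0 = np.array([math.log(0.2), math.log(0.1), math.log(2.0), math.log(4.0), 0.0])
    res = optimize.minimize(_nb_mix_nll, x0, args=(a, e), method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    a1, b1v, a2, b2v = np.exp(res.x[:4])
    w = 1.0 / (1.0 + np.exp(-res.x[4]))

    # posterior: mixture of Gamma(alpha_j + a, beta_j + e)
    def post_w(aa, ee):
        l1 = math.log(w) + float(
            special.gammaln(a1 + aa) - special.gammaln(a1) - special.gammaln(aa + 1)
            + a1 * math.log(b1v / (b1v + ee)) + aa * math.log(ee / (b1v + ee))
        )
        l2 = math.log1p(-w) + float(
            special.gammaln(a2 + aa) - special.gammaln(a2) - special.gammaln(aa + 1)
            + a2 * math.log(b2v / (b2v + ee)) + aa * math.log(ee / (b2v + ee))
        )
        m = max(l1, l2)
        w1 = math.exp(l1 - m)
        w2 = math.exp(l2 - m)
        return w1 / (w1 + w2)

    ebgm = np.empty_like(a)
    eb_q = np.empty_like(a)
    for i, (aa, ee) in enumerate(zip(a, e)):
        p1 = post_w(aa, ee)
        g1 = sps.gamma(a1 + aa, scale=1.0 / (b1v + ee))
        g2 = sps.gamma(a2 + aa, scale=1.0 / (b2v + ee))
        elog = p1 * (special.digamma(a1 + aa) - math.log(b1v + ee)) + (1 - p1) * (
            special.digamma(a2 + aa) - math.log(b2v + ee)
        )
        ebgm[i] = math.exp(elog)

        def cdf(x):
            return p1 * g1.cdf(x) + (1 - p1) * g2.cdf(x)

        lo = min(g1.ppf(q), g2.ppf(q))
        hi = max(g1.ppf(q), g2.ppf(q))
        if math.isclose(lo, hi):
            eb_q[i] = lo
        else:
            eb_q[i] = optimize.brentq(lambda x: cdf(x) - q, lo * 0.5, hi * 2 + 1e-9)
    return ebgm, eb_q
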