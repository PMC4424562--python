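"""Statistical machinery shared by all pipeline stages.

Implements the tests the original analyses ran through limma/edgeR/ROCR-style
tooling, re-derived here from first principles so that every stage is
self-contained and testable against independent oracles:

* empirical-Bayes moderated t with a method-of-moments variance prior,
* the negative-binomial exact test for count data conditioned on the total,
* a pooled method-of-moments common-dispersion estimator,
* Benjamini-Hochberg step-up FDR,
* Fisher's combined probability method (-2 sum ln p ~ chi^2 with 2k df),
* Mann-Whitney AUC with the ties-count-half convention,
* the upper-tail hypergeometric gene-set test,
* locus-bootstrap permutation enrichment for interval overlaps.

Distribution functions come from scipy; the statistic logic lives here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .intervals import IntervalSet, overlaps_any

_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class TestResult:
    """A single test outcome: statistic, p-value and effect size."""

    statistic: float
    p: float
    effect: float = math.nan
    df: float = math.nan
    dispersion: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class ModeratedTPrior:
    """Variance prior for the moderated t: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValueError("require d0 >= 0 and s0_sq > 0")


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on y -> trigamma(y); monotone decreasing on (0, inf)
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_t_prior(s2: np.ndarray, df: float) -> ModeratedTPrior:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    Under the scaled-F model, log s^2 has mean log s0^2 + digamma(d/2) -
    log(d/2) - digamma(d0/2) + log(d0/2) and excess variance trigamma(d0/2)
    beyond trigamma(d/2); matching both moments gives the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return ModeratedTPrior(0.0, float(np.median(s2)) if s2.size else 1.0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    ev = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if ev > 0:
        d0 = 2.0 * _trigamma_inverse(ev)
        s0_sq = math.exp(
            float(np.mean(e)) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(float(np.mean(e)))
    return ModeratedTPrior(d0, s0_sq)


def moderated_t(
    group_a: np.ndarray | pd.DataFrame,
    group_b: np.ndarray | pd.DataFrame,
    prior: ModeratedTPrior | None = None,
) -> pd.DataFrame:
    """Row-wise empirical-Bayes moderated t, group_a vs group_b.

    Posterior variance per row is (d0*s0^2 + d*s^2) / (d0 + d) with d the
    residual df; t uses d0 + d df. Positive effect means group_a higher.

    Returns a DataFrame with columns statistic, p, effect, df; the fitted
    prior and a variance-floor flag live in ``.attrs``.
    """
    index = group_a.index if isinstance(group_a, pd.DataFrame) else None
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("row counts differ between groups")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    d = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d

    floored = False
    if np.all(s2 <= 0):
        # degenerate input: no within-group variance anywhere
        floor = max(1e-8, float(np.abs(np.concatenate([a, b], axis=1)).max()) * 1e-8)
        s2 = np.full_like(s2, floor)
        floored = True
        warnings.warn("all rows have zero within-group variance; variance floored")

    if prior is None:
        prior = estimate_t_prior(s2, d)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d

    effect = mean_a - mean_b
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"statistic": t, "p": p, "effect": effect, "df": df_total}, index=index
    )
    out.attrs["prior"] = prior
    out.attrs["variance_floored"] = floored
    return out


def two_sample_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Ordinary pooled-variance two-sample t (scalar, one feature)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group")
    with warnings.catch_warnings():
        # near-constant input degenerates to t = 0 below; silence the moment
        # precision warning scipy raises on the way there
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return TestResult(float(stat), float(p), float(a.mean() - b.mean()),
                      df=a.size + b.size - 2)


# ---------------------------------------------------------------------------
# negative-binomial exact test


def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    # NB parameterized by mean and size r (var = mean + mean^2/r)
    r = size
    logp = (
        special.gammaln(k + r)
        - special.gammaln(r)
        - special.gammaln(k + 1)
        + r * (math.log(r) - math.log(r + mean))
        + k * (math.log(mean) - math.log(r + mean))
    )
    return logp


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_sizes: np.ndarray,
    dispersion: float,
) -> TestResult:
    """Two-sided exact test for a count difference between two groups.

    Counts are scaled to a common library size, summed per group, and the
    observed split of the total is compared with its conditional null
    distribution: group sums are NB with means proportional to group sizes
    and per-group size n_g / dispersion (Poisson when dispersion == 0).
    The two-sided p is the sum of probabilities of outcomes as or less
    likely than the observed one, ties included.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    libs = np.asarray(lib_sizes, dtype=float)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("counts must be non-negative")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be > 0")
    if libs.size != ca.size + cb.size:
        raise ValueError("lib_sizes must align with counts_a + counts_b")
    na, nb = ca.size, cb.size
    common = libs.mean()
    scaled = np.concatenate([ca, cb]) * (common / libs)
    sa = int(round(scaled[:na].sum()))
    sb = int(round(scaled[na:].sum()))
    total = sa + sb
    effect = math.log2(((sa + 0.5) / na) / ((sb + 0.5) / nb))
    if total == 0:
        return TestResult(0.0, 1.0, effect, dispersion=dispersion)

    frac_a = na / (na + nb)
    k = np.arange(total + 1)
    if dispersion == 0.0:
        # Poisson limit: conditional distribution is binomial
        logp = sps.binom.logpmf(k, total, frac_a)
    else:
        mu_a, mu_b = total * frac_a, total * (1.0 - frac_a)
        logp = _nb_logpmf(k, mu_a, na / dispersion) + _nb_logpmf(
            k[::-1], mu_b, nb / dispersion
        )
        logp -= special.logsumexp(logp)
    obs = logp[sa]
    p = float(np.exp(special.logsumexp(logp[logp <= obs + 1e-9])))
    p = min(1.0, p)
    return TestResult(float(sa - total * frac_a), p, effect, dispersion=dispersion)


def estimate_dispersion(
    count_matrix: np.ndarray | pd.DataFrame,
    lib_sizes: np.ndarray,
    groups: np.ndarray | list | None = None,
) -> float:
    """Pooled method-of-moments common NB dispersion, floored at zero.

    Counts are scaled to the mean library size; within each group the excess
    of the row variance over the row mean is pooled against squared means:
    phi = max(0, sum(v - m) / sum(m^2)).
    """
    y = np.atleast_2d(np.asarray(count_matrix, dtype=float))
    libs = np.asarray(lib_sizes, dtype=float)
    if np.any(libs <= 0):
        raise ValueError("library sizes must be > 0")
    z = y * (libs.mean() / libs)
    if groups is None:
        groups = np.zeros(y.shape[1], dtype=int)
    groups = np.asarray(groups)
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        cols = z[:, groups == g]
        if cols.shape[1] < 2:
            continue
        m = cols.mean(axis=1)
        v = cols.var(axis=1, ddof=1)
        keep = m > 0
        num += float(np.sum(v[keep] - m[keep]))
        den += float(np.sum(m[keep] ** 2))
    if den == 0:
        warnings.warn("no informative rows; dispersion set to 0")
        return 0.0
    return max(0.0, num / den)


# ---------------------------------------------------------------------------
# multiple testing and combination


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def fisher_combine(pvalues: np.ndarray) -> TestResult:
    """Fisher's combined probability method over independent p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need >= 1 p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    clamped = np.clip(p, _TINY_P, 1.0)
    x = float(-2.0 * np.log(clamped).sum())
    combined = float(sps.chi2.sf(x, 2 * p.size))
    return TestResult(x, combined, df=2 * p.size)


def auc_mann_whitney(positives: np.ndarray, negatives: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def hypergeom_test(hits_in_set: int, set_size: int, hits_total: int,
                   universe: int) -> TestResult:
    """Upper-tail hypergeometric test: P(X >= k) of overlap by chance."""
    k, K, n, N = hits_in_set, set_size, hits_total, universe
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    expected = n * K / N if N else math.nan
    fold = k / expected if expected > 0 else math.nan
    return TestResult(float(k), min(1.0, p), effect=fold)


# ---------------------------------------------------------------------------
# permutation enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap enrichment of a query set against a feature annotation."""

    observed: float
    expected: float
    fold: float
    p: float
    direction: str  # enriched | depleted


def permutation_enrichment(
    query: IntervalSet,
    feature: IntervalSet,
    universe: IntervalSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical overlap enrichment by bootstrap placement within a universe.

    The null re-draws |query| loci uniformly (with replacement) from the
    universe members, preserving the universe's locus length and CpG-density
    structure; fold is observed / mean null overlap and the empirical p uses
    the (1 + exceedances) / (1 + n_perm) estimator, mirrored for depletion.
    """
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    in_universe = overlaps_any(query, universe)
    if len(query) and not all(in_universe):
        raise ValueError("every query interval must overlap the universe")
    observed = float(sum(overlaps_any(query, feature)))
    hits = np.asarray(overlaps_any(universe, feature), dtype=float)
    rng = np.random.default_rng(seed)
    nq = len(query)
    if nq == 0:
        return EnrichmentResult(0.0, 0.0, math.nan, 1.0, "enriched")
    draws = rng.integers(0, len(universe), size=(n_perm, nq))
    null_counts = hits[draws].sum(axis=1)
    expected = float(null_counts.mean())
    fold = observed / expected if expected > 0 else math.inf
    if fold >= 1.0:
        p = (1.0 + float(np.sum(null_counts >= observed))) / (1.0 + n_perm)
        direction = "enriched"
    else:
        p = (1.0 + float(np.sum(null_counts <= observed))) / (1.0 + n_perm)
        direction = "depleted"
    return EnrichmentResult(observed, expected, fold, p, direction)
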