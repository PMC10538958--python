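"""Shared statistical primitives for every pipeline stage.

Pure functions over in-memory arrays: Benjamini-Hochberg adjustment,
hypergeometric / Fisher enrichment tails, one-way ANOVA with Dunnett's
many-to-one comparisons (Monte-Carlo adjusted), Grubbs's single-outlier
test, Mahalanobis distances, and the rank-based 1-D / 2-D annotation
position scores popularized by the Perseus environment.

No file I/O happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DunnettResult",
    "GrubbsResult",
    "bh_adjust",
    "hypergeom_upper_tail",
    "fisher_exact_enrichment",
    "anova_dunnett",
    "grubbs_one_sided_max",
    "mahalanobis_distance",
    "position_score_1d",
    "rank_manova_2d",
    "correlation",
]


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of (m * p_(j) / j), returned in the input order.

    Parameters
    ----------
    pvalues : sequence of float in [0, 1]

    Returns
    -------
    numpy.ndarray of q-values, same length and order as the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Exact enrichment tails


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly.

    N: population size; K: successes in the population; n: draws;
    k: observed successes among the draws.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy uses log-gamma internally
    return float(min(1.0, sps.hypergeom.sf(k - 1, N, K, n)))


def fisher_exact_enrichment(table: Sequence[Sequence[int]]) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 count table.

    Table layout::

        [[in_term & selected,     in_term & not_selected],
         [not_term & selected,    not_term & not_selected]]

    Equals the hypergeometric upper tail on the matched margins.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    N = a + b + c + d
    return hypergeom_upper_tail(N, K=a + b, n=a + c, k=a)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons


@dataclass(frozen=True)
class DunnettResult:
    """One treatment-vs-control comparison from a Dunnett procedure."""

    comparison: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    degenerate: bool = False


_DUNNETT_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _dunnett_null_max_abs_t(
    n_control: int, n_treatments: tuple[int, ...], df: int, mc_reps: int, seed: int
) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |T_j| under the global null.

    Group means and the pooled variance are simulated directly, which
    reproduces the equicorrelated multivariate-t law of the Dunnett
    statistics without evaluating its density.  The draw depends only on
    the design signature, so it is cached and shared across features.
    """
    key = (n_control, n_treatments, df, mc_reps, seed)
    cached = _DUNNETT_NULL_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    m0 = rng.standard_normal(mc_reps) / np.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, mc_reps) / df)
    max_abs = np.zeros(mc_reps)
    for ni in n_treatments:
        mi = rng.standard_normal(mc_reps) / np.sqrt(ni)
        ti = np.abs(mi - m0) / (s * np.sqrt(1.0 / ni + 1.0 / n_control))
        np.maximum(max_abs, ti, out=max_abs)
    max_abs.sort()
    _DUNNETT_NULL_CACHE[key] = max_abs
    return max_abs


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    mc_reps: int = 50_000,
    seed: int = 0,
) -> list[DunnettResult]:
    """One-way ANOVA with Dunnett's many-to-one post-hoc comparisons.

    Every treatment group is compared against ``control`` using the pooled
    residual variance; the family-wise adjusted p-value
    P(max_j |T_j| >= |t_i|) is estimated by Monte Carlo under the
    equicorrelated multivariate-t null (``mc_reps`` draws, fixed ``seed``).

    Groups must each contain at least two non-missing values.  A feature
    with zero pooled variance is reported with adjusted p = 1 and the
    ``degenerate`` flag set rather than raising.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    clean: dict[str, np.ndarray] = {}
    for g, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 non-missing values")
        clean[g] = v
    if len(clean) < 2:
        raise ValueError("need at least two groups")

    treatments = [g for g in clean if g != control]
    n0 = clean[control].size
    n_total = sum(v.size for v in clean.values())
    df = n_total - len(clean)
    ss_resid = sum(float(((v - v.mean()) ** 2).sum()) for v in clean.values())
    s2 = ss_resid / df

    if s2 <= 0.0:
        return [
            DunnettResult(comparison=f"{g} vs {control}", t=0.0, df=df,
                          p_raw=1.0, p_adjusted=1.0, degenerate=True)
            for g in treatments
        ]

    null_max = _dunnett_null_max_abs_t(
        n0, tuple(clean[g].size for g in treatments), df, mc_reps, seed
    )
    m0 = clean[control].mean()
    out = []
    for g in treatments:
        ni = clean[g].size
        t = (clean[g].mean() - m0) / np.sqrt(s2 * (1.0 / ni + 1.0 / n0))
        p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        exceed = null_max.size - np.searchsorted(null_max, abs(t), side="left")
        p_adj = max(float(exceed) / null_max.size, p_raw)
        out.append(DunnettResult(comparison=f"{g} vs {control}", t=float(t),
                                 df=df, p_raw=p_raw, p_adjusted=min(p_adj, 1.0)))
    return out


# ---------------------------------------------------------------------------
# Outlier analysis


@dataclass(frozen=True)
class GrubbsResult:
    """One-sided (maximum) Grubbs single-outlier test result."""

    G: float
    n: int
    p: float
    index: int
    is_outlier: bool


def grubbs_one_sided_max(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Grubbs's test for a single high outlier.

    G = (max - mean) / sd with the n-1 sd; the one-sided p-value is the
    Bonferroni-style bound ``min(1, n * P(T_{n-2} > tau))`` with
    ``tau = sqrt((n-2) G^2 / ((n-1)^2/n - G^2))``, which reproduces the
    classical critical values exactly.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("Grubbs's test needs at least 3 values")
    sd = v.std(ddof=1)
    idx = int(np.argmax(v))
    if sd == 0.0:
        return GrubbsResult(G=0.0, n=n, p=1.0, index=idx, is_outlier=False)
    G = float((v[idx] - v.mean()) / sd)
    bound = (n - 1) ** 2 / n - G**2
    if bound <= 0.0:
        p = 0.0
    else:
        tau = np.sqrt((n - 2) * G**2 / bound)
        p = float(min(1.0, n * sps.t.sf(tau, n - 2)))
    return GrubbsResult(G=G, n=n, p=p, index=idx, is_outlier=p <= alpha)


def mahalanobis_distance(
    point: Sequence[float],
    mean: Sequence[float],
    covariance: Sequence[Sequence[float]],
) -> tuple[float, bool]:
    """Covariance-scaled distance ``sqrt((x-mu)' S^-1 (x-mu))``.

    If the covariance condition number exceeds 1e8 a ridge
    ``1e-6 * trace(S)/dim * I`` is added and the returned flag is True.
    """
    x = np.asarray(point, dtype=float)
    mu = np.asarray(mean, dtype=float)
    S = np.asarray(covariance, dtype=float)
    if x.shape != mu.shape or S.shape != (x.size, x.size):
        raise ValueError("dimension mismatch between point, mean and covariance")
    regularized = False
    if x.size == 1:
        var = float(S[0, 0])
        if var <= 0:
            var = max(var, 0.0) + 1e-6 * max(var, 1.0)
            regularized = True
        return float(abs(x[0] - mu[0]) / np.sqrt(var)), regularized
    if np.linalg.cond(S) > 1e8:
        S = S + 1e-6 * (np.trace(S) / S.shape[0]) * np.eye(S.shape[0])
        regularized = True
    diff = x - mu
    d2 = float(diff @ np.linalg.solve(S, diff))
    return float(np.sqrt(max(d2, 0.0))), regularized


# ---------------------------------------------------------------------------
# Rank-based annotation enrichment scores


def _mann_whitney_p(ranks: np.ndarray, flags: np.ndarray) -> float:
    """Two-sided Mann-Whitney p from mid-ranks.

    Exact enumeration (no-ties statistic distribution) for N <= 20 without
    ties, otherwise the normal approximation with tie correction and
    continuity correction.
    """
    N = ranks.size
    n_in = int(flags.sum())
    n_out = N - n_in
    U = float(ranks[flags].sum()) - n_in * (n_in + 1) / 2.0
    ties = np.unique(ranks, return_counts=True)[1]
    has_ties = np.any(ties > 1)
    if N <= 20 and not has_ties:
        # exact null distribution of U by dynamic programming
        p_exact = _mann_whitney_exact_two_sided(int(round(U)), n_in, n_out)
        return p_exact
    mu = n_in * n_out / 2.0
    tie_term = float(((ties**3 - ties).sum())) / (N * (N - 1)) if N > 1 else 0.0
    var = n_in * n_out / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(U - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))


def _mann_whitney_exact_two_sided(U: int, n1: int, n2: int) -> float:
    """Exact two-sided Mann-Whitney p by enumerating the null U counts."""
    # counts[u] = number of arrangements with statistic u
    max_u = n1 * n2
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # recurrence over items of the first sample (Mann-Whitney convolution)
    for i in range(1, n1 + 1):
        new = np.zeros_like(counts)
        csum = 0.0
        # generating function approach: counts_i(u) = sum_{j=0..n2} counts_{i-1}(u-j)
        for u in range(max_u + 1):
            csum += counts[u]
            if u - n2 - 1 >= 0:
                csum -= counts[u - n2 - 1]
            new[u] = csum
        counts = new
    total = counts.sum()
    lo_tail = counts[: U + 1].sum() / total   # P(U' <= U)
    hi_tail = counts[U:].sum() / total        # P(U' >= U)
    return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))


def position_score_1d(
    values: Sequence[float], member_flags: Sequence[bool]
) -> tuple[float, float]:
    """Rank position score in [-1, 1] plus Mann-Whitney p for one term.

    The score is ``2 * (mean rank of members - mean rank of non-members) / N``
    (mid-ranks for ties), equivalently ``2U/(n_in*n_out) - 1``; +1 means all
    members sit at the highest values.
    """
    v = np.asarray(values, dtype=float)
    flags = np.asarray(member_flags, dtype=bool)
    if v.shape != flags.shape:
        raise ValueError("values and member_flags differ in length")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    n_in = int(flags.sum())
    if n_in == 0 or n_in == v.size:
        raise ValueError("need at least one member and one non-member")
    ranks = sps.rankdata(v)
    s = 2.0 * (ranks[flags].mean() - ranks[~flags].mean()) / v.size
    return float(s), _mann_whitney_p(ranks, flags)


def rank_manova_2d(
    values_x: Sequence[float],
    values_y: Sequence[float],
    member_flags: Sequence[bool],
) -> tuple[float, float, float, bool]:
    """Two-dimensional rank enrichment: per-dimension position scores plus a
    Hotelling-type T-squared test on the rank-transformed coordinates.

    Returns ``(s_x, s_y, p, regularized)`` where ``regularized`` reports
    whether the pooled rank covariance needed a ridge (e.g. the two
    dimensions were numerically collinear).
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    flags = np.asarray(member_flags, dtype=bool)
    if not (x.shape == y.shape == flags.shape):
        raise ValueError("inputs differ in length")
    for name, v in (("x", x), ("y", y)):
        if np.unique(v).size == 1:
            raise ValueError(f"degenerate dimension: all values tied in {name}")
    s_x, _ = position_score_1d(x, flags)
    s_y, _ = position_score_1d(y, flags)

    R = np.column_stack([sps.rankdata(x), sps.rankdata(y)])
    g1, g0 = R[flags], R[~flags]
    n1, n0 = len(g1), len(g0)
    if min(n1, n0) < 2:
        raise ValueError("need at least two members and two non-members")
    d = g1.mean(axis=0) - g0.mean(axis=0)
    Sp = ((n1 - 1) * np.cov(g1.T) + (n0 - 1) * np.cov(g0.T)) / (n1 + n0 - 2)
    regularized = False
    if np.linalg.cond(Sp) > 1e8:
        Sp = Sp + 1e-6 * (np.trace(Sp) / 2.0) * np.eye(2)
        regularized = True
    T2 = n1 * n0 / (n1 + n0) * float(d @ np.linalg.solve(Sp, d))
    n = n1 + n0
    F = (n - 3) / (2.0 * (n - 2)) * T2
    p = float(sps.f.sf(F, 2, n - 3))
    return float(s_x), float(s_y), p, regularized


# ---------------------------------------------------------------------------
# Correlation


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a t-approximation p-value.

    ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom; Spearman
    uses mid-ranks for ties.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y differ in length")
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise ValueError("values must be finite")
    if method == "spearman":
        xv = sps.rankdata(xv)
        yv = sps.rankdata(yv)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if xv.std() == 0.0 or yv.std() == 0.0:
        raise ValueError("zero variance in input")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    n = xv.size
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)
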