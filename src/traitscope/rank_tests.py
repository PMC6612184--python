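"""Nonparametric relative-effect comparisons of quantitative traits.

The relative effect between two samples X and Y is

    p = P(X < Y) + 1/2 P(X = Y),

the probability that a random observation from the second group exceeds one
from the first (ties split).  p = 1/2 means stochastic equality.  It is
computed here through midranks of the pooled sample (the placement
formulation), which equals the brute-force count over all |x| * |y| pairs.

``bm_contrast`` studentizes p_hat - 1/2 with the Brunner-Munzel variance
estimator and refers it to a t distribution with Satterthwaite degrees of
freedom; it is robust to non-normality and unequal variances, which suits
growth-envelope traits (pH, temperature, NaCl bounds) whose distributions
are skewed and heteroscedastic.  ``multi_contrast`` runs all pairwise
(Tukey-type) contrasts with a joint single-step adjustment based on the
equicoordinate quantile of a multivariate normal with the estimated contrast
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["RelativeEffectResult", "relative_effect", "bm_contrast", "multi_contrast"]


@dataclass
class RelativeEffectResult:
    pair: tuple[str, str]
    p_hat: float
    variance: float  # Brunner-Munzel variance of p_hat
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    n: tuple[int, int] = (0, 0)
    flags: list[str] = field(default_factory=list)


def _placements(x: np.ndarray, y: np.ndarray):
    """Pooled midranks split by sample, plus within-sample midranks."""
    pooled = np.concatenate([x, y])
    r = stats.rankdata(pooled)  # midranks
    rx, ry = r[: len(x)], r[len(x) :]
    return rx, ry, stats.rankdata(x), stats.rankdata(y)


def relative_effect(x, y) -> float:
    """p = P(X < Y) + 1/2 P(X = Y) via midranks of the pooled sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    _, ry, _, _ = _placements(x, y)
    return float((ry.mean() - (len(y) + 1) / 2.0) / len(x))


def bm_contrast(
    x,
    y,
    *,
    pair: tuple[str, str] = ("x", "y"),
) -> RelativeEffectResult:
    """Brunner-Munzel test of H0: relative effect = 1/2.

    Requires at least two observations per group (the variance estimate
    needs them).  With degenerate placement variance (e.g. complete
    separation or all-tied data) the studentized statistic is undefined;
    the result is flagged and the p-value set by convention: 1 when
    p_hat = 1/2, else the two-sided exhaustive-permutation lower bound
    2 / C(n1+n2, n1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs >= 2 observations")
    rx, ry, rxx, ryy = _placements(x, y)
    p_hat = float((ry.mean() - (n2 + 1) / 2.0) / n1)
    # placement variances (Brunner-Munzel)
    s1 = float(np.var(rx - rxx, ddof=1))
    s2 = float(np.var(ry - ryy, ddof=1))
    var_p = s1 / (n1 * n2**2) + s2 / (n2 * n1**2)
    flags: list[str] = []
    if var_p <= 0.0:
        flags.append("degenerate_variance")
        statistic = 0.0 if math.isclose(p_hat, 0.5) else math.copysign(math.inf, p_hat - 0.5)
        df = float("nan")
        if math.isclose(p_hat, 0.5):
            p = 1.0
        else:
            p = min(1.0, 2.0 / math.comb(n1 + n2, n1))
    else:
        statistic = (p_hat - 0.5) / math.sqrt(var_p)
        df = (n1 * s1 + n2 * s2) ** 2 / (
            (n1 * s1) ** 2 / (n1 - 1) + (n2 * s2) ** 2 / (n2 - 1)
        )
        p = 2.0 * float(stats.t.sf(abs(statistic), df))
    return RelativeEffectResult(
        pair=pair,
        p_hat=p_hat,
        variance=var_p,
        statistic=float(statistic),
        df=float(df),
        p_raw=float(p),
        p_adjusted=None,
        n=(n1, n2),
        flags=flags,
    )


def _contrast_correlation(results, var_parts, pairs):
    """Approximate correlation matrix of the studentized pairwise contrasts.

    Contrasts sharing a group are correlated through that group's placement
    variance contribution; disjoint contrasts are treated as uncorrelated.
    The shared-group covariance is approximated by the geometric mean of the
    group's variance contributions in the two contrasts, with sign +1 when
    the group sits on the same side of both contrasts and -1 otherwise.
    """
    m = len(pairs)
    corr = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            (i, j), (k, l) = pairs[a], pairs[b]
            shared = {i, j} & {k, l}
            if not shared:
                continue
            g = shared.pop()
            sign = 1.0 if ((g == i) == (g == k)) else -1.0
            cov = sign * math.sqrt(var_parts[a][g] * var_parts[b][g])
            denom = math.sqrt(results[a].variance * results[b].variance)
            corr[a, b] = corr[b, a] = cov / denom if denom > 0 else 0.0
    return corr


def multi_contrast(
    groups: dict,
    *,
    seed: int | None = None,
    n_mc: int = 20_000,
) -> list[RelativeEffectResult]:
    """All-pairwise relative-effect contrasts with joint multiplicity control.

    *groups* maps group label -> sample (each of size >= 2).  Every pair is
    tested with :func:`bm_contrast`; adjusted p-values are single-step
    equicoordinate probabilities P(max_j |Z_j| >= |t_obs|) under a
    multivariate normal with the estimated contrast correlation, evaluated by
    seeded Monte Carlo.  If the correlation estimate is not positive
    definite the adjustment falls back to Sidak and the results are flagged.
    With two groups the single contrast is returned with
    ``p_adjusted == p_raw``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")

    pairs = list(combinations(labels, 2))
    results: list[RelativeEffectResult] = []
    var_parts: list[dict] = []
    for i, j in pairs:
        res = bm_contrast(arrays[i], arrays[j], pair=(i, j))
        results.append(res)
        x, y = arrays[i], arrays[j]
        n1, n2 = len(x), len(y)
        rx, ry, rxx, ryy = _placements(x, y)
        s1 = float(np.var(rx - rxx, ddof=1))
        s2 = float(np.var(ry - ryy, ddof=1))
        var_parts.append({i: s1 / (n1 * n2**2), j: s2 / (n2 * n1**2)})

    if len(results) == 1:
        results[0].p_adjusted = results[0].p_raw
        return results

    corr = _contrast_correlation(results, var_parts, pairs)
    degenerate = [r for r in results if "degenerate_variance" in r.flags]
    try:
        chol = np.linalg.cholesky(corr)
        singular = False
    except np.linalg.LinAlgError:
        singular = True
    if singular or degenerate:
        # Sidak fallback
        m = len(results)
        for r in results:
            r.p_adjusted = 1.0 - (1.0 - min(r.p_raw, 1.0)) ** m
            r.flags.append("sidak_fallback")
        return results

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, len(results))) @ chol.T
    maxabs = np.abs(z).max(axis=1)
    for r in results:
        t_obs = abs(r.statistic)
        r.p_adjusted = float((maxabs >= t_obs).mean()) if math.isfinite(t_obs) else r.p_raw
        r.p_adjusted = max(r.p_adjusted, r.p_raw if math.isfinite(t_obs) else 0.0)
    return results
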