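"""Binary and categorical trait comparisons.

Binary traits are compared with a binomial-proportion model: each group's
prevalence is k/n with standard error sqrt(p(1-p)/n), an overall difference
is tested with a Pearson chi-square on the 2 x m positive/negative table,
and pairwise group contrasts use the z statistic built from the two binomial
standard errors.

Categorical traits (multiple unordered levels, several of which a species
may exhibit) are compared with a randomization test: group labels are
permuted while the observed outcomes stay fixed, which samples the null of
equal level proportions without replacement.  Per level, the statistic is
the spread (max - min; the absolute difference for two groups) of the level
proportion across groups; the overall statistic is the maximum over levels
under the same permutations, so the overall p-value needs no further
multiplicity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "binomial_proportion",
    "chi_square_overall",
    "pairwise_proportion_contrast",
    "randomization_test",
    "benjamini_hochberg",
]


@dataclass
class ComparisonResult:
    trait: str
    groups: tuple[str, ...]
    estimates: tuple[float, ...]
    ses: tuple[float, ...]
    statistic: float
    p_value: float
    direction: str  # group label with the larger estimate, or "none"
    n_per_group: tuple[int, ...]
    method: str
    level: str | None = None
    df: float | None = None
    resamples: int | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def _direction(groups, estimates) -> str:
    if len(estimates) == 2 and not math.isclose(estimates[0], estimates[1], abs_tol=1e-12):
        return groups[0] if estimates[0] > estimates[1] else groups[1]
    if len(estimates) > 2:
        i = int(np.argmax(estimates))
        if not all(math.isclose(estimates[i], e, abs_tol=1e-12) for e in estimates):
            return groups[i]
    return "none"


def binomial_proportion(k: int, n: int) -> tuple[float, float]:
    """Proportion estimate and its binomial standard error.

    p_hat = k/n, se = sqrt(p_hat (1 - p_hat) / n).  n must be >= 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1 (no known values)")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    p_hat = k / n
    return p_hat, math.sqrt(p_hat * (1.0 - p_hat) / n)


def chi_square_overall(counts) -> tuple[float, float, float, list[str]]:
    """Pearson chi-square test on a 2 x m positive/negative contingency table.

    Returns (statistic, df, p, flags).  df = m - 1.  A warning flag is set
    when any expected cell is below 5.  Degenerate margins (an empty group
    or an all-positive/all-negative table) raise.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x m table of positive/negative counts by group")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    if (obs.sum(axis=0) <= 0).any() or (obs.sum(axis=1) <= 0).any():
        raise ValueError("degenerate margin: empty row or column total")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    p = float(stats.chi2.sf(statistic, df))
    flags = ["low_expected_cell"] if (expected < 5).any() else []
    return statistic, float(df), p, flags


def pairwise_proportion_contrast(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    *,
    groups: tuple[str, str] = ("group1", "group2"),
    trait: str = "",
    pooled: bool = False,
) -> ComparisonResult:
    """Two-group proportion contrast using binomial standard errors.

    z = (p1 - p2) / sqrt(se1^2 + se2^2) with a two-sided normal p-value.
    With ``pooled=True`` the common-proportion variance is used instead, in
    which case z^2 equals the Pearson chi-square statistic of the 2x2 table.
    When both proportions sit at a common boundary (zero standard errors and
    p1 == p2) the contrast carries no information: p = 1 by convention,
    flagged ``boundary``.
    """
    p1, se1 = binomial_proportion(k1, n1)
    p2, se2 = binomial_proportion(k2, n2)
    flags: list[str] = []
    if pooled:
        p_pool = (k1 + k2) / (n1 + n2)
        var = p_pool * (1 - p_pool) * (1 / n1 + 1 / n2)
    else:
        var = se1**2 + se2**2
    if var <= 0.0:
        flags.append("boundary")
        z, p = 0.0, 1.0
        if not math.isclose(p1, p2):  # se=0 on both sides but estimates differ
            flags.append("degenerate_variance")
    else:
        z = (p1 - p2) / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return ComparisonResult(
        trait=trait,
        groups=groups,
        estimates=(p1, p2),
        ses=(se1, se2),
        statistic=z,
        p_value=p,
        direction=_direction(groups, (p1, p2)),
        n_per_group=(n1, n2),
        method="pairwise_binomial_z" + ("_pooled" if pooled else ""),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# randomization test


def _level_proportions(outcome_matrix: np.ndarray, group_sizes: np.ndarray) -> np.ndarray:
    """Per-group level proportions from a stacked indicator matrix.

    outcome_matrix: (n_obs, n_levels) 0/1 indicators, rows grouped by label
    blocks of the given sizes.  Returns (n_groups, n_levels).
    """
    bounds = np.concatenate([[0], np.cumsum(group_sizes)])
    return np.stack(
        [
            outcome_matrix[bounds[g] : bounds[g + 1]].mean(axis=0)
            for g in range(len(group_sizes))
        ]
    )


def randomization_test(
    labels,
    outcomes,
    B: int = 100_000,
    seed: int | None = None,
    *,
    trait: str = "",
    exact: bool = False,
) -> dict:
    """Permutation test of equal level proportions across groups.

    *labels* gives the group of each observation; *outcomes* the observed
    category (a single level, or a set/frozenset of levels for species
    exhibiting several).  Group labels are permuted ``B`` times with the
    outcome multiset fixed.  Per level the statistic is the spread of the
    level proportion across groups; p = (1 + #{spread* >= spread_obs}) /
    (B + 1).  The overall p-value uses the maximum spread over levels under
    the same permutations.  The literal fraction of strictly less extreme
    resamples is reported alongside as ``less_extreme``.

    With ``exact=True`` all distinct assignments of observations to groups
    are enumerated instead (feasible for pooled n around 10) and p-values are
    exact permutation fractions without the add-one correction.

    Returns a dict with per-level :class:`ComparisonResult` under ``levels``
    and an overall result under ``overall``.
    """
    labels = np.asarray(labels)
    group_names = sorted({str(g) for g in labels.tolist()})
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    if not exact and B < 1:
        raise ValueError("B must be >= 1")

    # indicator matrix over the union of observed levels
    outcome_sets = [o if isinstance(o, (set, frozenset)) else {o} for o in outcomes]
    levels = sorted({lvl for o in outcome_sets for lvl in o})
    indicator = np.zeros((len(outcome_sets), len(levels)), dtype=float)
    for i, o in enumerate(outcome_sets):
        for lvl in o:
            indicator[i, levels.index(lvl)] = 1.0
    if len(labels) != len(outcome_sets):
        raise ValueError("labels and outcomes length mismatch")

    labels_str = labels.astype(str)
    group_sizes = np.array([int((labels_str == g).sum()) for g in group_names])
    # canonical base ordering (groups sorted, rows sorted within each block):
    # resamples then depend only on the data multiset, not observation order
    order = np.concatenate([np.flatnonzero(labels_str == g) for g in group_names])
    base = indicator[order]
    bounds0 = np.concatenate([[0], np.cumsum(group_sizes)])
    for g in range(len(group_names)):
        block = base[bounds0[g] : bounds0[g + 1]]
        base[bounds0[g] : bounds0[g + 1]] = block[np.lexsort(block.T[::-1])]

    props_obs = _level_proportions(base, group_sizes)
    spread_obs = props_obs.max(axis=0) - props_obs.min(axis=0)
    overall_obs = spread_obs.max() if len(levels) else 0.0

    n_obs = len(outcome_sets)
    if exact:
        if len(group_names) != 2:
            raise ValueError("exact enumeration supports two groups")
        n1 = group_sizes[0]
        idx_all = np.arange(n_obs)
        spreads = []
        for combo in itertools.combinations(range(n_obs), n1):
            sel = np.array(combo)
            rest = np.setdiff1d(idx_all, sel, assume_unique=True)
            perm = base[np.concatenate([sel, rest])]
            props = _level_proportions(perm, group_sizes)
            spreads.append(props.max(axis=0) - props.min(axis=0))
        spreads = np.stack(spreads)
        n_perm = len(spreads)
        tol = 1e-12
        p_levels = (spreads >= spread_obs - tol).mean(axis=0)
        less_extreme = (spreads < spread_obs - tol).mean(axis=0)
        p_overall = float((spreads.max(axis=1) >= overall_obs - tol).mean())
        less_extreme_overall = float((spreads.max(axis=1) < overall_obs - tol).mean())
        B_used = n_perm
    else:
        rng = np.random.default_rng(seed)
        tol = 1e-12
        count_ge = np.zeros(len(levels))
        count_lt = np.zeros(len(levels))
        count_ge_overall = 0
        count_lt_overall = 0
        chunk = max(1, min(B, int(2e6 // max(1, n_obs * len(levels)))))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            # permute rows independently for each resample
            keys = rng.random((b, n_obs))
            perm_idx = np.argsort(keys, axis=1)
            permuted = base[perm_idx]  # (b, n_obs, n_levels)
            bounds = np.concatenate([[0], np.cumsum(group_sizes)])
            props = np.stack(
                [
                    permuted[:, bounds[g] : bounds[g + 1], :].mean(axis=1)
                    for g in range(len(group_sizes))
                ],
                axis=1,
            )  # (b, n_groups, n_levels)
            spread = props.max(axis=1) - props.min(axis=1)  # (b, n_levels)
            count_ge += (spread >= spread_obs - tol).sum(axis=0)
            count_lt += (spread < spread_obs - tol).sum(axis=0)
            mx = spread.max(axis=1)
            count_ge_overall += int((mx >= overall_obs - tol).sum())
            count_lt_overall += int((mx < overall_obs - tol).sum())
            done += b
        p_levels = (1.0 + count_ge) / (B + 1.0)
        less_extreme = count_lt / B
        p_overall = (1.0 + count_ge_overall) / (B + 1.0)
        less_extreme_overall = count_lt_overall / B
        B_used = B

    n_per_group = tuple(int(s) for s in group_sizes)
    level_results = {}
    for j, lvl in enumerate(levels):
        est = tuple(float(props_obs[g, j]) for g in range(len(group_names)))
        level_results[lvl] = ComparisonResult(
            trait=trait,
            level=lvl,
            groups=tuple(group_names),
            estimates=est,
            ses=tuple(
                math.sqrt(e * (1 - e) / n) if n else 0.0 for e, n in zip(est, n_per_group)
            ),
            statistic=float(spread_obs[j]),
            p_value=float(p_levels[j]),
            direction=_direction(tuple(group_names), est),
            n_per_group=n_per_group,
            method="randomization_exact" if exact else "randomization",
            resamples=B_used,
            seed=seed,
            extra={"less_extreme": float(less_extreme[j])},
        )
    overall = ComparisonResult(
        trait=trait,
        groups=tuple(group_names),
        estimates=tuple(float(x) for x in props_obs.max(axis=0)) if len(levels) else (),
        ses=(),
        statistic=float(overall_obs),
        p_value=float(p_overall),
        direction="none",
        n_per_group=n_per_group,
        method=("randomization_exact" if exact else "randomization") + "_max_level",
        resamples=B_used,
        seed=seed,
        extra={"less_extreme": float(less_extreme_overall)},
    )
    return {"levels": level_results, "overall": overall}


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
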