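"""Naive and phylogenetically corrected logistic regression.

Species are not independent observations: close relatives share traits
through common descent, so a naive logistic regression of group membership
(abundant vs rare, skin vs world) on a trait can mistake phylogenetic
conservation for a trait effect.  The corrected model here is a Bernoulli
GLMM in the Ives-Garland tradition:

    y_i ~ Bernoulli(p_i),   logit p_i = x_i' beta + u_i,
    u ~ N(0, sigma^2 * C(alpha)),

where C(alpha) is the tip-tip correlation of a mean-reverting
(Ornstein-Uhlenbeck) process evolving along the tree, conditioned on the
root state.  With shared depth s_ij (root-to-MRCA path length) and tip
depths T_i on a tree scaled to unit height,

    C_ij = exp(-alpha (T_i + T_j - 2 s_ij)) * (1 - exp(-2 alpha s_ij))
           / sqrt((1 - exp(-2 alpha T_i)) (1 - exp(-2 alpha T_j))),

which tends to the Brownian-motion correlation s_ij / sqrt(T_i T_j) as
alpha -> 0 and to zero as alpha -> inf.  Because the process is conditioned
on the root, tips with no shared ancestry (a star tree) are exactly
uncorrelated, and the model then collapses to the naive regression.

The fit maximizes the Laplace-approximated marginal likelihood over
(beta, sigma^2, alpha); sigma^2 -> 0 recovers the naive fit, so the
corrected log-likelihood is never below the naive one.  Model screening
uses a likelihood-ratio test against the intercept-only null.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "LogisticFit",
    "prune_to_overlap",
    "naive_logistic",
    "phylo_logistic",
    "lrt",
]

_LOGLIK_TOL = 1e-8
_MAX_ITER = 200
_SEPARATION_BETA = 12.0


def normalize_name(name: str) -> str:
    """Case-insensitive matching key; underscores and spaces are equivalent."""
    return re.sub(r"\s+", " ", name.strip().lower().replace("_", " "))


class Phylogeny:
    """Rooted tree with branch lengths, tips mapped to species names."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(normalize_name(l) for l in labels)) != len(labels):
            raise ValueError("tip names not unique after normalization")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool | None = None) -> "Phylogeny":
        if is_path is None:
            is_path = "(" not in source
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True).strip()

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    # -- geometry ----------------------------------------------------------

    def _depths(self) -> dict:
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    @property
    def height(self) -> float:
        depths = self._depths()
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    def scale_to_unit_height(self) -> "Phylogeny":
        """Return a copy with branch lengths divided by the tree height."""
        h = self.height
        if h <= 0:
            raise ValueError("tree has zero height")
        clone = dendropy.Tree(self.tree)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / h
        return Phylogeny(clone)

    def shared_depth_matrix(self, order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(S, T): root-to-MRCA depths S_ij and root-to-tip depths T_i.

        *order* lists tip names (normalized matching); S is symmetric with
        S_ii = T_i.
        """
        depths = self._depths()
        key_to_idx = {normalize_name(n): i for i, n in enumerate(order)}
        n = len(order)
        S = np.zeros((n, n))
        T = np.zeros(n)
        tip_sets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                idx = key_to_idx.get(normalize_name(node.taxon.label))
                tip_sets[node] = [idx] if idx is not None else []
                if idx is not None:
                    T[idx] = depths[node]
                    S[idx, idx] = depths[node]
            else:
                child_sets = [tip_sets.pop(c) for c in node.child_nodes()]
                d = depths[node]
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i in child_sets[a]:
                            for j in child_sets[b]:
                                S[i, j] = S[j, i] = d
                tip_sets[node] = [i for cs in child_sets for i in cs]
        if len(key_to_idx) != n:
            raise ValueError("duplicate names in order")
        return S, T


def prune_to_overlap(tree: Phylogeny, species: Iterable[str]) -> tuple[Phylogeny, list[str]]:
    """Restrict a tree to the tips matching *species*.

    Matching is case-insensitive with underscores and spaces equivalent.
    Returns the pruned tree and the species absent from the tree; reference
    ribosomal trees typically lack a handful of database taxa, and those are
    simply ignored downstream.  Degree-2 internal nodes left by pruning are
    suppressed with their branch lengths summed.  Raises on zero overlap.
    """
    species = list(species)
    if not species:
        raise ValueError("empty species list")
    tip_by_key = {normalize_name(n): n for n in tree.tip_names}
    matched = [tip_by_key[normalize_name(s)] for s in species if normalize_name(s) in tip_by_key]
    dropped = [s for s in species if normalize_name(s) not in tip_by_key]
    if not matched:
        raise ValueError("no overlap between species list and tree tips")
    clone = dendropy.Tree(tree.tree)
    clone.retain_taxa_with_labels(matched)
    clone.purge_taxon_namespace()
    return Phylogeny(clone), dropped


# ---------------------------------------------------------------------------
# logistic fits


@dataclass
class LogisticFit:
    betas: np.ndarray  # intercept first
    loglik: float
    converged: bool
    n: int
    method: str
    se: np.ndarray | None = None
    alpha: float | None = None  # mean-reversion rate (corrected fit only)
    sigma2: float | None = None  # phylogenetic variance (corrected fit only)
    n_dropped: int = 0
    predictor_names: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    trace: list = field(default_factory=list)

    @property
    def beta0(self) -> float:
        return float(self.betas[0])

    @property
    def beta1(self) -> float:
        if len(self.betas) < 2:
            raise AttributeError("intercept-only fit has no slope")
        return float(self.betas[1])

    @property
    def n_params(self) -> int:
        extra = 2 if self.sigma2 is not None and self.sigma2 > 0 else 0
        return len(self.betas) + extra


def _design(y, x, reference_level=None):
    """Validate response, drop unknown-x rows, dummy-code categorical x.

    Returns (y, X, predictor_names, n_dropped, kept_index).  ``x=None``
    builds the intercept-only design.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if x is None:
        keep = np.ones(n, dtype=bool)
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        x_arr = np.asarray(x, dtype=object)
        if len(x_arr) != n:
            raise ValueError("x and y length mismatch")
        is_missing = np.array(
            [v is None or (isinstance(v, float) and math.isnan(v)) for v in x_arr]
        )
        keep = ~is_missing
        x_kept = x_arr[keep]
        numeric = all(isinstance(v, (int, float, np.integer, np.floating, bool, np.bool_)) for v in x_kept)
        if numeric:
            col = x_kept.astype(float)
            X = np.column_stack([np.ones(len(col)), col])
            names = ["intercept", "x"]
        else:
            levels = sorted({str(v) for v in x_kept})
            ref = str(reference_level) if reference_level is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed")
            dummies = [lvl for lvl in levels if lvl != ref]
            cols = [np.array([1.0 if str(v) == lvl else 0.0 for v in x_kept]) for lvl in dummies]
            X = np.column_stack([np.ones(len(x_kept))] + cols)
            names = ["intercept"] + [f"x[{lvl}]" for lvl in dummies]
    y_kept = y[keep]
    classes = set(np.unique(y_kept))
    if not classes <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("response has a single class")
    return y_kept, X, names, int(n - keep.sum()), keep


def _bernoulli_loglik(y, eta):
    # numerically stable: -log(1 + exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(-np.logaddexp(0.0, -(2 * y - 1) * eta).sum())


def _irls_logistic(y, X):
    """Plain IRLS maximum-likelihood logistic fit."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(_MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / W
        XtW = X.T * W
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        ll = _bernoulli_loglik(y, X @ beta)
        if abs(ll - ll_old) < _LOGLIK_TOL:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    W = np.maximum(p * (1 - p), 1e-10)
    cov = np.linalg.pinv((X.T * W) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, ll_old, converged, se


def naive_logistic(y, x, *, reference_level=None) -> LogisticFit:
    """Species-as-independent logistic regression of y on a single trait.

    *x* may be binary/quantitative (numeric) or categorical (strings,
    dummy-coded against *reference_level*, default the first level).  Rows
    with unknown x (None/NaN) are dropped and counted.  Complete or
    quasi-complete separation is detected (runaway coefficients) and flagged
    rather than silently returned.
    """
    y_kept, X, names, n_dropped, _ = _design(y, x, reference_level)
    beta, ll, converged, se = _irls_logistic(y_kept, X)
    flags = []
    if np.abs(beta).max() > _SEPARATION_BETA:
        flags.append("separation")
    return LogisticFit(
        betas=beta,
        loglik=ll,
        converged=converged,
        n=len(y_kept),
        method="naive_logistic_irls",
        se=se,
        n_dropped=n_dropped,
        predictor_names=names,
        flags=flags,
    )


def ou_correlation(S: np.ndarray, T: np.ndarray, alpha: float) -> np.ndarray:
    """Tip correlation of a root-conditioned OU process on the tree."""
    denom_i = 1.0 - np.exp(-2.0 * alpha * T)
    denom_i = np.maximum(denom_i, 1e-12)
    decay = np.exp(-alpha * (T[:, None] + T[None, :] - 2.0 * S))
    shared = 1.0 - np.exp(-2.0 * alpha * S)
    C = decay * shared / np.sqrt(np.outer(denom_i, denom_i))
    np.fill_diagonal(C, 1.0)
    return C


def _laplace_loglik(y, X, L, sigma2, beta_init=None):
    """Laplace marginal loglik of the GLMM at (sigma2, C = L L').

    Latent effects are parameterized u = sigma * L * w with w ~ N(0, I);
    (beta, w) are found by penalized IRLS; the marginal likelihood uses the
    log-determinant of the Hessian I + sigma^2 L' W L.
    """
    n = len(y)
    p = X.shape[1]
    sigma = math.sqrt(sigma2)
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    w = np.zeros(n)
    obj_old = -np.inf
    converged = False
    A = np.empty((n, p + n))
    A[:, :p] = X
    A[:, p:] = sigma * L
    P = np.zeros((p + n, p + n))
    P[p:, p:] = np.eye(n)
    gamma = np.concatenate([beta, w])
    for _ in range(_MAX_ITER):
        eta = np.clip(A @ gamma, -30, 30)
        prob = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(prob * (1 - prob), 1e-10)
        z = eta + (y - prob) / W
        AtW = A.T * W
        H = AtW @ A + P
        try:
            gamma_new = np.linalg.solve(H, AtW @ z)
        except np.linalg.LinAlgError:
            return -np.inf, beta, False
        # step-halving on the penalized objective
        obj_new = None
        step = gamma_new - gamma
        for _half in range(30):
            cand = gamma + step
            eta_c = np.clip(A @ cand, -30, 30)
            obj_c = _bernoulli_loglik(y, eta_c) - 0.5 * float(cand[p:] @ cand[p:])
            if obj_c >= obj_old - 1e-12 or not np.isfinite(obj_old):
                gamma = cand
                obj_new = obj_c
                break
            step *= 0.5
        if obj_new is None:
            break
        if abs(obj_new - obj_old) < _LOGLIK_TOL:
            converged = True
            obj_old = obj_new
            break
        obj_old = obj_new
    beta = gamma[:p]
    w = gamma[p:]
    eta = np.clip(A @ gamma, -30, 30)
    prob = 1.0 / (1.0 + np.exp(-eta))
    W = np.maximum(prob * (1 - prob), 1e-10)
    M = np.eye(n) + sigma2 * (L.T * W) @ L
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf, beta, False
    ll = _bernoulli_loglik(y, eta) - 0.5 * float(w @ w) - 0.5 * logdet
    return ll, beta, converged


def phylo_logistic(
    y,
    x,
    tree: Phylogeny,
    species: Sequence[str] | None = None,
    *,
    reference_level=None,
    seed: int | None = 0,
    n_starts: int = 2,
    fix_sigma2: float | None = None,
    extra_starts: Sequence[tuple[float, float]] = (),
) -> LogisticFit:
    """Phylogenetically corrected logistic regression (Ives-Garland-type).

    *species* names the observations (defaults to the tree's tip order) and
    is matched against the tree; observations whose species is missing from
    the tree, and species without data, are dropped.  The tree is scaled to
    unit height, the mean-reverting correlation C(alpha) built from shared
    ancestry, and (beta, sigma^2, alpha) estimated by maximizing the
    Laplace-approximated marginal likelihood with seeded random restarts of
    the signal parameters.  ``fix_sigma2=0`` forces the no-correlation limit
    (exactly the naive fit).

    If the matched tree has no shared internal branches (a star tree) the
    correlation is identically zero whatever alpha; the naive fit is
    returned, flagged ``no_shared_ancestry``.
    """
    if species is None:
        species = tree.tip_names
    species = list(species)
    y = np.asarray(y, dtype=float)
    if len(species) != len(y):
        raise ValueError("species and y length mismatch")

    tip_keys = {normalize_name(n) for n in tree.tip_names}
    on_tree = np.array([normalize_name(s) in tip_keys for s in species])
    y_kept, X, names, n_dropped_x, keep_x = _design(y, x, reference_level)
    keep = keep_x & on_tree
    n_dropped = int(len(y) - keep.sum())
    # rebuild the design on the jointly kept rows
    y_use, X_use, names, _, _ = _design(
        y[keep], None if x is None else np.asarray(x, dtype=object)[keep], reference_level
    )
    kept_species = [s for s, k in zip(species, keep) if k]

    pruned, _ = prune_to_overlap(tree, kept_species)
    pruned = pruned.scale_to_unit_height()
    S, T = pruned.shared_depth_matrix(kept_species)

    # naive fit on the same design: the sigma2 -> 0 boundary of the GLMM
    beta_n, ll_naive, conv_n, se_n = _irls_logistic(y_use, X_use)

    off_diag = S.copy()
    np.fill_diagonal(off_diag, 0.0)
    star = off_diag.max() <= 1e-12
    if star or fix_sigma2 == 0.0:
        flags = ["no_shared_ancestry"] if star else ["sigma2_fixed_zero"]
        if np.abs(beta_n).max() > _SEPARATION_BETA:
            flags.append("separation")
        return LogisticFit(
            betas=beta_n,
            loglik=ll_naive,
            converged=conv_n,
            n=len(y_use),
            method="phylo_logistic_laplace",
            se=se_n,
            alpha=None,
            sigma2=0.0,
            n_dropped=n_dropped,
            predictor_names=names,
            flags=flags,
        )

    rng = np.random.default_rng(seed)
    chol_cache: dict[float, np.ndarray] = {}

    def chol_for(alpha: float) -> np.ndarray:
        key = round(float(alpha), 10)
        if key not in chol_cache:
            C = ou_correlation(S, T, alpha)
            try:
                chol_cache[key] = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                chol_cache[key] = np.linalg.cholesky(C + 1e-8 * np.eye(len(C)))
        return chol_cache[key]

    def neg_ll(theta) -> float:
        log_s2 = float(np.clip(theta[0], -18.0, 6.0))
        log_a = float(np.clip(theta[1], -6.0, 5.0))
        if fix_sigma2 is not None:
            s2 = fix_sigma2
        else:
            s2 = math.exp(log_s2)
        ll, _, _ = _laplace_loglik(y_use, X_use, chol_for(math.exp(log_a)), s2, beta_init=beta_n)
        return -ll

    starts = [np.array([math.log(1.0), math.log(1.0)])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.array([rng.uniform(-3, 2), rng.uniform(-2, 2.5)]))
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    best = None
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s0 in starts:
            res = optimize.minimize(
                neg_ll, s0, method="Nelder-Mead",
                options={"xatol": 2e-2, "fatol": 1e-4, "maxiter": 60},
            )
            trace.append((list(s0), float(-res.fun)))
            if best is None or res.fun < best.fun:
                best = res

    log_s2, log_a = float(np.clip(best.x[0], -18.0, 6.0)), float(np.clip(best.x[1], -6.0, 5.0))
    sigma2 = math.exp(log_s2) if fix_sigma2 is None else fix_sigma2
    alpha = math.exp(log_a)
    ll, beta, conv = _laplace_loglik(y_use, X_use, chol_for(alpha), sigma2, beta_init=beta_n)

    flags = []
    # the sigma2 -> 0 boundary is the naive model; never report a worse fit
    if ll < ll_naive:
        sigma2, alpha = 0.0, None
        beta, ll, conv, se = beta_n, ll_naive, conv_n, se_n
        flags.append("boundary_sigma2_zero")
    else:
        se = None
    if np.abs(beta).max() > _SEPARATION_BETA:
        flags.append("separation")
    if not conv:
        flags.append("not_converged")
    return LogisticFit(
        betas=np.asarray(beta),
        loglik=float(ll),
        converged=bool(conv),
        n=len(y_use),
        method="phylo_logistic_laplace",
        se=se,
        alpha=alpha,
        sigma2=float(sigma2),
        n_dropped=n_dropped,
        predictor_names=names,
        flags=flags,
        trace=trace,
    )


def phylo_lrt(
    y,
    x,
    tree: Phylogeny,
    species: Sequence[str] | None = None,
    *,
    reference_level=None,
    seed: int | None = 0,
    n_starts: int = 1,
) -> tuple[LogisticFit, LogisticFit, float, float]:
    """Corrected regression screened against its intercept-only null.

    Fits the null first and warm-starts the full model's signal-parameter
    search at the null's optimum, so the full likelihood can never fall
    below the null's for want of a good starting point (the two models are
    nested at equal signal parameters).  Returns
    (fit_full, fit_null, statistic, p).
    """
    if species is None:
        species = tree.tip_names
    # drop missing-x rows up front so both fits share the observation set
    x_arr = None if x is None else np.asarray(x, dtype=object)
    if x_arr is not None:
        known = np.array(
            [not (v is None or (isinstance(v, float) and math.isnan(v))) for v in x_arr]
        )
        y = np.asarray(y, dtype=float)[known]
        x_arr = x_arr[known]
        species = [s for s, k in zip(species, known) if k]
    x = x_arr
    fit_null = phylo_logistic(
        y, None, tree, species, seed=seed, n_starts=n_starts
    )
    def _hyper(fit):
        if fit.sigma2 and fit.alpha:
            return [(math.log(fit.sigma2), math.log(fit.alpha))]
        return []

    # symmetric cross-warm-starting: each model also starts its signal
    # search at the other's optimum, so neither enjoys an optimization
    # advantage in the LRT; iterate until the pair is consistent
    fit_full = phylo_logistic(
        y, x, tree, species,
        reference_level=reference_level, seed=seed, n_starts=n_starts,
        extra_starts=_hyper(fit_null),
    )
    for _round in range(2):
        fit_null_b = phylo_logistic(
            y, None, tree, species, seed=seed, n_starts=n_starts,
            extra_starts=_hyper(fit_full),
        )
        if fit_null_b.loglik > fit_null.loglik:
            fit_null = fit_null_b
        if fit_full.loglik >= fit_null.loglik - 1e-3:
            break
        fit_full_b = phylo_logistic(
            y, x, tree, species,
            reference_level=reference_level, seed=seed, n_starts=n_starts,
            extra_starts=_hyper(fit_null),
        )
        if fit_full_b.loglik > fit_full.loglik:
            fit_full = fit_full_b
        else:
            break
    statistic, p = lrt(fit_full, fit_null, df=len(fit_full.betas) - 1)
    return fit_full, fit_null, statistic, p


def lrt(fit_full: LogisticFit, fit_null: LogisticFit, df: int | None = None) -> tuple[float, float]:
    """Likelihood-ratio test of a full against a nested null fit.

    statistic = 2 (loglik_full - loglik_null), clipped at zero; p from a
    chi-square with df = difference in regression-parameter count (the
    variance/signal parameters are not counted when shared).  A full
    log-likelihood materially below the null one indicates an optimization
    failure and raises.
    """
    if fit_full.n != fit_null.n:
        raise ValueError("fits use different observation counts")
    delta = fit_full.loglik - fit_null.loglik
    # Laplace-approximated likelihoods do not preserve nesting exactly (the
    # curvature term is evaluated at different modes); small violations are
    # approximation noise and clip to 0, larger ones are genuine failures
    if delta < -5e-2:
        raise ValueError(
            f"full loglik {fit_full.loglik:.6f} below null {fit_null.loglik:.6f}: optimization failure"
        )
    statistic = max(0.0, 2.0 * delta)
    if df is None:
        df = len(fit_full.betas) - len(fit_null.betas)
    if df < 1:
        raise ValueError("null not nested in full (df < 1)")
    return statistic, float(stats.chi2.sf(statistic, df))
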