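"""Differentially methylated probe (DMP) selection between two subtypes.

A feature (probe or segment) is called *potentially discriminating* when it

1. differs significantly between the two groups (two-sided Mann-Whitney U,
   Benjamini-Hochberg adjusted p < 0.05),
2. stays significant in >= 95% of 100 stratified bootstrap resamples, and
3. shows an absolute difference in group median M values > 0.9 (the mean
   of the 0.4-1.4 cutoff range recommended for M-value effect sizes).

Probes, segments (via their member probes) and LASSO-selected HMM states
(via their member probes, with the per-probe ΔM filter) form three routes;
the final DMP set is their intersection, split by direction of the median
difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: recommended M-value cutoff range; the default threshold is its midpoint
DELTA_M_RANGE = (0.4, 1.4)


def recommended_delta_m(low: float = DELTA_M_RANGE[0], high: float = DELTA_M_RANGE[1]) -> float:
    """Midpoint of the recommended ΔM cutoff range (default 0.9)."""
    return (low + high) / 2.0


DEFAULT_DM_MIN = recommended_delta_m()
#: largest per-group size for which the exact MWU null is used (no ties)
EXACT_MWU_MAX_N = 12


def _mwu_asymptotic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided MWU p-values, rows = features.

    Normal approximation with tie correction and continuity correction;
    features whose pooled values are all tied get p = 1.
    """
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    pooled = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u_a = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    # tie term sum_t (t^3 - t) == sum_i (c_i^2 - 1), c_i = multiplicity of value i
    eq = pooled[:, :, None] == pooled[:, None, :]
    c = eq.sum(axis=2)
    tie_term = (c * c - 1).sum(axis=1)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u_a - mu) - 0.5) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


_exact_cache: dict[tuple[int, int], np.ndarray] = {}


def _exact_u_counts(na: int, nb: int) -> np.ndarray:
    """Null distribution of U (counts over 0..na*nb) by dynamic programming."""
    key = (na, nb)
    if key not in _exact_cache:
        # counts[u] after processing items; classic partition recurrence
        counts = np.zeros(na * nb + 1, dtype=float)
        counts[0] = 1.0
        # number of ways to choose ranks so that U = u: generating function
        # prod_{i=1..na} (1 - x^{nb+i}) / (1 - x^i)
        for i in range(1, na + 1):
            new = np.zeros_like(counts)
            for u in range(len(counts)):
                new[u] = counts[u] + (new[u - i] if u >= i else 0.0)
            counts = new
            for u in range(len(counts) - 1, -1, -1):
                if u >= nb + i:
                    counts[u] -= counts[u - (nb + i)]
        _exact_cache[key] = counts
    return _exact_cache[key]


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact two-sided MWU p-values (no ties assumed), rows = features."""
    na, nb = a.shape[1], b.shape[1]
    counts = _exact_u_counts(na, nb)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf_incl = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(U >= u)
    ranks = stats.rankdata(np.concatenate([a, b], axis=1), axis=1)
    u_a = (ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0).astype(int)
    p = 2.0 * np.minimum(cdf[u_a], sf_incl[u_a])
    return np.minimum(p, 1.0)


def mwu_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided MWU p per feature: exact for small tie-free groups,
    tie-corrected normal approximation with continuity correction otherwise."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    p = np.empty(a.shape[0])
    if a.shape[1] <= EXACT_MWU_MAX_N and b.shape[1] <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([a, b], axis=1)
        has_ties = (pooled[:, :, None] == pooled[:, None, :]).sum(axis=(1, 2)) > pooled.shape[1]
        if (~has_ties).any():
            p[~has_ties] = _mwu_exact(a[~has_ties], b[~has_ties])
        if has_ties.any():
            p[has_ties] = _mwu_asymptotic(a[has_ties], b[has_ties])
    else:
        p[:] = _mwu_asymptotic(a, b)
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mwu_bh(
    features: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-sided MWU with BH adjustment across all tested features.

    ``features`` is an M-value matrix (features × samples).  Returns a frame
    indexed like ``features`` with p_raw, p_adj and significant.
    """
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both groups must be non-empty")
    a = features[cols_a].to_numpy(dtype=float)
    b = features[cols_b].to_numpy(dtype=float)
    p_raw = mwu_pvalues(a, b)
    p_adj = bh_adjust(p_raw)
    return pd.DataFrame(
        {"p_raw": p_raw, "p_adj": p_adj, "significant": p_adj < alpha}, index=features.index
    )


def bootstrap_validate(
    features: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    adjust: Literal["bh", "raw"] = "bh",
) -> pd.Series:
    """Stratified-bootstrap stability of each feature's group difference.

    Each replicate resamples with replacement within each group (preserving
    group sizes); a feature counts as supported in a replicate when its MWU
    test is significant there (BH-adjusted across the candidate set within
    the replicate by default).  Returns the support fraction per feature.
    """
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ValueError("bootstrap needs at least 2 samples per group")
    a = features[cols_a].to_numpy(dtype=float)
    b = features[cols_b].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    supported = np.zeros(len(features), dtype=int)
    for _ in range(n_boot):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        # resampling duplicates values, so the tie-aware approximation applies
        p = _mwu_asymptotic(a[:, ia], b[:, ib])
        if adjust == "bh":
            p = bh_adjust(p)
        supported += p < alpha
    return pd.Series(supported / n_boot, index=features.index, name="support")


def delta_median(features: pd.DataFrame, cols_a: list[str], cols_b: list[str]) -> pd.Series:
    """median M(A) − median M(B) per feature."""
    da = np.median(features[cols_a].to_numpy(dtype=float), axis=1)
    db = np.median(features[cols_b].to_numpy(dtype=float), axis=1)
    return pd.Series(da - db, index=features.index, name="delta_m")


def evaluate_features(
    features: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    alpha: float = 0.05,
    n_boot: int = 100,
    support_min: float = 0.95,
    dm_min: float = DEFAULT_DM_MIN,
    seed: int = 0,
    boot_adjust: Literal["bh", "raw"] = "bh",
) -> pd.DataFrame:
    """Full per-feature discrimination test (significance, stability, effect).

    A feature passes iff BH-significant AND bootstrap support >= support_min
    AND |Δ median M| > dm_min (strict).  Direction is the sign of the median
    difference; bootstrap support is only evaluated for significant features
    (others get support 0).
    """
    res = mwu_bh(features, cols_a, cols_b, alpha=alpha)
    res["delta_m"] = delta_median(features, cols_a, cols_b)
    res["support"] = 0.0
    sig = res.index[res["significant"]]
    if len(sig):
        res.loc[sig, "support"] = bootstrap_validate(
            features.loc[sig], cols_a, cols_b, n_boot=n_boot, alpha=alpha, seed=seed, adjust=boot_adjust
        )
    res["passes"] = (
        res["significant"] & (res["support"] >= support_min) & (res["delta_m"].abs() > dm_min)
    )
    res["direction"] = np.where(
        res["passes"], np.where(res["delta_m"] > 0, "hyperA", "hyperB"), "none"
    )
    return res


def lasso_state_selection(
    state_medians: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    positive_only: bool = False,
) -> tuple[list, pd.Series]:
    """Select discriminating HMM states by L1 logistic regression (1-SE rule).

    ``state_medians`` is states × samples.  Features are standardized; a
    100-value λ path is walked from λ_max (all coefficients zero) downward;
    per-λ cross-validated binomial deviance with its standard error gives
    λ_1se = the largest λ whose CV error is within one SE of the minimum.
    States with nonzero coefficient in the λ_1se model are returned
    (``positive_only`` restricts to strictly positive coefficients).
    Deterministic given ``seed``.
    """
    if state_medians.shape[0] < 1:
        raise ValueError("need at least one state")
    cols = list(cols_a) + list(cols_b)
    if len(set(cols_a) & set(cols_b)):
        raise ValueError("groups overlap")
    X = state_medians[cols].to_numpy(dtype=float).T  # samples × states
    y = np.r_[np.ones(len(cols_a)), np.zeros(len(cols_b))]
    if y.min() == y.max():
        raise ValueError("both groups must be represented")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    n = len(y)

    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    if lam_max <= 0:
        lam_max = 1e-3
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    folds = min(n_folds, int(y.sum()), int((1 - y).sum()))
    if folds < n_folds:
        logger.warning("reducing CV folds from %d to %d (small groups)", n_folds, folds)
    if folds < 2:
        raise ValueError("need at least 2 samples per group for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def _fit(Xtr, ytr, lam):
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(ytr) * lam), solver="liblinear", tol=1e-7, max_iter=20000
        )
        clf.fit(Xtr, ytr)
        return clf

    eps = 1e-12
    dev = np.zeros((folds, n_lambda))
    for f, (tr, te) in enumerate(skf.split(Xs, y)):
        for j, lam in enumerate(lambdas):
            clf = _fit(Xs[tr], y[tr], lam)
            prob = np.clip(clf.predict_proba(Xs[te])[:, 1], eps, 1 - eps)
            dev[f, j] = -2.0 * np.mean(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob))
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(cv_mean))
    threshold = cv_mean[j_min] + cv_se[j_min]
    j_1se = int(np.flatnonzero(cv_mean <= threshold)[0])  # largest λ within 1 SE

    clf = _fit(Xs, y, lambdas[j_1se])
    coef = pd.Series(clf.coef_.ravel(), index=state_medians.index, name="coef")
    if positive_only:
        selected = list(coef.index[coef > 1e-8])
    else:
        selected = list(coef.index[coef.abs() > 1e-8])
    return selected, coef


@dataclass
class DmpSet:
    """Direction-labelled differential probes for one pairwise comparison."""

    comparison: tuple[str, str]
    hyper_a: set[str]
    hyper_b: set[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.hyper_a & self.hyper_b:
            raise ValueError("hyper_a and hyper_b must be disjoint")

    @property
    def n_total(self) -> int:
        return len(self.hyper_a) + len(self.hyper_b)

    def swapped(self) -> "DmpSet":
        return DmpSet(
            comparison=(self.comparison[1], self.comparison[0]),
            hyper_a=set(self.hyper_b),
            hyper_b=set(self.hyper_a),
            provenance=self.provenance,
        )


def intersect_dmps(
    state_route: dict[str, set[str]],
    segment_route: dict[str, set[str]],
    probe_route: dict[str, set[str]],
    comparison: tuple[str, str],
    universe: Iterable[str] | None = None,
) -> DmpSet:
    """Intersect the three routes, separately per direction.

    Each route maps direction ('hyperA' / 'hyperB') to the probe ids it
    admits.  A probe is a DMP iff all three routes admit it in the same
    direction.  ``universe`` (the valid-probe set) is used to reject routes
    computed on different probe universes.
    """
    routes = {"state": state_route, "segment": segment_route, "probe": probe_route}
    if universe is not None:
        uni = set(universe)
        for name, route in routes.items():
            for direction, ids in route.items():
                stray = ids - uni
                if stray:
                    raise ValueError(
                        f"{name} route ({direction}) contains probes outside the "
                        f"universe, e.g. {sorted(stray)[:3]}"
                    )
    out: dict[str, set[str]] = {}
    for direction in ("hyperA", "hyperB"):
        sets = [route.get(direction, set()) for route in routes.values()]
        out[direction] = set.intersection(*sets) if sets else set()
    rows = []
    for direction in ("hyperA", "hyperB"):
        for pid in sorted(out[direction]):
            rows.append(
                {
                    "probe_id": pid,
                    "direction": direction,
                    "routes": "state;segment;probe",
                }
            )
    return DmpSet(
        comparison=comparison,
        hyper_a=out["hyperA"],
        hyper_b=out["hyperB"],
        provenance=pd.DataFrame(rows, columns=["probe_id", "direction", "routes"]),
    )
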