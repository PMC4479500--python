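"""Enrichment, imprinting/X summaries and global distribution descriptors.

Enrichment of a DMP set in a functional category compares the category
membership of DMPs against non-DMPs in a 2×2 table (two-sided Fisher's
exact test) at a Bonferroni-corrected threshold covering the functional
categories, the chromosomes and the HMM states tested alongside.  The
effect is reported as log2(%DMPs in category / %non-DMPs in category),
the scale used to display over-/underrepresentation.

Imprinting-control-region (ICR) and X-chromosome summaries reduce each
group to median β and distribution descriptors; qualitative bands
(erased < 0.25 <= somatic <= 0.75 < uniparental) are an artifact-defined
reading aid, not a published convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .annotation import FunctionalCategories
from .preprocess import MethylationMatrix

logger = logging.getLogger(__name__)


def bonferroni_alpha(
    n_functional: int = 18, n_chromosomes: int = 24, n_states: int = 20, alpha: float = 0.05
) -> float:
    """Bonferroni-corrected per-test threshold: alpha / (categories + chromosomes + states)."""
    return alpha / (n_functional + n_chromosomes + n_states)


@dataclass
class EnrichmentResult:
    category: str
    n_dmp_in: int
    n_dmp_out: int
    n_non_in: int
    n_non_out: int
    odds_ratio: float
    p_value: float
    significant: bool
    log2_ratio: float | None  # None when 0 DMPs fall in the category

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n_dmp_in, self.n_dmp_out], [self.n_non_in, self.n_non_out]])


def fisher_enrichment(
    dmp_ids: set[str],
    universe: set[str],
    categories: dict[str, set[str]] | FunctionalCategories,
    alpha_bonf: float,
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact enrichment of a DMP set per category.

    The 2×2 table is (DMP vs non-DMP) × (in vs out of category) over the
    valid-probe universe.  Categories without universe members are skipped
    with a warning.  A zero DMP-in-category count leaves the log2 ratio
    undefined (reported as None) while the significance call is retained.
    """
    if isinstance(categories, FunctionalCategories):
        categories = categories.category_map
    if not dmp_ids <= universe:
        raise ValueError("DMP set must be a subset of the universe")
    non = universe - dmp_ids
    n_dmp, n_non = len(dmp_ids), len(non)
    results = []
    for name, members in categories.items():
        members = members & universe
        if not members:
            logger.warning("category %s has no universe members; skipped", name)
            continue
        a = len(dmp_ids & members)
        b = n_dmp - a
        c = len(non & members)
        d = n_non - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if a > 0 and n_dmp > 0 and c > 0:
            log2_ratio = float(np.log2((a / n_dmp) / (c / n_non)))
        elif a > 0 and n_dmp > 0 and c == 0:
            log2_ratio = float("inf")
        else:
            log2_ratio = None
        results.append(
            EnrichmentResult(
                category=name,
                n_dmp_in=a,
                n_dmp_out=b,
                n_non_in=c,
                n_non_out=d,
                odds_ratio=float(odds),
                p_value=float(p),
                significant=bool(p < alpha_bonf),
                log2_ratio=log2_ratio,
            )
        )
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "n_dmp_in": [r.n_dmp_in for r in results],
            "n_dmp_out": [r.n_dmp_out for r in results],
            "n_non_in": [r.n_non_in for r in results],
            "n_non_out": [r.n_non_out for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "log2_ratio": [r.log2_ratio for r in results],
        }
    )


# qualitative ICR methylation bands — an artifact convention for summaries
# and test assertions only, not a published definition
IMPRINT_BANDS = {"erased": (0.0, 0.25), "somatic": (0.25, 0.75), "uniparental": (0.75, 1.0)}


def imprint_band(median_beta: float) -> str:
    if median_beta < IMPRINT_BANDS["erased"][1]:
        return "erased"
    if median_beta <= IMPRINT_BANDS["somatic"][1]:
        return "somatic"
    return "uniparental"


@dataclass
class GroupDistributionSummary:
    group: str
    subset: str
    quantiles: dict[str, float]  # min, q25, median, q75, max
    density_grid: np.ndarray  # β grid on [0, 1]
    density: np.ndarray  # integrates to 1 on the grid

    @property
    def median(self) -> float:
        return self.quantiles["median"]


def distribution_summary(
    matrix: MethylationMatrix,
    probe_subset: set[str] | None,
    groups: dict[str, list[str]],
    subset_name: str = "all",
    bandwidth: float | None = None,
    grid_size: int = 256,
) -> list[GroupDistributionSummary]:
    """Pooled-β quantiles and Gaussian-kernel density per group.

    Pooling is over all probes of the subset and all samples of the group.
    Bandwidth defaults to Silverman's rule on the pooled values.  The
    density is renormalized to integrate to 1 on the [0, 1] grid.
    """
    if probe_subset is not None:
        rows = matrix.probes.df["probe_id"].isin(probe_subset).to_numpy()
        if not rows.any():
            raise ValueError("probe subset is empty within the matrix")
    else:
        rows = np.ones(len(matrix.probes), dtype=bool)
    grid = np.linspace(0.0, 1.0, grid_size)
    out = []
    for group, cols in groups.items():
        if not cols:
            raise ValueError(f"group {group} has no samples")
        vals = matrix.beta.loc[rows, cols].to_numpy().ravel()
        qs = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
        if np.ptp(vals) > 0:
            kde = stats.gaussian_kde(vals, bw_method=bandwidth)
            dens = kde(grid)
        else:
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - vals[0]))] = 1.0
        area = np.trapezoid(dens, grid)
        if area > 0:
            dens = dens / area
        out.append(
            GroupDistributionSummary(
                group=group,
                subset=subset_name,
                quantiles=dict(zip(["min", "q25", "median", "q75", "max"], map(float, qs))),
                density_grid=grid,
                density=dens,
            )
        )
    return out


def imprinting_summary(
    matrix: MethylationMatrix,
    categories: dict[str, set[str]],
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per group × category median β, quantiles and qualitative band.

    ``categories`` typically holds ICR_P, ICR_M and X_CHROM probe sets.
    """
    rows = []
    for cat, probe_ids in categories.items():
        if not probe_ids:
            raise ValueError(f"category {cat} is empty")
        summaries = distribution_summary(matrix, probe_ids, groups, subset_name=cat)
        for s in summaries:
            rows.append(
                {
                    "category": cat,
                    "group": s.group,
                    "median_beta": s.median,
                    "q25": s.quantiles["q25"],
                    "q75": s.quantiles["q75"],
                    "band": imprint_band(s.median),
                }
            )
    return pd.DataFrame(rows)


def pca_summary(
    m_values: pd.DataFrame,
    groups: dict[str, list[str]],
    n_boot: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-component PCA of samples with bootstrap silhouette validation.

    ``m_values`` is features × samples; samples are mean-centered per
    feature and projected on the first two principal components.  Group
    separation is summarized as the silhouette of the group labels in
    PC1-2 space, recomputed on stratified bootstrap resamples of samples.
    With fewer than 2 groups the silhouette is undefined (reported None).
    """
    cols = [c for g in groups.values() for c in g]
    labels = np.array([g for g, cs in groups.items() for _ in cs])
    if len(cols) < 3 or m_values.shape[0] < 2:
        raise ValueError("need at least 3 samples and 2 features")
    if len(set(cols)) < len(cols):
        raise ValueError("duplicate samples across groups")
    if len(cols) < len(groups):
        raise ValueError("fewer samples than groups")
    X = m_values[cols].to_numpy(dtype=float).T  # samples × features
    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(X - X.mean(axis=0))
    score_df = pd.DataFrame(scores, index=cols, columns=["PC1", "PC2"])
    score_df["group"] = labels

    report: dict = {"explained_variance_ratio": pca.explained_variance_ratio_.tolist()}
    if len(groups) < 2:
        report["silhouette"] = None
        report["bootstrap_silhouette"] = None
        return score_df, report
    report["silhouette"] = float(silhouette_score(scores, labels))
    rng = np.random.default_rng(seed)
    boots = []
    idx_by_group = {g: np.flatnonzero(labels == g) for g in groups}
    for _ in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True) for idx in idx_by_group.values()]
        )
        Xb = X[take]
        sb = PCA(n_components=2, random_state=seed).fit_transform(Xb - Xb.mean(axis=0))
        lb = labels[take]
        if len(set(lb)) > 1 and all(np.sum(lb == g) > 1 for g in set(lb)):
            boots.append(float(silhouette_score(sb, lb)))
    report["bootstrap_silhouette"] = float(np.mean(boots)) if boots else None
    return score_df, report
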