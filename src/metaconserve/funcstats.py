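"""Functional-category statistics and general test helpers.

Category abundances are weighted read counts per functional category as a
proportion of all category-mapped reads in a detection fraction (expressed
= SHARED, non-expressed = DNA_ONLY).  Proportional changes between
fractions get per-category 2x2 chi-squares; consistency of the direction
of change across samples is compared against the random expectation
C x 2 x (1/2)^S.  Samples are related by average-linkage clustering on
1 - centered Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "category_abundance",
    "fraction_change",
    "direction_consistency",
    "hcluster",
    "chisq_2x2",
    "t_test",
    "bonferroni",
]


# ---------------------------------------------------------------------------
# basic tests


def chisq_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[a, b], [c, d]].  Returns (chi2, p)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Welch (unequal-variance) t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals: Sequence[float], m: int) -> list[float]:
    """Adjusted p = min(1, p * m)."""
    return [min(1.0, p * m) for p in pvals]


# ---------------------------------------------------------------------------
# category abundances


def category_abundance(
    profiles: pd.DataFrame,
    fraction: str,
    level: str = "category_id",
    pool: str = "dna",
) -> pd.DataFrame:
    """Weighted read counts and proportions per functional category within a
    detection fraction.

    ``fraction`` is SHARED (expressed) or DNA_ONLY (non-expressed); counts
    are the profiles' weighted read counts (``dna_count`` by default) summed
    per annotation ``level``; proportions normalise to the category-mapped
    total within the fraction.
    """
    count_col = f"{pool}_count"
    sub = profiles[(profiles["fraction"] == fraction) & profiles[level].notna()]
    counts = sub.groupby(level)[count_col].sum().sort_index()
    total = counts.sum()
    return pd.DataFrame(
        {
            "count": counts,
            "proportion": counts / total if total > 0 else np.nan,
        }
    )


def fraction_change(
    expr_ab: pd.DataFrame,
    nonexpr_ab: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category proportional change between expressed and non-expressed
    abundances with chi-square tests.

    change = ((p_expr - p_nonexpr) / p_nonexpr) x 100.  The 2x2 chi-square
    per category uses read counts (category vs rest, expressed vs
    non-expressed); Bonferroni across the category universe.  Categories
    with p_nonexpr = 0 are flagged undefined.
    """
    cats = sorted(set(expr_ab.index) | set(nonexpr_ab.index))
    te = expr_ab["count"].sum()
    tn = nonexpr_ab["count"].sum()
    rows = []
    for cat in cats:
        ce = float(expr_ab["count"].get(cat, 0.0))
        cn = float(nonexpr_ab["count"].get(cat, 0.0))
        pe = ce / te if te else np.nan
        pn = cn / tn if tn else np.nan
        change = ((pe - pn) / pn * 100.0) if pn else math.nan
        chi2, p = chisq_2x2(ce, te - ce, cn, tn - cn)
        rows.append(
            dict(
                category=cat,
                p_expressed=pe,
                p_nonexpressed=pn,
                change_pct=change,
                chi2=chi2,
                p=p,
                defined=not math.isnan(change),
            )
        )
    out = pd.DataFrame(rows).set_index("category")
    out["p_adj"] = bonferroni(out["p"].tolist(), len(out))
    out["significant"] = (out["p_adj"] < alpha) & out["defined"]
    return out


def direction_consistency(
    changes: pd.DataFrame,
) -> tuple[int, float, float, float]:
    """Consistency of the direction of change across samples.

    ``changes`` is a categories x samples matrix of proportional changes
    (or signs).  A category is consistent when its sign is identical and
    nonzero across all S samples (a zero anywhere breaks consistency).
    Expected count under independent random directions is C x 2 x (1/2)^S.
    Returns (observed, expected, enrichment_ratio, chi-square p).
    """
    c, s = changes.shape
    if s < 2 or c < 1:
        raise ValueError("need >= 2 samples and >= 1 category")
    signs = np.sign(changes.to_numpy(dtype=float))
    consistent = ((signs == 1).all(axis=1)) | ((signs == -1).all(axis=1))
    observed = int(consistent.sum())
    expected = c * 2.0 * 0.5**s
    ratio = observed / expected if expected else math.nan
    # goodness of fit of (consistent, inconsistent) against expectation
    exp = np.array([expected, c - expected])
    obs = np.array([observed, c - observed])
    chi2 = float((((obs - exp) ** 2) / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return observed, expected, ratio, p


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]


def hcluster(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering of the matrix rows on the distance
    1 - centered Pearson correlation.

    Rows are samples (observations), columns their feature vectors (e.g.
    category proportions or amino-acid frequencies).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 vectors of >= 2 dimensions")
    x = matrix.to_numpy(dtype=float)
    dist = pdist(x, metric="correlation")  # 1 - centered Pearson
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    linkage = hierarchy.linkage(dist, method="average")
    return Dendrogram(labels=[str(i) for i in matrix.index], linkage=linkage)
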