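"""Environmental, phenotypic and genetic (patristic) distances, and the
RI ~ genetic + environmental/phenotypic distance regressions.

Trait matrices (populations x variables; e.g. 38 soil variables or 10
phenotypic traits) are column-standardised, ordinated by principal
components, and pairwise Euclidean distances are taken in the subspace of
axes explaining a target fraction of variance (classical metric MDS on
Euclidean distances of standardised data is equivalent to this PCA route).
Genetic distances are patristic: summed branch lengths between tips of a
phylogeny.  Reproductive isolation per population pair is then regressed on
genetic distance plus one other distance, with a sequential (type-I) F-test
for the second predictor after genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "DistanceError",
    "RegressionResult",
    "scale_columns",
    "reduce_and_distance",
    "patristic_distances",
    "ri_distance_regression",
]


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of RI on distances, with sequential F-tests.

    ``coefficients`` maps predictor name to estimate; ``f_statistics`` and
    ``p_values`` come from a type-I ANOVA in the order (genetic, other), so
    the second predictor is tested after controlling for genetic distance.
    ``small_n`` flags fits on six or fewer pairs.
    """

    coefficients: dict
    f_statistics: dict
    dfs: dict
    p_values: dict
    r_squared: float
    n_pairs: int
    small_n: bool


def scale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each variable to mean 0, sd 1 (n-1 denominator).

    Rejects constant (zero-variance) columns by name, and columns with fewer
    than two observed values.
    """
    numeric = matrix.astype(float)
    counts = numeric.notna().sum()
    thin = list(counts.index[counts < 2])
    if thin:
        raise DistanceError(f"columns with fewer than 2 values: {thin}")
    sd = numeric.std(ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        raise DistanceError(f"zero-variance columns cannot be standardised: {constant}")
    return (numeric - numeric.mean()) / sd


def explained_variance_fractions(scaled: pd.DataFrame) -> np.ndarray:
    """Fractions of total variance per principal axis (sum to 1)."""
    n_comp = min(scaled.shape)
    pca = PCA(n_components=n_comp)
    pca.fit(scaled.to_numpy())
    return pca.explained_variance_ratio_


def reduce_and_distance(
    scaled: pd.DataFrame,
    variance_target: float = 0.95,
    axes_override: int | None = None,
) -> pd.DataFrame:
    """Euclidean distances between populations in a truncated PC space.

    Retains the smallest number of principal axes whose cumulative explained
    variance reaches ``variance_target`` (or exactly ``axes_override`` axes
    when given, e.g. to force the 5-axis soil or 7-axis phenotype convention).
    Returns a symmetric distance matrix indexed by population.
    """
    if not (0.0 < variance_target <= 1.0):
        raise DistanceError("variance_target must lie in (0, 1]")
    x = scaled.to_numpy(dtype=float)
    max_axes = min(x.shape)
    if axes_override is not None:
        if not (1 <= axes_override <= max_axes):
            raise DistanceError(
                f"requested {axes_override} axes but only {max_axes} are available"
            )
        k = axes_override
    else:
        ratios = explained_variance_fractions(scaled)
        k = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12) + 1)
        k = min(k, max_axes)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    d = squareform(pdist(scores, metric="euclidean"))
    out = pd.DataFrame(d, index=scaled.index, columns=scaled.index)
    out.attrs["n_axes"] = k
    return out


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def patristic_distances(tree, populations) -> pd.DataFrame:
    """Patristic distance matrix: summed branch lengths between tips.

    ``tree`` is a dendropy Tree or a newick string; ``populations`` the tip
    labels wanted, in output order.  Missing tips and negative branch lengths
    raise :class:`DistanceError`.
    """
    t = _as_tree(tree)
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise DistanceError(f"negative branch length {edge.length} in tree")
    labels = {leaf.taxon.label: leaf.taxon for leaf in t.leaf_node_iter() if leaf.taxon}
    missing = [p for p in populations if p not in labels]
    if missing:
        raise DistanceError(f"populations absent from tree tips: {missing}")
    pdm = t.phylogenetic_distance_matrix()
    n = len(populations)
    d = np.zeros((n, n))
    for i, a in enumerate(populations):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(labels[a], labels[populations[j]])
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=list(populations), columns=list(populations))


def _pair_lookup(dm: pd.DataFrame, a: str, b: str) -> float:
    try:
        return float(dm.loc[a, b])
    except KeyError as exc:
        raise DistanceError(f"pair ({a}, {b}) not found in distance matrix") from exc


def ri_distance_regression(
    ri_pairs: pd.DataFrame,
    genetic: pd.DataFrame,
    other: pd.DataFrame,
    other_name: str = "other",
) -> RegressionResult:
    """OLS of per-pair RI on genetic distance plus one other distance.

    ``ri_pairs`` needs columns ``pop_a``, ``pop_b``, ``ri`` (reciprocal
    crosses pre-averaged, e.g. via :func:`dmicontinuum.ri.average_reciprocals`).
    The second predictor's F-test is sequential (type I), i.e. after
    controlling for genetic distance.  Fits on <= 6 pairs carry a small-n
    flag.
    """
    needed = {"pop_a", "pop_b", "ri"}
    if not needed.issubset(ri_pairs.columns):
        raise DistanceError(f"ri_pairs must have columns {sorted(needed)}")
    n = len(ri_pairs)
    if n < 4:  # 3 parameters + 1
        raise DistanceError(f"{n} pairs is too few to fit two predictors plus intercept")
    frame = pd.DataFrame(
        {
            "ri": ri_pairs["ri"].to_numpy(dtype=float),
            "genetic": [
                _pair_lookup(genetic, a, b)
                for a, b in zip(ri_pairs["pop_a"], ri_pairs["pop_b"])
            ],
            other_name: [
                _pair_lookup(other, a, b)
                for a, b in zip(ri_pairs["pop_a"], ri_pairs["pop_b"])
            ],
        }
    )
    fit = smf.ols(f"ri ~ genetic + {other_name}", data=frame).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    predictors = ["genetic", other_name]
    return RegressionResult(
        coefficients={p: float(fit.params[p]) for p in predictors},
        f_statistics={p: float(anova.loc[p, "F"]) for p in predictors},
        dfs={
            p: (float(anova.loc[p, "df"]), float(anova.loc["Residual", "df"]))
            for p in predictors
        },
        p_values={p: float(anova.loc[p, "PR(>F)"]) for p in predictors},
        r_squared=float(fit.rsquared),
        n_pairs=n,
        small_n=n <= 6,
    )
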