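"""Reproductive-isolation (RI) index pipeline for controlled crossing designs.

Crossing tables hold one row per controlled cross between (or within)
populations, with binomial outcomes at two stages: F1 seed set
(``seeds_fertilised`` of ``seeds_total``) and F1 viability
(``seeds_germinated`` of ``seeds_tested``).  Populations belong to an ecotype
(``D`` = dune, ``H`` = headland) and a phylogenetic clade; crosses are
classified by ordered maternal x paternal ecotype (DxD, HxH, DxH, HxD) and by
clade scope (within/between).  Intra-population crosses are controls.

The isolation index is the Sobel-Chen linear form

    RI = 1 - 2*H / (H + C)

with ``H`` the mean hybrid-cross proportion for a population comparison and
``C`` the mean of the two parental intra-population control means.  RI = 0
means hybrids match parents, 1 complete isolation, negative values hybrid
vigour.

Inference: one-sided one-sample t-tests of mean RI > 0 per design cell, and a
fixed-effects ecotype-similarity model (clade scope + same/different ecotype)
with a seeded permutation test at the population-comparison level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RIPipelineError",
    "SchemaError",
    "MissingControlError",
    "InsufficientDataError",
    "DegenerateDesignError",
    "UndefinedIndexError",
    "ContrastResult",
    "REQUIRED_COLUMNS",
    "ri_linear",
    "classify_cross",
    "compute_ri_table",
    "average_reciprocals",
    "test_class_vs_zero",
    "ecotype_effect_test",
]

REQUIRED_COLUMNS = [
    "mother_pop",
    "father_pop",
    "mother_ecotype",
    "father_ecotype",
    "mother_clade",
    "father_clade",
    "seeds_fertilised",
    "seeds_total",
    "seeds_germinated",
    "seeds_tested",
]

_ECOTYPES = {"D", "H"}


class RIPipelineError(ValueError):
    pass


class SchemaError(RIPipelineError):
    pass


class MissingControlError(RIPipelineError):
    pass


class InsufficientDataError(RIPipelineError):
    pass


class DegenerateDesignError(RIPipelineError):
    pass


class UndefinedIndexError(RIPipelineError):
    pass


@dataclass(frozen=True)
class ContrastResult:
    """Outcome of one statistical contrast on RI estimates."""

    contrast: str
    estimate: float
    statistic: float
    df: float
    p_value: float
    direction: str  # "one-sided-greater" or "two-sided"
    n_permutations: int | None = None

    def __post_init__(self):
        if not np.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise RIPipelineError("p-value outside [0, 1]")


def ri_linear(h: float, c: float) -> float:
    """Sobel-Chen linear RI index ``1 - 2H/(H+C)``.

    ``h`` is hybrid performance, ``c`` parental-control performance (both
    proportions in [0, 1]).  Returns 0 when ``h == c``, 1 when ``h == 0``,
    negative values for hybrid vigour; range [-1, 1].  ``h + c == 0`` (both
    parents and hybrids produced nothing) is undefined.
    """
    if not (0.0 <= h <= 1.0) or not (0.0 <= c <= 1.0):
        raise RIPipelineError(f"H and C must be proportions in [0, 1], got H={h}, C={c}")
    if h + c == 0.0:
        raise UndefinedIndexError("H + C = 0: RI undefined (no success in parents or hybrids)")
    return 1.0 - 2.0 * h / (h + c)


def classify_cross(
    mother_pop: str,
    father_pop: str,
    mother_ecotype: str,
    father_ecotype: str,
    mother_clade: str,
    father_clade: str,
) -> tuple[str, str]:
    """Classify one cross into (cross_class, clade_scope).

    Cross class is the ordered maternal x paternal ecotype pair ("DxD",
    "HxH", "DxH", "HxD") or "control" for an intra-population cross; clade
    scope is "within" if the parental clades match, else "between".
    """
    for label, value in (("mother_ecotype", mother_ecotype), ("father_ecotype", father_ecotype)):
        if value not in _ECOTYPES:
            raise SchemaError(f"unknown ecotype {value!r} in column {label} "
                              f"(cross {mother_pop} x {father_pop})")
    if not mother_clade or not father_clade or pd.isna(mother_clade) or pd.isna(father_clade):
        raise SchemaError(f"missing clade label for cross {mother_pop} x {father_pop}")
    scope = "within" if mother_clade == father_clade else "between"
    if mother_pop == father_pop:
        return "control", scope
    return f"{mother_ecotype}x{father_ecotype}", scope


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cross table is missing required columns: {missing}")
    bad = table.index[
        (table["seeds_fertilised"] > table["seeds_total"])
        | (table["seeds_germinated"] > table["seeds_tested"])
        | (table["seeds_total"] < 1)
        | (table[["seeds_fertilised", "seeds_germinated", "seeds_tested"]] < 0).any(axis=1)
    ]
    if len(bad):
        raise SchemaError(f"inconsistent seed counts in rows {list(bad[:10])}")
    return table


def _proportions(table: pd.DataFrame, stage: str) -> pd.Series:
    if stage == "seed_set":
        return table["seeds_fertilised"] / table["seeds_total"]
    if stage == "viability":
        zero = table["seeds_tested"] == 0
        if zero.any():
            warnings.warn(
                f"dropping {int(zero.sum())} cross(es) with zero tested seeds "
                "from viability means",
                stacklevel=3,
            )
        with np.errstate(invalid="ignore"):
            return (table["seeds_germinated"] / table["seeds_tested"]).where(~zero)
    raise RIPipelineError(f"unknown stage {stage!r}; expected 'seed_set' or 'viability'")


def compute_ri_table(table: pd.DataFrame, stage: str = "seed_set") -> pd.DataFrame:
    """One RI estimate per ordered population comparison.

    For each ordered pair (mother population, father population), ``H`` is
    the unweighted mean proportion across that pair's crosses and ``C`` the
    mean of the two parental intra-population control means.  Returns a frame
    with columns mother_pop, father_pop, stage, cross_class, clade_scope,
    H, C, ri, n_crosses.  Raises :class:`MissingControlError` naming any pair
    whose parental controls are absent.
    """
    table = _validate_table(table)
    props = _proportions(table, stage)
    work = table.assign(_prop=props).dropna(subset=["_prop"])

    classes = [
        classify_cross(
            r.mother_pop, r.father_pop, r.mother_ecotype, r.father_ecotype,
            r.mother_clade, r.father_clade,
        )
        for r in work.itertuples()
    ]
    work = work.assign(
        _class=[c for c, _ in classes], _scope=[s for _, s in classes]
    )

    controls = (
        work[work["_class"] == "control"].groupby("mother_pop")["_prop"].mean()
    )
    inter = work[work["_class"] != "control"]

    rows = []
    missing = []
    for (mpop, fpop), grp in inter.groupby(["mother_pop", "father_pop"], sort=True):
        absent = [p for p in (mpop, fpop) if p not in controls.index]
        if absent:
            missing.append((mpop, fpop, absent))
            continue
        h = float(grp["_prop"].mean())
        c = float((controls[mpop] + controls[fpop]) / 2.0)
        rows.append(
            {
                "mother_pop": mpop,
                "father_pop": fpop,
                "stage": stage,
                "cross_class": grp["_class"].iloc[0],
                "clade_scope": grp["_scope"].iloc[0],
                "H": h,
                "C": c,
                "ri": ri_linear(h, c),
                "n_crosses": int(len(grp)),
            }
        )
    if missing:
        raise MissingControlError(
            "missing intra-population control(s) for pair(s): "
            + "; ".join(f"{m}x{f} lacks {a}" for m, f, a in missing)
        )
    return pd.DataFrame(rows)


def average_reciprocals(ri_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse reciprocal comparisons (A x B and B x A) to unordered pairs.

    H, C and ri are averaged; the cross class is reported with ecotypes in
    sorted order (so DxH and HxD merge to "DxH").  Used to prepare
    regression inputs.
    """
    work = ri_table.copy()
    pairs = [tuple(sorted(p)) for p in zip(work["mother_pop"], work["father_pop"])]
    work["pop_a"] = [a for a, _ in pairs]
    work["pop_b"] = [b for _, b in pairs]
    work["cross_class"] = [
        "x".join(sorted(c.split("x"))) for c in work["cross_class"]
    ]
    agg = (
        work.groupby(["pop_a", "pop_b"], sort=True)
        .agg(
            stage=("stage", "first"),
            cross_class=("cross_class", "first"),
            clade_scope=("clade_scope", "first"),
            H=("H", "mean"),
            C=("C", "mean"),
            ri=("ri", "mean"),
            n_crosses=("n_crosses", "sum"),
        )
        .reset_index()
    )
    return agg


def _select_cell(ri_table: pd.DataFrame, cross_class: str, clade_scope: str | None):
    sel = ri_table["cross_class"] == cross_class
    if clade_scope is not None:
        sel &= ri_table["clade_scope"] == clade_scope
    return ri_table.loc[sel, "ri"].to_numpy(dtype=float)


def test_class_vs_zero(
    ri_table: pd.DataFrame, cross_class: str, clade_scope: str | None = None
) -> ContrastResult:
    """One-sided one-sample t-test that mean RI in a design cell exceeds zero.

    Operates on per-population-comparison RI values.  Requires at least two
    estimates in the cell.
    """
    values = _select_cell(ri_table, cross_class, clade_scope)
    if values.size < 2:
        raise InsufficientDataError(
            f"cell ({cross_class}, {clade_scope or 'any'}) has {values.size} estimate(s); "
            "need >= 2 for a t-test"
        )
    name = f"{cross_class}-{clade_scope or 'all'} vs 0"
    mean = float(values.mean())
    if values.std(ddof=1) == 0.0:
        stat = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
    else:
        res = stats.ttest_1samp(values, 0.0, alternative="greater")
        stat, p = float(res.statistic), float(res.pvalue)
    return ContrastResult(
        contrast=name,
        estimate=mean,
        statistic=stat,
        df=float(values.size - 1),
        p_value=p,
        direction="one-sided-greater",
    )


def _design_matrix(ri_table: pd.DataFrame):
    same = ri_table["cross_class"].isin(["DxD", "HxH"]).to_numpy()
    between = (ri_table["clade_scope"] == "between").to_numpy()
    y = ri_table["ri"].to_numpy(dtype=float)
    return y, same.astype(float), between.astype(float)


def ecotype_effect_test(
    ri_table: pd.DataFrame, n_permutations: int = 9999, seed: int = 0
) -> ContrastResult:
    """Test whether different-ecotype crosses show more isolation than
    same-ecotype crosses, controlling for clade scope.

    Fits RI ~ intercept + clade_scope + different_ecotype by least squares on
    per-comparison RI values, then obtains a two-sided permutation p-value by
    shuffling the ecotype-similarity labels across population comparisons
    (seeded, ``n_permutations`` shuffles).
    """
    y, same, between = _design_matrix(ri_table)
    diff = 1.0 - same
    if len(set(same)) < 2:
        raise DegenerateDesignError(
            "design needs both same-ecotype and different-ecotype comparisons"
        )
    if len(set(between)) < 2:
        raise DegenerateDesignError("design needs both within- and between-clade comparisons")

    def fit(d):
        x = np.column_stack([np.ones_like(y), between, d])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise DegenerateDesignError("rank-deficient design (collinear predictors)")
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return beta[2]

    observed = fit(diff)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(diff)
        try:
            b = fit(perm)
        except DegenerateDesignError:  # pragma: no cover - shuffles keep both levels
            continue
        if abs(b) >= abs(observed) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return ContrastResult(
        contrast="different-ecotype effect on RI (clade-adjusted)",
        estimate=float(observed),
        statistic=float(observed),
        df=float(len(y) - 3),
        p_value=float(p),
        direction="two-sided",
        n_permutations=n_permutations,
    )
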