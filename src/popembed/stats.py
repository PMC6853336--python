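"""Phenotype contrasts across genetic clusters.

The workflow: residualize the phenotype on covariates (age, age^2, height,
sex by default) with ordinary least squares pooled across groups, then run
Welch's unpaired t-test of each group against a reference group on the
residuals, with Bonferroni adjustment over the number of tested groups.
Samples can first be selected by their embedding coordinates (a logged
centroid-radius or polygon region), mirroring the practice of contrasting
phenotypes between individuals near a particular genetic cluster.

Embedding coordinates are used only to *select* samples; they are unsuitable
as regression covariates and no API here encourages that.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ols_residualize",
    "welch_t",
    "group_compare",
    "select_by_embedding",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "age2", "height", "sex")


@dataclass
class TestResult:
    group: object
    reference: object
    mean_difference: float  # group mean minus reference mean, phenotype units
    t: float
    df: float  # Welch-Satterthwaite degrees of freedom
    p: float
    p_adjusted: float  # Bonferroni: min(1, m * p)
    n_group: int
    n_reference: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def ols_residualize(y: np.ndarray, covariate_matrix: np.ndarray) -> np.ndarray:
    """OLS residuals of ``y`` on the covariates (intercept added).

    Residuals are orthogonal to every covariate column; rank-deficient
    designs are rejected.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariate_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient (after adding intercept)")
    return np.asarray(sm.OLS(y, design).fit().resid)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test: ``(t, df, p)``.

    ``t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p from the t
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both groups")
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _covariate_design(table: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "age2":
            cols.append(table["age"].to_numpy(dtype=float) ** 2)
        else:
            cols.append(table[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def group_compare(
    table: pd.DataFrame,
    reference_group: object,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    m_groups: int | None = None,
    group_col: str = "group",
    value_col: str = "phenotype",
    split_by_sex: bool = False,
) -> list[TestResult]:
    """Welch contrasts of every group against a reference, on OLS residuals.

    The phenotype is residualized once on the pooled table (all groups
    together), then each non-reference group is tested against the reference
    with Welch's t.  Bonferroni uses ``m = m_groups`` (default: the number of
    non-reference groups).  With ``split_by_sex=True`` the analysis is run
    separately within each sex (sex is then dropped from the covariates), the
    way sex-stratified cohort contrasts are reported.  Groups with fewer than
    2 samples are skipped with a warning.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = table[group_col]
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} not present")

    if split_by_sex:
        out: list[TestResult] = []
        covs = tuple(c for c in covariates if c != "sex")
        for sex_value, sub in table.groupby("sex"):
            res = group_compare(
                sub.reset_index(drop=True),
                reference_group,
                covariates=covs,
                m_groups=m_groups,
                group_col=group_col,
                value_col=value_col,
            )
            for r in res:
                r.group = (r.group, f"sex={sex_value}")
            out.extend(res)
        return out

    y = table[value_col].to_numpy(dtype=float)
    resid = (
        ols_residualize(y, _covariate_design(table, covariates)) if covariates else y
    )
    tested = [g for g in pd.unique(groups) if g != reference_group]
    m = m_groups if m_groups is not None else len(tested)
    if m < len(tested):
        raise ValueError(f"m_groups={m} below the {len(tested)} tested groups")
    ref_vals = resid[(groups == reference_group).to_numpy()]
    results = []
    for g in [reference_group] + tested:
        vals = resid[(groups == g).to_numpy()]
        if vals.size < 2:
            warnings.warn(f"group {g!r} has n<2; skipped", stacklevel=2)
            continue
        if g == reference_group:
            t, df, p = 0.0, float(2 * vals.size - 2), 1.0
            diff = 0.0
        else:
            t, df, p = welch_t(vals, ref_vals)
            diff = float(vals.mean() - ref_vals.mean())
        results.append(
            TestResult(
                group=g,
                reference=reference_group,
                mean_difference=diff,
                t=t,
                df=df,
                p=p,
                p_adjusted=min(1.0, m * p),
                n_group=int(vals.size),
                n_reference=int(ref_vals.size),
            )
        )
    return results


def results_table(results: list[TestResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in results])
    if not df.empty:
        df["significant"] = df["p_adjusted"] < 0.05
    return df


def select_by_embedding(
    table: pd.DataFrame,
    coords: np.ndarray,
    centroid: np.ndarray | None = None,
    radius: float | None = None,
    polygon: np.ndarray | None = None,
) -> pd.DataFrame:
    """Subset a sample table to rows whose embedding coordinates fall in a
    region (centroid + radius, or polygon vertices).

    Cluster membership in an embedding is a manual, figure-driven choice, so
    the selection region and the resulting count are logged for provenance.
    Boundary points are included.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(table):
        raise ValueError("one coordinate row per table row required")
    if (centroid is None or radius is None) == (polygon is None):
        raise ValueError("give either centroid+radius or polygon")
    if polygon is None:
        centroid = np.asarray(centroid, dtype=float)
        if radius < 0:
            raise ValueError("radius must be >= 0")
        inside = np.linalg.norm(coords - centroid[None, :], axis=1) <= radius
        region_desc = f"ball(centroid={centroid.tolist()}, radius={radius})"
    else:
        from shapely.geometry import Point, Polygon

        poly = Polygon(np.asarray(polygon, dtype=float))
        if not poly.is_valid:
            raise ValueError("polygon is not well formed")
        inside = np.array([poly.covers(Point(*c)) for c in coords])
        region_desc = f"polygon({len(polygon)} vertices)"
    logger.info(
        "select_by_embedding: %s selected %d/%d samples", region_desc, inside.sum(), len(table)
    )
    if not inside.any():
        warnings.warn("embedding region selected no samples", stacklevel=2)
    return table.loc[inside].reset_index(drop=True)
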