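"""Survey-weighted descriptive layer.

Weighted marginal and concurrent prevalence with design-adjusted (Taylor
linearization) standard errors respecting the stratified multistage cluster
sample, the 2 x 2 cross-classification of the two outcomes, and the Pearson
chi-square association test (continuity-corrected by default for the 2 x 2
case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass
class SurveyDesign:
    """Per-row sampling weight, cluster (PSU) and stratum identifiers."""

    weight: np.ndarray
    cluster: np.ndarray
    stratum: np.ndarray

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.stratum = np.asarray(self.stratum)
        if np.any(self.weight <= 0):
            raise ValueError("sampling weights must be positive")
        # every cluster must sit inside exactly one stratum
        df = pd.DataFrame({"c": self.cluster, "s": self.stratum})
        if (df.groupby("c")["s"].nunique() > 1).any():
            raise ValueError("a cluster spans more than one stratum")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(df["weight"].to_numpy(), df["cluster_id"].to_numpy(),
                   df["stratum_id"].to_numpy())


def weighted_prevalence(y, design: SurveyDesign, ci_level: float = 0.95):
    """Weighted prevalence with linearized cluster-robust SE and Wald CI.

    The estimate is the ratio sum(w y)/sum(w); its variance is the
    stratified between-cluster variance of the linearized residuals
    z_i = w_i (y_i - p) / sum(w), with the with-replacement factor
    n_h/(n_h - 1) per stratum.  A stratum containing a single cluster is
    handled by centering its cluster total at the grand mean of all cluster
    totals (certainty-unit convention).  The CI is symmetric on the
    proportion scale, truncated to [0, 1].
    """
    y = np.asarray(y, dtype=float)
    w = design.weight
    W = w.sum()
    p = float(np.sum(w * y) / W)
    z = w * (y - p) / W
    df = pd.DataFrame({"z": z, "c": design.cluster, "s": design.stratum})
    totals = df.groupby(["s", "c"])["z"].sum().reset_index()
    grand = totals["z"].mean()
    var = 0.0
    for s, grp in totals.groupby("s"):
        n_h = len(grp)
        if n_h == 1:
            var += float((grp["z"].iloc[0] - grand) ** 2)
        else:
            zc = grp["z"].to_numpy()
            var += n_h / (n_h - 1) * float(np.sum((zc - zc.mean()) ** 2))
    se = float(np.sqrt(var))
    from scipy.stats import norm

    zq = float(norm.ppf(0.5 + ci_level / 2.0))
    lo = max(0.0, p - zq * se)
    hi = min(1.0, p + zq * se)
    return p, se, (lo, hi)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts of the four joint outcome events (unweighted)."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]])


def crosstab(y1, y2) -> TwoByTwo:
    """2 x 2 cross-classification of the stunting/wasting indicators."""
    y1 = np.asarray(y1, dtype=int)
    y2 = np.asarray(y2, dtype=int)
    return TwoByTwo(
        n11=int(np.sum((y1 == 1) & (y2 == 1))),
        n10=int(np.sum((y1 == 1) & (y2 == 0))),
        n01=int(np.sum((y1 == 0) & (y2 == 1))),
        n00=int(np.sum((y1 == 0) & (y2 == 0))),
    )


def table_from_percentages(n: int, pct_outcome1: float, pct_outcome2: float,
                           pct_both: float) -> TwoByTwo:
    """Rebuild integer 2 x 2 counts from a total and printed percentages.

    Rounds n * pct/100 to the nearest integer for the two marginal counts
    and the joint count, then fills the table by additivity.
    """
    m1 = round(n * pct_outcome1 / 100.0)
    m2 = round(n * pct_outcome2 / 100.0)
    b = round(n * pct_both / 100.0)
    return TwoByTwo(n11=b, n10=m1 - b, n01=m2 - b, n00=n - m1 - m2 + b)


def chisq_association(table: TwoByTwo, correction: bool = True):
    """Pearson chi-square test of association on the 2 x 2 table.

    ``correction=True`` (default) applies the Yates continuity correction,
    the conventional choice for 2 x 2 tables.  Returns (statistic, df, p).
    """
    arr = table.as_array()
    exp = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if np.any(exp <= 0):
        raise ValueError("zero expected count in the 2x2 table")
    res = chi2_contingency(arr, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


#: categorical variables of the child/maternal/household profile
TABLE1_VARS = [
    "sex", "ethnicity", "maternal_education", "maternal_working",
    "wealth_quintile", "location", "head_gender", "toilet_improved",
    "water_on_premise", "water_treated",
]


def prevalence_table(df: pd.DataFrame, design: SurveyDesign | None = None,
                     variables: list[str] | None = None) -> pd.DataFrame:
    """Weighted prevalence of stunting, wasting and both, by category level.

    One row per (variable, level) plus an overall row, each carrying the
    weighted prevalence (percent), SE and 95% CI for the three outcomes.
    """
    design = design or SurveyDesign.from_frame(df)
    variables = variables if variables is not None else [
        v for v in TABLE1_VARS if v in df.columns
    ]
    y_s = df["y_stunt"].to_numpy()
    y_w = df["y_waste"].to_numpy()
    y_b = (y_s * y_w)

    def rows_for(mask, var, level):
        sub = SurveyDesign(design.weight[mask], design.cluster[mask],
                           design.stratum[mask])
        out = {"variable": var, "level": level,
               "n": int(mask.sum())}
        for nm, y in (("stunting", y_s), ("wasting", y_w), ("both", y_b)):
            p, se, (lo, hi) = weighted_prevalence(y[mask], sub)
            out[f"{nm}_pct"] = 100 * p
            out[f"{nm}_se"] = 100 * se
            out[f"{nm}_lo"] = 100 * lo
            out[f"{nm}_hi"] = 100 * hi
        return out

    all_mask = np.ones(len(df), dtype=bool)
    rows = [rows_for(all_mask, "overall", "all")]
    for var in variables:
        for level in pd.unique(df[var]):
            mask = (df[var] == level).to_numpy()
            if mask.any():
                rows.append(rows_for(mask, var, level))
    return pd.DataFrame(rows)
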