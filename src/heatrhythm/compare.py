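"""Group summaries and one-way ANOVA of behavior budgets under NS vs HS.

Animal-hours are treated as independent observations of the one-way layout
``y_ij = mu + tau_i + eps_ij`` with the stress level (NS/HS) as the single
factor; the F test with (k-1, N-k) degrees of freedom is Fisher's test for
this design (with two groups it coincides with the pooled-variance t test,
F = t²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MODELLED_BEHAVIORS

__all__ = ["GroupSummary", "AnovaResult", "group_summary", "one_way_anova",
           "comparison_table"]


@dataclass(frozen=True)
class GroupSummary:
    behavior: str
    group: str
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    behavior: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


def group_summary(labelled: pd.DataFrame, behavior: str) -> tuple[GroupSummary, GroupSummary]:
    """Mean ± standard error of one behavior for the NS and HS groups.

    ``se`` is the sample standard deviation (ddof=1) over √n; groups other
    than NS/HS are ignored.  An empty group raises ``ValueError``.
    """
    out = []
    for grp in ("NS", "HS"):
        vals = labelled.loc[labelled["stress"] == grp, behavior].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"no records labelled {grp} for behavior {behavior!r}")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(GroupSummary(behavior, grp, float(np.mean(vals)),
                                sd / np.sqrt(vals.size), int(vals.size)))
    return out[0], out[1]


def one_way_anova(values, group_labels, behavior: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    ss_between = Σ n_g (mean_g − grand_mean)²,
    ss_within  = Σ_g Σ_i (x_gi − mean_g)²,
    F = (ss_between/df_between) / (ss_within/df_within), with the p-value
    from the upper tail of the F distribution.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        x = values[labels == g]
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        ss_between += x.size * (x.mean() - grand) ** 2
        ss_within += float(np.sum((x - x.mean()) ** 2))
    df_between = groups.size - 1
    df_within = values.size - groups.size
    if ss_within == 0.0:
        if ss_between > 0.0:
            warnings.warn("zero within-group variance with nonzero between-group "
                          "variance; p reported as 0", RuntimeWarning)
            return AnovaResult(behavior, np.inf, df_between, df_within, 0.0,
                               ss_between, ss_within)
        return AnovaResult(behavior, 0.0, df_between, df_within, 1.0, 0.0, 0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(behavior, float(f), df_between, df_within, p,
                       float(ss_between), float(ss_within))


def comparison_table(labelled: pd.DataFrame,
                     behaviors=MODELLED_BEHAVIORS) -> pd.DataFrame:
    """Per-behavior NS/HS means ± s.e. and the NS-vs-HS ANOVA, one row each."""
    rows = []
    mask = labelled["stress"].isin(["NS", "HS"])
    sub = labelled[mask]
    for beh in behaviors:
        ns, hs = group_summary(sub, beh)
        res = one_way_anova(sub[beh].to_numpy(dtype=float),
                            sub["stress"].to_numpy(), behavior=beh)
        rows.append({
            "behavior": beh,
            "ns_mean": ns.mean, "ns_se": ns.se, "ns_n": ns.n,
            "hs_mean": hs.mean, "hs_se": hs.se, "hs_n": hs.n,
            "f": res.f_stat, "df1": res.df_between, "df2": res.df_within,
            "p": res.p_value,
        })
    return pd.DataFrame(rows)
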