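"""Cohort-level statistics: group comparisons and covariate adjustment.

The cohort table has one row per subject (see
:class:`relaxo.roi_stats.SubjectSummary`) with a prematurity group
(``preterm`` / ``term``) and ``sex`` factor.  Comparisons are two-sided
two-sample Student's t-tests with pooled variance (a Welch option is
available); significance is conventionally read at p < 0.05 and no
multiple-testing correction is applied by default (a Holm option exists but
goes beyond the original analysis it mirrors).

``compare_adjusted`` re-tests a group difference while controlling for a
continuous covariate (typically a brain-volume measure) via the linear model
``variable ~ group + covariate``; the reported p-value is that of the group
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = ["ComparisonResult", "compare_groups", "compare_adjusted", "cohort_report"]

_SPLITS = {"prematurity": "group", "sex": "sex"}


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group contrast of a cohort variable."""

    variable: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    t_statistic: float
    p_value: float
    adjusted: bool = False
    covariate: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _validate_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("empty cohort table")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_ids")
    bad_group = set(table["group"]) - {"preterm", "term"}
    bad_sex = set(table["sex"]) - {"male", "female"}
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")


def _two_sample(table: pd.DataFrame, variable: str, factor: str, labels: tuple[str, str], welch: bool) -> ComparisonResult:
    a = table.loc[table[factor] == labels[0], variable].to_numpy(dtype=float)
    b = table.loc[table[factor] == labels[1], variable].to_numpy(dtype=float)
    for lab, x in zip(labels, (a, b)):
        if x.size < 2:
            raise ValueError(f"stratum '{lab}' has fewer than 2 subjects")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(
        variable=variable,
        group_labels=labels,
        n=(int(a.size), int(b.size)),
        mean=(float(a.mean()), float(b.mean())),
        sd=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        t_statistic=float(t),
        p_value=float(p),
    )


def compare_groups(table: pd.DataFrame, variable: str, split: str = "prematurity", welch: bool = False):
    """Two-sample Student's t-test(s) of ``variable`` across a cohort split.

    ``split`` is ``"prematurity"`` (preterm vs term), ``"sex"`` (male vs
    female), or ``"both"``, which forms the four group-by-sex strata and
    returns all pairwise contrasts.  Pooled-variance Student's test by
    default; ``welch=True`` drops the equal-variance assumption.
    """
    _validate_table(table)
    if variable not in table.columns:
        raise KeyError(f"no such variable: {variable}")
    if split in _SPLITS:
        factor = _SPLITS[split]
        labels = ("preterm", "term") if split == "prematurity" else ("male", "female")
        return _two_sample(table, variable, factor, labels, welch)
    if split == "both":
        strata = table.assign(stratum=table["group"] + "_" + table["sex"])
        present = sorted(strata["stratum"].unique())
        return [
            _two_sample(strata, variable, "stratum", (s1, s2), welch)
            for s1, s2 in combinations(present, 2)
        ]
    raise ValueError(f"unknown split: {split!r} (expected prematurity|sex|both)")


def compare_adjusted(
    table: pd.DataFrame,
    variable: str,
    group_factor: str = "group",
    covariate: str = "wm_volume_l",
) -> ComparisonResult:
    """Group comparison of ``variable`` adjusted for a continuous covariate.

    Fits OLS ``variable ~ group + covariate`` and reports the t statistic and
    p-value of the group coefficient.  Raises if the covariate has zero
    variance (it would be collinear with the intercept).
    """
    _validate_table(table)
    for col in (variable, covariate):
        if col not in table.columns:
            raise KeyError(f"no such column: {col}")
    cov = table[covariate].to_numpy(dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError(f"covariate {covariate} has non-finite values")
    if np.ptp(cov) == 0:
        raise ValueError(f"covariate {covariate} has zero variance (collinear)")
    levels = sorted(table[group_factor].unique())
    if len(levels) != 2:
        raise ValueError(f"group factor {group_factor} must have exactly 2 levels, got {levels}")
    indicator = (table[group_factor] == levels[0]).to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([indicator, cov]))
    fit = sm.OLS(table[variable].to_numpy(dtype=float), X).fit()
    sub = [table.loc[table[group_factor] == lev, variable].to_numpy(dtype=float) for lev in levels]
    return ComparisonResult(
        variable=variable,
        group_labels=(str(levels[0]), str(levels[1])),
        n=(int(sub[0].size), int(sub[1].size)),
        mean=(float(sub[0].mean()), float(sub[1].mean())),
        sd=(float(sub[0].std(ddof=1)), float(sub[1].std(ddof=1))),
        t_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        adjusted=True,
        covariate=covariate,
    )


_REPORT_VARS = (
    "csf_volume_l",
    "gm_volume_l",
    "wm_volume_l",
    "icv_l",
    "csf_t2_ms",
    "gm_t2_ms",
    "wm_t2_ms",
    "wm_mwf",
    "wm_tissue_fraction",
)


def cohort_report(table: pd.DataFrame, variables=None) -> dict:
    """Publication-style cohort summary.

    Per stratum (group x sex, plus the marginal group and sex strata):
    mean ± sample SD of every summary variable.  Also reports the
    preterm/term ratio of mean volumes within each sex.  Single-subject
    strata get SD 0 with a warning.
    """
    _validate_table(table)
    if variables is None:
        variables = [v for v in _REPORT_VARS if v in table.columns]
    out: dict = {"n_subjects": int(len(table)), "strata": {}, "volume_ratios": {}}

    def stat(rows: pd.DataFrame) -> dict:
        d = {"n": int(len(rows))}
        if len(rows) == 1:
            import warnings

            warnings.warn("single-subject stratum: SD reported as 0", stacklevel=3)
        for v in variables:
            x = rows[v].to_numpy(dtype=float)
            d[v] = {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0}
        return d

    for g in ("preterm", "term"):
        rows = table[table["group"] == g]
        if len(rows):
            out["strata"][g] = stat(rows)
    for s in ("male", "female"):
        rows = table[table["sex"] == s]
        if len(rows):
            out["strata"][s] = stat(rows)
    for g in ("preterm", "term"):
        for s in ("male", "female"):
            rows = table[(table["group"] == g) & (table["sex"] == s)]
            if len(rows):
                out["strata"][f"{g}_{s}"] = stat(rows)

    vol_vars = [v for v in variables if v.endswith("_volume_l") or v == "icv_l"]
    for s in ("male", "female"):
        pre = table[(table["group"] == "preterm") & (table["sex"] == s)]
        term = table[(table["group"] == "term") & (table["sex"] == s)]
        if len(pre) and len(term):
            out["volume_ratios"][s] = {
                v: float(pre[v].mean() / term[v].mean()) for v in vol_vars if term[v].mean() != 0
            }
    return out
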