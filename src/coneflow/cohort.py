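"""Cohort statistics: group summaries, pooled two-sample t-tests and the
Spearman rank correlation between packing index and deep-plexus vessel
density, from a per-eye table.

The packaged study table (``coneflow/data/table1.csv``) transcribes the
per-case characteristics of an 11-eye diabetic-retinopathy cohort split
into eyes with normal deep-capillary-plexus (DCP) perfusion (n=3) and
eyes with DCP non-flow (n=8); one non-flow eye lacks a vessel-density
value (imaged by fluorescein angiography instead of OCTA), so density
summaries use n=7 and the correlation uses the 10 complete pairs.

Statistical choices mirror common clinical practice (SPSS defaults):
equal-variance pooled Student t with n1+n2-2 degrees of freedom (Welch
available behind a flag), and Spearman p-values from the
t-approximation t = r*sqrt((n-2)/(1-r^2)) with average ranks for ties;
an exact permutation p-value is available for small n.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "CohortSchemaError",
    "GroupComparison",
    "CorrelationResult",
    "packaged_table1_path",
    "load_cohort_csv",
    "group_summary",
    "t_test_pooled",
    "spearman",
    "reproduce_table1",
]

COHORT_COLUMNS = [
    "case_id", "sex", "age_y", "dm_type", "duration_y", "hba1c_pct",
    "study_eye", "bcva", "dr_stage", "laser", "medication",
    "dcp_density_pct", "hpi", "group",
]

NUMERIC_VARS = ["age_y", "duration_y", "hba1c_pct", "dcp_density_pct", "hpi"]
GROUPS = ("normal_dcp", "dcp_nonflow")


class CohortSchemaError(ValueError):
    """Cohort CSV does not conform to the per-eye schema."""


@dataclass
class GroupComparison:
    variable: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    t_statistic: float
    df: float
    p_two_tailed: float


@dataclass
class CorrelationResult:
    n: int
    spearman_r: float
    p_two_tailed: float
    method: str = "t-approximation"


def packaged_table1_path():
    """Path to the packaged per-case study table."""
    return resources.files("coneflow.data") / "table1.csv"


def _expected_values() -> dict:
    with (resources.files("coneflow.data") / "table1_expected.json").open() as fh:
        return json.load(fh)


def load_cohort_csv(path) -> pd.DataFrame:
    """Load and validate a per-eye cohort CSV (empty cell = missing).

    Raises :class:`CohortSchemaError` listing every offending field.
    """
    table = pd.read_csv(path, dtype={"sex": str, "group": str})
    problems = []
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortSchemaError(f"missing column(s): {missing}")
    for var in NUMERIC_VARS:
        coerced = pd.to_numeric(table[var], errors="coerce")
        bad = table[var].notna() & coerced.isna()
        if bad.any():
            problems.append(
                f"{var}: non-numeric value(s) in row(s) {list(table.index[bad])}"
            )
        table[var] = coerced
    unknown = set(table["group"].dropna()) - set(GROUPS)
    if unknown:
        problems.append(f"group: unknown label(s) {sorted(unknown)}")
    hpi_bad = table["hpi"].notna() & ~table["hpi"].between(-1, 1)
    if hpi_bad.any():
        problems.append(f"hpi: out of [-1, 1] in row(s) {list(table.index[hpi_bad])}")
    dens = table["dcp_density_pct"]
    dens_bad = dens.notna() & ~dens.between(0, 100)
    if dens_bad.any():
        problems.append(
            f"dcp_density_pct: out of [0, 100] in row(s) {list(table.index[dens_bad])}"
        )
    if problems:
        raise CohortSchemaError("; ".join(problems))
    return table


def _group_values(table: pd.DataFrame, variable: str):
    if variable not in table.columns:
        raise ValueError(f"unknown variable {variable!r}")
    out = []
    for g in GROUPS:
        vals = table.loc[table["group"] == g, variable].dropna().to_numpy(float)
        out.append(vals)
    return out


def group_summary(table: pd.DataFrame, variable: str) -> dict[str, dict]:
    """Per-group sample mean and SD (denominator n-1), missing values
    dropped per-variable."""
    result = {}
    for g, vals in zip(GROUPS, _group_values(table, variable)):
        if vals.size == 0:
            raise ValueError(f"group {g!r} has no non-missing {variable!r}")
        result[g] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }
    return result


def t_test_pooled(
    table: pd.DataFrame, variable: str, equal_var: bool = True
) -> GroupComparison:
    """Independent two-sample t-test between the two perfusion groups.

    Pooled-variance Student t by default (df = n1 + n2 - 2); Welch with
    ``equal_var=False``.
    """
    a, b = _group_values(table, variable)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"both groups need n >= 2 for {variable!r}")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return GroupComparison(
        variable=variable,
        n1=len(a), n2=len(b),
        mean1=float(a.mean()), sd1=float(a.std(ddof=1)),
        mean2=float(b.mean()), sd2=float(b.std(ddof=1)),
        t_statistic=float(res.statistic),
        df=float(df),
        p_two_tailed=float(res.pvalue),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p over all n! orderings of y (n <= 10)."""
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p supported for n <= 10 only")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom = math.sqrt((rx_c**2).sum())
    hits = 0
    total = 0
    thresh = abs(r_obs) - 1e-12
    for perm in itertools.permutations(ry):
        p = np.asarray(perm)
        p_c = p - p.mean()
        denom_y = math.sqrt((p_c**2).sum())
        r = float(rx_c @ p_c) / (denom * denom_y)
        if abs(r) >= thresh:
            hits += 1
        total += 1
    return hits / total


def spearman(
    table: pd.DataFrame,
    var_x: str = "hpi",
    var_y: str = "dcp_density_pct",
    exact: bool = False,
) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing rows.

    Average ranks for ties; r is the Pearson correlation of the rank
    vectors.  Two-tailed p via the t-approximation, or by exhaustive
    permutation for n <= 10 with ``exact=True``.
    """
    for v in (var_x, var_y):
        if v not in table.columns:
            raise ValueError(f"unknown variable {v!r}")
    pairs = table[[var_x, var_y]].dropna()
    x = pairs[var_x].to_numpy(float)
    y = pairs[var_y].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(stats.rankdata(x)).size == 1 or np.unique(stats.rankdata(y)).size == 1:
        raise ValueError("undefined correlation: zero variance in a rank vector")
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    if exact:
        p = _exact_spearman_p(x, y, r)
        method = "exact permutation"
    else:
        p = float(res.pvalue)
        method = "t-approximation"
    return CorrelationResult(n=len(x), spearman_r=r, p_two_tailed=p, method=method)


def _fmt_like(value: float, printed: str) -> str:
    """Format ``value`` with the same number of decimals as ``printed``."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return f"{value:.{decimals}f}"


def reproduce_table1(path=None) -> dict:
    """Recompute every published summary from the per-case table and
    compare at the printed precision.

    Returns a report dict with the computed statistics, a ``checks``
    list of {name, computed, expected, ok} and an ``all_ok`` flag.
    """
    if path is None:
        path = packaged_table1_path()
    table = load_cohort_csv(path)
    expected = _expected_values()
    checks: list[dict] = []

    def check(name: str, computed: float, printed: str) -> None:
        checks.append(
            {
                "name": name,
                "computed": float(computed),
                "expected": printed,
                "ok": _fmt_like(computed, printed) == printed,
            }
        )

    n_normal = int((table["group"] == "normal_dcp").sum())
    n_nonflow = int((table["group"] == "dcp_nonflow").sum())
    checks.append({"name": "n_rows", "computed": len(table),
                   "expected": str(expected["n_rows"]),
                   "ok": len(table) == expected["n_rows"]})
    checks.append({"name": "n_normal", "computed": n_normal,
                   "expected": str(expected["n_normal"]),
                   "ok": n_normal == expected["n_normal"]})
    checks.append({"name": "n_nonflow", "computed": n_nonflow,
                   "expected": str(expected["n_nonflow"]),
                   "ok": n_nonflow == expected["n_nonflow"]})

    summaries = {}
    tests = {}
    for var, exp in expected["groups"].items():
        summ = group_summary(table, var)
        summaries[var] = summ
        check(f"{var}.normal_mean", summ["normal_dcp"]["mean"], exp["normal_mean"])
        check(f"{var}.nonflow_mean", summ["dcp_nonflow"]["mean"], exp["nonflow_mean"])
        if "normal_sd" in exp:
            check(f"{var}.normal_sd", summ["normal_dcp"]["sd"], exp["normal_sd"])
        if "nonflow_sd" in exp:
            check(f"{var}.nonflow_sd", summ["dcp_nonflow"]["sd"], exp["nonflow_sd"])
        comp = t_test_pooled(table, var)
        tests[var] = comp
        check(f"{var}.p", comp.p_two_tailed, exp["p"])

    corr = spearman(table, "hpi", "dcp_density_pct")
    check("spearman.r", corr.spearman_r, expected["spearman"]["r"])
    check("spearman.p", corr.p_two_tailed, expected["spearman"]["p"])
    checks.append({"name": "spearman.n", "computed": corr.n,
                   "expected": str(expected["spearman"]["n"]),
                   "ok": corr.n == expected["spearman"]["n"]})

    check("median_age_y", float(table["age_y"].median()), expected["median_age_y"])
    check("median_duration_y", float(table["duration_y"].median()),
          expected["median_duration_y"])

    return {
        "n_rows": len(table),
        "n_normal": n_normal,
        "n_nonflow": n_nonflow,
        "group_summaries": summaries,
        "t_tests": {
            v: {
                "t": c.t_statistic, "df": c.df, "p_two_tailed": c.p_two_tailed,
            }
            for v, c in tests.items()
        },
        "spearman": {
            "n": corr.n, "r": corr.spearman_r, "p_two_tailed": corr.p_two_tailed,
        },
        "median_age_y": float(table["age_y"].median()),
        "median_duration_y": float(table["duration_y"].median()),
        "checks": checks,
        "all_ok": all(c["ok"] for c in checks),
    }
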