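"""Reproducibility and concordance statistics for specific-IgE measurements.

Covers the assay-QC analyses that accompany the quantification pipeline:
coefficient-of-variation summaries at three replication levels (within
slide, between slides within a day, between days), main-effects ANOVA
variance partitioning, pairwise replicate-array regression, matched-pairs
t-tests between allergen fractions, ELISA positivity calls and the 2x2
microarray-vs-ELISA concordance table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

INTRA_SLIDE = "intra-slide"
INTER_SLIDE = "inter-slide"
INTER_ASSAY = "inter-assay"

ELISA_CUTOFF = 0.35  # kU/L


# -- coefficient of variation --------------------------------------------


@dataclass
class CVReport:
    """Median CV per allergen class at one replication level.

    ``per_cell`` holds every qualifying cell's CV; ``summary`` is indexed by
    allergen class with columns ``median_cv`` and ``n``.
    """

    level: str
    per_cell: pd.DataFrame
    summary: pd.DataFrame
    mean_floor: float = 0.5

    @property
    def empty(self) -> bool:
        return len(self.per_cell) == 0


def _cv(values: np.ndarray) -> float:
    """Sample standard deviation divided by the mean."""
    return float(np.std(values, ddof=1) / np.mean(values))


def cv_report(long: pd.DataFrame,
              level: str,
              classes: Mapping[str, str] | None = None,
              mean_floor: float = 0.5) -> CVReport:
    """CV = sd/mean of replicates at a replication level.

    *long* must have columns serum_id, allergen, day, slide_id, array,
    value.  Replicates are grouped as:

    - ``intra-slide``: arrays within one (serum, allergen, day, slide) cell;
    - ``inter-slide``: per-slide means within one (serum, allergen, day);
    - ``inter-assay``: per-day means within one (serum, allergen).

    Cells with fewer than two replicates or replicate mean <= *mean_floor*
    are excluded (low means make CV explode on noise); medians are then
    taken within allergen class.
    """
    df = long.dropna(subset=["value"]).copy()
    if level == INTRA_SLIDE:
        keys = ["serum_id", "allergen", "day", "slide_id"]
        reps = df
    elif level == INTER_SLIDE:
        reps = (df.groupby(["serum_id", "allergen", "day", "slide_id"],
                           as_index=False)["value"].mean())
        keys = ["serum_id", "allergen", "day"]
    elif level == INTER_ASSAY:
        reps = (df.groupby(["serum_id", "allergen", "day"],
                           as_index=False)["value"].mean())
        keys = ["serum_id", "allergen"]
    else:
        raise AnalysisError(f"unknown CV level {level!r}")

    records = []
    for key, grp in reps.groupby(keys):
        vals = grp["value"].to_numpy(float)
        if vals.size < 2:
            continue
        mean = float(np.mean(vals))
        if mean <= mean_floor:
            continue
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["cv"] = _cv(vals)
        rec["n_replicates"] = int(vals.size)
        records.append(rec)
    per_cell = pd.DataFrame(records)

    if classes and len(per_cell):
        per_cell["allergen_class"] = per_cell["allergen"].map(classes)
        summary = (per_cell.dropna(subset=["allergen_class"])
                   .groupby("allergen_class")["cv"]
                   .agg(median_cv="median", n="size"))
    elif len(per_cell):
        summary = pd.DataFrame({"median_cv": [per_cell["cv"].median()],
                                "n": [len(per_cell)]}, index=["all"])
    else:
        summary = pd.DataFrame(columns=["median_cv", "n"])
    return CVReport(level=level, per_cell=per_cell, summary=summary,
                    mean_floor=mean_floor)


# -- ANOVA variance partitioning -----------------------------------------


@dataclass
class VarianceComponents:
    """Sequential sums of squares per design factor plus residual error.

    ``table`` is indexed by factor name (ending with ``Error``) with columns
    ``SS``, ``df`` and ``pct_ss_total`` (share of the total SS including
    error, in percent, summing to 100).
    """

    table: pd.DataFrame

    def pct(self, factor: str) -> float:
        return float(self.table.loc[factor, "pct_ss_total"])


def variance_shares(ss: Mapping[str, float]) -> pd.Series:
    """Percent of total sum of squares per component: SS / sum(SS) * 100."""
    s = pd.Series(ss, dtype=float)
    total = s.sum()
    if total <= 0:
        raise AnalysisError("total sum of squares must be positive")
    return s / total * 100.0


def anova_components(long: pd.DataFrame,
                     response: str = "value",
                     factors: Sequence[str] = ("array", "slide_id",
                                               "serum_id", "allergen"),
                     ) -> VarianceComponents:
    """Main-effects fixed ANOVA with sequential (type I) sums of squares.

    Factors enter in the given order as crossed categorical main effects;
    the residual is reported as ``Error``.  Factors with a single observed
    level are dropped with a warning-free skip (their SS would be zero and
    the design matrix singular).  The percent column is computed against
    the total SS including error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = long.dropna(subset=[response]).copy()
    usable = [f for f in factors if df[f].nunique() > 1]
    if not usable:
        raise AnalysisError("no factor has >= 2 levels")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in usable)
    fit = smf.ols(formula, data=df).fit()
    aov = anova_lm(fit, typ=1)

    rename = {f"C({f})": f for f in usable}
    rename["Residual"] = "Error"
    aov = aov.rename(index=rename)
    table = pd.DataFrame({"SS": aov["sum_sq"], "df": aov["df"].astype(int)})
    if table["SS"].sum() > 1e-20:
        table["pct_ss_total"] = variance_shares(table["SS"].to_dict())
    else:  # constant response: shares undefined
        table["pct_ss_total"] = np.nan
    table.index.name = "factor"
    return VarianceComponents(table=table)


# -- replicate regression -------------------------------------------------


@dataclass
class RegressionEntry:
    slope: float
    r_squared: float
    n: int


@dataclass
class ReplicateRegression:
    """Pairwise replicate regressions and their medians."""

    entries: pd.DataFrame  # columns: pair_x, pair_y, slope, r_squared, n
    median_slope: float
    median_r_squared: float


def replicate_regression(x: Sequence[float], y: Sequence[float]) -> RegressionEntry:
    """Least-squares regression of one replicate profile on another.

    Pairs with missing values are dropped; needs >= 3 shared values and
    nonzero variance in *x*.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise AnalysisError("need >= 3 shared non-missing values")
    if np.ptp(x) == 0.0:
        raise AnalysisError("zero variance in x: slope undefined")
    res = sps.linregress(x, y)
    return RegressionEntry(slope=float(res.slope),
                           r_squared=float(res.rvalue ** 2), n=int(x.size))


def pairwise_replicate_regression(profiles: pd.DataFrame,
                                  group: Sequence | None = None
                                  ) -> ReplicateRegression:
    """All pairwise regressions among replicate rows of *profiles*.

    *profiles* has one row per replicate array (allergens as columns).  If
    *group* labels are given (e.g. serum ids), only rows sharing a label
    are paired.  Degenerate pairs are skipped.
    """
    idx = list(range(len(profiles)))
    labels = list(group) if group is not None else [0] * len(profiles)
    rows = []
    for i in idx:
        for j in idx:
            if j <= i or labels[i] != labels[j]:
                continue
            try:
                e = replicate_regression(profiles.iloc[i], profiles.iloc[j])
            except AnalysisError:
                continue
            rows.append({"pair_x": profiles.index[i], "pair_y": profiles.index[j],
                         "slope": e.slope, "r_squared": e.r_squared, "n": e.n})
    entries = pd.DataFrame(rows)
    if not len(entries):
        raise AnalysisError("no valid replicate pairs")
    return ReplicateRegression(entries=entries,
                               median_slope=float(entries["slope"].median()),
                               median_r_squared=float(entries["r_squared"].median()))


# -- matched-pairs comparison ---------------------------------------------


@dataclass
class PairedComparison:
    """Two-tailed matched-pairs t-test between two allergen fractions."""

    fraction_a: str
    fraction_b: str
    t: float
    df: int
    p_value: float
    mean_difference: float
    n_pairs: int


def paired_fraction_test(matrix: pd.DataFrame,
                         fraction_a: str,
                         fraction_b: str) -> PairedComparison:
    """Paired t-test of per-serum differences between two allergen columns.

    Missing pairs are dropped (complete-case); requires >= 2 complete pairs.
    All-zero differences make the test undefined and raise rather than
    reporting p = 1.
    """
    a = matrix[fraction_a].to_numpy(float)
    b = matrix[fraction_b].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    n = d.size
    if n < 2:
        raise AnalysisError("need >= 2 complete pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise AnalysisError("zero variance of differences: t-test undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedComparison(fraction_a=fraction_a, fraction_b=fraction_b,
                            t=t, df=n - 1, p_value=p,
                            mean_difference=float(np.mean(d)), n_pairs=n)


# -- ELISA calls and concordance ------------------------------------------


def elisa_calls(values: Sequence[float], cutoff: float = ELISA_CUTOFF) -> np.ndarray:
    """Positive <=> value strictly above the clinical cutoff (0.35 kU/L)."""
    v = np.asarray(values, float)
    if np.any(v < 0):
        raise AnalysisError("ELISA values must be >= 0 kU/L")
    return v > cutoff


@dataclass
class ConcordanceTable:
    """2x2 cross-tabulation of microarray vs ELISA positivity.

    ``counts``/``proportions`` are indexed ARRAY+/ARRAY- with columns
    ELISA+/ELISA-.  ``elisa_capture`` is the fraction of ELISA positives
    that the array also calls positive.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    elisa_capture: float
    n: int

    @classmethod
    def from_counts(cls, array_pos_elisa_pos: int, array_pos_elisa_neg: int,
                    array_neg_elisa_pos: int, array_neg_elisa_neg: int
                    ) -> "ConcordanceTable":
        counts = pd.DataFrame(
            [[array_pos_elisa_pos, array_pos_elisa_neg],
             [array_neg_elisa_pos, array_neg_elisa_neg]],
            index=["ARRAY+", "ARRAY-"], columns=["ELISA+", "ELISA-"],
        )
        n = int(counts.to_numpy().sum())
        if n == 0:
            raise AnalysisError("no call pairs")
        elisa_pos = array_pos_elisa_pos + array_neg_elisa_pos
        capture = (array_pos_elisa_pos / elisa_pos) if elisa_pos else float("nan")
        return cls(counts=counts, proportions=counts / n,
                   elisa_capture=capture, n=n)


def concordance_table(array_calls: Sequence[bool],
                      elisa_calls_: Sequence[bool]) -> ConcordanceTable:
    """Cross-tabulate paired boolean calls; pairs with missing entries dropped."""
    a = pd.array(array_calls, dtype="boolean")
    e = pd.array(elisa_calls_, dtype="boolean")
    if len(a) != len(e):
        raise AnalysisError("call vectors must have equal length")
    ok = ~(pd.isna(a) | pd.isna(e))
    a, e = a[ok].astype(bool), e[ok].astype(bool)
    if len(a) == 0:
        raise AnalysisError("no call pairs")
    return ConcordanceTable.from_counts(
        int(np.sum(a & e)), int(np.sum(a & ~e)),
        int(np.sum(~a & e)), int(np.sum(~a & ~e)),
    )
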