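"""Autofluorescence correction, threshold calibration and IgE quantification.

The measurement model: every spot's red-channel intensity is the sum of
autofluorescence and bound-antibody fluorescence, R = R_AF + R_IgE, while
the green channel is autofluorescence only (G = G_AF).  Mock arrays
(buffer + secondary antibody, no serum) show a linear red-on-green
relationship, R_AF = m*G_AF + b, fitted separately for each allergen
because autofluorescence varies from allergen to allergen.  Sample arrays
are corrected by subtracting the fitted prediction from the observed red
channel, leaving an estimate of the IgE-driven signal.

Processing order: (1) discard flagged spots, (2) log2-transform both
channels, (3) correct for autofluorescence, (4) subtract allergen-specific
detection thresholds set at the 99th percentile of corrected mock values —
so that a null spot is called positive about 1% of the time.  Replicate
spots are aggregated with a one-step Tukey biweight mean into "microarray
units"; a serum-allergen cell with more than 50% of its replicates missing
is discarded.

By default the linear fit operates on log2 intensities (the transform
precedes correction in the processing order); set ``scale="raw"`` to fit
and correct raw intensities instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .array_io import ArrayScan
from .errors import AnalysisError, CalibrationError
from .layout import ArrayLayout

LOG2_FLOOR = 1.0  # intensities are floored at 1 before log2 (log2(1) = 0)


@dataclass
class ProcessedArray:
    """Unflagged spots of one array on the analysis scale.

    ``data`` columns: block, column, row, name, replicate_index, log2_red,
    log2_green, and — once filled by :func:`correct` and
    :func:`apply_thresholds` — ``corrected`` and ``thresholded``.
    """

    data: pd.DataFrame
    meta: object = None
    scale: str = "log2"

    def __len__(self) -> int:
        return len(self.data)


def preprocess(scan: ArrayScan, scale: str = "log2") -> ProcessedArray:
    """Discard flagged spots (flag < 0) and log2-transform both channels.

    Intensities are floored at 1 so zero-intensity spots map to log2 = 0
    rather than -inf.  An all-flagged array yields an empty result with a
    warning rather than an error.
    """
    df = scan.to_frame()
    kept = df[df["flag"] >= 0].drop(columns=["flag"]).reset_index(drop=True)
    if len(kept) == 0 and len(df) > 0:
        warnings.warn("all spots flagged; empty array after preprocessing",
                      stacklevel=2)
    if scale == "log2":
        kept["log2_red"] = np.log2(np.maximum(kept["red_median"], LOG2_FLOOR))
        kept["log2_green"] = np.log2(np.maximum(kept["green_median"], LOG2_FLOOR))
    elif scale == "raw":
        kept["log2_red"] = kept["red_median"].astype(float)
        kept["log2_green"] = kept["green_median"].astype(float)
    else:
        raise AnalysisError(f"unknown scale {scale!r}")
    kept = kept.drop(columns=["red_median", "green_median"])
    return ProcessedArray(data=kept, meta=scan.meta, scale=scale)


@dataclass
class CalibrationModel:
    """Per-allergen autofluorescence fits and detection thresholds.

    ``table`` is indexed by allergen with columns ``m`` (slope), ``b``
    (intercept), ``resid_sd``, ``n_fit`` (mock spots used by the fit),
    ``tau`` (detection threshold, corrected-scale units), ``n_tau``
    (mock values behind the threshold) and ``low_confidence`` (True when
    fewer than ``min_tau_values`` values supported the threshold).
    Allergens without a fit carry NaN in ``m`` — explicitly uncalibratable.
    """

    table: pd.DataFrame
    percentile: float = 0.99
    scale: str = "log2"

    def is_calibrated(self, allergen: str) -> bool:
        return (allergen in self.table.index
                and np.isfinite(self.table.loc[allergen, "m"]))

    def has_threshold(self, allergen: str) -> bool:
        return (self.is_calibrated(allergen)
                and np.isfinite(self.table.loc[allergen, "tau"]))

    @property
    def uncalibratable(self) -> list[str]:
        return list(self.table.index[~np.isfinite(self.table["m"])])

    def to_json(self, path: str | Path, extra: Mapping | None = None) -> Path:
        path = Path(path)
        payload = {
            "percentile": self.percentile,
            "scale": self.scale,
            "allergens": {
                str(a): {k: (None if not np.isfinite(v) else round(float(v), 12))
                         if isinstance(v, (int, float, np.floating, np.integer))
                         else bool(v)
                         for k, v in row.items()}
                for a, row in self.table.iterrows()
            },
        }
        if extra:
            payload.update(extra)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        table = pd.DataFrame.from_dict(payload["allergens"], orient="index")
        table.index.name = "allergen"
        for col in ("m", "b", "resid_sd", "tau"):
            table[col] = table[col].astype(float)
        return cls(table=table, percentile=payload["percentile"],
                   scale=payload.get("scale", "log2"))


_MODEL_COLUMNS = ["m", "b", "resid_sd", "n_fit", "tau", "n_tau", "low_confidence"]


def fit_autofluorescence(mock_arrays: Sequence[ProcessedArray],
                         layout: ArrayLayout,
                         min_spots: int = 3) -> CalibrationModel:
    """Fit the per-allergen red-on-green line over pooled mock spots.

    Ordinary least squares of log2 red on log2 green, one fit per allergen,
    pooling all unflagged mock spots across arrays.  Allergens with fewer
    than *min_spots* spots are marked uncalibratable; an allergen whose
    green channel has zero variance gets an intercept-only fallback
    (m = 0, b = mean log2 red) with a warning.
    """
    if not mock_arrays:
        raise CalibrationError("no mock arrays: cannot fit autofluorescence models")
    pooled = pd.concat([a.data for a in mock_arrays], ignore_index=True)
    rows = {}
    for allergen in layout.allergen_names:
        sub = pooled[pooled["name"] == allergen]
        n = len(sub)
        if n < min_spots:
            rows[allergen] = dict(m=np.nan, b=np.nan, resid_sd=np.nan, n_fit=n,
                                  tau=np.nan, n_tau=0, low_confidence=True)
            continue
        g = sub["log2_green"].to_numpy(float)
        r = sub["log2_red"].to_numpy(float)
        if np.ptp(g) == 0.0:
            warnings.warn(f"{allergen}: zero green variance; intercept-only fit",
                          stacklevel=2)
            m, b = 0.0, float(np.mean(r))
        else:
            m, b = np.polyfit(g, r, 1)
        resid = r - (m * g + b)
        # residual sd with 2 fitted parameters
        dof = max(n - 2, 1)
        rows[allergen] = dict(m=float(m), b=float(b),
                              resid_sd=float(np.sqrt(np.sum(resid ** 2) / dof)),
                              n_fit=n, tau=np.nan, n_tau=0, low_confidence=False)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_MODEL_COLUMNS)
    table.index.name = "allergen"
    scale = mock_arrays[0].scale
    return CalibrationModel(table=table, scale=scale)


def correct(array: ProcessedArray, model: CalibrationModel) -> ProcessedArray:
    """Subtract the fitted autofluorescence prediction from the red channel.

    corrected = log2 R - (m_a * log2 G + b_a); spots of uncalibrated
    allergens (and non-allergen spots) get NaN.
    """
    df = array.data.copy()
    m = df["name"].map(model.table["m"])
    b = df["name"].map(model.table["b"])
    df["corrected"] = df["log2_red"] - (m * df["log2_green"] + b)
    return ProcessedArray(data=df, meta=array.meta, scale=array.scale)


def pool_corrected(arrays: Iterable[ProcessedArray],
                   layout: ArrayLayout) -> dict[str, np.ndarray]:
    """Per-allergen corrected values pooled across arrays (NaN dropped)."""
    pooled = pd.concat([a.data for a in arrays], ignore_index=True)
    out: dict[str, np.ndarray] = {}
    for allergen in layout.allergen_names:
        vals = pooled.loc[pooled["name"] == allergen, "corrected"].to_numpy(float)
        out[allergen] = vals[np.isfinite(vals)]
    return out


#: quantile plotting-position conventions: name -> numpy.quantile method
QUANTILE_CONVENTIONS = {
    "exceedance": "weibull",  # (n+1)p position: held-out exceedance = 1 - p
    "linear": "linear",       # (n-1)p + 1 position: the textbook/R default
}


def empirical_quantile(values: Sequence[float], p: float,
                       convention: str = "exceedance") -> float:
    """Interpolated empirical quantile under a named plotting-position convention.

    ``"exceedance"`` interpolates at position (n+1)p so that the probability
    a fresh null draw exceeds the estimate is 1 - p on average — the right
    calibration when the quantile is a detection threshold.  ``"linear"``
    interpolates at (n-1)p + 1 (the numpy/R default), which at small n calls
    roughly 2/(n+1) of fresh nulls positive at p = 0.99.
    """
    try:
        method = QUANTILE_CONVENTIONS[convention]
    except KeyError:
        raise AnalysisError(f"unknown quantile convention {convention!r}") from None
    return float(np.quantile(np.asarray(values, float), p, method=method))


def calibrate_thresholds(corrected_mock_values: Mapping[str, Sequence[float]],
                         model: CalibrationModel,
                         p: float = 0.99,
                         min_values: int = 20,
                         convention: str = "exceedance") -> CalibrationModel:
    """Set per-allergen detection thresholds at the empirical *p*-quantile.

    tau_a is the interpolated empirical quantile of the allergen's corrected
    mock values, exceedance-calibrated by default so that the realized
    false-positive rate on fresh null spots matches the nominal 1 - p.
    Fewer than *min_values* values still yield a threshold but flag it
    low-confidence; an empty value list leaves the allergen without a
    threshold.
    """
    table = model.table.copy()
    for allergen, values in corrected_mock_values.items():
        if allergen not in table.index:
            continue
        vals = np.asarray(values, float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            table.loc[allergen, ["tau", "n_tau"]] = [np.nan, 0]
            table.loc[allergen, "low_confidence"] = True
            continue
        table.loc[allergen, "tau"] = empirical_quantile(vals, p, convention)
        table.loc[allergen, "n_tau"] = int(vals.size)
        if vals.size < min_values:
            table.loc[allergen, "low_confidence"] = True
    return CalibrationModel(table=table, percentile=p, scale=model.scale)


def calibrate(mock_arrays: Sequence[ProcessedArray],
              layout: ArrayLayout,
              p: float = 0.99,
              min_spots: int = 3,
              min_values: int = 20,
              convention: str = "exceedance") -> CalibrationModel:
    """Fit autofluorescence models and thresholds in one pass over mocks."""
    model = fit_autofluorescence(mock_arrays, layout, min_spots=min_spots)
    corrected = [correct(a, model) for a in mock_arrays]
    values = pool_corrected(corrected, layout)
    return calibrate_thresholds(values, model, p=p, min_values=min_values,
                                convention=convention)


def apply_thresholds(array: ProcessedArray, model: CalibrationModel) -> ProcessedArray:
    """Subtract allergen-specific thresholds; positive call <=> thresholded > 0.

    Values at exactly the threshold are negative calls (strict inequality).
    Missing corrected values propagate to missing thresholded values.
    """
    df = array.data.copy()
    if "corrected" not in df.columns:
        raise AnalysisError("array must be corrected before thresholding")
    tau = df["name"].map(model.table["tau"])
    df["thresholded"] = df["corrected"] - tau
    return ProcessedArray(data=df, meta=array.meta, scale=array.scale)


def is_positive(thresholded: float) -> bool:
    """Positive signal cutoff: strictly above the allergen-specific threshold."""
    return bool(np.isfinite(thresholded) and thresholded > 0.0)


def tukey_biweight(values: Sequence[float], c: float = 5.0) -> float:
    """One-step Tukey biweight location estimate.

    Location starts at the median, scale is the (unscaled) median absolute
    deviation; points beyond ``c * MAD`` get zero weight.  A zero MAD
    (majority of values identical) returns the median.
    """
    x = np.asarray(values, float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    u = np.clip((x - med) / (c * mad), -1.0, 1.0)  # |u| >= 1 gets weight 0 anyway
    w = (1.0 - u ** 2) ** 2
    if w.sum() == 0.0:  # pragma: no cover - cannot happen: median has u=0
        return med
    return float(np.sum(w * x) / np.sum(w))


def tukey_trimean(values: Sequence[float]) -> float:
    """Tukey trimean (Q1 + 2*median + Q3) / 4 — alternative aggregator."""
    x = np.asarray(values, float)
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return float((q1 + 2.0 * q2 + q3) / 4.0)


def aggregate_replicates(values: Sequence[float],
                         expected_n: int,
                         method: str = "biweight",
                         c: float = 5.0) -> float:
    """Aggregate one serum-allergen cell's replicate values.

    Returns NaN when more than 50% of the *expected_n* replicates are
    missing (non-finite or absent); otherwise the one-step Tukey biweight
    mean (default) or the Tukey trimean of the present values.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if expected_n <= 0 or x.size <= expected_n / 2.0:
        return float("nan")
    if method == "biweight":
        return tukey_biweight(x, c=c)
    if method == "trimean":
        return tukey_trimean(x)
    if method == "mean":
        return float(np.mean(x))
    raise AnalysisError(f"unknown aggregation method {method!r}")


@dataclass
class IgEMatrix:
    """Sera x allergens specific-IgE matrix in microarray units.

    ``values`` holds threshold-subtracted, replicate-aggregated corrected
    log2 intensities (NaN = missing); ``counts`` the number of replicate
    spots behind each cell.  When replicate arrays are kept separate, rows
    are (serum_id, array_key) pairs.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    collapsed: bool = True

    @property
    def sera(self) -> list:
        return list(self.values.index)

    @property
    def allergens(self) -> list[str]:
        return list(self.values.columns)

    def positive_calls(self) -> pd.DataFrame:
        """Boolean calls: value strictly > 0 (missing -> False)."""
        return self.values.gt(0.0) & self.values.notna()

    def to_csv(self, path: str | Path, comment: str | None = None) -> Path:
        path = Path(path)
        text = self.values.to_csv(float_format="%.10g")
        if comment:
            text = f"# {comment}\n" + text
        path.write_text(text)
        return path


def build_ige_matrix(arrays: Sequence[ProcessedArray],
                     layout: ArrayLayout,
                     model: CalibrationModel,
                     collapse_replicate_arrays: bool = True,
                     method: str = "biweight") -> IgEMatrix:
    """Assemble the specific-IgE matrix from thresholded sample arrays.

    Each array contributes one cell per calibrated allergen: the aggregate
    of its replicate spots' thresholded values under the >50%-missing rule.
    With ``collapse_replicate_arrays`` the replicate arrays of one serum are
    then averaged (a cell stays missing if over half its arrays are
    missing); otherwise rows are (serum_id, array_key) pairs.
    Uncalibratable allergens contribute no column.
    """
    sample_arrays = [a for a in arrays if a.meta is not None and not a.meta.is_mock]
    if not sample_arrays:
        raise AnalysisError("no sample (serum) arrays to quantify")
    allergens = [a for a in layout.allergen_names if model.has_threshold(a)]
    expected = layout.replicates_per_allergen

    rows = {}
    counts = {}
    for arr in sample_arrays:
        m = arr.meta
        key = (m.serum_id, f"{m.slide_id}:{m.array_position}")
        if "thresholded" not in arr.data.columns:
            raise AnalysisError("arrays must be thresholded before assembly")
        by_name = arr.data.groupby("name")["thresholded"]
        vals = {}
        cnts = {}
        grouped = {name: grp.to_numpy(float) for name, grp in by_name}
        for a in allergens:
            cell = grouped.get(a, np.array([]))
            vals[a] = aggregate_replicates(cell, expected, method=method)
            cnts[a] = int(np.isfinite(cell).sum())
        rows[key] = vals
        counts[key] = cnts

    values = pd.DataFrame.from_dict(rows, orient="index")[allergens]
    ncounts = pd.DataFrame.from_dict(counts, orient="index")[allergens]
    values.index = pd.MultiIndex.from_tuples(values.index, names=["serum_id", "array"])
    ncounts.index = values.index

    if not collapse_replicate_arrays:
        return IgEMatrix(values=values, counts=ncounts, collapsed=False)

    def collapse(group: pd.DataFrame) -> pd.Series:
        present = group.notna().sum(axis=0)
        out = group.mean(axis=0, skipna=True)
        out[present <= len(group) / 2.0] = np.nan
        return out

    collapsed = values.groupby(level="serum_id", sort=True).apply(collapse)
    total_counts = ncounts.groupby(level="serum_id", sort=True).sum()
    return IgEMatrix(values=collapsed, counts=total_counts, collapsed=True)


@dataclass
class StandardCurveQC:
    """Result of the IgE standard-curve monotonicity check."""

    passed: bool
    rho: float        # Spearman rank correlation of signal vs pg/spot
    n_points: int
    skipped: bool = False


def qc_standard_curve(array: ProcessedArray,
                      layout: ArrayLayout,
                      min_rho: float = 0.9) -> StandardCurveQC:
    """Check that IgE standard spots brighten with printed amount.

    Rank-correlates mean red signal against pg/spot over the IgE standard
    dilution series; passes when Spearman rho exceeds *min_rho*.  Serves
    only as a secondary-antibody sanity check — standards are never used
    for normalization.  IgG/IgA standards are ignored.
    """
    concs = []
    means = []
    for conc in layout.standard_concentrations:
        from .layout import standard_label
        label = standard_label("IgE", conc)
        sub = array.data[array.data["name"] == label]
        if len(sub):
            concs.append(conc)
            means.append(float(sub["log2_red"].mean()))
    if len(concs) < 3:
        warnings.warn("IgE standards absent or too few; QC skipped", stacklevel=2)
        return StandardCurveQC(passed=False, rho=float("nan"),
                               n_points=len(concs), skipped=True)
    rho = float(sps.spearmanr(concs, means).statistic)
    return StandardCurveQC(passed=rho > min_rho, rho=rho, n_points=len(concs))
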