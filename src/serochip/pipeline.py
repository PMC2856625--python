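"""End-to-end orchestration: calibrate -> quantify -> report -> cluster.

``run_pipeline`` executes the full processing chain on a slide manifest:
preprocess every array, fit per-allergen autofluorescence models and
detection thresholds on the mock arrays, correct and threshold the serum
arrays, aggregate replicates into the specific-IgE matrix, compute
reproducibility statistics, and cluster allergen profiles with bootstrap
support.  Every artifact records the config hash and seed that produced
it, and every discarded spot or allergen is counted in the run report —
stages skip loudly, never silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correction, stats as st
from .array_io import ManifestEntry, read_manifest, load_scans
from .clustering import (average_linkage_cluster, bootstrap_support,
                         correlation_distance, export_newick, multiscale_au,
                         DEFAULT_SCALES)
from .errors import AnalysisError, CalibrationError
from .layout import ArrayLayout, default_layout


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run."""

    manifest: str
    out_dir: str
    base_dir: str | None = None
    scale: str = "log2"
    aggregation: str = "biweight"
    percentile: float = 0.99
    mean_floor: float = 0.5
    collapse_replicate_arrays: bool = True
    cluster_B: int = 1000
    cluster_scales: tuple[float, ...] = DEFAULT_SCALES
    compute_au: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Paths of the artifacts a run produced, plus the run report."""

    out_dir: Path
    calibration: Path | None
    ige_matrix: Path | None
    report: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def _long_table(matrix_per_array: correction.IgEMatrix,
                entries: list[ManifestEntry]) -> pd.DataFrame:
    """Tidy (serum, allergen, slide, day, array, value) table for the stats stage."""
    meta = {(e.serum_id, f"{e.slide_id}:{e.array_position}"): e for e in entries}
    rows = []
    for key, row in matrix_per_array.values.iterrows():
        e = meta.get(key)
        for allergen, value in row.items():
            rows.append({
                "serum_id": key[0],
                "array_id": key[1],  # unique physical array
                "array": e.array_position if e else key[1],  # position on slide
                "slide_id": e.slide_id if e else "",
                "day": e.day if e else "",
                "allergen": allergen, "value": value,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, layout: ArrayLayout | None = None) -> RunResult:
    """Run the full pipeline described by *config*; returns artifact paths."""
    if layout is None:
        layout = default_layout()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config={config.config_hash()} seed={config.seed}"
    report: dict = {"config": dataclasses.asdict(config),
                    "config_hash": config.config_hash(),
                    "seed": config.seed,
                    "notices": [], "counts": {}}
    artifacts: dict[str, Path] = {}

    entries = read_manifest(config.manifest)
    base = config.base_dir or str(Path(config.manifest).parent)
    scans = load_scans(entries, layout, base_dir=base)
    mock_scans = [s for s in scans if s.meta.is_mock]
    sample_scans = [s for s in scans if not s.meta.is_mock]
    if not mock_scans:
        raise CalibrationError(
            "manifest contains no MOCK arrays; thresholds cannot be calibrated — "
            "add mock (buffer-only) arrays to the manifest")
    report["counts"]["arrays_total"] = len(scans)
    report["counts"]["arrays_mock"] = len(mock_scans)
    report["counts"]["arrays_sample"] = len(sample_scans)
    n_spots = sum(len(s) for s in scans)
    n_flagged = sum(1 for s in scans for sp in s.spots if sp.flagged)
    report["counts"]["spots_total"] = n_spots
    report["counts"]["spots_flagged_discarded"] = n_flagged

    # -- calibrate ---------------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mock_proc = [correction.preprocess(s, scale=config.scale) for s in mock_scans]
        model = correction.calibrate(mock_proc, layout, p=config.percentile)
    report["notices"].extend(str(w.message) for w in caught)
    report["counts"]["allergens_uncalibratable"] = len(model.uncalibratable)
    report["uncalibratable_allergens"] = model.uncalibratable
    calib_path = out / "calibration.json"
    model.to_json(calib_path, extra={"config_hash": config.config_hash(),
                                     "seed": config.seed})
    artifacts["calibration"] = calib_path

    # standard-curve QC on mocks (never used for normalization)
    qc = [correction.qc_standard_curve(a, layout) for a in mock_proc]
    evaluated = [q for q in qc if not q.skipped]
    report["standard_curve_qc"] = {
        "arrays_evaluated": len(evaluated),
        "arrays_passed": sum(q.passed for q in evaluated),
    }

    matrix_path = None
    if not sample_scans:
        report["notices"].append("no sample arrays: quantification, statistics "
                                 "and clustering stages skipped")
        _write_report(report, out, artifacts)
        return RunResult(out_dir=out, calibration=calib_path,
                         ige_matrix=None, report=report, artifacts=artifacts)

    # -- quantify ----------------------------------------------------------
    processed = []
    for s in sample_scans:
        arr = correction.preprocess(s, scale=config.scale)
        arr = correction.correct(arr, model)
        arr = correction.apply_thresholds(arr, model)
        processed.append(arr)
    per_array = correction.build_ige_matrix(
        processed, layout, model, collapse_replicate_arrays=False,
        method=config.aggregation)
    matrix = correction.build_ige_matrix(
        processed, layout, model,
        collapse_replicate_arrays=config.collapse_replicate_arrays,
        method=config.aggregation)
    matrix_path = out / "ige_matrix.csv"
    matrix.to_csv(matrix_path, comment=tag)
    artifacts["ige_matrix"] = matrix_path
    per_array_path = out / "ige_matrix_per_array.csv"
    per_array.to_csv(per_array_path, comment=tag)
    artifacts["ige_matrix_per_array"] = per_array_path
    report["counts"]["matrix_missing_cells"] = int(matrix.values.isna().sum().sum())

    # -- statistics --------------------------------------------------------
    long = _long_table(per_array, entries)
    for level in (st.INTRA_SLIDE, st.INTER_SLIDE, st.INTER_ASSAY):
        try:
            cv = st.cv_report(long, level, classes=layout.allergen_classes,
                              mean_floor=config.mean_floor)
        except AnalysisError as exc:
            report["notices"].append(f"CV {level}: {exc}")
            continue
        if cv.empty:
            report["notices"].append(f"CV {level}: no qualifying cells")
            continue
        p = out / f"cv_{level.replace('-', '_')}.csv"
        p.write_text(f"# {tag}\n" + cv.summary.to_csv(float_format="%.6g"))
        artifacts[f"cv_{level}"] = p
    try:
        aov = st.anova_components(long)
        p = out / "anova.csv"
        p.write_text(f"# {tag}\n" + aov.table.to_csv(float_format="%.6g"))
        artifacts["anova"] = p
    except AnalysisError as exc:
        report["notices"].append(f"ANOVA skipped: {exc}")
    try:
        reg = st.pairwise_replicate_regression(
            per_array.values.reset_index(drop=True),
            group=[k[0] for k in per_array.values.index])
        p = out / "replicate_regression.csv"
        p.write_text(f"# {tag}\n" + reg.entries.to_csv(index=False, float_format="%.6g"))
        artifacts["replicate_regression"] = p
        report["replicate_regression"] = {
            "median_slope": reg.median_slope,
            "median_r_squared": reg.median_r_squared,
            "n_pairs": int(len(reg.entries)),
        }
    except AnalysisError as exc:
        report["notices"].append(f"replicate regression skipped: {exc}")

    # -- clustering --------------------------------------------------------
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            dist = correlation_distance(matrix.values)
            tree = average_linkage_cluster(dist)
            if config.compute_au:
                support = multiscale_au(matrix.values, scales=config.cluster_scales,
                                        B=config.cluster_B, seed=config.seed,
                                        dendrogram=tree)
            else:
                support = bootstrap_support(matrix.values, B=config.cluster_B,
                                            seed=config.seed, dendrogram=tree)
        report["notices"].extend(str(w.message) for w in caught)
        tree_path = out / "tree.nwk"
        tree_path.write_text(f"[{tag}]\n" + export_newick(tree, support) + "\n")
        artifacts["tree"] = tree_path
        support_path = out / "cluster_support.csv"
        support.to_csv(support_path, comment=tag)
        artifacts["cluster_support"] = support_path
    except AnalysisError as exc:
        report["notices"].append(f"clustering skipped: {exc}")

    _write_report(report, out, artifacts)
    return RunResult(out_dir=out, calibration=calib_path,
                     ige_matrix=matrix_path, report=report, artifacts=artifacts)


def _write_report(report: dict, out: Path, artifacts: dict[str, Path]) -> None:
    report["artifacts"] = {k: str(v) for k, v in artifacts.items()}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return str(o)

    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=default) + "\n")
    artifacts["run_report"] = out / "run_report.json"
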