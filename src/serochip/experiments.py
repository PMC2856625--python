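"""Self-contained simulation experiments that exercise the whole pipeline.

Each routine simulates its inputs from the generative model, runs the
method under study, and measures the quantity of interest — false-positive
calibration, autofluorescence parameter recovery, replicate-array
concordance, and recovery of planted correlation blocks by bootstrap-
supported clustering.  They are used by the example scripts and the
acceptance checks, and are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correction
from .clustering import (average_linkage_cluster, bootstrap_support,
                         correlation_distance)
from .stats import pairwise_replicate_regression
from .synth import SimulationConfig, _rng, _TAG_ARRAYS, simulate_mock_array, simulate_study


@dataclass
class FprResult:
    """Held-out false-positive calibration measurement."""

    fpr: float                   # fraction of held-out null spots called positive
    n_held_out: int
    n_training_arrays: int
    nominal: float               # 1 - percentile
    binomial_se: float           # se of a binomial proportion at the nominal rate


def held_out_false_positive_rate(seed: int = 0,
                                 n_training_arrays: int = 36,
                                 min_held_out_values: int = 20000,
                                 percentile: float = 0.99,
                                 convention: str = "exceedance",
                                 config: SimulationConfig | None = None) -> FprResult:
    """Calibrate thresholds on training mocks; score fresh null spots.

    Simulates *n_training_arrays* mock arrays, fits per-allergen
    autofluorescence models and percentile thresholds on them, then scores
    an independent held-out stream of mock arrays (at least
    *min_held_out_values* unflagged allergen spots) against those
    thresholds.  Returns the positive-call fraction, whose target is the
    nominal rate 1 - percentile.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    layout = config.layout
    rng = _rng(config.seed, _TAG_ARRAYS, 99)
    training = [simulate_mock_array(config, rng=rng)
                for _ in range(n_training_arrays)]
    proc = [correction.preprocess(s) for s in training]
    model = correction.calibrate(proc, layout, p=percentile,
                                 convention=convention)

    spots_per_array = (len(layout.allergen_names)
                       * layout.replicates_per_allergen
                       * (1.0 - config.flag_rate))
    n_arrays = math.ceil(min_held_out_values / max(spots_per_array, 1.0)) + 2
    held = [simulate_mock_array(config, rng=rng) for _ in range(n_arrays)]
    frames = []
    for scan in held:
        arr = correction.preprocess(scan)
        arr = correction.apply_thresholds(correction.correct(arr, model), model)
        frames.append(arr.data)
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled[pooled["name"].isin(layout.allergen_names)]
    vals = pooled["thresholded"].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    nominal = 1.0 - percentile
    return FprResult(
        fpr=float(np.mean(vals > 0.0)),
        n_held_out=int(vals.size),
        n_training_arrays=n_training_arrays,
        nominal=nominal,
        binomial_se=float(np.sqrt(nominal * (1 - nominal) / vals.size)),
    )


@dataclass
class RecoveryResult:
    """Autofluorescence parameter-recovery measurement."""

    frac_m_within_3se: float
    frac_b_within_3se: float
    max_abs_corrected_mean: float   # training-mock corrected means (exact 0 for OLS)
    n_allergens: int
    n_spots_per_allergen: float


def autofluorescence_recovery(seed: int = 0,
                              spots_per_allergen: int = 200,
                              config: SimulationConfig | None = None) -> RecoveryResult:
    """Fit mocks simulated from known (m, b); compare estimates to truth.

    Simulates enough mock arrays for about *spots_per_allergen* unflagged
    spots per allergen, fits the per-allergen models, and reports the
    fraction of allergens whose slope and intercept estimates fall within
    three standard errors of the generating values, plus the largest
    per-allergen mean of corrected values on the training mocks themselves
    (an exact zero-mean property of least squares with intercept).
    """
    from .synth import allergen_params

    if config is None:
        config = SimulationConfig(seed=seed)
    layout = config.layout
    reps = layout.replicates_per_allergen
    n_arrays = math.ceil(spots_per_allergen / (reps * (1.0 - config.flag_rate)))
    rng = _rng(config.seed, _TAG_ARRAYS, 98)
    mocks = [simulate_mock_array(config, rng=rng) for _ in range(n_arrays)]
    proc = [correction.preprocess(s) for s in mocks]
    model = correction.fit_autofluorescence(proc, layout)
    truth = allergen_params(config)

    pooled = pd.concat([a.data for a in proc], ignore_index=True)
    ok_m = ok_b = 0
    n_tested = 0
    for a in layout.allergen_names:
        row = model.table.loc[a]
        if not np.isfinite(row["m"]):
            continue
        sub = pooled[pooled["name"] == a]
        g = sub["log2_green"].to_numpy(float)
        n = len(g)
        sxx = float(np.sum((g - g.mean()) ** 2))
        se_m = row["resid_sd"] / np.sqrt(sxx)
        se_b = row["resid_sd"] * np.sqrt(1.0 / n + g.mean() ** 2 / sxx)
        n_tested += 1
        if abs(row["m"] - truth.loc[a, "m"]) <= 3.0 * se_m:
            ok_m += 1
        if abs(row["b"] - truth.loc[a, "b"]) <= 3.0 * se_b:
            ok_b += 1

    corrected = [correction.correct(a, model) for a in proc]
    values = correction.pool_corrected(corrected, layout)
    max_mean = max(abs(float(np.mean(v))) for v in values.values() if v.size)
    return RecoveryResult(
        frac_m_within_3se=ok_m / n_tested,
        frac_b_within_3se=ok_b / n_tested,
        max_abs_corrected_mean=max_mean,
        n_allergens=n_tested,
        n_spots_per_allergen=len(pooled) and len(
            pooled[pooled["name"].isin(layout.allergen_names)]) / n_tested,
    )


@dataclass
class ConcordanceResult:
    """Replicate-array concordance on a simulated reproducibility study."""

    median_r_squared: float
    median_slope: float
    n_pairs: int


def replicate_concordance(seed: int = 0,
                          config: SimulationConfig | None = None) -> ConcordanceResult:
    """Full reproducibility study; pairwise regressions among replicate arrays.

    Simulates the default design (6 sera x 18 replicate arrays + 36 mocks),
    runs calibration and quantification, and regresses every pair of
    replicate arrays of the same serum against each other (918 pairs at the
    default design), reporting median R^2 and median slope.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    scans, _ = simulate_study(config)
    mocks = [s for s in scans if s.meta.is_mock]
    samples = [s for s in scans if not s.meta.is_mock]
    model = correction.calibrate([correction.preprocess(s) for s in mocks],
                                 config.layout)
    processed = []
    for s in samples:
        arr = correction.preprocess(s)
        arr = correction.apply_thresholds(correction.correct(arr, model), model)
        processed.append(arr)
    per_array = correction.build_ige_matrix(processed, config.layout, model,
                                            collapse_replicate_arrays=False)
    reg = pairwise_replicate_regression(
        per_array.values.reset_index(drop=True),
        group=[k[0] for k in per_array.values.index])
    return ConcordanceResult(median_r_squared=reg.median_r_squared,
                             median_slope=reg.median_slope,
                             n_pairs=len(reg.entries))


@dataclass
class BlockRecoveryResult:
    """Planted two-block recovery by bootstrap-supported clustering."""

    blocks_are_maximal_clades: bool
    bp_block_1: float
    bp_block_2: float
    B: int


def planted_block_matrix(n_rows: int = 40,
                         block_size: int = 5,
                         within_corr: float = 0.9,
                         seed: int = 0) -> tuple[pd.DataFrame, list[list[str]]]:
    """Profiles with two blocks of mutually correlated columns.

    Columns within a block share a latent factor with correlation
    *within_corr*; cross-block correlation is zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    blocks = [[f"X{j + 1}" for j in range(block_size)],
              [f"Y{j + 1}" for j in range(block_size)]]
    cols = {}
    for block in blocks:
        factor = rng.normal(size=n_rows)
        for name in block:
            cols[name] = (np.sqrt(within_corr) * factor
                          + np.sqrt(1.0 - within_corr) * rng.normal(size=n_rows))
    return pd.DataFrame(cols), blocks


def two_block_recovery(B: int = 1000, seed: int = 0,
                       n_rows: int = 40, block_size: int = 5,
                       within_corr: float = 0.9) -> BlockRecoveryResult:
    """Cluster a planted two-block matrix; measure BP of the block clades."""
    matrix, blocks = planted_block_matrix(n_rows=n_rows, block_size=block_size,
                                          within_corr=within_corr, seed=seed)
    tree = average_linkage_cluster(correlation_distance(matrix))
    maximal = sorted(frozenset(ch.leaves) for ch in tree.root.children)
    target = sorted(frozenset(b) for b in blocks)
    support = bootstrap_support(matrix, B=B, seed=seed, dendrogram=tree)
    bp = []
    for b in target:
        try:
            bp.append(support.bp_of(b))
        except KeyError:
            bp.append(0.0)
    return BlockRecoveryResult(blocks_are_maximal_clades=maximal == target,
                               bp_block_1=bp[0], bp_block_2=bp[1], B=B)
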