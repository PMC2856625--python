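"""Synthetic two-channel allergen arrays with known ground truth.

The generator emulates the statistical structure the correction pipeline
assumes.  Every spot autofluoresces in both channels; on the log2 scale the
green channel of allergen *a* is Normal(mu_G[a], sigma_G[a]) and the red
channel follows a per-allergen linear model

    log2 R_AF = m[a] * log2 G + b[a] + eps,   eps ~ Normal(0, sigma_eps[a])

Serum-specific IgE adds signal to the red channel only; the green channel is
identical in distribution between mock and serum arrays.  The magnitude of
the added signal scales with serum dilution through a monotone map
``h(d) = d / d_ref`` (proportional response on the log2 scale, the simplest
map consistent with the observed predictable decrease of signal under
dilution).  IgE standard-curve spots gain red signal increasing with the
printed pg/spot, because the anti-IgE secondary antibody binds printed IgE
directly — on mock arrays too; IgG/IgA standards gain nothing.

All generators are pure functions of (config, seed): the per-allergen
autofluorescence parameters, the spot noise and the flag pattern are drawn
from streams deterministically derived from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_io import ArrayMeta, ArrayScan, ManifestEntry, SpotRecord
from .errors import DesignError
from .layout import ArrayLayout, default_layout, standard_label

#: flag value assigned to simulated bad spots (scanner "bad" code)
BAD_SPOT_FLAG = -100

# stream tags for deterministic sub-seeding
_TAG_PARAMS = 1
_TAG_ARRAYS = 2
_TAG_PROFILES = 3
_TAG_ELISA = 4
_TAG_DESIGN = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of a synthetic study.

    Autofluorescence parameters are drawn once per spot label from the
    uniform ranges below (the spot-to-spot, allergen-to-allergen variation
    of autofluorescence has no published distribution, so the ranges are a
    modelling choice): mean log2 green in ``mu_g_range``, red-on-green slope
    in ``slope_range``, intercept in ``intercept_range``; ``sigma_g`` and
    ``sigma_eps`` are shared across labels.  ``signal_scale`` selects whether
    serum IgE signal adds on the log2 scale (default, matching the pipeline's
    log-then-correct order) or on the raw intensity scale.

    The default design is the reproducibility study: 6 sera x 18 replicate
    arrays (2 arrays on each of 3 shared slides per day, over 3 days) plus
    36 mock arrays, i.e. 144 arrays on 12 twelve-array slides — a layout
    with replication at all three levels the CV report distinguishes
    (within slide, between slides within a day, between days).
    """

    layout: ArrayLayout = field(default_factory=default_layout)
    mu_g_range: tuple[float, float] = (7.0, 11.0)
    sigma_g: float = 0.8
    slope_range: tuple[float, float] = (0.7, 1.1)
    intercept_range: tuple[float, float] = (-1.0, 2.0)
    sigma_eps: float = 0.3
    flag_rate: float = 0.02
    signal_scale: str = "log2"  # or "raw"
    standard_gain: float = 0.8  # log2 red per log2(1 + pg/spot) on IgE standards
    reference_dilution: float = 0.25
    n_sera: int = 6
    arrays_per_serum: int = 18
    n_mock_arrays: int = 36
    n_days: int = 3
    dilution_series: tuple[float, ...] = (0.5, 0.25, 0.125, 0.0625, 0.03125)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_g < 0 or self.sigma_eps < 0:
            raise DesignError("standard deviations must be >= 0")
        if not 0.0 <= self.flag_rate <= 1.0:
            raise DesignError("flag_rate must be in [0, 1]")
        if self.signal_scale not in ("log2", "raw"):
            raise DesignError("signal_scale must be 'log2' or 'raw'")
        if self.reference_dilution <= 0:
            raise DesignError("reference_dilution must be > 0")


@dataclass(frozen=True)
class SerumProfile:
    """Per-allergen specific-IgE effect of one serum.

    Effects are nonnegative log2-scale red-channel increments at the
    reference dilution; zero means not sensitized.  A mock profile has all
    effects zero.
    """

    serum_id: str
    effects: Mapping[str, float]
    total_ige_class: str = "none"  # none | low | moderate | high

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.effects.values()):
            raise DesignError("specific-IgE effects must be >= 0")

    def effect_of(self, name: str) -> float:
        return float(self.effects.get(name, 0.0))


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(t) for t in tags]))


def allergen_params(config: SimulationConfig) -> pd.DataFrame:
    """Per-label generative parameters, indexed by spot label.

    Columns: ``mu_g``, ``sigma_g``, ``m``, ``b``, ``sigma_eps``.  Drawn
    deterministically from the config seed; identical for every array of the
    study.
    """
    layout = config.layout
    labels = list(layout.expected_counts())
    # standard-curve spots are one material printed at several amounts, so
    # every concentration of an isotype shares one parameter draw
    groups: list[str] = []
    for label in labels:
        std = layout.standard_concentration_of(label)
        groups.append(std[0] if std is not None else label)
    unique = list(dict.fromkeys(groups))
    rng = _rng(config.seed, _TAG_PARAMS)
    n = len(unique)
    drawn = pd.DataFrame(
        {
            "mu_g": rng.uniform(*config.mu_g_range, size=n),
            "sigma_g": np.full(n, config.sigma_g),
            "m": rng.uniform(*config.slope_range, size=n),
            "b": rng.uniform(*config.intercept_range, size=n),
            "sigma_eps": np.full(n, config.sigma_eps),
        },
        index=pd.Index(unique),
    )
    out = drawn.loc[groups].set_index(pd.Index(labels, name="name"))
    return out


def _spot_order(layout: ArrayLayout) -> list[tuple[str, int]]:
    """(label, replicate_index) in print order."""
    order: list[tuple[str, int]] = []
    for name, n in layout.expected_counts().items():
        order.extend((name, r) for r in range(1, n + 1))
    return order


def _grid(i: int, n_cols: int = 12) -> tuple[int, int, int]:
    """Row-major grid position (block, column, row) of print index *i* (0-based)."""
    return (1, i % n_cols + 1, i // n_cols + 1)


def _simulate_array(config: SimulationConfig,
                    profile: SerumProfile | None,
                    dilution: float,
                    meta: ArrayMeta,
                    rng: np.random.Generator,
                    params: pd.DataFrame | None = None) -> ArrayScan:
    if params is None:
        params = allergen_params(config)
    pdict = {name: (row[0], row[1], row[2], row[3], row[4])
             for name, row in zip(params.index, params.to_numpy())}
    layout = config.layout
    h = dilution / config.reference_dilution
    spots: list[SpotRecord] = []
    for i, (name, rep) in enumerate(_spot_order(layout)):
        mu_g, sigma_g, m, b, sigma_eps = pdict[name]
        g_log = rng.normal(mu_g, sigma_g)
        r_log = m * g_log + b + rng.normal(0.0, sigma_eps)
        std = layout.standard_concentration_of(name)
        if std is not None and std[0] == "IgE":
            # secondary antibody binds printed IgE regardless of serum
            r_log += config.standard_gain * math.log2(1.0 + std[1])
        green = 2.0 ** g_log
        red = 2.0 ** r_log
        if profile is not None:
            effect = profile.effect_of(name)
            if effect > 0.0:
                if config.signal_scale == "log2":
                    red = 2.0 ** (r_log + h * effect)
                else:
                    red = red + h * (2.0 ** effect - 1.0)
        flag = BAD_SPOT_FLAG if rng.random() < config.flag_rate else 0
        block, col, row = _grid(i)
        spots.append(SpotRecord(block=block, column=col, row=row, name=name,
                                replicate_index=rep, red_median=red,
                                green_median=green, flag=flag))
    return ArrayScan(spots=spots, meta=meta)


def simulate_mock_array(config: SimulationConfig,
                        meta: ArrayMeta | None = None,
                        rng: np.random.Generator | None = None) -> ArrayScan:
    """One mock array: buffer + secondary antibody, no serum — pure autofluorescence."""
    if meta is None:
        meta = ArrayMeta(serum_id=None)
    if rng is None:
        rng = _rng(config.seed, _TAG_ARRAYS, 0)
    return _simulate_array(config, None, config.reference_dilution, meta, rng)


def simulate_serum_array(config: SimulationConfig,
                         profile: SerumProfile,
                         dilution: float | None = None,
                         meta: ArrayMeta | None = None,
                         rng: np.random.Generator | None = None) -> ArrayScan:
    """One serum-probed array at the given dilution fraction (in (0, 1])."""
    if dilution is None:
        dilution = config.reference_dilution
    if dilution <= 0:
        raise DesignError(f"dilution must be > 0, got {dilution}")
    if meta is None:
        meta = ArrayMeta(serum_id=profile.serum_id, dilution=dilution)
    else:
        meta = replace(meta, serum_id=profile.serum_id, dilution=dilution)
    if rng is None:
        rng = _rng(config.seed, _TAG_ARRAYS, 1)
    return _simulate_array(config, profile, dilution, meta, rng)


def random_profiles(config: SimulationConfig,
                    n: int | None = None,
                    sensitization_rate: float = 0.15,
                    effect_range: tuple[float, float] = (1.5, 5.0),
                    blocks: Sequence[Sequence[str]] | None = None) -> list[SerumProfile]:
    """Random serum profiles over the config's allergen panel.

    Sera differ in overall reactivity (emulating panels chosen to span a
    wide range of specific-IgE levels): each serum draws a breadth
    multiplier uniform in [1/3, 5/3] of ``sensitization_rate`` and is then
    sensitized to that fraction of allergens with log2 effects uniform in
    ``effect_range``.  If *blocks* are given (groups of allergen labels),
    each serum additionally receives a shared per-block latent level,
    making within-block allergen effects mutually correlated across sera —
    the structure that downstream clustering should recover as clades.
    """
    if n is None:
        n = config.n_sera
    rng = _rng(config.seed, _TAG_PROFILES)
    allergens = config.layout.allergen_names
    lo, hi = effect_range
    classes = ("low", "moderate", "high")
    profiles: list[SerumProfile] = []
    for i in range(n):
        effects: dict[str, float] = {}
        rate = min(1.0, sensitization_rate * rng.uniform(1 / 3, 5 / 3))
        if blocks is None:
            for a in allergens:
                if rng.random() < rate:
                    effects[a] = float(rng.uniform(lo, hi))
        else:
            for block in blocks:
                level = float(rng.uniform(0.0, hi))
                for a in block:
                    effects[a] = max(0.0, level + float(rng.normal(0.0, 0.25)))
        total = sum(effects.values())
        cls = "none" if total == 0 else classes[min(2, int(total // 20))]
        profiles.append(SerumProfile(serum_id=f"serum{i + 1:02d}",
                                     effects=effects, total_ige_class=cls))
    return profiles


@dataclass
class StudyTruth:
    """Ground truth of a simulated study, for parameter-recovery tests."""

    allergen_params: pd.DataFrame        # per-label mu_g, m, b, sigma_eps
    effects: pd.DataFrame                # sera x allergens true log2 effects
    manifest: list[ManifestEntry]


def simulate_study(config: SimulationConfig,
                   profiles: Sequence[SerumProfile] | None = None
                   ) -> tuple[list[ArrayScan], StudyTruth]:
    """Simulate a full study: mock arrays plus replicated serum arrays.

    Each serum is probed on ``arrays_per_serum / n_days`` arrays per day,
    spread round-robin across that day's shared slides, across ``n_days``
    days.  Mock arrays fill their own slides, spread across days.  Returns
    the scans and a ground-truth table.
    """
    if profiles is None:
        profiles = random_profiles(config)
    layout = config.layout
    aps = layout.arrays_per_slide
    n_days = config.n_days
    if profiles:
        if config.arrays_per_serum % n_days != 0:
            raise DesignError("arrays_per_serum must be divisible by n_days")
        per_day = config.arrays_per_serum // n_days
        if per_day < 1:
            raise DesignError("each serum needs at least one array per day")
    params = allergen_params(config)
    rng = _rng(config.seed, _TAG_ARRAYS)

    scans: list[ArrayScan] = []
    manifest: list[ManifestEntry] = []
    slide_no = 0

    def add(scan: ArrayScan) -> None:
        m = scan.meta
        manifest.append(ManifestEntry(
            path=f"{m.slide_id}_a{m.array_position:02d}.gpr",
            slide_id=m.slide_id, array_position=m.array_position,
            serum_id=m.serum_id, day=m.day, dilution=m.dilution))
        scans.append(scan)

    # mock arrays, spread across days on dedicated slides
    mocks_left = config.n_mock_arrays
    day_cycle = 0
    while mocks_left > 0:
        slide_no += 1
        slide_id = f"S{slide_no:02d}"
        day = f"day{day_cycle % n_days + 1}"
        day_cycle += 1
        for pos in range(1, min(aps, mocks_left) + 1):
            meta = ArrayMeta(slide_id=slide_id, array_position=pos,
                             serum_id=None, day=day,
                             dilution=config.reference_dilution)
            add(_simulate_array(config, None, config.reference_dilution,
                                meta, rng, params))
        mocks_left -= min(aps, mocks_left)

    # serum arrays: per day, each serum's arrays are spread across that
    # day's shared slides (round-robin over replicates), so every serum is
    # seen on several slides per day and replicate levels within slide,
    # between slides and between days all have >= 2 observations where the
    # slide capacity allows
    design_rng = _rng(config.seed, _TAG_DESIGN)
    for d in range(1, n_days + 1) if profiles else []:
        day = f"day{d}"
        slots = [(prof, r) for r in range(per_day) for prof in profiles]
        # randomize serum-to-position assignment so array position is not
        # confounded with serum identity in downstream variance analyses
        slots = [slots[k] for k in design_rng.permutation(len(slots))]
        day_slides = -(-len(slots) // aps)  # ceil
        first_slide = slide_no + 1
        slide_no += day_slides
        fill: dict[int, int] = {}
        for k, (prof, _) in enumerate(slots):
            s_idx = first_slide + k // aps
            fill[s_idx] = fill.get(s_idx, 0) + 1
            meta = ArrayMeta(slide_id=f"S{s_idx:02d}", array_position=fill[s_idx],
                             serum_id=prof.serum_id, day=day,
                             dilution=config.reference_dilution)
            add(_simulate_array(config, prof, config.reference_dilution,
                                meta, rng, params))

    effects = pd.DataFrame(
        {a: [p.effect_of(a) for p in profiles] for a in layout.allergen_names},
        index=pd.Index([p.serum_id for p in profiles], name="serum_id"),
    )
    truth = StudyTruth(allergen_params=params, effects=effects, manifest=manifest)
    return scans, truth


ELISA_CUTOFF = 0.35  # kU/L, clinical positivity cutoff (strict >)


def simulate_elisa_panel(profiles: Sequence[SerumProfile],
                         allergens: Sequence[str],
                         noise_sd: float = 0.05,
                         seed: int = 0,
                         sensitized_positive_rate: float = 0.81,
                         ) -> pd.DataFrame:
    """Synthetic ELISA panel in kU/L for the given serum-allergen pairs.

    Non-sensitized pairs measure pure noise, ``max(0, Normal(0, noise_sd))``
    — zero when ``noise_sd`` is zero.  Sensitized pairs exceed the 0.35 kU/L
    clinical cutoff with probability ``sensitized_positive_rate`` (the
    remainder fall below it, emulating analyte-dependent ELISA sensitivity);
    positive magnitudes scale with the true effect.  Returns a tidy frame
    with columns serum_id, allergen, kU_per_L, sensitized.
    """
    rng = _rng(seed, _TAG_ELISA)
    rows = []
    for prof in profiles:
        for a in allergens:
            effect = prof.effect_of(a)
            if effect > 0:
                if rng.random() < sensitized_positive_rate:
                    value = ELISA_CUTOFF + 0.05 + rng.exponential(0.5 * effect)
                else:
                    value = rng.uniform(0.0, ELISA_CUTOFF)
            else:
                value = max(0.0, rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            rows.append({"serum_id": prof.serum_id, "allergen": a,
                         "kU_per_L": value, "sensitized": effect > 0})
    return pd.DataFrame(rows)
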