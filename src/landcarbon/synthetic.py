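"""Seeded synthetic scenario generation.

Everything downstream (classification, change detection, Markov projection,
agreement validation, carbon accounting) is exercised against rasters drawn
from a :class:`SyntheticScenario` whose transition matrices, driver effects
and spectral signatures are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    DEFAULT_NODATA,
    DEFAULT_PIXEL_SIZE,
    LulcMap,
    check_row_stochastic,
    substream,
)
from .errors import ConfigurationError, SamplingError, ValidationError

#: Default 6-class legend: forest, rangeland, cropland, barren, artificial, water.
DEFAULT_CLASS_CODES = (1, 2, 3, 4, 5, 6)
DEFAULT_CLASS_NAMES = {
    1: "forest",
    2: "rangeland",
    3: "cropland",
    4: "barren",
    5: "artificial",
    6: "water",
}

DRIVER_NAMES = (
    "elevation",
    "slope",
    "aspect",
    "dist_forest",
    "dist_rangeland",
    "dist_cropland",
    "dist_artificial",
    "dist_water",
    "dist_road",
)


@dataclass
class DriverSpec:
    """Spatial model for one driver surface.

    ``model`` is either ``"smooth"`` (Gaussian-filtered noise rescaled to
    ``value_range``) or ``"distance"`` (Euclidean distance in metres to the
    nearest pixel of class ``distance_to`` on the current map).
    ``effect_weights`` maps a target class code to the additive log-odds
    weight applied per standardized driver unit during :func:`evolve_lulc`.
    """

    name: str
    model: str = "smooth"
    smoothness: float = 10.0
    value_range: tuple[float, float] = (0.0, 1.0)
    units: str = ""
    distance_to: int | None = None
    effect_weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("smooth", "distance"):
            raise ConfigurationError(f"unknown driver model {self.model!r}")
        if self.model == "distance" and self.distance_to is None:
            raise ConfigurationError(f"driver {self.name!r}: distance model needs distance_to")


@dataclass
class DriverField:
    """A realised continuous driver raster."""

    name: str
    raster: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        finite = self.raster[np.isfinite(self.raster)]
        if self.name.startswith("dist") and finite.size and finite.min() < 0:
            raise ValidationError(f"distance driver {self.name!r} has negative values")


@dataclass
class SyntheticScenario:
    """Ground-truth description of a synthetic multi-epoch landscape."""

    grid_rows: int
    grid_cols: int
    class_codes: tuple[int, ...] = DEFAULT_CLASS_CODES
    pixel_size: float = DEFAULT_PIXEL_SIZE
    epoch_years: tuple[int, ...] = (1985, 2000, 2010, 2020)
    true_transition_matrices: tuple[np.ndarray, ...] = ()
    class_prevalence: tuple[float, ...] | None = None
    driver_spec: tuple[DriverSpec, ...] = ()
    spectral_signatures: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    nodata: int = DEFAULT_NODATA
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_codes = tuple(int(c) for c in self.class_codes)
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid must have positive dimensions")
        if len(self.class_codes) < 2:
            raise ConfigurationError("at least 2 classes are required")
        if len(set(self.class_codes)) != len(self.class_codes):
            raise ConfigurationError("class codes must be unique")
        years = list(self.epoch_years)
        if years != sorted(years) or len(set(years)) != len(years):
            raise ConfigurationError("epoch_years must be strictly increasing")
        mats = tuple(np.asarray(M, dtype=float) for M in self.true_transition_matrices)
        if mats and len(mats) != len(years) - 1:
            raise ConfigurationError("need one transition matrix per consecutive epoch pair")
        for M in mats:
            if M.shape != (len(self.class_codes),) * 2:
                raise ConfigurationError("transition matrix shape must match class count")
            check_row_stochastic(M)
        self.true_transition_matrices = mats
        if self.class_prevalence is not None:
            w = np.asarray(self.class_prevalence, dtype=float)
            if w.size != len(self.class_codes) or np.any(w < 0) or w.sum() <= 0:
                raise ConfigurationError("class_prevalence must be nonnegative per class")
            self.class_prevalence = tuple(float(x) for x in w / w.sum())
        for code, (mean, sd) in self.spectral_signatures.items():
            if code not in self.class_codes:
                raise ConfigurationError(f"signature for unknown class {code}")
            if np.any(np.asarray(sd, dtype=float) < 0):
                raise ConfigurationError("spectral standard deviations must be >= 0")


@dataclass
class ImageCollection:
    """Stack of co-registered multiband scenes from one epoch."""

    scenes: list[np.ndarray]  # each (n_bands, rows, cols)
    band_names: tuple[str, ...]
    acquisition_dates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.scenes:
            raise ValidationError("an ImageCollection needs at least one scene")
        shape = self.scenes[0].shape
        for s in self.scenes:
            if s.shape != shape:
                raise ValidationError("all scenes must share grid and band count")
        if len(self.band_names) != shape[0]:
            raise ValidationError("band_names length must equal band count")

    @property
    def n_scenes(self) -> int:
        return len(self.scenes)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.scenes[0].shape[1:]


def _prevalence(scenario: SyntheticScenario) -> np.ndarray:
    if scenario.class_prevalence is not None:
        return np.asarray(scenario.class_prevalence, dtype=float)
    k = len(scenario.class_codes)
    return np.full(k, 1.0 / k)


def generate_initial_lulc(scenario: SyntheticScenario) -> LulcMap:
    """Draw the first-epoch categorical map.

    A Gaussian-smoothed noise field is thresholded at the cumulative
    class-prevalence quantiles, which yields spatially contiguous patches with
    the requested class frequencies (exactly, up to quantile ties).
    Deterministic for a fixed scenario seed.
    """
    rng = substream(scenario.seed, "initial_lulc")
    weights = _prevalence(scenario)
    field_ = rng.standard_normal((scenario.grid_rows, scenario.grid_cols))
    field_ = ndimage.gaussian_filter(field_, sigma=max(scenario.grid_rows, 8) / 25.0)
    # rank-transform so quantile thresholds give exact prevalences
    order = np.argsort(field_, axis=None, kind="stable")
    ranks = np.empty(field_.size, dtype=np.int64)
    ranks[order] = np.arange(field_.size)
    cum = np.cumsum(weights)
    thresholds = np.floor(cum * field_.size).astype(np.int64)
    data = np.full(field_.size, scenario.nodata, dtype=np.uint8)
    lo = 0
    for code, hi in zip(scenario.class_codes, thresholds):
        data[(ranks >= lo) & (ranks < hi)] = code
        lo = hi
    # rounding can leave a handful of top-rank pixels unassigned
    data[ranks >= lo] = scenario.class_codes[int(np.argmax(weights))]
    return LulcMap(
        data.reshape(field_.shape),
        scenario.class_codes,
        nodata=scenario.nodata,
        pixel_size=scenario.pixel_size,
    )


def generate_drivers(
    scenario: SyntheticScenario, lulc: LulcMap, seed: int | None = None
) -> list[DriverField]:
    """Realise every driver in ``scenario.driver_spec`` on the current map."""
    seed = scenario.seed if seed is None else seed
    fields = []
    for i, spec in enumerate(scenario.driver_spec):
        if spec.model == "smooth":
            rng = substream(seed, "drivers", i)
            raw = ndimage.gaussian_filter(
                rng.standard_normal(lulc.shape), sigma=spec.smoothness
            )
            lo, hi = spec.value_range
            rmin, rmax = raw.min(), raw.max()
            raster = lo + (raw - rmin) / max(rmax - rmin, 1e-12) * (hi - lo)
        else:
            target = lulc.data == spec.distance_to
            if target.any():
                raster = ndimage.distance_transform_edt(~target) * lulc.pixel_size
            else:
                raster = np.full(lulc.shape, float(max(lulc.shape)) * lulc.pixel_size)
        fields.append(DriverField(spec.name, raster.astype(float), spec.units))
    return fields


def _standardize(raster: np.ndarray) -> np.ndarray:
    v = raster[np.isfinite(raster)]
    sd = v.std()
    if sd == 0:
        return np.zeros_like(raster)
    return (raster - v.mean()) / sd


def evolve_lulc(
    lulc: LulcMap,
    M: np.ndarray,
    drivers: list[DriverField] | None = None,
    effect_weights: dict[str, dict[int, float]] | None = None,
    seed: int = 0,
) -> LulcMap:
    """Advance a map one step under transition matrix ``M``.

    Each pixel's new class is drawn from its origin row of ``M``.  When
    drivers carry nonzero ``effect_weights`` the row log-odds are tilted
    additively by ``weight * standardized_driver_value`` for each target class
    before renormalisation; all-zero weights recover the pure Markov draw
    exactly.  Nodata pixels are never reassigned.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (len(lulc.class_codes),) * 2:
        raise ValidationError("matrix classes must match map classes")
    check_row_stochastic(M)
    rng = substream(seed, "evolve_lulc")
    k = len(lulc.class_codes)
    code_to_idx = {c: i for i, c in enumerate(lulc.class_codes)}
    out = np.full(lulc.shape, lulc.nodata, dtype=np.uint8)
    codes = np.asarray(lulc.class_codes, dtype=np.uint8)

    tilt = np.zeros((k, *lulc.shape))
    if drivers and effect_weights:
        for drv in drivers:
            per_target = effect_weights.get(drv.name)
            if not per_target:
                continue
            z = _standardize(drv.raster)
            for target_code, w in per_target.items():
                if w != 0.0:
                    tilt[code_to_idx[target_code]] += w * z
    tilted = bool(np.any(tilt))

    u = rng.random(lulc.shape)
    for i, code in enumerate(lulc.class_codes):
        sel = lulc.data == code
        if not sel.any():
            continue
        row = M[i]
        if tilted:
            with np.errstate(divide="ignore"):
                logits = np.log(row)[:, None] + tilt[:, sel]
            logits -= logits.max(axis=0, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=0, keepdims=True)
            cdf = np.cumsum(probs, axis=0)
            idx = (u[sel][None, :] > cdf).sum(axis=0)
        else:
            cdf = np.cumsum(row)
            idx = np.searchsorted(cdf, u[sel], side="right")
        idx = np.clip(idx, 0, k - 1)
        out[sel] = codes[idx]
    return LulcMap(out, lulc.class_codes, nodata=lulc.nodata, pixel_size=lulc.pixel_size)


def generate_lulc_series(scenario: SyntheticScenario) -> dict[int, LulcMap]:
    """Generate the full epoch series by chaining the true matrices.

    Driver tilts are applied per interval when driver specs carry effect
    weights; the tilt is what makes transition locations learnable downstream.
    """
    if not scenario.true_transition_matrices:
        raise ConfigurationError("scenario has no transition matrices")
    maps = {scenario.epoch_years[0]: generate_initial_lulc(scenario)}
    weights = {
        spec.name: spec.effect_weights for spec in scenario.driver_spec if spec.effect_weights
    }
    for step, (year, M) in enumerate(
        zip(scenario.epoch_years[1:], scenario.true_transition_matrices)
    ):
        prev = maps[scenario.epoch_years[step]]
        drivers = generate_drivers(scenario, prev) if weights else None
        maps[year] = evolve_lulc(
            prev, M, drivers, weights or None, seed=scenario.seed * 1000 + step
        )
    return maps


def generate_image_stack(
    scenario: SyntheticScenario,
    lulc: LulcMap,
    n_scenes: int,
    seed: int | None = None,
    band_names: tuple[str, ...] = ("blue", "green", "red", "nir", "swir1", "swir2"),
) -> ImageCollection:
    """Simulate a growing-season stack of multiband reflectance scenes.

    Per scene and band, pixel reflectance is the class mean plus independent
    Gaussian noise with the class standard deviation.  Nodata pixels are NaN.
    """
    if n_scenes < 1:
        raise ConfigurationError("n_scenes must be >= 1")
    missing = [c for c in scenario.class_codes if c not in scenario.spectral_signatures]
    if missing:
        raise ConfigurationError(f"classes without spectral signatures: {missing}")
    seed = scenario.seed if seed is None else seed
    n_bands = len(band_names)
    mean_img = np.full((n_bands, *lulc.shape), np.nan)
    sd_img = np.zeros((n_bands, *lulc.shape))
    for code in scenario.class_codes:
        mean, sd = scenario.spectral_signatures[code]
        mean = np.asarray(mean, dtype=float)
        sd = np.asarray(sd, dtype=float)
        if mean.size != n_bands or sd.size != n_bands:
            raise ConfigurationError(f"signature for class {code} must have {n_bands} bands")
        sel = lulc.data == code
        mean_img[:, sel] = mean[:, None]
        sd_img[:, sel] = sd[:, None]
    scenes = []
    for s in range(n_scenes):
        rng = substream(seed, "image_stack", s)
        noise = rng.standard_normal(mean_img.shape) * sd_img
        scenes.append((mean_img + noise).astype(np.float64))
    dates = tuple(f"scene_{i:02d}" for i in range(n_scenes))
    return ImageCollection(scenes, tuple(band_names), dates)


def generate_reference_samples(
    lulc: LulcMap,
    n_samples: int | None = None,
    seed: int = 0,
    per_class: int | None = None,
) -> pd.DataFrame:
    """Draw labelled reference pixels from the map.

    Either ``n_samples`` total (allocated over classes proportionally to their
    pixel frequency, largest-remainder rounding) or ``per_class`` samples from
    every class.  Returns a frame with columns ``row, col, class_code``.
    """
    if (n_samples is None) == (per_class is None):
        raise SamplingError("specify exactly one of n_samples / per_class")
    rng = substream(seed, "reference_samples")
    counts = lulc.class_counts()
    total_valid = sum(counts.values())
    if per_class is not None:
        alloc = {}
        for c in lulc.class_codes:
            if counts[c] == 0:
                raise SamplingError(f"class {c} absent from map; cannot stratify")
            alloc[c] = per_class
    else:
        if n_samples < 0:
            raise SamplingError("n_samples must be >= 0")
        if n_samples > total_valid:
            raise SamplingError("more samples requested than valid pixels")
        exact = {c: n_samples * counts[c] / total_valid for c in lulc.class_codes if counts[c]}
        alloc = {c: int(np.floor(v)) for c, v in exact.items()}
        remainder = n_samples - sum(alloc.values())
        for c in sorted(exact, key=lambda c: exact[c] - alloc[c], reverse=True)[:remainder]:
            alloc[c] += 1
    rows_out, cols_out, labels = [], [], []
    for c in lulc.class_codes:
        take = alloc.get(c, 0)
        if take == 0:
            continue
        rr, cc = np.nonzero(lulc.data == c)
        if take > rr.size:
            raise SamplingError(f"class {c} has only {rr.size} pixels, {take} requested")
        pick = rng.choice(rr.size, size=take, replace=False)
        rows_out.append(rr[pick])
        cols_out.append(cc[pick])
        labels.append(np.full(take, c, dtype=int))
    if not rows_out:
        return pd.DataFrame(columns=["row", "col", "class_code"]).astype(int)
    return pd.DataFrame(
        {
            "row": np.concatenate(rows_out),
            "col": np.concatenate(cols_out),
            "class_code": np.concatenate(labels),
        }
    )


def default_spectral_signatures(
    class_codes: tuple[int, ...] = DEFAULT_CLASS_CODES,
    n_bands: int = 6,
    separation: float = 6.0,
    noise_sd: float = 0.01,
    seed: int = 7,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Well-separated per-class band signatures on a [0, 1] reflectance scale.

    ``separation`` is the guaranteed between-class mean gap in units of
    ``noise_sd`` on at least one band (class means are spread on a lattice, so
    the realised gaps are much larger on most bands).
    """
    rng = np.random.default_rng(seed)
    sigs = {}
    for i, code in enumerate(class_codes):
        base = 0.08 + 0.12 * i
        mean = np.clip(base + rng.normal(0, noise_sd * separation / 2, n_bands), 0.01, 0.95)
        mean[i % n_bands] = np.clip(base + separation * noise_sd * (i + 1), 0.01, 0.98)
        sigs[code] = (mean, np.full(n_bands, noise_sd))
    return sigs


def default_scenario(
    grid_rows: int = 120,
    grid_cols: int = 120,
    seed: int = 0,
    epoch_years: tuple[int, ...] = (1985, 2000, 2010, 2020),
    persistence: float = 0.94,
) -> SyntheticScenario:
    """A ready-to-run 6-class scenario with sparse, persistence-heavy dynamics.

    Off-diagonal mass mimics the study system: forest <-> rangeland exchange,
    cropland expansion onto rangeland, slow artificial growth, inert water.
    """
    codes = DEFAULT_CLASS_CODES
    k = len(codes)
    M = np.eye(k) * persistence + np.zeros((k, k))
    leak = 1.0 - persistence
    # forest(0) rangeland(1) cropland(2) barren(3) artificial(4) water(5)
    M[0, 0] = persistence
    M[0, 1] = leak * 0.7
    M[0, 2] = leak * 0.3
    M[1, 1] = persistence
    M[1, 0] = leak * 0.5
    M[1, 2] = leak * 0.5
    M[2, 2] = persistence
    M[2, 1] = leak * 0.6
    M[2, 4] = leak * 0.4
    M[3, 3] = persistence
    M[3, 1] = leak
    M[4, 4] = 1.0
    M[5, 5] = 1.0
    check_row_stochastic(M)
    mats = tuple(M.copy() for _ in epoch_years[1:])
    drivers = (
        DriverSpec(
            "elevation",
            model="smooth",
            smoothness=grid_rows / 8.0,
            value_range=(400.0, 3800.0),
            units="m",
            effect_weights={2: 1.5, 1: 0.75},
        ),
        DriverSpec("dist_artificial", model="distance", distance_to=5, units="m",
                   effect_weights={5: -0.5}),
        DriverSpec("dist_water", model="distance", distance_to=6, units="m"),
    )
    return SyntheticScenario(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        class_codes=codes,
        epoch_years=epoch_years,
        true_transition_matrices=mats,
        class_prevalence=(0.45, 0.22, 0.14, 0.09, 0.06, 0.04),
        driver_spec=drivers,
        spectral_signatures=default_spectral_signatures(codes),
        seed=seed,
    )
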