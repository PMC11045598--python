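"""Markov transition estimation, transition-potential modelling, projection.

The projection pipeline is: estimate a row-stochastic transition matrix from a
calibration map pair, raise it to the number of calibration intervals spanned
by the target date, turn the resulting probabilities into an integer
transition-area demand, rank candidate pixels of each origin class by a
driver-trained change potential, and convert exactly the demanded counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .change import CrossTab, crosstab
from .core import LulcMap, check_row_stochastic, require_same_grid, substream
from .errors import AllocationError, ValidationError
from .synthetic import DriverField


@dataclass
class TransitionMatrix:
    """Row-stochastic class transition probabilities with their counts."""

    P: np.ndarray
    counts: np.ndarray
    class_codes: tuple[int, ...]
    interval_years: float
    identity_rows: tuple[int, ...] = ()  # class codes whose origin count was 0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        check_row_stochastic(self.P)

    @property
    def origin_totals(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.class_codes)
        return pd.DataFrame(self.P, index=labels, columns=labels)


def estimate_transition_matrix(
    map_t1: LulcMap, map_t2: LulcMap, interval_years: float
) -> TransitionMatrix:
    """Estimate P_ij = n_ij / n_i from a co-registered map pair.

    Rows whose origin class has zero pixels become identity rows and are
    flagged (and warned about) rather than left undefined.
    """
    tab = crosstab(map_t1, map_t2)
    if tab.total == 0:
        raise ValidationError("no jointly valid pixels")
    return transition_matrix_from_crosstab(tab, interval_years)


def transition_matrix_from_crosstab(tab: CrossTab, interval_years: float) -> TransitionMatrix:
    counts = np.asarray(tab.counts, dtype=float)
    n_i = counts.sum(axis=1)
    P = np.zeros_like(counts)
    identity_rows = []
    for i in range(counts.shape[0]):
        if n_i[i] > 0:
            P[i] = counts[i] / n_i[i]
        else:
            P[i, i] = 1.0
            identity_rows.append(tab.class_codes[i])
    if identity_rows:
        warnings.warn(
            f"classes with no origin pixels set to identity rows: {identity_rows}",
            stacklevel=2,
        )
    return TransitionMatrix(
        P, counts.astype(int), tab.class_codes, interval_years, tuple(identity_rows)
    )


def markov_project(v_t1: np.ndarray, M: np.ndarray, n_steps: int = 1) -> np.ndarray:
    """Propagate a class-count vector n steps: v_t2 = v_t1 @ M**n."""
    v = np.asarray(v_t1, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(v < 0):
        raise ValidationError("class vector must be nonnegative")
    check_row_stochastic(M)
    if v.shape[0] != M.shape[0]:
        raise ValidationError("dimension mismatch between vector and matrix")
    if n_steps < 0:
        raise ValidationError("n_steps must be >= 0")
    return v @ np.linalg.matrix_power(M, n_steps)


def transition_area_matrix(
    current_counts: np.ndarray, M_scaled: np.ndarray
) -> np.ndarray:
    """Integer pixel demand per (origin, target) transition.

    Expected counts ``n_i * P_ij`` are rounded per row with the largest-
    remainder rule so every row sums exactly to the origin class count.
    """
    n = np.asarray(current_counts, dtype=float)
    check_row_stochastic(M_scaled)
    expected = n[:, None] * np.asarray(M_scaled, dtype=float)
    demand = np.floor(expected).astype(np.int64)
    for i in range(expected.shape[0]):
        short = int(round(n[i])) - int(demand[i].sum())
        if short > 0:
            frac = expected[i] - demand[i]
            for j in np.argsort(-frac, kind="stable")[:short]:
                demand[i, j] += 1
    return demand


@dataclass
class TransitionPotentialModel:
    """Per-transition MLP change-potential model over standardized drivers."""

    transition: tuple[int, int]  # (origin code, target code)
    estimator: MLPRegressor
    driver_names: tuple[str, ...]
    driver_means: np.ndarray
    driver_sds: np.ndarray
    training_rmse: float
    testing_rmse: float
    rmse_trace: tuple[float, ...]
    stopping: dict = field(default_factory=dict)

    def predict_potential(self, drivers: list[DriverField]) -> np.ndarray:
        """Change-potential surface in [0, 1] on the driver grid."""
        X = _driver_matrix(drivers, self.driver_names)
        X = (X - self.driver_means) / self.driver_sds
        p = self.estimator.predict(X)
        shape = drivers[0].raster.shape
        return np.clip(p, 0.0, 1.0).reshape(shape)


def _driver_matrix(drivers: list[DriverField], names: tuple[str, ...]) -> np.ndarray:
    by_name = {d.name: d for d in drivers}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ValidationError(f"missing drivers: {missing}")
    cols = [by_name[n].raster.ravel() for n in names]
    return np.column_stack(cols)


def train_transition_potential(
    drivers: list[DriverField],
    change_labels: np.ndarray,
    valid_mask: np.ndarray | None = None,
    rms_target: float = 0.01,
    max_iterations: int = 1000,
    seed: int = 0,
    transition: tuple[int, int] = (0, 0),
    hidden_width: int | None = None,
    test_fraction: float = 0.3,
    max_train_per_side: int = 4000,
) -> TransitionPotentialModel:
    """Fit an MLP regression of changed(1)/persistent(0) labels on drivers.

    Training draws equal numbers of changed and persistent pixels (balanced
    classes), standardizes drivers, and iterates until the training RMSE
    reaches ``rms_target`` or ``max_iterations`` epochs; both training and
    held-out testing RMSE are reported.  One hidden layer of width
    ``max(4, n_drivers)`` with logistic activations.
    """
    labels = np.asarray(change_labels, dtype=float).ravel()
    X_all = _driver_matrix(drivers, tuple(d.name for d in drivers))
    if valid_mask is not None:
        keep = np.asarray(valid_mask, dtype=bool).ravel()
        labels = labels[keep]
        X_all = X_all[keep]
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("labels contain a single class; nothing to learn")

    rng = substream(seed, "transition_potential")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_side = min(pos.size, neg.size, max_train_per_side)
    pos = rng.choice(pos, size=n_side, replace=False)
    neg = rng.choice(neg, size=n_side, replace=False)
    idx = np.concatenate([pos, neg])
    rng.shuffle(idx)
    n_test = max(1, int(np.floor(idx.size * test_fraction)))
    test_idx, train_idx = idx[:n_test], idx[n_test:]

    means = X_all.mean(axis=0)
    sds = X_all.std(axis=0)
    sds[sds == 0] = 1.0
    X = (X_all - means) / sds
    X_train, y_train = X[train_idx], labels[train_idx]
    X_test, y_test = X[test_idx], labels[test_idx]

    width = hidden_width or max(4, len(drivers))
    mlp = MLPRegressor(
        hidden_layer_sizes=(width,),
        activation="logistic",
        solver="lbfgs",
        max_iter=1,
        warm_start=True,
        random_state=int(seed) % (2**32),
    )
    trace = []
    chunk = 50
    done = 0
    train_rmse = np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are expected per chunk
        while done < max_iterations:
            mlp.max_iter = min(chunk, max_iterations - done)
            mlp.fit(X_train, y_train)
            done += mlp.max_iter
            train_rmse = float(np.sqrt(np.mean((mlp.predict(X_train) - y_train) ** 2)))
            trace.append(train_rmse)
            if train_rmse <= rms_target:
                break
    test_rmse = float(np.sqrt(np.mean((mlp.predict(X_test) - y_test) ** 2)))
    return TransitionPotentialModel(
        transition=transition,
        estimator=mlp,
        driver_names=tuple(d.name for d in drivers),
        driver_means=means,
        driver_sds=sds,
        training_rmse=train_rmse,
        testing_rmse=test_rmse,
        rmse_trace=tuple(trace),
        stopping={"rms_target": rms_target, "max_iterations": max_iterations,
                  "iterations_run": done},
    )


@dataclass
class ProbabilityImageSet:
    """Per-class conditional probability rasters for the projection date."""

    probabilities: np.ndarray  # (n_classes, rows, cols); NaN on nodata
    class_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        sums = np.nansum(self.probabilities, axis=0)
        valid = np.isfinite(self.probabilities).all(axis=0)
        if valid.any() and not np.allclose(sums[valid], 1.0, atol=1e-6):
            raise ValidationError("per-pixel class probabilities must sum to 1")


def probability_images(current: LulcMap, M_scaled: np.ndarray) -> ProbabilityImageSet:
    """Status-probability rasters: pixel of class i gets row i of the matrix."""
    check_row_stochastic(M_scaled)
    k = len(current.class_codes)
    probs = np.full((k, *current.shape), np.nan)
    for i, code in enumerate(current.class_codes):
        sel = current.data == code
        probs[:, sel] = np.asarray(M_scaled, dtype=float)[i][:, None]
    return ProbabilityImageSet(probs, current.class_codes)


def allocate_change(
    current: LulcMap,
    potentials: dict[tuple[int, int], np.ndarray] | None,
    demand: np.ndarray,
    seed: int = 0,
) -> LulcMap:
    """Convert exactly the demanded pixel counts per transition.

    For each ordered off-diagonal transition (processed by descending demand),
    the ``demand[i, j]`` not-yet-converted pixels of class i with the highest
    i->j potential are switched to class j.  Missing potential surfaces fall
    back to a seeded uniform surface; exact ties are broken by flat
    (row-major) pixel index, so the result is fully deterministic.
    """
    codes = current.class_codes
    k = len(codes)
    demand = np.asarray(demand)
    if demand.shape != (k, k):
        raise ValidationError("demand must be square over the class set")
    if np.any(demand < 0):
        raise ValidationError("demand must be nonnegative")
    counts = current.class_vector()
    row_sums = demand.sum(axis=1)
    for i, code in enumerate(codes):
        if row_sums[i] > counts[i]:
            raise AllocationError(
                f"demand from class {code} ({int(row_sums[i])}) exceeds its "
                f"{int(counts[i])} available pixels"
            )
    rng = substream(seed, "allocation")
    out = current.data.copy()
    converted = np.zeros(current.shape, dtype=bool)

    transitions = [
        (int(demand[i, j]), i, j)
        for i in range(k)
        for j in range(k)
        if i != j and demand[i, j] > 0
    ]
    transitions.sort(key=lambda t: (-t[0], t[1], t[2]))
    for want, i, j in transitions:
        surface = None if potentials is None else potentials.get((codes[i], codes[j]))
        if surface is None:
            surface = rng.random(current.shape)
        eligible = (current.data == codes[i]) & ~converted
        flat_idx = np.flatnonzero(eligible.ravel())
        if flat_idx.size < want:
            raise AllocationError(
                f"transition {codes[i]}->{codes[j]}: {want} pixels demanded, "
                f"only {flat_idx.size} remain"
            )
        scores = surface.ravel()[flat_idx]
        # descending score, ties by ascending flat index (stable sort)
        order = np.argsort(-scores, kind="stable")
        chosen = flat_idx[order[:want]]
        rr, cc = np.unravel_index(chosen, current.shape)
        out[rr, cc] = codes[j]
        converted[rr, cc] = True
    return LulcMap(out, codes, nodata=current.nodata, pixel_size=current.pixel_size)


def _scaled_matrix(tm: TransitionMatrix, target_interval: float) -> np.ndarray:
    """Scale a calibration-interval matrix to the projection interval.

    Whole multiples use the matrix power; fractional remainders linearly
    interpolate the transition probabilities between consecutive powers
    (stochastic roots need not exist, so no root is attempted).
    """
    ratio = target_interval / tm.interval_years
    if ratio < 0:
        raise ValidationError("projection target precedes the calibration end")
    lo = int(np.floor(ratio))
    frac = ratio - lo
    M_lo = np.linalg.matrix_power(tm.P, lo)
    if frac == 0:
        return M_lo
    M_hi = np.linalg.matrix_power(tm.P, lo + 1)
    M = (1 - frac) * M_lo + frac * M_hi
    return M / M.sum(axis=1, keepdims=True)


def project_lulc(
    maps_by_year: dict[int, LulcMap],
    drivers: list[DriverField] | None,
    target_year: int,
    calibration_years: tuple[int, int] | None = None,
    rms_target: float = 0.01,
    max_iterations: int = 1000,
    seed: int = 0,
    min_demand_for_model: int = 20,
) -> tuple[LulcMap, ProbabilityImageSet]:
    """Project the categorical map to ``target_year``.

    Composition: estimate the transition matrix from the calibration pair
    (default: the two most recent observed epochs), scale it to the target
    interval, derive the integer transition-area demand, train per-transition
    change potentials on the calibration interval's observed changes (when
    drivers are supplied and the transition has enough examples), and allocate.
    Also emits per-class status probability images.
    """
    years = sorted(maps_by_year)
    if len(years) < 2:
        raise ValidationError("need at least 2 observed epochs")
    if target_year <= years[-1]:
        raise ValidationError("target year must be after the last observation")
    y1, y2 = calibration_years or (years[-2], years[-1])
    base = maps_by_year[y2]
    tm = estimate_transition_matrix(maps_by_year[y1], maps_by_year[y2], y2 - y1)
    M_scaled = _scaled_matrix(tm, target_year - y2)
    demand = transition_area_matrix(base.class_vector(), M_scaled)

    potentials: dict[tuple[int, int], np.ndarray] = {}
    if drivers:
        codes = base.class_codes
        m1, m2 = maps_by_year[y1], maps_by_year[y2]
        require_same_grid(m1, m2)
        for i, ci in enumerate(codes):
            for j, cj in enumerate(codes):
                if i == j or demand[i, j] < min_demand_for_model:
                    continue
                origin = (m1.data == ci) & m2.valid_mask
                changed = origin & (m2.data == cj)
                if changed.sum() < 10 or (origin & ~changed).sum() < 10:
                    continue
                model = train_transition_potential(
                    drivers,
                    changed.astype(float),
                    valid_mask=origin,
                    rms_target=rms_target,
                    max_iterations=max_iterations,
                    seed=seed + 31 * i + j,
                    transition=(ci, cj),
                )
                potentials[(ci, cj)] = model.predict_potential(drivers)

    projected = allocate_change(base, potentials or None, demand, seed=seed)
    probs = probability_images(base, M_scaled)
    return projected, probs
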