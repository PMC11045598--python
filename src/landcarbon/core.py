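"""Core raster container and seeding utilities.

Conventions used throughout the package:

* categorical rasters are 2-D ``uint8`` arrays, row-major, top-left origin,
  0-based pixel indices, with an explicit integer nodata value (default 255);
* continuous rasters are 2-D ``float32``/``float64`` arrays with ``NaN``
  nodata;
* a single integer run seed fans out to per-operation substreams through
  :func:`substream` using a fixed operation-code table, so adding scenes to
  one stage never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ValidationError

DEFAULT_NODATA = 255
DEFAULT_PIXEL_SIZE = 30.0

#: Documented operation codes for the seed fan-out scheme.  A run seed ``s``
#: and operation ``op`` give the stream ``SeedSequence([s, OP_CODES[op]])``.
OP_CODES = {
    "initial_lulc": 0,
    "evolve_lulc": 1,
    "image_stack": 2,
    "reference_samples": 3,
    "split_samples": 4,
    "classifier": 5,
    "transition_potential": 6,
    "allocation": 7,
    "drivers": 8,
}


def substream(seed: int, operation: str, index: int = 0) -> np.random.Generator:
    """Return the RNG substream for ``operation`` under run seed ``seed``.

    ``index`` distinguishes repeated uses within one operation (e.g. scene
    number); the mapping is the documented counter scheme, so identical
    (seed, operation, index) triples always yield identical draws.
    """
    if operation not in OP_CODES:
        raise KeyError(f"unknown operation {operation!r}; known: {sorted(OP_CODES)}")
    ss = np.random.SeedSequence([int(seed), OP_CODES[operation], int(index)])
    return np.random.default_rng(ss)


@dataclass
class LulcMap:
    """Categorical land-cover raster.

    Parameters
    ----------
    data
        2-D integer array of class codes; ``nodata`` marks invalid pixels.
    class_codes
        Ordered class codes the map may contain.
    nodata
        Integer nodata code (never a member of ``class_codes``).
    pixel_size
        Ground pixel edge length in metres.
    """

    data: np.ndarray
    class_codes: tuple[int, ...]
    nodata: int = DEFAULT_NODATA
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.class_codes = tuple(int(c) for c in self.class_codes)
        if self.data.ndim != 2:
            raise ValidationError("LulcMap.data must be 2-D")
        if self.nodata in self.class_codes:
            raise ValidationError("nodata code collides with a class code")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        valid = self.data[self.data != self.nodata]
        unknown = np.setdiff1d(np.unique(valid), np.asarray(self.class_codes))
        if unknown.size:
            raise ValidationError(f"map contains codes outside class set: {unknown.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    @property
    def pixel_area_m2(self) -> float:
        return float(self.pixel_size) ** 2

    def class_counts(self) -> dict[int, int]:
        """Pixel count per class code (zero for absent classes)."""
        valid = self.data[self.valid_mask]
        return {c: int(np.count_nonzero(valid == c)) for c in self.class_codes}

    def class_vector(self) -> np.ndarray:
        """Counts as a vector ordered like ``class_codes``."""
        counts = self.class_counts()
        return np.array([counts[c] for c in self.class_codes], dtype=float)

    def copy(self) -> "LulcMap":
        return LulcMap(self.data.copy(), self.class_codes, self.nodata, self.pixel_size)


def require_same_grid(a: LulcMap, b: LulcMap) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"grid mismatch: {a.shape} vs {b.shape}")
    if a.class_codes != b.class_codes:
        raise GridMismatchError(f"class sets differ: {a.class_codes} vs {b.class_codes}")


def check_row_stochastic(P: np.ndarray, atol: float = 1e-9) -> None:
    """Raise :class:`ValidationError` unless ``P`` is a row-stochastic square matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("transition matrix must be square")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=atol):
        raise ValidationError(f"rows must sum to 1; got {rows}")
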