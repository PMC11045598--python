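"""Cross-tabulation of map pairs and per-epoch area / change reporting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LulcMap, require_same_grid
from .errors import ValidationError

M2_PER_HA = 10_000.0


@dataclass
class CrossTab:
    """Pixel-count contingency table: rows = earlier map, cols = later map.

    Pixels that are nodata in either epoch are excluded entirely.
    """

    counts: np.ndarray
    class_codes: tuple[int, ...]
    pixel_area: float  # m^2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_codes)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be square over the class set")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.class_codes)
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def crosstab(map_t1: LulcMap, map_t2: LulcMap) -> CrossTab:
    """Count class-to-class pixel transitions between two co-registered maps."""
    require_same_grid(map_t1, map_t2)
    both = map_t1.valid_mask & map_t2.valid_mask
    codes = map_t1.class_codes
    idx = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    a = np.vectorize(idx.get)(map_t1.data[both]) if both.any() else np.array([], dtype=int)
    b = np.vectorize(idx.get)(map_t2.data[both]) if both.any() else np.array([], dtype=int)
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    return CrossTab(counts, codes, map_t1.pixel_area_m2)


def area_stats(lulc: LulcMap, pixel_area: float | None = None) -> pd.Series:
    """Per-class area in hectares: count * pixel_area / 10,000."""
    pixel_area = lulc.pixel_area_m2 if pixel_area is None else pixel_area
    if pixel_area <= 0:
        raise ValidationError("pixel_area must be positive")
    counts = lulc.class_counts()
    return pd.Series(
        {c: counts[c] * pixel_area / M2_PER_HA for c in lulc.class_codes}, name="area_ha"
    )


@dataclass
class ChangeReport:
    """Per-epoch class areas plus per-interval absolute and percent change."""

    areas: pd.DataFrame  # index = class code, columns = years
    changes: pd.DataFrame  # columns: interval, class_code, change_ha, percent, direction


def change_report(maps_by_year: dict[int, LulcMap], pixel_area: float | None = None) -> ChangeReport:
    """Summarise area trajectories across >= 2 epochs.

    Percent change is 100*(A2-A1)/A1; a zero baseline with later area flags
    the percent as NaN (undefined) rather than inventing a rate.
    """
    years = sorted(maps_by_year)
    if len(years) < 2:
        raise ValidationError("need at least 2 epochs")
    areas = pd.DataFrame({y: area_stats(maps_by_year[y], pixel_area) for y in years})
    rows = []
    for y1, y2 in zip(years[:-1], years[1:]):
        for code in areas.index:
            a1, a2 = areas.loc[code, y1], areas.loc[code, y2]
            delta = a2 - a1
            pct = 100.0 * delta / a1 if a1 > 0 else (np.nan if a2 > 0 else 0.0)
            rows.append(
                {
                    "interval": f"{y1}-{y2}",
                    "class_code": code,
                    "change_ha": delta,
                    "percent": pct,
                    "direction": "gain" if delta > 0 else ("loss" if delta < 0 else "stable"),
                }
            )
    return ChangeReport(areas, pd.DataFrame(rows))
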