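"""Epoch-difference change detection, patch extraction and zonal summaries.

The change signal is the pixelwise difference of two multi-year mean
composites (by default 2005–2010 minus 1995–2000, in calibrated DN). Pixels
saturated in every year of both epochs carry no trend information and are
masked out. Remaining pixels are classified with strict ±threshold
inequalities (default 3 DN): increase iff diff > +3, decrease iff diff < −3.
Contiguous same-class pixels form discrete change patches (8-connectivity by
default), and per-region proportions of increasing / decreasing land plus
annual mean brightness series summarize trends over areas of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

from .composites import DN_MAX, AnnualComposite, RegionMask
from .errors import ValidationError
from .intercalibration import select_most_recent

# class raster codes (documented in the byte-raster output)
CLASS_NONE = 0
CLASS_INCREASE = 1
CLASS_DECREASE = 2
CLASS_MASKED = 254
CLASS_NODATA = 255

#: saturation test tolerance on the calibrated scale
SATURATION_EPS = 1e-6


@dataclass
class ChangeParams:
    """Epoch definitions and classification parameters."""

    epoch1: Tuple[int, ...] = tuple(range(1995, 2001))
    epoch2: Tuple[int, ...] = tuple(range(2005, 2011))
    threshold: float = 3.0
    connectivity: int = 8

    def __post_init__(self):
        self.epoch1 = tuple(sorted(self.epoch1))
        self.epoch2 = tuple(sorted(self.epoch2))
        if not self.epoch1 or not self.epoch2:
            raise ValidationError("epochs must be non-empty")
        if set(self.epoch1) & set(self.epoch2):
            raise ValidationError("epochs must be disjoint")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")


@dataclass
class ChangeMap:
    """Epoch difference plus saturation mask and three-way classification."""

    diff: np.ndarray
    saturation_mask: np.ndarray
    classes: np.ndarray
    threshold: float
    pixel_area_km2: float = 1.0

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.classes == CLASS_NODATA

    @property
    def land_mask(self) -> np.ndarray:
        return self.classes != CLASS_NODATA


@dataclass
class Patch:
    """One connected component of same-sign change."""

    patch_id: int
    change_class: str  # "increase" | "decrease"
    pixels: np.ndarray  # (n, 2) array of (row, col)
    area_px: int
    area_km2: float
    mean_diff: float


@dataclass
class RegionSummary:
    """Per-region change proportions and the annual brightness series.

    Proportions are reported with two denominators: all land pixels in the
    region, and unsaturated land pixels only.
    """

    region_id: str
    n_land: int
    n_unsaturated: int
    prop_increase: float
    prop_decrease: float
    prop_increase_unsat: float
    prop_decrease_unsat: float
    annual_means: Dict[int, float]


def _select_years(
    series: Sequence[AnnualComposite], years: Sequence[int]
) -> List[AnnualComposite]:
    by_year = {}
    for comp in series:
        if comp.year in by_year:
            raise ValidationError(
                f"two composites for year {comp.year}; resolve overlap years "
                "(most-recent-satellite rule) before change analysis"
            )
        by_year[comp.year] = comp
    missing = [y for y in years if y not in by_year]
    if missing:
        raise ValidationError(f"years missing from series: {missing}")
    return [by_year[y] for y in years]


def epoch_mean(series: Sequence[AnnualComposite], years: Sequence[int]) -> np.ndarray:
    """Pixelwise mean over the epoch's years; NaN where any year is nodata."""
    if not years:
        raise ValidationError("empty epoch year set")
    comps = _select_years(series, years)
    stack = np.stack([c.grid.astype(np.float64) for c in comps])
    mean = stack.mean(axis=0)
    missing = np.any([c.nodata_mask for c in comps], axis=0)
    mean[missing] = np.nan
    return mean


def saturation_mask(series: Sequence[AnnualComposite], params: ChangeParams) -> np.ndarray:
    """True where the pixel is saturated in every year of both epochs."""
    comps = _select_years(series, params.epoch1 + params.epoch2)
    mask = np.ones(comps[0].shape, dtype=bool)
    for c in comps:
        mask &= (c.grid >= DN_MAX - SATURATION_EPS) & c.valid_mask
    return mask


def classify_change(
    diff: np.ndarray,
    saturation: np.ndarray,
    threshold: float = 3.0,
    nodata: Optional[np.ndarray] = None,
    pixel_area_km2: float = 1.0,
) -> ChangeMap:
    """Three-way classification with strict ±threshold inequalities.

    Mask precedence: nodata, then saturation, then the threshold test.
    A diff of exactly ±threshold is classified as no change.
    """
    if nodata is None:
        nodata = ~np.isfinite(diff)
    else:
        nodata = nodata | ~np.isfinite(diff)
    classes = np.full(diff.shape, CLASS_NONE, dtype=np.uint8)
    classes[diff > threshold] = CLASS_INCREASE
    classes[diff < -threshold] = CLASS_DECREASE
    classes[saturation & ~nodata] = CLASS_MASKED
    classes[nodata] = CLASS_NODATA
    return ChangeMap(
        diff=diff, saturation_mask=saturation, classes=classes,
        threshold=threshold, pixel_area_km2=pixel_area_km2,
    )


def extract_patches(change: ChangeMap, connectivity: int = 8) -> List[Patch]:
    """Connected components within each change class, deterministically ordered.

    Components are computed separately for the increase and the decrease
    class. Patches are numbered by their top-left member pixel in row-major
    order across both classes.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    raw: List[Tuple[int, str, np.ndarray]] = []
    for code, name in ((CLASS_INCREASE, "increase"), (CLASS_DECREASE, "decrease")):
        labels = measure.label(change.classes == code, connectivity=skimage_conn)
        for lab in range(1, labels.max() + 1):
            pix = np.argwhere(labels == lab)
            order = np.lexsort((pix[:, 1], pix[:, 0]))
            pix = pix[order]
            anchor = int(pix[0, 0]) * change.classes.shape[1] + int(pix[0, 1])
            raw.append((anchor, name, pix))
    raw.sort(key=lambda t: t[0])
    patches = []
    for i, (anchor, name, pix) in enumerate(raw, start=1):
        vals = change.diff[pix[:, 0], pix[:, 1]]
        patches.append(
            Patch(
                patch_id=i,
                change_class=name,
                pixels=pix,
                area_px=len(pix),
                area_km2=len(pix) * change.pixel_area_km2,
                mean_diff=float(np.mean(vals)),
            )
        )
    return patches


def summarize_region(
    change: ChangeMap,
    series: Sequence[AnnualComposite],
    region: RegionMask,
) -> RegionSummary:
    """Change proportions and annual mean brightness within one region.

    Land pixels are region pixels that are not nodata in the change map;
    proportions use both the all-land and the unsaturated-land denominator.
    Annual means are taken over valid region pixels of each year's composite.
    """
    land = region.mask & change.land_mask
    n_land = int(land.sum())
    if n_land == 0:
        raise ValidationError(f"region {region.region_id!r} has no land pixels")
    cls = change.classes
    n_inc = int(((cls == CLASS_INCREASE) & land).sum())
    n_dec = int(((cls == CLASS_DECREASE) & land).sum())
    unsat = land & (cls != CLASS_MASKED)
    n_unsat = int(unsat.sum())
    annual_means: Dict[int, float] = {}
    for comp in sorted(series, key=lambda c: c.year):
        sel = region.mask & comp.valid_mask
        if sel.any():
            annual_means[comp.year] = float(comp.grid[sel].mean())
    return RegionSummary(
        region_id=region.region_id,
        n_land=n_land,
        n_unsaturated=n_unsat,
        prop_increase=n_inc / n_land,
        prop_decrease=n_dec / n_land,
        prop_increase_unsat=n_inc / n_unsat if n_unsat else float("nan"),
        prop_decrease_unsat=n_dec / n_unsat if n_unsat else float("nan"),
        annual_means=annual_means,
    )


class ChangeDetector(BaseEstimator):
    """Epoch-difference change detection over a calibrated series.

    ``fit`` expects one composite per year (overlap years already resolved);
    it computes the epoch means, difference, saturation mask, classification
    and patch list.

    Attributes
    ----------
    mean_epoch1_, mean_epoch2_ : ndarray
    change_map_ : ChangeMap
    patches_ : list of Patch
    """

    def __init__(self, epoch1=tuple(range(1995, 2001)), epoch2=tuple(range(2005, 2011)),
                 threshold: float = 3.0, connectivity: int = 8):
        self.epoch1 = epoch1
        self.epoch2 = epoch2
        self.threshold = threshold
        self.connectivity = connectivity

    def _params(self) -> ChangeParams:
        return ChangeParams(tuple(self.epoch1), tuple(self.epoch2),
                            self.threshold, self.connectivity)

    def fit(self, series: Sequence[AnnualComposite]):
        params = self._params()
        series = list(series)
        self.mean_epoch1_ = epoch_mean(series, params.epoch1)
        self.mean_epoch2_ = epoch_mean(series, params.epoch2)
        sat = saturation_mask(series, params)
        diff = self.mean_epoch2_ - self.mean_epoch1_
        self.change_map_ = classify_change(
            diff, sat, params.threshold,
            pixel_area_km2=series[0].pixel_area_km2,
        )
        self.patches_ = extract_patches(self.change_map_, params.connectivity)
        return self

    def summarize(self, series: Sequence[AnnualComposite], region: RegionMask) -> RegionSummary:
        return summarize_region(self.change_map_, series, region)


def detect_changes(
    series: Sequence[AnnualComposite],
    params: Optional[ChangeParams] = None,
    precedence: Optional[Sequence[str]] = None,
) -> Tuple[ChangeMap, List[Patch]]:
    """One-call change detection; resolves overlap years first."""
    params = params or ChangeParams()
    selected = sorted(select_most_recent(series, precedence).values(), key=lambda c: c.year)
    det = ChangeDetector(params.epoch1, params.epoch2, params.threshold, params.connectivity)
    det.fit(selected)
    return det.change_map_, det.patches_
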