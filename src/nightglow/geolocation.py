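"""Integer-pixel geolocation correction by exhaustive correlation search.

Annual composites from different years can be mutually offset by a few pixels.
Each image is compared with the previous (already corrected) image at every
integer offset within a search radius (default ±5 pixels in both axes, 121
candidates), scoring each candidate by the Pearson correlation over the
jointly valid overlap, and the maximizing offset is applied.

Axis convention: ``dx`` moves content along columns (x / longitude), ``dy``
along rows; positive values move content toward larger indices. Vacated
margins become nodata, and the geotransform is left untouched — the data
moves within the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .composites import AnnualComposite, align_check
from .errors import (
    InsufficientOverlapError,
    UndefinedCorrelationError,
)


@dataclass
class ShiftCorrection:
    """An integer offset correction and the correlation that selected it."""

    dx: int
    dy: int
    correlation: float
    reference_year: int
    n_candidates: int
    year: int = None
    satellite_id: str = None


def translate(grid: np.ndarray, nodata_mask: np.ndarray, dx: int, dy: int):
    """Translate a grid by (dx, dy) pixels; vacated margins become nodata."""
    out = np.zeros_like(grid)
    out_mask = np.ones_like(nodata_mask, dtype=bool)
    rows, cols = grid.shape

    def _sl(n, d):
        if d >= 0:
            return slice(d, n), slice(0, n - d)
        return slice(0, n + d), slice(-d, n)

    rdst, rsrc = _sl(rows, dy)
    cdst, csrc = _sl(cols, dx)
    if rdst.stop > rdst.start and cdst.stop > cdst.start:
        out[rdst, cdst] = grid[rsrc, csrc]
        out_mask[rdst, cdst] = nodata_mask[rsrc, csrc]
    return out, out_mask


def pearson_correlation(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    """Pearson r between two grids over the jointly valid pixels.

    Raises :class:`UndefinedCorrelationError` when either grid is constant on
    the valid set (zero variance), where r is undefined.
    """
    if a.shape != b.shape or a.shape != valid.shape:
        raise ValueError("grids and mask must share one shape")
    av = a[valid].astype(np.float64)
    bv = b[valid].astype(np.float64)
    if av.size < 2:
        raise InsufficientOverlapError(f"only {av.size} valid pixels")
    av -= av.mean()
    bv -= bv.mean()
    sa = np.sqrt(av @ av)
    sb = np.sqrt(bv @ bv)
    if sa == 0.0 or sb == 0.0:
        raise UndefinedCorrelationError("constant grid on the valid set")
    return float((av @ bv) / (sa * sb))


def find_best_shift(
    image: AnnualComposite,
    reference: AnnualComposite,
    max_shift: int = 5,
    min_overlap: int = 64,
) -> ShiftCorrection:
    """Exhaustively search offsets in [-max_shift, max_shift]².

    Every candidate correlation is computed on the overlap region only
    (shifted-out margins and nodata excluded). Ties are broken by smallest
    dx²+dy², then lexicographically by (dy, dx). Candidates whose overlap
    falls below ``min_overlap`` pixels are not scored; if no candidate
    qualifies an :class:`InsufficientOverlapError` is raised.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference must share one grid")
    s = int(max_shift)
    ref_grid = reference.grid
    ref_valid = reference.valid_mask
    n_candidates = (2 * s + 1) ** 2

    best = None  # (-(r), dx²+dy², dy, dx)
    any_overlap = False
    for dy in range(-s, s + 1):
        for dx in range(-s, s + 1):
            shifted, shifted_nodata = translate(image.grid, image.nodata_mask, dx, dy)
            valid = ~shifted_nodata & ref_valid
            if int(valid.sum()) < min_overlap:
                continue
            any_overlap = True
            try:
                r = pearson_correlation(shifted, ref_grid, valid)
            except UndefinedCorrelationError:
                continue
            key = (-r, dx * dx + dy * dy, dy, dx)
            if best is None or key < best[0]:
                best = (key, dx, dy, r)
    if best is None:
        if not any_overlap:
            raise InsufficientOverlapError(
                f"no candidate offset has >= {min_overlap} overlapping valid pixels"
            )
        raise UndefinedCorrelationError("correlation undefined at every candidate offset")
    _, dx, dy, r = best
    return ShiftCorrection(
        dx=dx,
        dy=dy,
        correlation=r,
        reference_year=reference.year,
        n_candidates=n_candidates,
        year=image.year,
        satellite_id=image.satellite_id,
    )


def apply_shift(image: AnnualComposite, shift: ShiftCorrection) -> AnnualComposite:
    """Apply a correction; moved-out margins are marked nodata."""
    grid, mask = translate(image.grid, image.nodata_mask, shift.dx, shift.dy)
    return image.with_grid(grid, nodata_mask=mask)


class ShiftAligner(BaseEstimator):
    """Chained geolocation correction for a composite series.

    Each image (sorted by year) is aligned against the already-corrected
    previous image, mirroring a consecutive year-on-year comparison; with
    ``mode="anchor"`` every image is instead aligned to the earliest image.

    Parameters
    ----------
    max_shift : int, default 5
        Search radius in pixels; (2·max_shift+1)² candidates are evaluated.
    min_overlap : int, default 64
        Minimum jointly valid pixels for a candidate to be scored.
    mode : {"chained", "anchor"}, default "chained"

    Attributes
    ----------
    corrections_ : list of ShiftCorrection
        One entry per non-anchor composite, in series order.
    """

    def __init__(self, max_shift: int = 5, min_overlap: int = 64, mode: str = "chained"):
        self.max_shift = max_shift
        self.min_overlap = min_overlap
        self.mode = mode

    def fit_transform(self, series: Sequence[AnnualComposite]):
        series = list(series)
        if len(series) == 1:
            self.corrections_ = []
            return list(series)
        series = align_check(series)
        if self.mode not in ("chained", "anchor"):
            raise ValueError(f"unknown mode {self.mode!r}")
        corrected = [series[0]]
        corrections: List[ShiftCorrection] = []
        for comp in series[1:]:
            reference = corrected[0] if self.mode == "anchor" else corrected[-1]
            corr = find_best_shift(comp, reference, self.max_shift, self.min_overlap)
            corrected.append(apply_shift(comp, corr))
            corrections.append(corr)
        self.corrections_ = corrections
        return corrected

    def fit(self, series: Sequence[AnnualComposite]):
        self.fit_transform(series)
        return self


def align_series(
    series: Sequence[AnnualComposite], max_shift: int = 5, min_overlap: int = 64,
    mode: str = "chained",
) -> Tuple[list, list]:
    """Correct a sorted series against the previous corrected image.

    Returns the corrected series and one :class:`ShiftCorrection` per
    non-anchor composite. A length-1 series is returned unchanged with an
    empty correction list.
    """
    aligner = ShiftAligner(max_shift=max_shift, min_overlap=min_overlap, mode=mode)
    corrected = aligner.fit_transform(series)
    return corrected, aligner.corrections_
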