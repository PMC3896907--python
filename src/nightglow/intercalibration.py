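"""Robust intercalibration of uncalibrated DN series to a base-year scale.

The sensors carry no onboard calibration and gain is adjusted on the fly, so
each satellite-year has its own unknown monotone response. Every year t is
mapped onto the scale of a base year by a 6th-order polynomial regression of
DN_base on DN_t,

    DN_base = c0 + c1·DN_t + ... + c6·DN_t^6,

fitted as quantile regression on the median (minimum sum of absolute
residuals) within a calibration window, then applied scene-wide with the
result truncated to [0, 63]. Estimating the conditional median rather than
the mean makes the fit insensitive to pixels whose brightness genuinely
changed: up to (but not including) half of the calibration pixels may change
arbitrarily without dragging the curve — the median's 0.5 breakdown point.
The base year is the one with the highest proportion of window pixels at
DN 0 plus DN 63, so no year's image is stretched beyond the scale's ends.

Internally the DN axis is rescaled to [0, 1] before building the degree-6
design matrix (raw 63^6 monomials are catastrophically ill-conditioned); the
reported coefficients are mapped back to the raw-DN basis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .composites import DN_MAX, AnnualComposite, RegionMask
from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)

#: scale factor taking raw DN to the unit interval for the polynomial design
_DN_SCALE = float(DN_MAX)


def _vander(x_scaled: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x_scaled, degree + 1, increasing=True)


def fit_median_polynomial(
    source_dn: np.ndarray, base_dn: np.ndarray, degree: int = 6,
    solver: str = "lp", max_iter: int = 5000, p_tol: float = 1e-6,
) -> np.ndarray:
    """Degree-``degree`` median (L1) polynomial fit of base on source DN.

    Returns coefficients on the rescaled basis (powers of DN/63). When an
    exact polynomial interpolation of the pairs exists (e.g. source equals
    base) it is returned directly.

    ``solver="lp"`` (default) solves the median-regression linear program in
    its dual form with scipy's HiGHS backend and reads the coefficients off
    the equality-constraint duals; this is exact and robust to the heavy DN
    ties (point masses at 0 and 63) of calibration windows. ``solver="irls"``
    uses the statsmodels iteratively-reweighted fit instead; its
    non-convergence raises :class:`FitError`.
    """
    x = np.asarray(source_dn, dtype=np.float64) / _DN_SCALE
    y = np.asarray(base_dn, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("source and base samples differ in length")
    n_distinct = np.unique(x).size
    if n_distinct < degree + 1:
        raise FitError(
            f"only {n_distinct} distinct source DN levels; "
            f"degree-{degree} fit needs at least {degree + 1}"
        )
    V = _vander(x, degree)

    # exact-fit shortcut: degenerate-but-valid cases (identity, noise-free
    # affine maps) have zero residuals and defeat both solvers' assumptions
    c_ls, *_ = np.linalg.lstsq(V, y, rcond=None)
    if np.max(np.abs(V @ c_ls - y)) < 1e-9:
        return c_ls

    if solver == "lp":
        # dual of min Σ|y - Vc|: max y'a s.t. V'a = ½·V'1, 0 ≤ a ≤ 1;
        # the primal coefficients are minus the equality duals
        res = linprog(
            -y, A_eq=V.T, b_eq=0.5 * V.sum(axis=0),
            bounds=[(0.0, 1.0)] * x.size, method="highs",
        )
        if res.status != 0 or res.eqlin is None:
            raise FitError(f"median-regression LP failed: {res.message}")
        params = -np.asarray(res.eqlin.marginals, dtype=np.float64)
    elif solver == "irls":
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = QuantReg(y, V).fit(q=0.5, max_iter=max_iter, p_tol=p_tol)
        for w in caught:
            if issubclass(w.category, IterationLimitWarning):
                raise FitError(
                    f"median regression did not converge in {max_iter} iterations "
                    f"(n={x.size}, degree={degree})"
                )
        params = np.asarray(res.params, dtype=np.float64)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if not np.all(np.isfinite(params)):
        raise FitError("median regression returned non-finite coefficients")
    return params


def eval_scaled_poly(coeffs_scaled: np.ndarray, dn) -> np.ndarray:
    """Evaluate a scaled-basis polynomial at raw DN values."""
    u = np.asarray(dn, dtype=np.float64) / _DN_SCALE
    return np.polynomial.polynomial.polyval(u, coeffs_scaled)


def l1_objective(coeffs_scaled: np.ndarray, source_dn, base_dn) -> float:
    """Sum of absolute residuals of a scaled-basis polynomial on DN pairs."""
    return float(np.sum(np.abs(eval_scaled_poly(coeffs_scaled, source_dn)
                               - np.asarray(base_dn, dtype=np.float64))))


@dataclass
class CalibrationModel:
    """Polynomial map from one satellite-year's DN onto the base-year scale."""

    base_year: int
    source_year: int
    satellite_id: str
    coefficients_scaled: np.ndarray
    n_pixels: int
    calibration_window: str = "window"

    def __post_init__(self):
        self.coefficients_scaled = np.asarray(self.coefficients_scaled, dtype=np.float64)
        vals = self.evaluate(np.arange(DN_MAX + 1))
        if not np.all(np.isfinite(vals)):
            raise FitError("calibration curve is not finite on DN 0..63")

    @property
    def degree(self) -> int:
        return self.coefficients_scaled.size - 1

    @property
    def coefficients(self) -> np.ndarray:
        """c0..c_degree on the raw-DN basis (DN_base = Σ c_k · DN_t^k)."""
        k = np.arange(self.coefficients_scaled.size)
        return self.coefficients_scaled / _DN_SCALE**k

    def evaluate(self, dn) -> np.ndarray:
        """Calibrated (un-truncated) value of the polynomial at raw DN."""
        return eval_scaled_poly(self.coefficients_scaled, dn)

    @classmethod
    def identity(cls, year: int, satellite_id: str, degree: int = 6) -> "CalibrationModel":
        c = np.zeros(degree + 1)
        c[1] = _DN_SCALE
        return cls(year, year, satellite_id, c, n_pixels=0,
                   calibration_window="identity")


@dataclass
class BaseYearScore:
    """Fractions of window land pixels pinned at the scale's ends."""

    year: int
    satellite_id: str
    frac_zero: float
    frac_sat: float

    @property
    def score(self) -> float:
        return self.frac_zero + self.frac_sat


def satellite_precedence_key(satellite_id: str, precedence: Optional[Sequence[str]] = None):
    """Sort key ranking satellites oldest-first; the max is the most recent.

    With an explicit ``precedence`` list (oldest to newest) its order rules;
    otherwise the trailing number in the label (F10 < F12 < F15) is used.
    """
    if precedence is not None and satellite_id in precedence:
        return (1, list(precedence).index(satellite_id), satellite_id)
    digits = "".join(ch for ch in satellite_id if ch.isdigit())
    return (0, int(digits) if digits else -1, satellite_id)


def select_most_recent(
    series: Sequence[AnnualComposite], precedence: Optional[Sequence[str]] = None
) -> Dict[int, AnnualComposite]:
    """One composite per year: in overlap years, the most recent satellite."""
    by_year: Dict[int, AnnualComposite] = {}
    for comp in series:
        cur = by_year.get(comp.year)
        if cur is None or (
            satellite_precedence_key(comp.satellite_id, precedence)
            > satellite_precedence_key(cur.satellite_id, precedence)
        ):
            by_year[comp.year] = comp
    return by_year


def base_year_scores(
    series: Sequence[AnnualComposite],
    window: RegionMask,
    precedence: Optional[Sequence[str]] = None,
) -> List[BaseYearScore]:
    if window.n_pixels == 0:
        raise ValidationError("calibration window is empty")
    scores = []
    selected = select_most_recent(series, precedence)
    for year in sorted(selected):
        comp = selected[year]
        sel = window.mask & comp.valid_mask
        n = int(sel.sum())
        if n == 0:
            raise ValidationError(f"no valid window pixels in year {year}")
        vals = comp.grid[sel]
        scores.append(
            BaseYearScore(
                year=year,
                satellite_id=comp.satellite_id,
                frac_zero=float(np.count_nonzero(vals == 0)) / n,
                frac_sat=float(np.count_nonzero(vals == DN_MAX)) / n,
            )
        )
    return scores


def select_base_year(
    series: Sequence[AnnualComposite],
    window: RegionMask,
    precedence: Optional[Sequence[str]] = None,
    combine: str = "sum",
) -> int:
    """Year maximizing the window fraction of DN-0 plus DN-63 pixels.

    Anchoring to this year keeps every other year's calibrated image within
    the span between the detection floor and saturation. Ties go to the
    earliest year. ``combine`` may be "sum" (default) or "min" of the two
    fractions.
    """
    if len({c.year for c in series}) < 2:
        raise ValidationError("base-year selection requires at least 2 years")
    scores = base_year_scores(series, window, precedence)
    if combine == "sum":
        key = lambda s: s.score
    elif combine == "min":
        key = lambda s: min(s.frac_zero, s.frac_sat)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    best = max(scores, key=lambda s: (key(s), -s.year))
    return best.year


def fit_calibration(
    base: AnnualComposite,
    source: AnnualComposite,
    window: RegionMask,
    degree: int = 6,
) -> CalibrationModel:
    """Fit the median polynomial mapping ``source`` DN to ``base`` DN.

    Pairs are taken from window pixels valid in both composites; DN 0 and
    DN 63 pixels are included so the curve is constrained at both ends of
    the scale.
    """
    if window.mask.shape != base.shape:
        raise ValidationError("window mask not on the series grid")
    sel = window.mask & base.valid_mask & source.valid_mask
    n = int(sel.sum())
    if n < degree + 1:
        raise FitError(f"only {n} valid calibration pixels in window")
    coeffs = fit_median_polynomial(source.grid[sel], base.grid[sel], degree=degree)
    return CalibrationModel(
        base_year=base.year,
        source_year=source.year,
        satellite_id=source.satellite_id,
        coefficients_scaled=coeffs,
        n_pixels=n,
        calibration_window=window.region_id,
    )


def apply_calibration(image: AnnualComposite, model: CalibrationModel) -> AnnualComposite:
    """Map every valid pixel through the polynomial and truncate to [0, 63]."""
    if model.source_year != image.year or (
        model.satellite_id != image.satellite_id and model.calibration_window != "identity"
    ):
        raise ValidationError(
            f"model for {model.satellite_id}_{model.source_year} applied to "
            f"{image.satellite_id}_{image.year}"
        )
    out = np.clip(model.evaluate(image.grid), 0.0, float(DN_MAX))
    out[image.nodata_mask] = 0.0
    return image.with_grid(out, calibrated=True)


@dataclass
class DualSatelliteReport:
    """Pixelwise agreement of two same-year composites, before vs after."""

    year: int
    satellite_a: str
    satellite_b: str
    n_pixels: int
    bias_before: float
    mean_abs_before: float
    bias_after: float
    mean_abs_after: float


def dual_satellite_check(
    cal_a: AnnualComposite,
    cal_b: AnnualComposite,
    raw_a: AnnualComposite,
    raw_b: AnnualComposite,
) -> DualSatelliteReport:
    """Compare calibrations of two satellites observing the same year.

    Statistics are computed over jointly valid pixels unsaturated in both
    calibrated composites; an effective intercalibration removes most of the
    systematic between-satellite bias.
    """
    if cal_a.year != cal_b.year:
        raise ValidationError("dual-satellite check needs two composites of one year")
    sel = (
        cal_a.valid_mask & cal_b.valid_mask
        & (cal_a.grid < DN_MAX - 1e-6) & (cal_b.grid < DN_MAX - 1e-6)
    )
    n = int(sel.sum())
    if n == 0:
        raise ValidationError("no jointly valid unsaturated pixels")
    d_after = cal_a.grid[sel] - cal_b.grid[sel]
    d_before = raw_a.grid[sel].astype(np.float64) - raw_b.grid[sel].astype(np.float64)
    return DualSatelliteReport(
        year=cal_a.year,
        satellite_a=cal_a.satellite_id,
        satellite_b=cal_b.satellite_id,
        n_pixels=n,
        bias_before=float(d_before.mean()),
        mean_abs_before=float(np.abs(d_before).mean()),
        bias_after=float(d_after.mean()),
        mean_abs_after=float(np.abs(d_after).mean()),
    )


class MedianIntercalibrator(BaseEstimator):
    """Series-wide robust intercalibration to an automatically chosen base year.

    Parameters
    ----------
    degree : int, default 6
        Polynomial order of the DN_t → DN_base map.
    base_year : int or None
        Fix the base year instead of selecting it by the end-pinned-pixel
        score.
    precedence : sequence of str or None
        Satellite labels oldest-to-newest; rules which product represents an
        overlap year downstream. Default: trailing number in the label.

    Attributes
    ----------
    base_year_ : int
    scores_ : list of BaseYearScore
    models_ : dict mapping (year, satellite_id) to CalibrationModel
    failures_ : dict mapping (year, satellite_id) to the error message
    """

    def __init__(self, degree: int = 6, base_year: Optional[int] = None,
                 precedence: Optional[Sequence[str]] = None):
        self.degree = degree
        self.base_year = base_year
        self.precedence = precedence

    def fit(self, series: Sequence[AnnualComposite], window: RegionMask):
        series = list(series)
        self.scores_ = base_year_scores(series, window, self.precedence)
        self.base_year_ = (
            self.base_year
            if self.base_year is not None
            else select_base_year(series, window, self.precedence)
        )
        selected = select_most_recent(series, self.precedence)
        if self.base_year_ not in selected:
            raise ValidationError(f"base year {self.base_year_} not in series")
        base_comp = selected[self.base_year_]
        self.window_ = window
        self.models_: Dict[Tuple[int, str], CalibrationModel] = {}
        self.failures_: Dict[Tuple[int, str], str] = {}
        for comp in series:
            if comp is base_comp:
                self.models_[comp.key] = CalibrationModel.identity(
                    comp.year, comp.satellite_id, self.degree
                )
                continue
            try:
                self.models_[comp.key] = fit_calibration(
                    base_comp, comp, window, self.degree
                )
            except FitError as exc:
                logger.warning("calibration failed for %s_%s: %s",
                               comp.satellite_id, comp.year, exc)
                self.failures_[comp.key] = str(exc)
        if not self.models_:
            raise FitError("every calibration fit failed")
        return self

    def transform(self, series: Sequence[AnnualComposite]) -> List[AnnualComposite]:
        out = []
        for comp in series:
            model = self.models_.get(comp.key)
            if model is None:
                continue
            out.append(apply_calibration(comp, model))
        return out

    def fit_transform(self, series: Sequence[AnnualComposite], window: RegionMask):
        return self.fit(series, window).transform(series)


def calibrate_series(
    series: Sequence[AnnualComposite],
    window: RegionMask,
    base_year: Optional[int] = None,
    degree: int = 6,
    precedence: Optional[Sequence[str]] = None,
) -> Tuple[List[AnnualComposite], List[CalibrationModel]]:
    """Calibrate every satellite-year onto the base-year scale.

    The base-year image passes through unchanged (identity model); fit
    failures are logged per year and the remaining years proceed.
    """
    cal = MedianIntercalibrator(degree=degree, base_year=base_year, precedence=precedence)
    calibrated = cal.fit_transform(series, window)
    models = [cal.models_[c.key] for c in calibrated]
    return calibrated, models


# ---------------------------------------------------------------------------
# robustness diagnostics: empirical breakdown of the median fit
# ---------------------------------------------------------------------------

#: monotone degree-6 reference curve on the scaled basis (maps 0..63 onto
#: 0..63 with mid-scale curvature), used by the contamination diagnostics
TRUE_CURVE_SCALED = np.array([0.0, 0.55, 0.25, 0.0, 0.0, 0.0, 0.20]) * float(DN_MAX)


def contamination_sweep(
    fractions: Sequence[float],
    n_pairs: int = 20000,
    n_seeds: int = 20,
    seed: int = 0,
    noise_sd: float = 0.25,
    contam_value: float = 1000.0,
    degree: int = 6,
) -> Dict[float, float]:
    """Worst-case fitted-curve deviation under one-sided contamination.

    For each contamination fraction f, ``n_seeds`` synthetic calibration sets
    of ``n_pairs`` (source, base) pairs are drawn from the known monotone
    degree-6 curve with small Gaussian noise; a random fraction f of base
    values is replaced by an arbitrary large value. The returned deviation is
    the max over seeds of the max over DN 0..63 of |fitted − true|; a fit
    that fails or does not converge counts as infinite deviation (the
    estimate is unbounded-sensitive there).
    """
    dn_axis = np.arange(DN_MAX + 1, dtype=np.float64)
    true_vals = eval_scaled_poly(TRUE_CURVE_SCALED, dn_axis)
    out: Dict[float, float] = {}
    for f in fractions:
        worst = 0.0
        for i in range(n_seeds):
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 3, i])
            x = rng.integers(0, DN_MAX + 1, n_pairs).astype(np.float64)
            y = eval_scaled_poly(TRUE_CURVE_SCALED, x) + rng.normal(0.0, noise_sd, n_pairs)
            n_bad = int(round(f * n_pairs))
            idx = rng.choice(n_pairs, size=n_bad, replace=False)
            y[idx] = contam_value
            try:
                coeffs = fit_median_polynomial(x, y, degree=degree)
                dev = float(np.max(np.abs(eval_scaled_poly(coeffs, dn_axis) - true_vals)))
            except FitError:
                dev = np.inf
            worst = max(worst, dev)
        out[float(f)] = worst
    return out


def breakdown_fraction(sweep: Dict[float, float], divergence_threshold: float = 10.0) -> float:
    """Smallest contamination fraction at which the fit diverges."""
    for f in sorted(sweep):
        if sweep[f] > divergence_threshold:
            return f
    return float("nan")
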