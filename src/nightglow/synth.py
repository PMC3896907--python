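"""Synthetic multi-satellite nighttime-lights benchmarks with known truth.

The generator emulates the structure of annual "stable lights" composites:

* a static true-radiance scene — dark rural background, Gaussian urban blobs
  (a fraction bright enough to saturate every sensor), scattered dim villages,
  and a sea margin carried as nodata;
* localised step changes (brightening or dimming discs) switching on at a
  planted onset year and persisting thereafter;
* per-satellite monotone saturating gain curves (no onboard calibration, so
  each satellite maps radiance to DN differently);
* additive Gaussian radiance noise, integer geolocation jitter of up to
  ±3 pixels per year, and 6-bit quantization to DN 0..63;
* overlap years observed by two satellites simultaneously.

Change-affected pixels are kept a minority of land pixels, matching the
assumption under which median-based intercalibration is valid; a spec that
violates this raises :class:`SceneSpecError`.

Radiance is in arbitrary linear units scaled so that the default sensors map
roughly one radiance unit to one DN at the dark end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .composites import (
    DEFAULT_CRS,
    DEFAULT_GEOTRANSFORM,
    AnnualComposite,
    RegionMask,
    pixel_area_km2,
)
from .errors import SceneSpecError
from .geolocation import translate

DN_MAX = 63


@dataclass
class GainCurve:
    """Monotone saturating radiance→DN response: A·(1 − exp(−r/τ)), clipped at 63.

    ``amplitude`` must exceed 63 so the curve reaches saturation at finite
    radiance; ``tau`` sets the curvature (smaller τ → faster saturation).
    """

    amplitude: float
    tau: float

    def __post_init__(self):
        if self.amplitude <= DN_MAX or self.tau <= 0:
            raise SceneSpecError(
                "gain curve must be monotone and saturate at 63 "
                f"(amplitude>{DN_MAX}, tau>0; got A={self.amplitude}, tau={self.tau})"
            )

    def __call__(self, radiance):
        r = np.maximum(np.asarray(radiance, dtype=np.float64), 0.0)
        return np.clip(self.amplitude * (1.0 - np.exp(-r / self.tau)), 0.0, float(DN_MAX))

    @property
    def saturation_radiance(self) -> float:
        """Radiance above which the sensor reads DN 63."""
        return -self.tau * np.log(1.0 - DN_MAX / self.amplitude)


@dataclass
class SatelliteSpec:
    satellite_id: str
    start_year: int
    end_year: int
    gain: GainCurve

    def covers(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass
class ChangeEvent:
    """A localised step change in true radiance from ``onset_year`` onwards."""

    center: Tuple[int, int]
    radius: int
    onset_year: int
    sign: int
    magnitude: float

    def __post_init__(self):
        if self.radius < 1:
            raise SceneSpecError("change event radius must be >= 1 pixel")
        if self.sign not in (-1, 1):
            raise SceneSpecError("change event sign must be +1 or -1")


@dataclass
class BlobFieldSpec:
    """Parameters of the static radiance field."""

    n_blobs: int = 25
    blob_sigma_range: Tuple[float, float] = (2.0, 8.0)
    peak_range: Tuple[float, float] = (15.0, 85.0)
    saturating_frac: float = 0.2
    saturating_peak_range: Tuple[float, float] = (160.0, 260.0)
    background: float = 0.0
    sea_frac: float = 0.12
    n_villages: int = 120
    village_peak_range: Tuple[float, float] = (2.0, 10.0)


def _default_satellites(y0: int, y1: int) -> List[SatelliteSpec]:
    span = y1 - y0
    b1 = y0 + max(2, span * 6 // 18)
    b2 = y0 + max(4, span * 12 // 18)
    return [
        SatelliteSpec("F10", y0, min(b1 + 1, y1), GainCurve(75.0, 55.0)),
        SatelliteSpec("F12", b1, min(b2 + 1, y1), GainCurve(90.0, 70.0)),
        SatelliteSpec("F15", b2, y1, GainCurve(70.0, 50.0)),
    ]


@dataclass
class SceneSpec:
    """Full description of one synthetic benchmark.

    ``change_events=None`` asks the generator to plant ``n_auto_events``
    well-separated discs itself (dimming events on lit blobs, brightening
    events on dark land). ``window`` is the calibration sub-region as
    fractional bounds ((r0, r1), (c0, c1)); a saturating urban core is always
    planted at its centre so the window spans the full DN range.
    """

    shape: Tuple[int, int] = (256, 256)
    years: Tuple[int, int] = (1992, 2010)
    base_scene: BlobFieldSpec = field(default_factory=BlobFieldSpec)
    change_events: Optional[List[ChangeEvent]] = None
    n_auto_events: int = 12
    satellites: Optional[List[SatelliteSpec]] = None
    jitter_max: int = 3
    noise_sd: float = 0.5
    seed: int = 0
    window: Tuple[Tuple[float, float], Tuple[float, float]] = ((0.50, 0.92), (0.35, 0.90))

    def __post_init__(self):
        if self.jitter_max > 3:
            raise SceneSpecError("jitter_max must be <= 3 pixels")
        if self.satellites is None:
            self.satellites = _default_satellites(*self.years)
        y0, y1 = self.years
        for y in range(y0, y1 + 1):
            if not any(s.covers(y) for s in self.satellites):
                raise SceneSpecError(f"year {y} covered by no satellite")

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)

    def window_bounds(self) -> Tuple[int, int, int, int]:
        (r0, r1), (c0, c1) = self.window
        rows, cols = self.shape
        return (int(r0 * rows), int(r1 * rows), int(c0 * cols), int(c1 * cols))

    def window_mask(self, geotransform=DEFAULT_GEOTRANSFORM) -> RegionMask:
        r0, r1, c0, c1 = self.window_bounds()
        mask = np.zeros(self.shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return RegionMask("calibration_window", mask, pixel_area_km2(geotransform))

    def to_dict(self) -> dict:
        d = {
            "shape": list(self.shape),
            "years": list(self.years),
            "base_scene": asdict(self.base_scene),
            "n_auto_events": self.n_auto_events,
            "jitter_max": self.jitter_max,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "window": [list(self.window[0]), list(self.window[1])],
            "satellites": [
                {
                    "satellite_id": s.satellite_id,
                    "start_year": s.start_year,
                    "end_year": s.end_year,
                    "amplitude": s.gain.amplitude,
                    "tau": s.gain.tau,
                }
                for s in self.satellites
            ],
        }
        if self.change_events is not None:
            d["change_events"] = [
                {
                    "center": list(e.center),
                    "radius": e.radius,
                    "onset_year": e.onset_year,
                    "sign": e.sign,
                    "magnitude": e.magnitude,
                }
                for e in self.change_events
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        kwargs = dict(d)
        kwargs["shape"] = tuple(d.get("shape", (256, 256)))
        kwargs["years"] = tuple(d.get("years", (1992, 2010)))
        if "base_scene" in d:
            bs = dict(d["base_scene"])
            for k in ("blob_sigma_range", "peak_range", "saturating_peak_range",
                      "village_peak_range"):
                if k in bs:
                    bs[k] = tuple(bs[k])
            kwargs["base_scene"] = BlobFieldSpec(**bs)
        if "window" in d:
            kwargs["window"] = (tuple(d["window"][0]), tuple(d["window"][1]))
        if d.get("satellites"):
            kwargs["satellites"] = [
                SatelliteSpec(
                    s["satellite_id"], s["start_year"], s["end_year"],
                    GainCurve(s["amplitude"], s["tau"]),
                )
                for s in d["satellites"]
            ]
        if d.get("change_events"):
            kwargs["change_events"] = [
                ChangeEvent(tuple(e["center"]), e["radius"], e["onset_year"],
                            e["sign"], e["magnitude"])
                for e in d["change_events"]
            ]
        return cls(**kwargs)


@dataclass
class RealizedEvent:
    """A planted change event together with its land-pixel footprint."""

    event_id: int
    event: ChangeEvent
    footprint: np.ndarray  # boolean, True on affected land pixels


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the pipeline's estimates."""

    spec: SceneSpec
    applied_shift_per_year: Dict[int, Tuple[int, int]]
    satellites: List[SatelliteSpec]
    events: List[RealizedEvent]
    radiance_by_year: Dict[int, np.ndarray]
    sea_mask: np.ndarray

    @property
    def land_mask(self) -> np.ndarray:
        return ~self.sea_mask

    def change_mask(self) -> np.ndarray:
        m = np.zeros(self.sea_mask.shape, dtype=bool)
        for ev in self.events:
            m |= ev.footprint
        return m

    def unchanged_land_mask(self) -> np.ndarray:
        return self.land_mask & ~self.change_mask()

    def gain_for(self, satellite_id: str) -> GainCurve:
        for s in self.satellites:
            if s.satellite_id == satellite_id:
                return s.gain
        raise KeyError(satellite_id)

    def expected_dn_change(self, event: RealizedEvent, epoch1, epoch2,
                           gain: GainCurve) -> float:
        """Mean footprint DN change between epoch means, under one gain curve."""
        fp = event.footprint
        if not fp.any():
            return 0.0
        m1 = np.mean([gain(self.radiance_by_year[y][fp]) for y in epoch1], axis=0)
        m2 = np.mean([gain(self.radiance_by_year[y][fp]) for y in epoch2], axis=0)
        return float(np.mean(m2 - m1))


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class _Scene:
    """Realized static field + events for one SceneSpec (internal)."""

    def __init__(self, spec: SceneSpec):
        self.spec = spec
        rows, cols = spec.shape
        bs = spec.base_scene
        rng = np.random.default_rng([_entropy(spec.seed), 0])

        sea_cols = int(round(bs.sea_frac * cols))
        self.sea_mask = np.zeros(spec.shape, dtype=bool)
        self.sea_mask[:, :sea_cols] = True
        land_rows, land_cols = rows, cols - sea_cols

        base = np.full(spec.shape, bs.background, dtype=np.float64)
        rr, cc = np.mgrid[0:rows, 0:cols]

        def add_blob(center, sigma, peak):
            d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
            np.add(base, peak * np.exp(-d2 / (2.0 * sigma**2)), out=base)

        # one saturating core pinned at the calibration-window centre so the
        # window always spans dark land up to saturated DN 63
        r0, r1, c0, c1 = spec.window_bounds()
        add_blob(((r0 + r1) // 2, (c0 + c1) // 2), 4.0, bs.saturating_peak_range[1])

        self.blobs = []
        n_sat = int(round(bs.saturating_frac * bs.n_blobs))
        for i in range(bs.n_blobs):
            center = (
                int(rng.integers(4, rows - 4)),
                int(rng.integers(sea_cols + 4, cols - 4)),
            )
            sigma = float(rng.uniform(*bs.blob_sigma_range))
            if i < n_sat:
                peak = float(rng.uniform(*bs.saturating_peak_range))
            else:
                peak = float(rng.uniform(*bs.peak_range))
            add_blob(center, sigma, peak)
            self.blobs.append((center, sigma, peak))
        for _ in range(bs.n_villages):
            center = (
                int(rng.integers(2, rows - 2)),
                int(rng.integers(sea_cols + 2, cols - 2)),
            )
            add_blob(center, float(rng.uniform(0.8, 1.6)), float(rng.uniform(*bs.village_peak_range)))
        base[self.sea_mask] = 0.0
        self.base_radiance = base

        events = spec.change_events
        if events is None:
            events = self._auto_events(rng)
        self.events = self._realize(events)

        land = ~self.sea_mask
        changed = np.zeros(spec.shape, dtype=bool)
        for ev in self.events:
            changed |= ev.footprint
        if land.sum() and changed.sum() >= 0.5 * land.sum():
            raise SceneSpecError(
                "change events cover >= 50% of land pixels; the median-based "
                "calibration assumption requires changes on a minority of pixels"
            )

    def _auto_events(self, rng) -> List[ChangeEvent]:
        spec = self.spec
        rows, cols = spec.shape
        sea_cols = int(round(spec.base_scene.sea_frac * cols))
        y0, y1 = spec.years
        onset_lo, onset_hi = y0 + 3, y1 - 3
        n = spec.n_auto_events
        n_dim = n * 2 // 5
        placed: List[ChangeEvent] = []

        def far_enough(center, radius):
            return all(
                (center[0] - e.center[0]) ** 2 + (center[1] - e.center[1]) ** 2
                > (3 * (radius + e.radius)) ** 2
                for e in placed
            )

        # dimming events sit on moderately lit (non-saturating) blobs so the
        # drop is visible above the dark background
        lit = [b for b in self.blobs if 25.0 <= b[2] <= 100.0]
        rng.shuffle(lit)
        for center, sigma, peak in lit:
            if len(placed) >= n_dim:
                break
            radius = int(np.clip(round(sigma), 2, 6))
            if not far_enough(center, radius):
                continue
            mag = float(np.clip(0.6 * peak, 8.0, 35.0))
            placed.append(ChangeEvent(center, radius, int(rng.integers(onset_lo, onset_hi + 1)),
                                      -1, mag))
        tries = 0
        while len(placed) < n and tries < 2000:
            tries += 1
            center = (int(rng.integers(8, rows - 8)), int(rng.integers(sea_cols + 8, cols - 8)))
            radius = int(rng.integers(2, 7))
            if not far_enough(center, radius):
                continue
            mag = float(rng.uniform(10.0, 35.0))
            placed.append(ChangeEvent(center, radius, int(rng.integers(onset_lo, onset_hi + 1)),
                                      +1, mag))
        return placed

    def _realize(self, events) -> List[RealizedEvent]:
        out = []
        for i, ev in enumerate(events):
            y0, y1 = self.spec.years
            if not (y0 <= ev.onset_year <= y1):
                raise SceneSpecError(
                    f"event onset {ev.onset_year} outside series years {y0}-{y1}"
                )
            fp = _disc(self.spec.shape, ev.center, ev.radius) & ~self.sea_mask
            out.append(RealizedEvent(i, ev, fp))
        return out

    def radiance(self, year: int) -> np.ndarray:
        r = self.base_radiance.copy()
        for ev in self.events:
            if year >= ev.event.onset_year:
                r[ev.footprint] += ev.event.sign * ev.event.magnitude
        np.maximum(r, 0.0, out=r)
        return r


def _entropy(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def generate_scene(spec: SceneSpec) -> Dict[int, np.ndarray]:
    """Per-year true radiance grids (identical outside event footprints)."""
    scene = _Scene(spec)
    return {y: scene.radiance(y) for y in spec.year_range}


def simulate_sensor(
    radiance: np.ndarray,
    satellite_gain: GainCurve,
    noise_sd: float,
    shift: Tuple[int, int] = (0, 0),
    seed=0,
    sea_mask: Optional[np.ndarray] = None,
    year: int = 0,
    satellite_id: str = "SIM",
    geotransform=DEFAULT_GEOTRANSFORM,
) -> AnnualComposite:
    """Observe a radiance grid through one satellite.

    Gaussian noise (sd in radiance units) is added to the radiance, the
    monotone gain curve maps it to continuous DN saturating at 63, values are
    rounded to integers in 0..63, and the grid is translated by ``shift``
    with the vacated margin marked nodata.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radiance = np.asarray(radiance, dtype=np.float64)
    if sea_mask is None:
        sea_mask = np.zeros(radiance.shape, dtype=bool)
    noisy = radiance + (rng.normal(0.0, noise_sd, radiance.shape) if noise_sd > 0 else 0.0)
    dn = np.clip(np.rint(satellite_gain(noisy)), 0, DN_MAX).astype(np.int16)
    dn[sea_mask] = 0
    grid, nodata = translate(dn, sea_mask.copy(), shift[0], shift[1])
    return AnnualComposite(
        year=year,
        satellite_id=satellite_id,
        grid=grid,
        geotransform=geotransform,
        crs_id=DEFAULT_CRS,
        nodata_mask=nodata,
    )


def make_benchmark(spec: SceneSpec) -> Tuple[List[AnnualComposite], GroundTruth]:
    """Generate one composite per satellite-year plus full ground truth.

    The first year's jitter is fixed at (0, 0) so the anchor of the alignment
    chain coincides with the true scene frame; later years draw independent
    integer jitters in [-jitter_max, jitter_max]². Both satellites of an
    overlap year share that year's jitter (geolocation error is a property of
    the year's compositing, not of the sensor).
    """
    scene = _Scene(spec)
    radiance_by_year = {y: scene.radiance(y) for y in spec.year_range}

    shift_rng = np.random.default_rng([_entropy(spec.seed), 1])
    shifts: Dict[int, Tuple[int, int]] = {}
    for y in spec.year_range:
        if y == spec.years[0] or spec.jitter_max == 0:
            shifts[y] = (0, 0)
        else:
            shifts[y] = (
                int(shift_rng.integers(-spec.jitter_max, spec.jitter_max + 1)),
                int(shift_rng.integers(-spec.jitter_max, spec.jitter_max + 1)),
            )

    composites = []
    for y in spec.year_range:
        for i_sat, sat in enumerate(spec.satellites):
            if not sat.covers(y):
                continue
            rng = np.random.default_rng([_entropy(spec.seed), 2, y, i_sat])
            composites.append(
                simulate_sensor(
                    radiance_by_year[y],
                    sat.gain,
                    spec.noise_sd,
                    shift=shifts[y],
                    seed=rng,
                    sea_mask=scene.sea_mask,
                    year=y,
                    satellite_id=sat.satellite_id,
                )
            )
    truth = GroundTruth(
        spec=spec,
        applied_shift_per_year=shifts,
        satellites=list(spec.satellites),
        events=scene.events,
        radiance_by_year=radiance_by_year,
        sea_mask=scene.sea_mask,
    )
    return composites, truth
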