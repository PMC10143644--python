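"""Synthetic drought-stress phenotyping scenes.

Generates every input the analysis pipeline consumes — hyperspectral
cubes, RGB view triplets, pot-weight series and greenhouse weather — with
the statistical structure the method assumes, so the whole pipeline is
testable without any imagery download.

The spectral model is a logistic red edge: reflectance rises from a red
plateau ``r_red`` to a NIR plateau ``r_nir`` around an inflection
wavelength, with steepness ``rate``.  Water stress is encoded by
attenuating ``rate`` and ``r_nir`` by a factor (1 − stress_level), which
flattens the red edge — the physiological signature the maximum-slope
H-index is designed to detect.  Scenes contain a flat 75%-reflectance
reference panel, a dark background, and plant pixels split into
illuminated ones (full spectrum) and shaded ones (same spectral shape,
multiplicatively dimmed), which is exactly the structure that makes
one-band percentile selection of illuminated leaf area work.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .hypercube_io import Hypercube, PanelRegion

__all__ = [
    "RedEdgeModel",
    "SceneConfig",
    "SceneTruth",
    "ExperimentDesign",
    "ETModel",
    "generate_hypercube",
    "generate_rgb_views",
    "generate_weight_series",
    "generate_weather",
    "simulate_experiment",
    "default_wavelengths",
]

#: camera-style grid: 650–820 nm at 2.5 nm spacing → 69 bands
def default_wavelengths(start: float = 650.0, stop: float = 820.0, step: float = 2.5) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class RedEdgeModel:
    """Logistic red-edge reflectance model.

    reflectance(λ) = r_red + (r_nir − r_red) / (1 + exp(−rate·(λ − lambda_infl)))

    The analytic maximum slope is (r_nir − r_red)·rate/4 at the inflection.
    Defaults describe a healthy leaf: dark red plateau, bright NIR plateau,
    inflection near 715 nm.
    """

    r_red: float = 0.05
    r_nir: float = 0.50
    lambda_infl: float = 715.0
    rate: float = 0.08          # nm⁻¹
    noise_sd: float = 0.01      # reflectance units, additive per band

    def __post_init__(self) -> None:
        if not 0 <= self.r_red < self.r_nir <= 1:
            raise ValueError("need 0 <= r_red < r_nir <= 1")
        if not 650 < self.lambda_infl < 820:
            raise ValueError("lambda_infl must lie inside (650, 820) nm")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def reflectance(self, wavelengths) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.r_red + (self.r_nir - self.r_red) / (
            1.0 + np.exp(-self.rate * (wl - self.lambda_infl))
        )

    @property
    def max_slope(self) -> float:
        """Analytic maximum derivative, reflectance·nm⁻¹."""
        return (self.r_nir - self.r_red) * self.rate / 4.0

    def attenuate(self, stress_level: float) -> "RedEdgeModel":
        """Stress-attenuated model: rate and r_nir scaled by (1 − stress_level)."""
        if not 0 <= stress_level <= 1:
            raise ValueError("stress_level must be in [0, 1]")
        if stress_level == 0:
            return self
        f = 1.0 - stress_level
        r_nir = max(self.r_red + 1e-6, self.r_nir * f)
        return replace(self, r_nir=r_nir, rate=self.rate * f)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and radiometry of one synthetic acquisition."""

    frame_rows: int = 128
    frame_cols: int = 128
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    plant_fraction: float = 0.12
    shaded_fraction: float = 0.35
    shade_factor_range: tuple[float, float] = (0.35, 0.75)
    background_reflectance: float = 0.05
    panel_roi: tuple[int, int, int, int] = (0, 0, 24, 24)
    panel_reflectance: float = 0.75
    radiance_scale: float = 1000.0  # mW/(nm·sr·m²) at unit reflectance
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        dw = np.diff(self.wavelengths)
        if len(dw) == 0 or np.any(dw <= 0) or np.ptp(dw) > 1e-9:
            raise ValueError("wavelengths must be uniform ascending")
        if self.plant_fraction <= 0:
            raise ValueError("plant_fraction must be positive")
        lo, hi = self.shade_factor_range
        if not 0 < lo <= hi < 1:
            raise ValueError("shade_factor_range must lie inside (0, 1)")
        for name in ("background_reflectance", "panel_reflectance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        panel_frac = self._panel_area() / (self.frame_rows * self.frame_cols)
        if self.plant_fraction + panel_frac >= 1:
            raise ValueError("plant_fraction + panel area fraction must be < 1")

    def _panel_area(self) -> int:
        r0, c0, r1, c1 = self.panel_roi
        return max(0, r1 - r0) * max(0, c1 - c0)

    @property
    def panel(self) -> PanelRegion:
        return PanelRegion(self.panel_roi, self.panel_reflectance)

    @classmethod
    def camera_native(cls, **kwargs) -> "SceneConfig":
        """Preset at the snapshot camera's native 1024×1024 frame."""
        kwargs.setdefault("frame_rows", 1024)
        kwargs.setdefault("frame_cols", 1024)
        kwargs.setdefault("panel_roi", (0, 0, 192, 192))
        return cls(**kwargs)


@dataclass
class SceneTruth:
    """Generator ground truth for recovery tests."""

    plant_mask: np.ndarray
    illuminated_mask: np.ndarray
    stress_level: float
    red_edge: RedEdgeModel  # the stress-attenuated model actually rendered

    def __post_init__(self) -> None:
        self.plant_mask = np.asarray(self.plant_mask, dtype=bool)
        self.illuminated_mask = np.asarray(self.illuminated_mask, dtype=bool)
        if np.any(self.illuminated_mask & ~self.plant_mask):
            raise ValueError("illuminated_mask must be a subset of plant_mask")


def _blob_mask(
    frame_shape: tuple[int, int], n_pixels: int, center: tuple[float, float], aspect: float = 1.3
) -> np.ndarray:
    """Compact elliptical blob with an exact pixel count: the ``n_pixels``
    pixels closest to ``center`` in elliptical distance."""
    rows, cols = frame_shape
    n_pixels = min(n_pixels, rows * cols)
    rr, cc = np.mgrid[0:rows, 0:cols]
    d = ((rr - center[0]) / aspect) ** 2 + (cc - center[1]) ** 2
    order = np.argsort(d, axis=None, kind="stable")
    mask = np.zeros(rows * cols, dtype=bool)
    mask[order[:n_pixels]] = True
    return mask.reshape(rows, cols)


def generate_hypercube(
    config: SceneConfig,
    truth_params: RedEdgeModel | None = None,
    stress_level: float = 0.0,
    seed: int | None = None,
) -> tuple[Hypercube, SceneTruth]:
    """Render one radiance-unit hypercube plus its ground truth.

    The scene is built in reflectance: panel pixels flat at the panel's
    nominal value, background flat and dark, illuminated plant pixels on
    the (stress-attenuated) logistic red edge, shaded plant pixels the same
    spectrum times a per-pixel shade factor.  Additive Gaussian band noise
    is applied and truncated to [0, 1], then the cube is scaled by a smooth
    band-dependent illuminant into radiance units (which the white-panel
    calibration later divides out).
    """
    if truth_params is None:
        truth_params = RedEdgeModel()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.frame_rows, config.frame_cols
    wl = config.wavelengths
    model = truth_params.attenuate(stress_level)

    n_plant = int(round(config.plant_fraction * rows * cols))
    if n_plant <= 0:
        raise ValueError("plant_fraction too small for this frame")
    r0, c0, r1, c1 = config.panel_roi
    # centre the plant in the free area right/below the panel
    center = ((r1 + rows) / 2.0, (c1 + cols) / 2.0)
    plant_mask = _blob_mask((rows, cols), n_plant, center)
    panel_mask = np.zeros((rows, cols), dtype=bool)
    panel_mask[r0:r1, c0:c1] = True
    if np.any(plant_mask & panel_mask):
        raise ValueError("plant region overlaps the panel roi; shrink plant_fraction")

    shaded = np.zeros((rows, cols), dtype=bool)
    plant_idx = np.flatnonzero(plant_mask)
    n_shaded = int(round(config.shaded_fraction * len(plant_idx)))
    if n_shaded:
        pick = rng.choice(len(plant_idx), size=n_shaded, replace=False)
        shaded.flat[plant_idx[pick]] = True
    illuminated = plant_mask & ~shaded

    refl = np.full((len(wl), rows, cols), config.background_reflectance)
    refl[:, panel_mask] = config.panel_reflectance
    spectrum = model.reflectance(wl)
    refl[:, illuminated] = spectrum[:, None]
    if n_shaded:
        factors = rng.uniform(*config.shade_factor_range, size=n_shaded)
        refl[:, shaded] = spectrum[:, None] * factors[None, :]
    if model.noise_sd > 0:
        refl = refl + rng.normal(0.0, model.noise_sd, size=refl.shape)
        refl = np.clip(refl, 0.0, 1.0)

    # smooth illuminant; cancels exactly in the panel-ratio calibration
    illuminant = config.radiance_scale * (1.0 + 0.2 * np.sin(np.pi * (wl - wl[0]) / (wl[-1] - wl[0])))
    cube = Hypercube(
        data=refl * illuminant[:, None, None],
        wavelengths=wl,
        units="radiance",
        provenance=f"synthetic scene (stress={stress_level:g})",
    )
    truth = SceneTruth(plant_mask, illuminated, stress_level, model)
    return cube, truth


# ---------------------------------------------------------------------------
# RGB views

def generate_rgb_views(
    truth: SceneTruth | None,
    stress_level: float,
    seed: int,
    frame_shape: tuple[int, int] = (128, 128),
    base_areas: tuple[int, int, int] = (1800, 2200, 2100),
    area_reduction: float = 0.5,
    area_cv: float = 0.06,
    senescence: float | None = None,
    senescence_gain: float = 0.6,
    hue_sigma: float = 12.0,
    saturation: float = 0.8,
    value: float = 0.7,
    background_value: float = 0.03,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One top view and two side views of a plant, with per-view masks.

    Plant-pixel hue is drawn from Normal(120° − 60°·senescence, hue_sigma)
    clipped to [60°, 180°] — green canopies drift toward yellow as they
    senesce.  Unless given explicitly, senescence = senescence_gain ·
    stress_level.  Per-view mask areas shrink linearly with stress (growth
    reduction) and carry a multiplicative plant-size factor of spread
    ``area_cv`` (set it to 0 for exactly the configured areas); the
    background is near-black.  Returns ``{view: (uint8 RGB image, bool
    mask)}`` for TV, SV0, SV90.
    """
    if not 0 <= stress_level <= 1:
        raise ValueError("stress_level must be in [0, 1]")
    if senescence is None:
        senescence = senescence_gain * stress_level
    senescence = float(np.clip(senescence, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    rows, cols = frame_shape
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    from .rgb_index import VIEWS

    size_factor = max(0.2, rng.normal(1.0, area_cv)) if area_cv > 0 else 1.0
    for view, base_area in zip(VIEWS, base_areas):
        area = int(round(base_area * (1.0 - area_reduction * stress_level) * size_factor))
        mask = _blob_mask(frame_shape, area, (rows / 2.0, cols / 2.0), aspect=1.2)
        hues = 120.0 - 60.0 * senescence
        if hue_sigma > 0:
            hues = hues + rng.normal(0.0, hue_sigma, size=area)
        hues = np.clip(np.atleast_1d(np.asarray(hues, dtype=float)), 60.0, 180.0)
        if hues.size == 1 and area > 1:
            hues = np.full(area, hues[0])
        hsv = np.zeros((rows, cols, 3))
        hsv[..., 2] = background_value
        hsv[mask, 0] = hues / 360.0
        hsv[mask, 1] = saturation
        hsv[mask, 2] = value
        img = np.round(hsv2rgb(hsv) * 255.0).astype(np.uint8)
        out[view] = (img, mask)
    return out


# ---------------------------------------------------------------------------
# experiment design, weights, weather

@dataclass(frozen=True)
class ExperimentDesign:
    """Two stress/recovery cycles on a genotype × treatment × replicate grid.

    Five acquisition timepoints bracket the cycles; the first is the
    pre-stress baseline and each of the other four closes one phase.
    ``stress_effect`` is the fractional red-edge attenuation a genotype
    suffers under deficit irrigation at the end of a stress phase (higher =
    more susceptible); in recovery phases the attenuation relaxes to
    ``recovery_effect``.
    """

    genotypes: tuple[str, ...] = ("770P", "990P", "Red Setter", "Torremaggiore")
    treatments: tuple[str, str] = ("control", "stressed")
    replicates: int = 6
    acquisitions: tuple[tuple[str, str], ...] = (
        ("2021-05-27", "baseline"),
        ("2021-06-02", "I stress"),
        ("2021-06-08", "I recovery"),
        ("2021-06-15", "II stress"),
        ("2021-06-22", "II recovery"),
    )
    stress_effect: tuple[float, ...] = (0.45, 0.45, 0.30, 0.30)
    recovery_effect: float = 0.0
    biological_cv: float = 0.05   # replicate-to-replicate spread of rate, r_nir
    infl_sd_nm: float = 2.0       # replicate spread of the inflection wavelength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.stress_effect) != len(self.genotypes):
            raise ValueError("one stress_effect per genotype")
        if not all(0 <= e <= 1 for e in self.stress_effect):
            raise ValueError("stress_effect values must be in [0, 1]")

    @property
    def dates(self) -> list[pd.Timestamp]:
        return [pd.Timestamp(d) for d, _ in self.acquisitions]

    @property
    def phases(self) -> list[str]:
        return [p for _, p in self.acquisitions]

    def effect_of(self, genotype: str) -> float:
        return self.stress_effect[self.genotypes.index(genotype)]

    def stress_level_at(self, genotype: str, treatment: str, phase: str) -> float:
        """Red-edge attenuation of this genotype × treatment at a phase end."""
        if treatment != "stressed" or phase == "baseline":
            return 0.0
        if "stress" in phase:
            return self.effect_of(genotype)
        return self.recovery_effect

    def stress_windows(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Half-open [start, end) date windows of deficit irrigation."""
        windows = []
        for i, (_, phase) in enumerate(self.acquisitions[1:], start=1):
            if "stress" in phase:
                windows.append((self.dates[i - 1], self.dates[i]))
        return windows

    def pots(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.genotypes):
            for t in self.treatments:
                for r in range(1, self.replicates + 1):
                    rows.append(
                        {
                            "pot_id": f"{g.replace(' ', '')}-{t[:4]}-{r:02d}",
                            "genotype": g,
                            "treatment": t,
                            "replicate": r,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ETModel:
    """Daily water-loss model for the weight-series generator.

    Control pots evapotranspire ``base_et_g`` growing by ``growth_per_day``
    (fractional, compounding the canopy expansion); stressed pots
    transpire ``stress_et_factor`` of that during deficit windows.  Water
    is restored after the morning weighing: 100% of the day's loss for
    controls, ``restoration_stressed`` during deficit windows.
    """

    initial_weight_g: float = 2800.0
    base_et_g: float = 400.0
    growth_per_day: float = 0.015
    stress_et_factor: float = 0.7
    restoration_stressed: float = 0.7
    noise_sd_g: float = 10.0
    refill_on_recovery: bool = True

    def __post_init__(self) -> None:
        if self.base_et_g < 0 or self.noise_sd_g < 0:
            raise ValueError("negative ET parameters")


def generate_weight_series(
    design: ExperimentDesign, et_model: ETModel | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Daily morning pot weights and restored water for every pot.

    Columns: pot_id, genotype, treatment, replicate, date, weight_g,
    water_added_g.  Weighing precedes watering; the recorded weight is the
    pre-watering one.  Deterministic given (design, seed).
    """
    if et_model is None:
        et_model = ETModel()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    days = pd.date_range(design.dates[0], design.dates[-1], freq="D")
    windows = design.stress_windows()
    recovery_starts = {end for _, end in windows if end != days[-1]}

    def in_stress(day: pd.Timestamp) -> bool:
        return any(start <= day < end for start, end in windows)

    frames = []
    for pot in design.pots().itertuples(index=False):
        pot_factor = rng.normal(1.0, 0.05)
        weight = et_model.initial_weight_g
        recs = []
        for i, day in enumerate(days):
            et = et_model.base_et_g * (1 + et_model.growth_per_day) ** i * pot_factor
            stressed_today = pot.treatment == "stressed" and in_stress(day)
            if stressed_today:
                et *= et_model.stress_et_factor
            if et_model.noise_sd_g > 0:
                et += rng.normal(0.0, et_model.noise_sd_g)
            et = max(et, 0.0)
            restoration = et_model.restoration_stressed if stressed_today else 1.0
            added = restoration * et
            if (
                et_model.refill_on_recovery
                and pot.treatment == "stressed"
                and day in recovery_starts
            ):
                added += et_model.initial_weight_g - weight  # re-wet to capacity
            recs.append(
                {
                    "pot_id": pot.pot_id,
                    "genotype": pot.genotype,
                    "treatment": pot.treatment,
                    "replicate": pot.replicate,
                    "date": day,
                    "weight_g": weight,
                    "water_added_g": added,
                }
            )
            weight = weight + added - et
            if weight <= 0:
                raise RuntimeError("pot ran dry; implausible ET parameters")
        frames.append(pd.DataFrame(recs))
    return pd.concat(frames, ignore_index=True)


def generate_weather(
    days: int,
    seed: int = 0,
    start: str = "2021-05-27",
    t_mean_c: float = 26.0,
    t_amp_c: float = 7.0,
    t_trend_c_per_day: float = 0.06,
    rh_mean_pct: float = 60.0,
    rh_amp_pct: float = 22.0,
    noise_sd_t: float = 0.4,
    noise_sd_rh: float = 2.0,
) -> pd.DataFrame:
    """15-minute greenhouse RH/T series: sinusoidal diurnal cycle (warm,
    dry afternoons), a slow seasonal warming trend, plus noise.

    96 records per day; RH clipped to (1, 100]; deterministic given seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start=start, periods=days * 96, freq="15min")
    hours = ts.hour + ts.minute / 60.0
    day_idx = np.arange(len(ts)) // 96
    diurnal = np.sin(2 * np.pi * (hours - 9.0) / 24.0)  # peak at 15:00
    t = t_mean_c + t_trend_c_per_day * day_idx + t_amp_c * diurnal
    rh = rh_mean_pct - rh_amp_pct * diurnal
    if noise_sd_t > 0:
        t = t + rng.normal(0.0, noise_sd_t, size=len(ts))
    if noise_sd_rh > 0:
        rh = rh + rng.normal(0.0, noise_sd_rh, size=len(ts))
    rh = np.clip(rh, 1.0, 100.0)
    return pd.DataFrame({"timestamp": ts, "rh_pct": rh, "t_c": t})


# ---------------------------------------------------------------------------
# full experiment emission

def _pot_red_edge(base: RedEdgeModel, rng: np.random.Generator, design: ExperimentDesign) -> RedEdgeModel:
    """Replicate-level biological variation around the base leaf model."""
    return replace(
        base,
        rate=base.rate * max(0.1, rng.normal(1.0, design.biological_cv)),
        r_nir=float(np.clip(base.r_nir * rng.normal(1.0, design.biological_cv),
                            base.r_red + 1e-3, 1.0)),
        lambda_infl=float(np.clip(base.lambda_infl + rng.normal(0.0, design.infl_sd_nm),
                                  651.0, 819.0)),
    )


def simulate_experiment(
    design: ExperimentDesign,
    config: SceneConfig | None = None,
    outdir=None,
    base_red_edge: RedEdgeModel | None = None,
    et_model: ETModel | None = None,
    cube_format: str = "envi",
    senescence_base: float = 0.2,
    senescence_per_day: float = 0.012,
    senescence_stress_gain: float = 0.6,
) -> pd.DataFrame:
    """Emit a complete synthetic experiment to ``outdir``.

    Writes one hypercube and three RGB view PNGs per pot per acquisition
    date, daily ``weights.csv``, 15-min ``weather.csv``, and a
    ``manifest.csv`` tying pot id, genotype, treatment, replicate, date and
    phase to the file paths (relative to the manifest).  Returns the
    manifest as a DataFrame.

    Canopy senescence progresses linearly over the season
    (``senescence_base`` + ``senescence_per_day``·days) and is pushed
    further by stress (``senescence_stress_gain``·stress_level), driving
    the HUE drift and SI rise the optical indices track.
    """
    import imageio.v3 as iio

    from .hypercube_io import write_cube

    if config is None:
        config = SceneConfig()
    if base_red_edge is None:
        base_red_edge = RedEdgeModel()
    outdir = Path(outdir)
    (outdir / "cubes").mkdir(parents=True, exist_ok=True)
    (outdir / "rgb").mkdir(exist_ok=True)

    pots = design.pots()
    rows = []
    for pi, pot in enumerate(pots.itertuples(index=False)):
        pot_rng = np.random.default_rng([design.seed, pi])
        pot_model = _pot_red_edge(base_red_edge, pot_rng, design)
        for di, (date, phase) in enumerate(design.acquisitions):
            stress = design.stress_level_at(pot.genotype, pot.treatment, phase)
            seed_cube = int(np.random.default_rng([design.seed, pi, di, 0]).integers(2**31))
            seed_rgb = int(np.random.default_rng([design.seed, pi, di, 1]).integers(2**31))
            cube, _truth = generate_hypercube(config, pot_model, stress, seed=seed_cube)
            stem = f"{pot.pot_id}_{date}"
            ext = ".tif" if cube_format.startswith("tif") else ".bsq"
            cube_rel = f"cubes/{stem}{ext}"
            write_cube(cube, outdir / cube_rel, format=cube_format)
            day_offset = (pd.Timestamp(date) - design.dates[0]).days
            senescence = min(
                1.0,
                senescence_base
                + senescence_per_day * day_offset
                + senescence_stress_gain * stress,
            )
            views = generate_rgb_views(None, stress, seed=seed_rgb, senescence=senescence)
            paths = {}
            for view, (img, _mask) in views.items():
                rel = f"rgb/{stem}_{view}.png"
                iio.imwrite(outdir / rel, img)
                paths[view] = rel
            rows.append(
                {
                    "pot_id": pot.pot_id,
                    "genotype": pot.genotype,
                    "treatment": pot.treatment,
                    "replicate": pot.replicate,
                    "date": date,
                    "phase": phase,
                    "cube_path": cube_rel,
                    "tv_path": paths["TV"],
                    "sv0_path": paths["SV0"],
                    "sv90_path": paths["SV90"],
                }
            )

    weights = generate_weight_series(design, et_model, seed=design.seed + 1)
    weights_out = weights.copy()
    weights_out["date"] = weights_out["date"].dt.strftime("%Y-%m-%d")
    weights_out.to_csv(outdir / "weights.csv", index=False, float_format="%.6f")
    n_days = (design.dates[-1] - design.dates[0]).days + 1
    weather = generate_weather(n_days, seed=design.seed + 2, start=str(design.dates[0].date()))
    weather.to_csv(outdir / "weather.csv", index=False, float_format="%.6f")

    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
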