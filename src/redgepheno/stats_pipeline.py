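"""Experiment-level statistics and the end-to-end analysis pipeline.

The experiment contrasts well-watered and deficit-irrigated plants of
several genotypes over alternating stress/recovery phases.  For every
genotype × phase × index cell a one-way ANOVA compares the stressed
against the control replicates (n = 6 each by design), yielding a
significance grid; each optical index is additionally regressed against
the H-index to quantify how much of the hyperspectral signal the RGB
indices carry.

``run_pipeline`` drives the full chain over an experiment manifest:
calibrate → segment → signature → H-index → optical indices → ET/VPD →
phase table → regressions, writing tidy CSV outputs, an aggregated
storage-reduction report and a log.  The pipeline holds no randomness of
its own: outputs are a pure function of (manifest, config).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import env_metrics, hyperseg, rgb_index, spectral_index
from .hypercube_io import PanelRegion, read_cube, to_reflectance

__all__ = [
    "AnovaResult",
    "PipelineConfig",
    "anova_one_way",
    "phase_table",
    "regress_oi_vs_hindex",
    "run_pipeline",
]

logger = logging.getLogger("redgepheno")

DEFAULT_INDICES = ("h_index", "psa", "hue", "si")


class AnovaResult(NamedTuple):
    f: float
    p: float
    degenerate: bool = False          # 0/0: no variance anywhere, equal means
    zero_within_variance: bool = False  # separation without noise: p reported as 0


class DegenerateGroupsError(ValueError):
    pass


def anova_one_way(groups) -> AnovaResult:
    """Classical one-way ANOVA over two or more groups of scalars.

    Degenerate inputs are flagged rather than propagated as NaN surprises:
    zero within-group variance with equal means is a 0/0 (error flag);
    zero within-group variance with unequal means reports F = inf, p = 0
    with its own flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DegenerateGroupsError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise DegenerateGroupsError("every group needs at least 2 values")
    if any(not np.isfinite(g).all() for g in groups):
        raise DegenerateGroupsError("non-finite values")
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [g.mean() for g in groups]
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return AnovaResult(float("nan"), float("nan"), degenerate=True)
        return AnovaResult(float("inf"), 0.0, zero_within_variance=True)
    f, p = scipy.stats.f_oneway(*groups)
    return AnovaResult(float(f), float(p))


def phase_table(
    records: pd.DataFrame,
    alpha: float = 0.05,
    indices: tuple[str, ...] = DEFAULT_INDICES,
    exclude_phases: tuple[str, ...] = ("baseline",),
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Stress-vs-control significance grid, one ANOVA per genotype × phase
    × index.

    Returns a long-format table with F, p and a significance flag at level
    ``alpha`` (Bonferroni-divided by the number of cells when requested;
    off by default, matching per-comparison testing).  Cells with a missing
    treatment group or fewer than 2 replicates are reported with status
    ``"missing"`` rather than dropped.
    """
    needed = {"genotype", "treatment", "phase"} | set(indices)
    missing_cols = needed - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns {sorted(missing_cols)}")
    genotypes = sorted(records["genotype"].unique())
    phases = [p for p in records["phase"].unique() if p not in exclude_phases]
    n_cells = len(genotypes) * len(phases) * len(indices)
    alpha_eff = alpha / n_cells if bonferroni else alpha
    rows = []
    for genotype in genotypes:
        for phase in phases:
            cell = records[(records["genotype"] == genotype) & (records["phase"] == phase)]
            for index in indices:
                groups = [
                    grp[index].dropna().to_numpy()
                    for _, grp in cell.groupby("treatment")
                ]
                row = {"genotype": genotype, "phase": phase, "index": index}
                try:
                    res = anova_one_way(groups)
                except DegenerateGroupsError as exc:
                    row.update(f=np.nan, p=np.nan, significant=False, status=f"missing ({exc})")
                else:
                    row.update(
                        f=res.f,
                        p=res.p,
                        significant=bool(res.p < alpha_eff) if np.isfinite(res.p) else False,
                        status="degenerate" if res.degenerate else "ok",
                    )
                rows.append(row)
    table = pd.DataFrame(rows)
    assert len(table) == n_cells
    return table


def regress_oi_vs_hindex(
    records: pd.DataFrame, ois: tuple[str, ...] = ("psa", "hue", "si")
) -> pd.DataFrame:
    """OLS of each optical index against the H-index over all records.

    Returns slope, intercept, r² and p per optical index.  Requires ≥ 3
    paired observations and a non-constant H-index.
    """
    if "h_index" not in records.columns:
        raise ValueError("records need an h_index column")
    rows = []
    for oi in ois:
        pair = records[["h_index", oi]].dropna()
        if len(pair) < 3:
            raise ValueError(f"{oi}: need at least 3 paired observations")
        x = pair["h_index"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("constant H-index predictor")
        res = scipy.stats.linregress(x, pair[oi].to_numpy(dtype=float))
        rows.append(
            {
                "oi": oi,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.rvalue**2,
                "p": res.pvalue,
                "n": len(pair),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter recovery

def hindex_stress_trial(
    stress_level: float,
    n_per_group: int = 6,
    seed: int = 0,
    frame: int = 48,
    noise_sd: float = 0.01,
    biological_cv: float = 0.05,
    infl_sd_nm: float = 2.0,
) -> AnovaResult:
    """One simulated stress-vs-control comparison of the H-index.

    Renders ``n_per_group`` control and ``n_per_group`` stressed pots
    (replicate-level biological variation around a common leaf model, band
    noise ``noise_sd``), pushes each cube through the full chain —
    white-panel calibration, percentile segmentation at 750 nm, mean
    signature, H-index — and returns the one-way ANOVA of the two groups.
    With ``stress_level`` 0 this is a null trial for type-I calibration;
    with the red-edge slope reduced ≥ 30% it measures detection power.
    """
    from .hypercube_io import to_reflectance as _to_reflectance
    from .spectral_index import h_index as _h, mean_signature as _mean_sig
    from .synthetic_scene import (
        ExperimentDesign,
        RedEdgeModel,
        SceneConfig,
        _pot_red_edge,
        generate_hypercube,
    )

    panel = max(6, frame // 6)
    config = SceneConfig(
        frame_rows=frame, frame_cols=frame, panel_roi=(0, 0, panel, panel)
    )
    base = RedEdgeModel(noise_sd=noise_sd)
    design = ExperimentDesign(biological_cv=biological_cv, infl_sd_nm=infl_sd_nm)
    rng = np.random.default_rng(seed)
    groups = []
    for level in (0.0, stress_level):
        values = []
        for _ in range(n_per_group):
            pot_model = _pot_red_edge(base, rng, design)
            cube_seed = int(rng.integers(2**31))
            cube, _ = generate_hypercube(config, pot_model, level, seed=cube_seed)
            ref = _to_reflectance(cube, config.panel)
            masked, _ = hyperseg.segment_cube(ref, config.panel)
            values.append(_h(_mean_sig(masked)).h_index)
        groups.append(values)
    return anova_one_way(groups)


# ---------------------------------------------------------------------------
# pipeline

@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the end-to-end analysis."""

    panel_roi: tuple[int, int, int, int] = (0, 0, 24, 24)
    panel_reflectance: float = 0.75
    apply_panel_scale: bool = True
    band_nm: float = 750.0
    percentile: float = 96.0
    px_area_cm2: float = 0.04
    alpha: float = 0.05
    bonferroni: bool = False
    indices: tuple[str, ...] = DEFAULT_INDICES
    weights_csv: str = "weights.csv"
    weather_csv: str = "weather.csv"
    seed: int = 0

    @property
    def panel(self) -> PanelRegion:
        return PanelRegion(tuple(self.panel_roi), self.panel_reflectance)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("panel_roi", "indices"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["panel_roi"] = list(d["panel_roi"])
        d["indices"] = list(d["indices"])
        return yaml.safe_dump(d, sort_keys=False)


def _phase_mean_et(weights: pd.DataFrame, design_dates: pd.Series) -> pd.DataFrame:
    """Mean daily ET per pot for the phase ending at each acquisition date."""
    et = env_metrics.et_daily(weights)
    bounds = sorted(pd.to_datetime(design_dates.unique()))
    rows = []
    for pot_id, grp in et.groupby("pot_id"):
        for i, date in enumerate(bounds):
            if i == 0:
                continue  # baseline acquisition has no preceding phase
            window = grp[(grp["date"] >= bounds[i - 1]) & (grp["date"] < date)]
            if len(window):
                rows.append({"pot_id": pot_id, "date": date, "et": window["et_g"].mean()})
    return pd.DataFrame(rows)


def _process_cube(path: Path, cfg: PipelineConfig):
    cube = read_cube(path)
    if cube.units == "radiance":
        cube = to_reflectance(cube, cfg.panel, apply_panel_scale=cfg.apply_panel_scale)
    elif cube.units != "reflectance":
        raise ValueError(f"{path.name}: cube in {cube.units} units; supply gain/offset upstream")
    masked, _mask = hyperseg.segment_cube(cube, cfg.panel, cfg.band_nm, cfg.percentile)
    sig = spectral_index.mean_signature(masked)
    h = spectral_index.h_index(sig)
    report = hyperseg.reduction_report(cube, masked)
    return h, sig, report


def _process_rgb(paths: dict[str, Path], cfg: PipelineConfig):
    import imageio.v3 as iio

    views = {
        v: rgb_index.RGBView(iio.imread(p), v, cfg.px_area_cm2) for v, p in paths.items()
    }
    return rgb_index.compute_oi_record(views, cfg.px_area_cm2)


def run_pipeline(manifest_path, config: PipelineConfig | None = None, outdir=None) -> dict:
    """Run the full analysis over an experiment manifest.

    Writes ``indices.csv`` (one row per pot per date), ``phase_table.csv``,
    ``regressions.csv``, ``vpd_daily.csv``, ``reduction.json`` (aggregated
    over all cubes) and ``run.log`` into ``outdir``.  Per-file failures are
    logged and surfaced in the returned summary; the run aborts only if
    nothing could be processed.
    """
    t0 = time.monotonic()
    cfg = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    outdir = Path(outdir) if outdir is not None else base / "results"
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start; config:\n%s", cfg.to_yaml())

    manifest = pd.read_csv(manifest_path)
    records, failures = [], []
    bytes_before = bytes_after = 0
    try:
        for row in manifest.itertuples(index=False):
            try:
                h, sig, report = _process_cube(base / row.cube_path, cfg)
                oi = _process_rgb(
                    {
                        "TV": base / row.tv_path,
                        "SV0": base / row.sv0_path,
                        "SV90": base / row.sv90_path,
                    },
                    cfg,
                )
            except Exception as exc:  # per-file failure: log, keep going
                logger.error("row %s %s failed: %s", row.pot_id, row.date, exc)
                failures.append({"pot_id": row.pot_id, "date": row.date, "error": str(exc)})
                continue
            bytes_before += report.bytes_before
            bytes_after += report.bytes_after
            records.append(
                {
                    "pot_id": row.pot_id,
                    "genotype": row.genotype,
                    "treatment": row.treatment,
                    "replicate": row.replicate,
                    "date": row.date,
                    "phase": row.phase,
                    "h_index": h.h_index,
                    "lambda_max_slope": h.lambda_max_slope,
                    "n_pixels": sig.n_pixels,
                    "psa": oi.psa,
                    "hue": oi.hue,
                    "si": oi.si,
                }
            )
        if not records:
            raise RuntimeError("no manifest row could be processed")
        indices = pd.DataFrame(records)

        weights_path = base / cfg.weights_csv
        if weights_path.exists():
            weights = env_metrics.read_weights_csv(weights_path)
            et = _phase_mean_et(weights, manifest["date"])
            et["date"] = et["date"].dt.strftime("%Y-%m-%d")
            indices = indices.merge(et, on=["pot_id", "date"], how="left")
        else:
            logger.warning("no weights file at %s; et column omitted", weights_path)
            indices["et"] = np.nan

        weather_path = base / cfg.weather_csv
        if weather_path.exists():
            vpd = env_metrics.vpd_daily(env_metrics.read_weather_csv(weather_path))
            vpd.to_csv(outdir / "vpd_daily.csv", index=False, float_format="%.6f")

        table = phase_table(
            indices, alpha=cfg.alpha, indices=cfg.indices, bonferroni=cfg.bonferroni
        )
        regressions = regress_oi_vs_hindex(indices)
        reduction = hyperseg.reduction_from_bytes(bytes_before, bytes_after)

        indices.to_csv(outdir / "indices.csv", index=False, float_format="%.9g")
        table.to_csv(outdir / "phase_table.csv", index=False, float_format="%.9g")
        regressions.to_csv(outdir / "regressions.csv", index=False, float_format="%.9g")
        (outdir / "reduction.json").write_text(reduction.to_json())
        logger.info(
            "pipeline done: %d records, %d failures, %.1f%% storage reduction, %.1fs",
            len(indices),
            len(failures),
            reduction.reduction_pct,
            time.monotonic() - t0,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "indices": indices,
        "phase_table": table,
        "regressions": regressions,
        "reduction": reduction,
        "failures": failures,
        "outdir": outdir,
    }
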