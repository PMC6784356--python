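"""End-to-end pipeline orchestration with reproducible run manifests.

Stage order: demosaic -> unmix -> calibrate -> select_bands ->
crop_and_mask -> k-means segmentation -> per-cluster model inversion ->
diagnostics.  ``process_frames`` is the in-memory library surface;
``run_pipeline`` adds file I/O (TIFF frames in, maps/tables/manifest out).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import SaturationMap, assemble_saturation_map
from .errors import OximapError, PipelineStageError
from .inversion import DEFAULT_FREE, FitConfig, fit_all_clusters
from .io import read_raw_frame, write_so2_png, write_so2_tiff
from .optics import (
    SkinParams,
    default_chromophore_table,
    read_chromophore_table,
)
from .phantom import make_sensitivity_fixture
from .preprocess import (
    DEFAULT_TARGET_BANDS,
    RawMosaicFrame,
    SensitivityMatrix,
    calibrate_reflectance,
    crop_and_mask,
    default_band_layout,
    demosaic,
    read_sensitivity_csv,
    select_bands,
    unmix,
)
from .segmentation import ClusterResult, kmeans_cluster

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths, geometry and stage settings for one pipeline run."""

    raw: str = ""
    white: str = ""
    dark: str = ""
    sensitivity: str | None = None      # CSV; None -> bundled synthetic fixture
    chromophores: str | None = None     # CSV; None -> bundled table
    output_dir: str = "oximap_run"
    bit_depth: int = 10
    mosaic_period: int = 4
    band_layout: dict | None = None     # None -> row-major position -> channel
    target_bands: tuple = DEFAULT_TARGET_BANDS
    clip: tuple = (0.0, 1.5)
    bad_pixel_tol: float = 0.01
    k: int = 10
    seed: int = 0
    n_init: int = 10
    max_iter: int = 300
    fit_starts: int = 8
    fix_melanin: float | None = None
    fix_thickness: float | None = None
    sensitivity_crosstalk: float = 0.15  # for the bundled fixture only
    write_png: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.band_layout is not None:
            cfg.band_layout = {
                tuple(map(int, k.split(","))) if isinstance(k, str) else tuple(k): v
                for k, v in cfg.band_layout.items()
            }
        return cfg

    def fit_config(self) -> FitConfig:
        free = list(DEFAULT_FREE)
        base = SkinParams(B=1e-3, SO2=0.8, M=0.02, d_e_um=90.0)
        if self.fix_melanin is not None:
            free.remove("M")
            base = replace(base, M=self.fix_melanin)
        if self.fix_thickness is not None:
            free.remove("d_e_um")
            base = replace(base, d_e_um=self.fix_thickness)
        return FitConfig(free=tuple(free), base=base, n_starts=self.fit_starts,
                         seed=self.seed)


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    saturation: SaturationMap
    clusters: ClusterResult
    fits: list
    band_centers_nm: np.ndarray
    n_flagged_fits: int
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except OximapError as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


def process_frames(raw: RawMosaicFrame, white: RawMosaicFrame,
                   dark: RawMosaicFrame, sens: SensitivityMatrix,
                   table=None, config: PipelineConfig | None = None,
                   fit_config: FitConfig | None = None) -> PipelineResult:
    """Run the full analysis chain on in-memory frames."""
    if table is None:
        table = default_chromophore_table()
    if config is None:
        config = PipelineConfig()
    if fit_config is None:
        fit_config = config.fit_config()
    centers = sens.channel_centers_nm

    cubes = _stage("demosaic")(lambda: [
        demosaic(f, band_centers_nm=centers) for f in (raw, white, dark)
    ])()
    cubes = _stage("unmix")(lambda: [unmix(c, sens) for c in cubes])()
    refl = _stage("calibrate")(calibrate_reflectance)(
        cubes[0], cubes[1], cubes[2],
        clip=config.clip, bad_pixel_tol=config.bad_pixel_tol)
    refl = _stage("select_bands")(select_bands)(refl, config.target_bands)
    refl = _stage("crop_and_mask")(crop_and_mask)(refl)
    clusters = _stage("kmeans")(kmeans_cluster)(
        refl, k=config.k, seed=config.seed, n_init=config.n_init,
        max_iter=config.max_iter)
    fits = _stage("fit_clusters")(fit_all_clusters)(
        clusters, refl.band_centers_nm, fit_config, table)
    cluster_so2 = np.array([
        f.so2_pct if f is not None else np.nan for f in fits
    ])
    sat = _stage("diagnostics")(assemble_saturation_map)(
        clusters.labels, refl.roi_mask, cluster_so2)
    n_flagged = sum(1 for f in fits if f is not None and not f.converged)
    return PipelineResult(saturation=sat, clusters=clusters, fits=fits,
                          band_centers_nm=refl.band_centers_nm,
                          n_flagged_fits=n_flagged)


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    sat, clusters = result.saturation, result.clusters

    write_so2_tiff(sat.so2_map, out / "so2_map.tiff")
    if config.write_png:
        write_so2_png(sat.so2_map, out / "so2_map.png")

    bands = result.band_centers_nm
    cl = pd.DataFrame(clusters.centroids,
                      columns=[f"R_{b:g}nm" for b in bands])
    cl.insert(0, "cluster", np.arange(clusters.K))
    cl.insert(1, "weight", clusters.weights)
    cl.to_csv(out / "clusters.csv", index=False)

    rows = []
    for k, f in enumerate(result.fits):
        if f is None:
            rows.append(dict(cluster=k, weight=0.0, B=np.nan, SO2_pct=np.nan,
                             M=np.nan, d_e_um=np.nan, residual=np.nan,
                             converged=False))
        else:
            rows.append(dict(cluster=k, weight=clusters.weights[k],
                             B=f.params.B, SO2_pct=f.so2_pct, M=f.params.M,
                             d_e_um=f.params.d_e_um,
                             residual=f.residual_norm, converged=f.converged))
    pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)

    pd.DataFrame([dict(so2_mean_pct=sat.so2_mean, so2_sd_pct=sat.so2_sd,
                       K=clusters.K, seed=config.seed)]
                 ).to_csv(out / "diagnostics.csv", index=False)

    # append-only run log (timestamped; not part of the deterministic outputs)
    log_path = out / "run_log.csv"
    entry = pd.DataFrame([dict(
        timestamp=datetime.now(timezone.utc).isoformat(),
        so2_mean_pct=sat.so2_mean, so2_sd_pct=sat.so2_sd,
        K=clusters.K, seed=config.seed)])
    entry.to_csv(log_path, mode="a", header=not log_path.exists(), index=False)

    import scipy
    import sklearn
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k != "band_layout"},
        "band_layout": {f"{r},{c}": ch for (r, c), ch
                        in (config.band_layout or default_band_layout(
                            config.mosaic_period)).items()},
        "seed": config.seed,
        "versions": {
            "oximap": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__,
            "python": platform.python_version(),
        },
        "diagnostics": {"so2_mean_pct": sat.so2_mean,
                        "so2_sd_pct": sat.so2_sd},
        "n_flagged_fits": result.n_flagged_fits,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes maps, tables and a manifest."""
    for name in ("raw", "white", "dark"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise PipelineStageError("load", f"missing {name} frame: {p!r}")
    layout = config.band_layout or default_band_layout(config.mosaic_period)
    frames = [read_raw_frame(getattr(config, n), bit_depth=config.bit_depth,
                             mosaic_period=config.mosaic_period,
                             band_layout=layout)
              for n in ("raw", "white", "dark")]
    if config.sensitivity:
        sens = read_sensitivity_csv(config.sensitivity)
    else:
        sens = make_sensitivity_fixture(crosstalk=config.sensitivity_crosstalk)
    table = (read_chromophore_table(config.chromophores)
             if config.chromophores else default_chromophore_table())
    result = process_frames(*frames, sens=sens, table=table, config=config)
    result.manifest = _write_outputs(result, config, Path(config.output_dir))
    return result
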