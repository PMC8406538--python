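"""End-to-end orchestration: simulate -> features -> morphospace ->
trajectory -> geometric model -> proliferation, with reproducible outputs.

A run writes a deterministic directory layout::

    out/
      config_echo.yaml     # config + hash (the provenance key)
      provenance.yaml      # config hash, package version, per-file listing
      labels.tif, nuclei.csv, annotations.csv, ground_truth.csv
      features.csv
      morphospace/model.json, morphospace/coords.csv
      traj/pseudotime.csv, traj/curve.json
      geo/mean_cell_params.csv, geo/scenarios.csv, geo/beta.csv
      prolif/landscape.csv
      summary.json         # headline statistics
      run.log

All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import geomodel as gm
from . import io
from . import morphospace as ms
from . import proliferation as pl
from . import shape_metrics as sm
from . import synthetic as syn
from . import trajectory as tj

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run"
    simulate: bool = True
    labels_path: str | None = None  # used when simulate is False
    nuclei_path: str | None = None
    annotations_path: str | None = None
    voxel_size_um: float | None = None
    generator: syn.GeneratorConfig = field(default_factory=syn.default_config)
    n_components: int = 5
    redundancy_threshold: float = 0.95
    trajectory_span: float = 0.6
    neighborhood_n: int = 10
    region: str | None = None  # e.g. "trunk"; None = all regions
    prolif_embryos_per_stage: int = 3
    prolif_nuclei_per_embryo: int = 40
    seed: int = 0


def _log(lines: list[str], msg: str) -> None:
    lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config)
    log: list[str] = []
    _log(log, f"notomorph {__version__} config hash {chash}")
    summary: dict = {"config_hash": chash, "version": __version__}
    files: list[str] = []

    def save_table(rel: str, df: pd.DataFrame) -> None:
        path = out / rel
        path.parent.mkdir(exist_ok=True)
        io.write_table(path, df)
        files.append(rel)

    io.write_config_echo(out / "config_echo.yaml", config)
    files.append("config_echo.yaml")

    # ---- simulate / load ----
    t0 = time.time()
    if config.simulate:
        gen_cfg = replace(config.generator, seed=config.seed)
        data = syn.generate_notochord(gen_cfg)
        volume, voxel = data.volume, data.voxel_size_um
        nuclei, annotations = data.nucleus_table, data.annotations
        io.write_label_volume(out / "labels.tif", volume, voxel)
        files.append("labels.tif")
        save_table("nuclei.csv", nuclei)
        save_table("annotations.csv", annotations)
        save_table("ground_truth.csv", data.ground_truth)
        _log(log, f"simulated {len(data.ground_truth)} cells in {time.time()-t0:.1f}s")
    else:
        if not config.labels_path or not Path(config.labels_path).exists():
            raise FileNotFoundError(
                f"labels volume not found: {config.labels_path!r} "
                "(enable simulate or point labels_path at a TIFF)"
            )
        volume, voxel = io.read_label_volume(config.labels_path)
        if config.voxel_size_um:
            voxel = config.voxel_size_um
        if not np.isfinite(voxel):
            raise ValueError("voxel size missing: set voxel_size_um")
        nuclei = (
            pd.read_csv(config.nuclei_path) if config.nuclei_path else None
        )
        annotations = (
            pd.read_csv(config.annotations_path) if config.annotations_path else None
        )
        _log(log, f"loaded labels {volume.shape} from {config.labels_path}")

    # ---- features ----
    t0 = time.time()
    cells = sm.extract_cells(volume, voxel, nuclei)
    feats = sm.feature_table(cells, annotations)
    save_table("features.csv", feats)
    _log(log, f"features for {len(feats)} cells in {time.time()-t0:.1f}s")

    # ---- morphospace ----
    t0 = time.time()
    central = feats[feats["layer"] == "central"] if "layer" in feats else feats
    if config.region:
        central = central[central["region"] == config.region]
    retained = ms.screen_redundant_features(
        feats, threshold=config.redundancy_threshold
    )
    model = ms.fit_morphospace(feats, features=retained,
                               n_components=config.n_components)
    coords = ms.embed(model, feats)
    (out / "morphospace").mkdir(exist_ok=True)
    model.to_json(out / "morphospace" / "model.json")
    files.append("morphospace/model.json")
    save_table("morphospace/coords.csv", coords)
    summary["variance_fraction"] = model.variance_fraction.tolist()
    summary["retained_features"] = retained
    _log(log, f"morphospace ({len(retained)} features) in {time.time()-t0:.1f}s")

    # ---- trajectory (central cells) ----
    t0 = time.time()
    cc = coords[coords["layer"] == "central"].reset_index(drop=True)
    if config.region:
        cc = cc[cc["region"] == config.region].reset_index(drop=True)
    labels = tj.cluster_inputs(cc, mode="stage")
    stages = sorted(cc["stage"].unique())
    traj = tj.infer_trajectory(
        cc, labels, start=stages[0], ends=stages[-1], span=config.trajectory_span
    )
    ptab = traj.as_frame(cc[["cell_id", "stage", "ap_position_norm"]])
    save_table("traj/pseudotime.csv", ptab)
    io.write_json(
        out / "traj" / "curve.json",
        {
            "lineages": [
                {"path": [int(p) for p in lin.path], "curve": lin.curve.tolist(),
                 "converged": bool(lin.converged)}
                for lin in traj.lineages
            ]
        },
    )
    files.append("traj/curve.json")
    corr = tj.stage_pseudotime_correlation(traj, cc["stage"].to_numpy())
    summary["stage_pseudotime_pearson_r"] = corr["pearson_r"]
    profile = tj.spatial_pseudotime_profile(
        traj, cc["ap_position_norm"].to_numpy(), cc["stage"].to_numpy()
    )
    save_table("traj/ap_profile.csv", profile)
    _log(log, f"trajectory r={corr['pearson_r']:.3f} in {time.time()-t0:.1f}s")

    # ---- geometric model ----
    t0 = time.time()
    geo_tab = central
    params = gm.mean_cell_params(geo_tab)
    nl = gm.neighbourhood_lengths(geo_tab, n=config.neighborhood_n)
    series = gm.IntercalationSeries(n=config.neighborhood_n, table=nl)
    scen = pd.concat(
        [gm.scenario_neighborhood(params, series, s) for s in gm.SCENARIOS],
        ignore_index=True,
    )
    save_table("geo/mean_cell_params.csv", params.table.reset_index())
    save_table("geo/beta.csv", nl.reset_index())
    save_table("geo/scenarios.csv", scen)
    summary["beta_by_stage"] = nl["beta"].to_dict()
    summary["scenario_pct_change_final"] = {
        s: float(scen[scen["scenario"] == s]["pct_change"].iloc[-1])
        for s in gm.SCENARIOS
    }
    _log(log, f"geometric model in {time.time()-t0:.1f}s")

    # ---- proliferation ----
    t0 = time.time()
    prolif = syn.generate_proliferation_table(
        stages=tuple(sorted(feats["stage"].unique())),
        embryos_per_stage=config.prolif_embryos_per_stage,
        nuclei_per_embryo=config.prolif_nuclei_per_embryo,
        seed=config.seed + 1,
    )
    prolif = pl.normalize_positions(prolif)
    lengths = prolif.groupby("stage")["axis_length_um"].mean()
    landscape = pl.build_landscape(prolif, lengths)
    save_table("prolif/landscape.csv", landscape)
    modes = pl.landscape_modes(landscape)
    save_table("prolif/modes.csv", modes)
    summary["prolif_mode_norm_by_stage"] = (
        modes[modes["marker"] == "EdU"].set_index("stage")["mode_norm"].to_dict()
    )
    _log(log, f"proliferation landscape in {time.time()-t0:.1f}s")

    io.write_json(out / "summary.json", summary)
    files.append("summary.json")
    io.write_config_echo(
        out / "provenance.yaml",
        {"config_hash": chash, "version": __version__, "files": files},
    )
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
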