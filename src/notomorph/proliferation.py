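"""Proliferation landscapes along the normalised AP axis.

EdU (S phase) and PhH3 (mitosis) labelled nuclei are mapped to a normalised
anteroposterior position per embryo, pooled per somite stage, and rescaled
to the stage's mean axis length.  The landscape is a per-stage, per-marker
Gaussian kernel density with reflective boundaries, scaled so each curve
integrates to the mean labelled-nucleus count per embryo at that stage
("mean frequency" rather than probability).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = ["normalize_positions", "build_landscape", "landscape_modes"]


def normalize_positions(table: pd.DataFrame, tolerance: float = 0.02) -> pd.DataFrame:
    """Add ``ap_norm`` = (x - anterior)/(posterior - anterior) per nucleus.

    Requires columns x_um, anterior_um, posterior_um (per-embryo axis
    references).  Values outside [0, 1] by at most ``tolerance`` are clipped
    with a warning; larger excursions are an error.
    """
    out = table.copy()
    for col in ("x_um", "anterior_um", "posterior_um"):
        if col not in out:
            raise ValueError(f"missing column {col!r}")
    if out[["anterior_um", "posterior_um"]].isna().any().any():
        bad = out.loc[
            out[["anterior_um", "posterior_um"]].isna().any(axis=1), "embryo"
        ].unique()
        raise ValueError(f"missing axis references for embryos: {list(bad)}")
    span = out["posterior_um"] - out["anterior_um"]
    if np.any(span <= 0):
        raise ValueError("anterior reference must precede posterior reference")
    p = (out["x_um"] - out["anterior_um"]) / span
    if np.any(p < -tolerance) or np.any(p > 1 + tolerance):
        worst = float(np.max(np.abs(p - np.clip(p, 0, 1))))
        raise ValueError(
            f"nucleus {worst:.3f} beyond the axis exceeds tolerance {tolerance}"
        )
    if np.any((p < 0) | (p > 1)):
        warnings.warn("clipped out-of-range normalised positions to [0, 1]")
        p = np.clip(p, 0.0, 1.0)
    out["ap_norm"] = p
    return out


def _reflected_kde(x: np.ndarray, grid: np.ndarray, lo: float, hi: float,
                   bandwidth) -> np.ndarray:
    kde = gaussian_kde(x, bw_method=bandwidth or "silverman")
    y = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
    return y


def build_landscape(
    table: pd.DataFrame,
    stage_mean_lengths: dict | pd.Series,
    bandwidth: float | None = None,
    min_nuclei: int = 5,
    grid: int = 256,
) -> pd.DataFrame:
    """Per-stage, per-marker labelled-nucleus density over the scaled axis.

    ``table`` must carry embryo, stage, marker and ``ap_norm`` (from
    :func:`normalize_positions`).  The axis for stage ``s`` spans
    [0, mean length L(s)]; each curve is scaled so its integral equals the
    mean labelled count per embryo at that stage.  (stage, marker) groups
    with fewer than ``min_nuclei`` nuclei are skipped with a warning.
    """
    if "ap_norm" not in table:
        raise ValueError("run normalize_positions first (missing ap_norm)")
    frames = []
    for (stage, marker), grp in table.groupby(["stage", "marker"]):
        length = float(
            stage_mean_lengths[stage]
            if not isinstance(stage_mean_lengths, pd.Series)
            else stage_mean_lengths.loc[stage]
        )
        if length <= 0:
            raise ValueError(f"stage {stage}: non-positive mean length")
        if len(grp) < min_nuclei:
            warnings.warn(
                f"stage {stage} marker {marker}: only {len(grp)} nuclei, skipped"
            )
            continue
        x = grp["ap_norm"].to_numpy(float) * length
        t = np.linspace(0.0, length, grid)
        y = _reflected_kde(x, t, 0.0, length, bandwidth)
        mean_count = len(grp) / grp["embryo"].nunique()
        y = y / np.trapezoid(y, t) * mean_count
        frames.append(
            pd.DataFrame(
                {
                    "stage": stage,
                    "marker": marker,
                    "position_um": t,
                    "density": y,
                    "mean_count_per_embryo": mean_count,
                }
            )
        )
    if not frames:
        raise ValueError("no (stage, marker) group had enough nuclei")
    return pd.concat(frames, ignore_index=True)


def landscape_modes(landscape: pd.DataFrame) -> pd.DataFrame:
    """Normalised AP position of each curve's density mode (peak), a compact
    summary of how the proliferative domain shifts along the axis."""
    rows = []
    for (stage, marker), grp in landscape.groupby(["stage", "marker"]):
        i = grp["density"].idxmax()
        length = grp["position_um"].max()
        rows.append(
            dict(
                stage=stage,
                marker=marker,
                mode_um=float(grp.loc[i, "position_um"]),
                mode_norm=float(grp.loc[i, "position_um"] / length),
            )
        )
    return pd.DataFrame(rows)
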