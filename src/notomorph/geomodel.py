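"""Geometric model of notochord cell and neighbourhood elongation.

A mean cell at stage ``s`` is summarised by its AP length ``l_AP(s)``,
volume ``V(s)`` and transverse cross-sectional area ``A(s)``, related by the
prism approximation

    l_AP(s) ~= V(s) / A(s).                                   (length model)

Counterfactual scenarios predict how the length of a mean starting-stage
(``s0``) cell would evolve if a single transformation acted alone:

* AP anisotropy (shape, no growth):  l(s) = V(s0) / A(s)
* isotropic growth:                  l(s) = l(s0) * (V(s)/V(s0))^(1/3)
* anisotropic growth:                l(s) = V(s) / A(s0)

Neighbourhood (group-of-n) length couples the single-cell length to an
intercalation index

    beta(s) = l_n(s) / (n * l_AP(s)),    l_n = beta * n * l_AP,

where beta = 1 is a perfect stack-of-coins (group length equals the summed
cell lengths) and beta < 1 means cells are displaced off the midline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MeanCellParams",
    "IntercalationSeries",
    "mean_cell_params",
    "ap_length_eq1",
    "scenario_ap_anisotropy",
    "scenario_isotropic_growth",
    "scenario_anisotropic_growth",
    "intercalation_index",
    "neighborhood_length_eq2",
    "scenario_neighborhood",
    "elongation_comparison",
    "neighbourhood_lengths",
    "SCENARIOS",
]

SCENARIOS = (
    "intercalation_only",
    "shape_no_growth",
    "isotropic_growth_only",
    "anisotropic_growth_only",
    "full",
)


@dataclass
class MeanCellParams:
    """Per-stage mean cell geometry (means and SEMs), stages increasing."""

    table: pd.DataFrame  # index: stage; columns l_ap, volume, area, area_bb (+ _sem)

    def __post_init__(self) -> None:
        t = self.table
        stages = t.index.to_numpy()
        if np.any(np.diff(stages) <= 0):
            raise ValueError("stages must be strictly increasing")
        for col in ("l_ap", "volume", "area"):
            if np.any(t[col].to_numpy() <= 0):
                raise ValueError(f"non-positive mean {col}")

    @property
    def stages(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def s0(self) -> int:
        return int(self.stages[0])

    def at(self, s, col: str) -> float:
        if s not in self.table.index:
            raise KeyError(f"stage {s} missing from mean-cell parameters")
        return float(self.table.loc[s, col])

    def eq1_model_error(self) -> pd.Series:
        """Relative error of the prism approximation, |l - V/A| / l, per stage."""
        t = self.table
        return (t["volume"] / t["area"] - t["l_ap"]).abs() / t["l_ap"]


@dataclass
class IntercalationSeries:
    """Measured neighbourhood lengths and intercalation index per stage."""

    n: int
    table: pd.DataFrame  # index: stage; columns l_n (+ l_n_sem), beta

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("neighbourhood size n must be >= 2")

    def beta(self, s) -> float:
        if s not in self.table.index:
            raise KeyError(f"stage {s} missing from intercalation series")
        return float(self.table.loc[s, "beta"])


def mean_cell_params(
    table: pd.DataFrame,
    stages=None,
    l_col: str = "l_ap_um",
    v_col: str = "volume_um3",
    a_col: str = "area_transverse_um2",
    abb_col: str = "area_bb_transverse_um2",
) -> MeanCellParams:
    """Arithmetic per-stage means and SEMs of the mean-cell quantities.

    The feature table should already be filtered to the region/layer of
    interest.  Each requested stage needs >= 3 cells.
    """
    if stages is None:
        stages = sorted(table["stage"].unique())
    missing = [s for s in stages if s not in set(table["stage"])]
    if missing:
        raise ValueError(f"stages missing from the table: {missing}")
    rows = {}
    for s in stages:
        grp = table[table["stage"] == s]
        if len(grp) < 3:
            raise ValueError(f"stage {s}: need >= 3 cells, got {len(grp)}")
        row = {}
        for name, col in (
            ("l_ap", l_col), ("volume", v_col), ("area", a_col), ("area_bb", abb_col)
        ):
            if col in grp:
                v = grp[col].to_numpy(float)
                row[name] = float(np.mean(v))
                row[name + "_sem"] = float(np.std(v, ddof=1) / np.sqrt(len(v)))
        rows[s] = row
    out = pd.DataFrame(rows).T
    out.index.name = "stage"
    return MeanCellParams(out)


def ap_length_eq1(volume: float, area: float) -> float:
    """Prism approximation of AP length, l = V / A."""
    volume = np.asarray(volume, float)
    area = np.asarray(area, float)
    if np.any(volume <= 0) or np.any(area <= 0):
        raise ValueError("volume and area must be positive")
    return volume / area


def scenario_ap_anisotropy(params: MeanCellParams, s) -> float:
    """Shape change without growth: area follows its measured course while
    volume stays at its starting value; l(s) = V(s0) / A(s)."""
    return float(ap_length_eq1(params.at(params.s0, "volume"), params.at(s, "area")))


def scenario_isotropic_growth(params: MeanCellParams, s) -> float:
    """Growth scales the starting cell equally in all directions:
    l(s) = l(s0) * (V(s)/V(s0))^(1/3)."""
    v0 = params.at(params.s0, "volume")
    return float(
        params.at(params.s0, "l_ap") * (params.at(s, "volume") / v0) ** (1.0 / 3.0)
    )


def scenario_anisotropic_growth(params: MeanCellParams, s) -> float:
    """Growth acts on AP length only (area frozen at s0): l(s) = V(s)/A(s0)."""
    return float(ap_length_eq1(params.at(s, "volume"), params.at(params.s0, "area")))


def intercalation_index(l_n_measured: float, n: int, l_ap_mean: float) -> float:
    """beta = l_n / (n * mean AP length); values > 1 (measurement noise on
    small groups) are clipped to 1 with a warning."""
    if n < 2:
        raise ValueError("n must be >= 2")
    l_n_measured = float(l_n_measured)
    l_ap_mean = float(l_ap_mean)
    if l_n_measured <= 0 or l_ap_mean <= 0:
        raise ValueError("lengths must be positive")
    beta = l_n_measured / (n * l_ap_mean)
    if beta > 1.0:
        warnings.warn(f"beta = {beta:.4f} > 1 clipped to 1")
        beta = 1.0
    return beta


def neighborhood_length_eq2(beta: float, n: int, l_ap_mean: float) -> float:
    """Group length of n cells at intercalation index beta: l_n = beta*n*l_AP."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must be in (0, 1]")
    if l_ap_mean <= 0:
        raise ValueError("mean AP length must be positive")
    return beta * n * l_ap_mean


def scenario_neighborhood(
    params: MeanCellParams,
    series: IntercalationSeries,
    scenario: str,
) -> pd.DataFrame:
    """Predicted neighbourhood length per stage under one scenario.

    intercalation_only       : beta(s) applied to frozen s0 cells
    shape_no_growth          : beta(s) with the constant-volume cell length
    isotropic_growth_only    : beta frozen at beta(s0), isotropic-growth length
    anisotropic_growth_only  : beta frozen at beta(s0), anisotropic-growth length
    full                     : beta(s) with the measured mean length
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    n = series.n
    s0 = params.s0
    beta0 = series.beta(s0)
    rows = []
    for s in params.stages:
        if scenario == "intercalation_only":
            beta, length = series.beta(s), params.at(s0, "l_ap")
        elif scenario == "shape_no_growth":
            beta, length = series.beta(s), scenario_ap_anisotropy(params, s)
        elif scenario == "isotropic_growth_only":
            beta, length = beta0, scenario_isotropic_growth(params, s)
        elif scenario == "anisotropic_growth_only":
            beta, length = beta0, scenario_anisotropic_growth(params, s)
        else:  # full
            beta, length = series.beta(s), params.at(s, "l_ap")
        rows.append(
            dict(stage=s, scenario=scenario, beta_used=beta, cell_length_um=length,
                 neighborhood_length_um=neighborhood_length_eq2(beta, n, length))
        )
    out = pd.DataFrame(rows)
    base = out["neighborhood_length_um"].iloc[0]
    out["pct_change"] = 100.0 * (out["neighborhood_length_um"] - base) / base
    return out


def elongation_comparison(
    neighborhood: pd.Series, tissue: pd.Series
) -> pd.DataFrame:
    """Relative-change curves at the cell (neighbourhood) and tissue scale.

    Both series are stage-indexed lengths; each is normalised to its value at
    the first shared stage.  The gap column (tissue minus neighbourhood) is
    the excess tissue elongation attributable to cell addition.
    """
    if not neighborhood.index.equals(tissue.index):
        raise ValueError("neighbourhood and tissue series must share stages")
    rel_n = neighborhood / neighborhood.iloc[0]
    rel_t = tissue / tissue.iloc[0]
    return pd.DataFrame(
        {
            "stage": neighborhood.index,
            "neighborhood_rel": rel_n.to_numpy(),
            "tissue_rel": rel_t.to_numpy(),
            "gap": (rel_t - rel_n).to_numpy(),
        }
    )


def neighbourhood_lengths(
    table: pd.DataFrame,
    n: int = 10,
    x_left_col: str | None = None,
    x_right_col: str | None = None,
    centroid_col: str = "centroid_ap_um",
    l_col: str = "l_ap_um",
) -> pd.DataFrame:
    """Measure n-cell neighbourhood AP extents from a per-cell table.

    Cells (one stage, one row/layer) are ordered by AP centroid; every
    window of n consecutive cells contributes one extent (posterior face of
    the last cell minus anterior face of the first).  Returns per-stage mean
    extent, mean cell length and the recovered intercalation index.
    """
    rows = []
    for s, grp in table.groupby("stage"):
        grp = grp.sort_values(centroid_col)
        if x_left_col and x_right_col:
            left = grp[x_left_col].to_numpy(float)
            right = grp[x_right_col].to_numpy(float)
        else:
            c = grp[centroid_col].to_numpy(float)
            l = grp[l_col].to_numpy(float)
            left, right = c - l / 2, c + l / 2
        if len(grp) < n:
            continue
        extents = [right[i + n - 1] - left[i] for i in range(len(grp) - n + 1)]
        lbar = float(np.mean(right - left))
        l_n = float(np.mean(extents))
        rows.append(
            dict(
                stage=s, n=n, l_n_um=l_n,
                l_n_sem=float(np.std(extents, ddof=1) / np.sqrt(len(extents)))
                if len(extents) > 1 else 0.0,
                l_ap_mean_um=lbar,
                beta=intercalation_index(l_n, n, lbar),
            )
        )
    if not rows:
        raise ValueError(f"no stage had >= {n} cells")
    out = pd.DataFrame(rows).set_index("stage")
    return out
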