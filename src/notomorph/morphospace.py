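"""PCA morphospace: redundancy screen, standardised PCA, embedding.

Each cell's shape feature vector is z-scored and projected onto the
eigenvectors of the feature correlation structure.  The resulting
low-dimensional "morphospace" is the coordinate system in which shape
trajectories are inferred.  Spatial position and developmental stage are
never used as features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shape_metrics import DEFAULT_PCA_FEATURES

__all__ = [
    "MorphospaceModel",
    "screen_redundant_features",
    "fit_morphospace",
    "significant_contributors",
    "embed",
    "DEFAULT_FEATURE_PRIORITY",
]

#: keep-priority for the redundancy screen: derived shape descriptors first,
#: orientation and size next, raw length-like quantities last.  When a pair
#: of features correlates above threshold the lower-priority one is dropped.
DEFAULT_FEATURE_PRIORITY = [
    "ap_anisotropy",
    "cuboidness",
    "sphericity",
    "flatness",
    "prolate_ellipticity",
    "oblate_ellipticity",
    "aspect_ap_dv",
    "aspect_ap_ml",
    "aspect_dv_ml",
    "orientation_ap",
    "orientation_dv",
    "orientation_ml",
    "nuc_disp_ap_um",
    "nuc_disp_dv_um",
    "nuc_disp_ml_um",
    "volume_um3",
    "surface_area_um2",
    "n_triangles",
    "area_transverse_um2",
    "area_bb_transverse_um2",
    "ax_a_um",
    "ax_b_um",
    "ax_c_um",
    "l_ap_um",
    "l_dv_um",
    "l_ml_um",
    "o1_um",
    "o2_um",
    "o3_um",
]

_EXCLUDED_ALWAYS = {
    "stage", "ap_position_norm", "region", "embryo", "layer", "cell_type",
    "centroid_ap_um", "centroid_dv_um", "centroid_ml_um",
}


def screen_redundant_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    threshold: float = 0.95,
    priority: list[str] | None = None,
) -> list[str]:
    """Drop one feature of every pair with |Pearson r| >= threshold.

    Removal is greedy on the most-correlated pair first; within a pair the
    feature ranked later in ``priority`` is dropped.  Constant features are
    removed up front (correlation undefined) with a warning.  Spatial
    position and stage are never considered.
    """
    if features is None:
        features = [f for f in DEFAULT_PCA_FEATURES if f in table.columns]
    features = [f for f in features if f not in _EXCLUDED_ALWAYS]
    if len(features) < 2 or len(table) < 3:
        raise ValueError("need at least 2 features and 3 cells")
    prio = priority or DEFAULT_FEATURE_PRIORITY
    rank = {f: prio.index(f) if f in prio else len(prio) + i
            for i, f in enumerate(features)}

    x = table[features].to_numpy(float)
    keep = list(features)
    sd = np.nanstd(x, axis=0)
    constant = [f for f, s in zip(features, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        warnings.warn(f"removed constant features: {constant}")
        keep = [f for f in keep if f not in constant]

    while True:
        sub = table[keep].to_numpy(float)
        ok = ~np.any(np.isnan(sub), axis=1)
        r = np.corrcoef(sub[ok], rowvar=False)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        if abs(r[i, j]) < threshold:
            break
        drop = keep[i] if rank[keep[i]] > rank[keep[j]] else keep[j]
        keep.remove(drop)
        if len(keep) < 2:
            break
    return keep


@dataclass
class MorphospaceModel:
    """Standardisation constants + loadings of a fitted morphospace."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    variance_fraction: np.ndarray  # over the retained components
    all_variance_fraction: np.ndarray  # over every component (sums to 1)
    n_cells: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def contributions(self) -> pd.DataFrame:
        """% contribution of each feature to each component (columns sum to 100)."""
        c = 100.0 * self.loadings**2
        return pd.DataFrame(
            c,
            index=self.features,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def to_json(self, path) -> None:
        obj = dict(
            features=self.features,
            mean=self.mean.tolist(),
            sd=self.sd.tolist(),
            loadings=self.loadings.tolist(),
            variance_fraction=self.variance_fraction.tolist(),
            all_variance_fraction=self.all_variance_fraction.tolist(),
            n_cells=self.n_cells,
        )
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MorphospaceModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            features=obj["features"],
            mean=np.asarray(obj["mean"]),
            sd=np.asarray(obj["sd"]),
            loadings=np.asarray(obj["loadings"]),
            variance_fraction=np.asarray(obj["variance_fraction"]),
            all_variance_fraction=np.asarray(obj["all_variance_fraction"]),
            n_cells=obj["n_cells"],
        )


def fit_morphospace(
    table: pd.DataFrame,
    features: list[str] | None = None,
    n_components: int | None = None,
) -> MorphospaceModel:
    """Z-score the features and eigendecompose their correlation structure.

    Cells with any missing retained feature are excluded listwise.  The sign
    of each component is fixed so its largest-|loading| feature loads
    positively, making embeddings reproducible.
    """
    if features is None:
        features = screen_redundant_features(table)
    x = table[features].to_numpy(float)
    ok = ~np.any(np.isnan(x), axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} cells with missing features")
    x = x[ok]
    n, p = x.shape
    if n_components is None:
        n_components = p
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} features")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [f for f, s in zip(features, sd) if s == 0]
        raise ValueError(f"constant features cannot be standardised: {bad}")
    z = (x - mean) / sd
    _, svals, vt = np.linalg.svd(z / np.sqrt(n - 1), full_matrices=False)
    eigvals = svals**2
    loadings = vt.T  # (p, p)
    # sign convention: the dominant feature of each component loads positively
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    all_frac = eigvals / eigvals.sum()
    return MorphospaceModel(
        features=list(features),
        mean=mean,
        sd=sd,
        loadings=loadings[:, :n_components],
        variance_fraction=all_frac[:n_components],
        all_variance_fraction=all_frac,
        n_cells=n,
    )


def significant_contributors(model: MorphospaceModel, component: int | str) -> list[str]:
    """Features whose contribution to the component exceeds the mean
    contribution (100 / n_features percent)."""
    if isinstance(component, str):
        if not component.upper().startswith("PC"):
            raise ValueError(f"unknown component {component!r}")
        component = int(component[2:])
    if not (1 <= component <= model.n_components):
        raise ValueError(f"component {component} not in 1..{model.n_components}")
    contrib = 100.0 * model.loadings[:, component - 1] ** 2
    cutoff = 100.0 / len(model.features)
    return [f for f, c in zip(model.features, contrib) if c > cutoff]


def embed(model: MorphospaceModel, table: pd.DataFrame) -> pd.DataFrame:
    """Project cells into morphospace; annotation columns pass through.

    Missing-feature cells are dropped (as in fitting); a feature column
    absent from ``table`` is an error naming it.
    """
    for f in model.features:
        if f not in table.columns:
            raise ValueError(f"feature {f!r} missing from table")
    x = table[model.features].to_numpy(float)
    ok = ~np.any(np.isnan(x), axis=1)
    z = (x[ok] - model.mean) / model.sd
    coords = z @ model.loadings
    out = table.loc[ok, [c for c in table.columns if c not in model.features]].copy()
    for k in range(coords.shape[1]):
        out[f"PC{k + 1}"] = coords[:, k]
    return out.reset_index(drop=True)
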