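"""Cluster-guided principal-curve trajectory inference and pseudotime.

Following the Slingshot recipe: cluster centres in morphospace are joined by
a Euclidean minimum spanning tree; paths from a start cluster to one or more
end clusters define lineages; each lineage is fitted by an iterated
principal curve (project -> order by arc length -> smooth each coordinate
against arc length -> re-parameterise).  A cell's pseudotime is the
arc-length position of its projection on its best (closest) lineage curve,
rescaled to [0, 1] per lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde, linregress, pearsonr
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TrajectoryModel",
    "Lineage",
    "cluster_inputs",
    "infer_trajectory",
    "pseudotime_density",
    "stage_pseudotime_correlation",
    "spatial_pseudotime_profile",
    "project_to_polyline",
]


# ---------------------------------------------------------------------------
# clustering inputs
# ---------------------------------------------------------------------------


def cluster_inputs(
    table: pd.DataFrame,
    mode: str = "stage",
    k: int = 6,
    seed: int = 0,
    embedding_cols: tuple[str, ...] = ("PC1", "PC2", "PC3"),
) -> np.ndarray:
    """Cluster labels guiding the MST.

    mode='stage'   : somite stage is the cluster label.
    mode='ap_bins' : k equal half-open bins of normalised AP position
                     (1-based labels; positions at 1.0 fall in bin k).
    mode='kmeans'  : seeded k-means on the embedding columns.
    """
    if mode == "stage":
        return table["stage"].to_numpy()
    if mode == "ap_bins":
        p = table["ap_position_norm"].to_numpy(float)
        labels = np.minimum(np.floor(p * k).astype(int), k - 1) + 1
        # merge empty bins into their lower neighbour
        for b in range(2, k + 1):
            if not np.any(labels == b):
                warnings.warn(f"ap bin {b} empty; merged with neighbour")
        return labels
    if mode == "kmeans":
        x = table[list(embedding_cols)].to_numpy(float)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        return km.fit_predict(x)
    raise ValueError(f"unknown cluster mode {mode!r}")


# ---------------------------------------------------------------------------
# polyline projection
# ---------------------------------------------------------------------------


def project_to_polyline(points: np.ndarray, vertices: np.ndarray):
    """Project points onto a polyline.

    Returns (arc_length_parameter, distance) per point, with the parameter
    measured along the polyline from its first vertex.
    """
    pts = np.asarray(points, float)
    v = np.asarray(vertices, float)
    seg = v[1:] - v[:-1]
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 1e-12
    v = np.vstack([v[:-1][keep], v[-1]])
    seg = v[1:] - v[:-1]
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    diff = pts[:, None, :] - v[None, :-1, :]  # (n, m, d)
    t = np.einsum("nmd,md->nm", diff, seg) / (seg_len**2)
    t = np.clip(t, 0.0, 1.0)
    proj = v[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    d2 = np.sum((pts[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(pts))
    param = cum[best] + t[rows, best] * seg_len[best]
    dist = np.sqrt(d2[rows, best])
    return param, dist


def _densify(vertices: np.ndarray, n: int = 200) -> np.ndarray:
    v = np.asarray(vertices, float)
    seg_len = np.linalg.norm(np.diff(v, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if cum[-1] <= 0:
        return v
    t = np.linspace(0.0, cum[-1], n)
    return np.column_stack([np.interp(t, cum, v[:, d]) for d in range(v.shape[1])])


# ---------------------------------------------------------------------------
# principal curve
# ---------------------------------------------------------------------------


def _extend_ends(curve: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Linearly extend the curve beyond its end vertices far enough that no
    point has to project onto a bare endpoint (princurve-style extension)."""
    v = curve
    d0 = v[0] - v[1]
    n0 = np.linalg.norm(d0)
    if n0 > 1e-12:
        d0 = d0 / n0
        over = float(np.max((pts - v[0]) @ d0, initial=0.0))
        if over > 1e-12:
            v = np.vstack([v[0] + d0 * over, v])
    d1 = v[-1] - v[-2]
    n1 = np.linalg.norm(d1)
    if n1 > 1e-12:
        d1 = d1 / n1
        over = float(np.max((pts - v[-1]) @ d1, initial=0.0))
        if over > 1e-12:
            v = np.vstack([v, v[-1] + d1 * over])
    return v


def _fit_principal_curve(
    points: np.ndarray,
    init_vertices: np.ndarray,
    span: float = 0.6,
    max_iter: int = 50,
    tol: float = 1e-4,
):
    """Iterated principal curve (local-linear smoothing of each coordinate
    against arc length).  Returns (polyline, params, distances, converged)."""
    pts = np.asarray(points, float)
    curve = _extend_ends(_densify(init_vertices), pts)
    best = None
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        param, dist = project_to_polyline(pts, curve)
        score = float(dist.mean())
        if best is None or score <= best[0]:
            best = (score, curve, param, dist)
        if prev - score < tol * max(prev, 1e-12):
            converged = True
            break
        prev = score
        order = np.argsort(param, kind="stable")
        t = param[order]
        # guard duplicate parameters for the smoother
        t = t + np.arange(len(t)) * 1e-9
        smoothed = np.column_stack(
            [
                lowess(pts[order, d], t, frac=span, it=1, xvals=t)
                for d in range(pts.shape[1])
            ]
        )
        curve = _extend_ends(smoothed, pts)
    score, curve, param, dist = best
    return curve, param, dist, converged


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class Lineage:
    path: list  # ordered cluster labels from start to end
    curve: np.ndarray  # polyline vertices
    total_length: float
    converged: bool


@dataclass
class TrajectoryModel:
    cluster_labels: np.ndarray
    cluster_centres: pd.DataFrame  # index = cluster label
    lineages: list[Lineage]
    pseudotime: np.ndarray  # per cell, in [0, 1]
    branch: np.ndarray  # per cell, lineage index
    projection_distance: np.ndarray
    embedding_cols: tuple[str, ...]

    def as_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "pseudotime": self.pseudotime,
                "branch": self.branch,
                "projection_distance": self.projection_distance,
                "cluster": self.cluster_labels,
            }
        )
        if table is not None:
            out = pd.concat([table.reset_index(drop=True), out], axis=1)
        return out


def _mst_predecessors(centres: np.ndarray, start: int) -> np.ndarray:
    d = cdist(centres, centres)
    mst = minimum_spanning_tree(d)
    graph = mst + mst.T
    _, pred = shortest_path(
        graph, directed=False, return_predecessors=True, indices=start
    )
    return pred


def _walk_to_start(pred: np.ndarray, node: int, start: int) -> list[int]:
    path = [node]
    while path[-1] != start:
        p = pred[path[-1]]
        if p < 0:
            raise ValueError("clusters are disconnected in the MST")
        path.append(int(p))
    return path


def infer_trajectory(
    embedding: pd.DataFrame,
    cluster_labels: np.ndarray,
    start: object,
    ends: object | list,
    embedding_cols: tuple[str, ...] = ("PC1", "PC2", "PC3"),
    span: float = 0.6,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> TrajectoryModel:
    """Fit one principal curve per start->end MST path and assign pseudotime.

    Cells are assigned to the lineage whose curve they project closest to
    (ties break to the lower branch index); pseudotime is the scaled
    arc-length of that projection, oriented so the start cluster precedes
    the end cluster.
    """
    cols = [c for c in embedding_cols if c in embedding.columns]
    if len(cols) < 2:
        raise ValueError(f"embedding lacks columns {embedding_cols}")
    x = embedding[cols].to_numpy(float)
    labels = np.asarray(cluster_labels)
    if len(labels) != len(x):
        raise ValueError("cluster labels do not match the embedding")
    if not isinstance(ends, (list, tuple)):
        ends = [ends]

    uniq = sorted(pd.unique(labels).tolist())
    counts = {u: int((labels == u).sum()) for u in uniq}
    small = [u for u, c in counts.items() if c < 3]
    if len(uniq) < 2 or small:
        raise ValueError(
            f"need >= 2 clusters of >= 3 cells (singletons/small: {small})"
        )
    if start not in uniq or any(e not in uniq for e in ends):
        raise ValueError("start/end clusters not present in the labels")
    centres = np.vstack([x[labels == u].mean(axis=0) for u in uniq])
    idx = {u: i for i, u in enumerate(uniq)}
    pred = _mst_predecessors(centres, idx[start])
    path_sets = []
    for end in ends:
        path_idx = _walk_to_start(pred, idx[end], idx[start])[::-1]
        path_sets.append(path_idx)
    on_any_path = set().union(*map(set, path_sets))

    # clusters off every lineage path (MST spurs) contribute their cells to
    # the lineages containing their anchor node, slingshot-style
    fit_members: list[set] = [set(p) for p in path_sets]
    for u in range(len(uniq)):
        if u in on_any_path:
            continue
        chain = _walk_to_start(pred, u, idx[start])
        anchor = next(node for node in chain[1:] if node in on_any_path)
        for members, p in zip(fit_members, path_sets):
            if anchor in p:
                members.add(u)

    lineages: list[Lineage] = []
    for path_idx, members in zip(path_sets, fit_members):
        end = uniq[path_idx[-1]]
        path = [uniq[i] for i in path_idx]
        member = np.isin(labels, [uniq[i] for i in sorted(members)])
        pts = x[member]
        init = centres[path_idx]
        curve, param, dist, conv = _fit_principal_curve(
            pts, init, span=span, max_iter=max_iter, tol=tol
        )
        if not conv:
            warnings.warn(f"principal curve for lineage -> {end} did not converge")
        # orient: start-cluster cells project before end-cluster cells
        start_mean = param[labels[member] == start].mean()
        end_mean = param[labels[member] == end].mean()
        total = float(project_to_polyline(curve[-1:], curve)[0][0])
        if start_mean > end_mean:
            curve = curve[::-1]
        lineages.append(Lineage(path=path, curve=curve, total_length=total,
                                converged=conv))

    n = len(x)
    all_param = np.empty((len(lineages), n))
    all_dist = np.empty((len(lineages), n))
    for i, lin in enumerate(lineages):
        param, dist = project_to_polyline(x, lin.curve)
        total = max(lin.total_length, 1e-12)
        all_param[i] = np.clip(param / total, 0.0, 1.0)
        all_dist[i] = dist
    branch = np.argmin(all_dist, axis=0)
    rows = np.arange(n)
    pseudotime = all_param[branch, rows]
    proj = all_dist[branch, rows]
    return TrajectoryModel(
        cluster_labels=labels,
        cluster_centres=pd.DataFrame(centres, index=uniq, columns=cols),
        lineages=lineages,
        pseudotime=pseudotime,
        branch=branch,
        projection_distance=proj,
        embedding_cols=tuple(cols),
    )


# ---------------------------------------------------------------------------
# pseudotime structure
# ---------------------------------------------------------------------------


def pseudotime_density(
    model: TrajectoryModel,
    stages: np.ndarray,
    bandwidth: float | None = None,
    grid: int = 512,
) -> pd.DataFrame:
    """Per-stage kernel density of cells over pseudotime on [0, 1].

    Each curve is renormalised to integrate to exactly 1.  Stages with fewer
    than 2 cells are skipped with a warning.  Default bandwidth is
    Silverman's rule.
    """
    stages = np.asarray(stages)
    t = np.linspace(0.0, 1.0, grid)
    frames = []
    for s in np.unique(stages):
        pt = model.pseudotime[stages == s]
        if len(pt) < 2 or np.std(pt) == 0:
            warnings.warn(f"stage {s}: fewer than 2 distinct cells, skipped")
            continue
        kde = gaussian_kde(pt, bw_method=bandwidth or "silverman")
        y = kde(t)
        norm = np.trapezoid(y, t)
        if not np.isfinite(norm) or norm <= 0:
            warnings.warn(f"stage {s}: degenerate pseudotime spread, skipped")
            continue
        y = y / norm
        frames.append(pd.DataFrame({"stage": s, "pseudotime": t, "density": y}))
    if not frames:
        raise ValueError("no stage had enough cells for a density")
    return pd.concat(frames, ignore_index=True)


def stage_pseudotime_correlation(model: TrajectoryModel, stages: np.ndarray) -> dict:
    """Cell-wise Pearson correlation between somite stage and pseudotime,
    plus per-stage mean +/- SD and the linear regression line."""
    stages = np.asarray(stages, float)
    pt = model.pseudotime
    if len(np.unique(stages)) < 2:
        raise ValueError("need at least two stages")
    if np.std(pt) == 0 or np.std(stages) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, pval = pearsonr(stages, pt)
    fit = linregress(stages, pt)
    per_stage = (
        pd.DataFrame({"stage": stages, "pseudotime": pt})
        .groupby("stage")["pseudotime"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return {
        "pearson_r": float(r),
        "p_value": float(pval),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "per_stage": per_stage,
    }


def spatial_pseudotime_profile(
    model: TrajectoryModel,
    ap_positions: np.ndarray,
    stages: np.ndarray | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean pseudotime in equal half-open AP bins, per stage.

    Empty bins are reported with NaN means.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(ap_positions, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("AP positions must lie in [0, 1]")
    bins = np.minimum(np.floor(p * n_bins).astype(int), n_bins - 1) + 1
    df = pd.DataFrame(
        {
            "bin": bins,
            "pseudotime": model.pseudotime,
            "stage": stages if stages is not None else 0,
        }
    )
    out = (
        df.groupby(["stage", "bin"])["pseudotime"]
        .agg(["mean", "count"])
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [out["stage"].unique(), range(1, n_bins + 1)], names=["stage", "bin"]
    )
    out = (
        out.set_index(["stage", "bin"]).reindex(full).reset_index()
        .rename(columns={"mean": "mean_pseudotime", "count": "n_cells"})
    )
    out["n_cells"] = out["n_cells"].fillna(0).astype(int)
    return out
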