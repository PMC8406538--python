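"""Synthetic notochord generator.

Builds labelled 3D volumes of notochord-like cells, together with ground-truth
tables, so that every downstream stage of the pipeline (shape metrics,
morphospace, trajectories, geometric model, proliferation landscapes) can be
exercised and validated without microscopy data.

Model
-----
Each cell is a superellipse-prism along the anteroposterior (AP) axis with an
optional pair of flared end flanges that imitate the transient "bowtie"
morphology of central notochord cells: wide margins at the AP faces and a
narrower waist.  Cell geometry over development is driven by piecewise-linear
*shape programs* in a scalar maturity ``m``: AP length ``l_AP(m)``, transverse
projection area ``A(m)``, DV:ML aspect ``rho(m)`` and flare ``f(m)``; volume
follows analytically from the shape family.  Maturity follows a mid-to-tips
gradient ``m = s - gamma * |p - 0.5|`` for somite stage ``s`` and normalised
AP position ``p``.

Cells are arranged single-file along AP with dorsoventral row offsets solved
so that the measured 10-cell neighbourhood length matches a per-stage
intercalation target ``beta(s)`` (beta = 1 is a perfect stack-of-coins).

Axis convention: array axes (0, 1, 2) = (AP=x, DV=y, ML=z); physical units µm;
voxel centres at (index + 0.5) * voxel_size.  AP cell faces are snapped to
voxel boundaries so that stacked arrangements are exact on the grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

__all__ = [
    "ShapeProgram",
    "GeneratorConfig",
    "SyntheticNotochord",
    "default_central_program",
    "default_muller_program",
    "default_config",
    "trunk_config",
    "generate_notochord",
    "generate_fixture_shapes",
    "random_superellipsoid_cells",
    "flare_sweep",
    "generate_proliferation_table",
    "superellipse_fill_factor",
    "superellipsoid_volume_factor",
]


def superellipse_fill_factor(p: float) -> float:
    """Area of |y|^p + |z|^p <= 1 over its bounding square, i.e. area/(4*ry*rz)."""
    return _gamma(1.0 + 1.0 / p) ** 2 / _gamma(1.0 + 2.0 / p)


def superellipsoid_volume_factor(p: float) -> float:
    """Volume of |x|^p + |y|^p + |z|^p <= 1 over its bounding box (8*rx*ry*rz)."""
    return _gamma(1.0 + 1.0 / p) ** 3 / _gamma(1.0 + 3.0 / p)


# ---------------------------------------------------------------------------
# Shape programs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeProgram:
    """Piecewise-linear cell-shape program over maturity ``m``.

    Attributes
    ----------
    knots : maturity values at which the program is specified (increasing).
    l_ap, area, dv_ml, flare : program values at the knots.  ``area`` is the
        transverse (DV-ML) projection area of the cell in µm²; ``flare`` is
        the fractional radial widening of the AP end flanges (0 = plain prism).
    exponent : superellipse squareness of the transverse cross-section
        (2 = ellipse, larger = boxier).
    flange_frac : fraction of the AP length occupied by the two end flanges
        combined (half at each end).
    """

    knots: tuple[float, ...]
    l_ap: tuple[float, ...]
    area: tuple[float, ...]
    dv_ml: tuple[float, ...]
    flare: tuple[float, ...]
    exponent: float = 4.0
    flange_frac: float = 0.3

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, float)
        if k.ndim != 1 or len(k) < 2 or np.any(np.diff(k) <= 0):
            raise ValueError("program knots must be increasing and >= 2 values")
        for name in ("l_ap", "area", "dv_ml", "flare"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != k.shape:
                raise ValueError(f"program curve {name!r} must match knots")
            if name == "flare":
                if np.any(v < 0):
                    raise ValueError("flare must be >= 0")
            elif np.any(v <= 0):
                raise ValueError(f"program curve {name!r} must be positive")

    @property
    def domain(self) -> tuple[float, float]:
        return (self.knots[0], self.knots[-1])

    def __call__(self, m: float, voxel_size: float | None = None) -> dict[str, float]:
        """Program values at maturity ``m``.

        With ``voxel_size`` the targets are expressed on the raster: the AP
        length snaps to whole voxels and the volume uses the discrete
        flange-slab split actually realised by the voxeliser.
        """
        lo, hi = self.domain
        if m < lo - 1e-9 or m > hi + 1e-9:
            raise ValueError(
                f"maturity {m:g} outside program domain [{lo:g}, {hi:g}]"
            )
        k = np.asarray(self.knots, float)
        out = {
            name: float(np.interp(m, k, np.asarray(getattr(self, name), float)))
            for name in ("l_ap", "area", "dv_ml", "flare")
        }
        if voxel_size is not None:
            out["l_ap"] = max(
                round(out["l_ap"] / voxel_size) * voxel_size, 2 * voxel_size
            )
        out["volume"] = self.volume_from(
            out["l_ap"], out["area"], out["flare"], voxel_size
        )
        return out

    def volume_from(
        self,
        l_ap: float,
        area: float,
        flare: float,
        voxel_size: float | None = None,
    ) -> float:
        """Analytic cell volume of the flanged prism realisation.

        The body cross-section is the projection area divided by (1+f)^2 so
        that the flared margins set the projected (spreading) area; flaring at
        fixed projection area therefore *reduces* volume, the signature of the
        bowtie's low cuboidness.
        With ``voxel_size`` the flange slab is split at voxel-slice
        resolution, matching the voxelised realisation.
        """
        w = self.flange_frac
        area_body = area / (1.0 + flare) ** 2
        if voxel_size is None:
            return l_ap * ((1.0 - w) * area_body + w * area)
        h = voxel_size
        nx = int(round(l_ap / h))
        xs = (np.arange(nx) + 0.5) * h - l_ap / 2.0
        n_flange = int(np.sum(np.abs(xs) > (1.0 - w) * (l_ap / 2.0)))
        return h * (area_body * (nx - n_flange) + area * n_flange)


def default_central_program() -> ShapeProgram:
    """Central-cell program: ML-elongated progenitor -> flat flared bowtie
    (transverse spreading, AP shortening, growth) -> tall stacked cuboid
    (AP elongation, flare loss)."""
    return ShapeProgram(
        knots=(2.0, 6.0, 10.0, 14.0),
        l_ap=(7.0, 8.0, 4.0, 9.0),
        area=(22.0, 30.0, 120.0, 130.0),
        dv_ml=(0.5, 0.5, 1.2, 2.0),
        flare=(0.0, 0.0, 0.35, 0.0),
        exponent=4.0,
    )


def default_muller_program(ventral: bool = False) -> ShapeProgram:
    """Müller-cell program: shared progenitor morphology, then AP elongation
    at the expense of transverse area.  The ventral row runs a slightly
    shorter variant so the two sub-rows differ in AP anisotropy."""
    scale = 0.88 if ventral else 1.0
    return ShapeProgram(
        knots=(2.0, 6.0, 10.0, 14.0),
        l_ap=(7.0, 8.0, 14.0 * scale, 20.0 * scale),
        area=(22.0, 30.0, 18.0, 12.0),
        dv_ml=(0.5, 0.5, 0.8, 1.0),
        flare=(0.0, 0.0, 0.0, 0.0),
        exponent=2.0,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    stages: tuple[int, ...] = (6, 8, 10, 12, 14)
    cells_per_stage: int | dict[int, int] = 60
    muller_per_stage: int | dict[int, int] = 20
    voxel_size_um: float = 0.5
    gradient_gamma: float = 4.0
    beta_schedule: dict[int, float] = field(
        default_factory=lambda: {6: 0.45, 8: 0.55, 10: 0.75, 12: 0.9, 14: 1.0}
    )
    central_program: ShapeProgram = field(default_factory=default_central_program)
    muller_program: ShapeProgram = field(default_factory=default_muller_program)
    muller_program_ventral: ShapeProgram = field(
        default_factory=lambda: default_muller_program(ventral=True)
    )
    noise_cv: float = 0.05
    max_roll_deg: float = 5.0
    posterior_prolif_fraction: dict[int, float] = field(
        default_factory=lambda: {6: 1.0, 8: 0.35, 10: 0.25, 12: 0.18, 14: 0.12}
    )
    ap_range: tuple[float, float] = (0.02, 0.98)
    seed: int = 0

    def n_central(self, stage: int) -> int:
        c = self.cells_per_stage
        return c[stage] if isinstance(c, dict) else c

    def n_muller(self, stage: int) -> int:
        c = self.muller_per_stage
        return c[stage] if isinstance(c, dict) else c

    def validate(self) -> None:
        if not self.stages or list(self.stages) != sorted(set(self.stages)):
            raise ValueError("stages must be a non-empty increasing sequence")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        lo, hi = self.ap_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("ap_range must satisfy 0 <= lo < hi <= 1")
        for s in self.stages:
            if self.n_central(s) < 1:
                raise ValueError(f"stage {s}: need at least one central cell")
            beta = self.beta_schedule.get(s)
            if beta is None:
                raise ValueError(f"stage {s}: missing beta in schedule")
            if not (0.0 < beta <= 1.0):
                raise ValueError(f"stage {s}: beta must be in (0, 1]")
            frac = self.posterior_prolif_fraction.get(s, 0.0)
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"stage {s}: posterior fraction must be in [0, 1]")
            # every maturity that will be evaluated must be inside the domain
            for prog in (
                self.central_program,
                self.muller_program,
                self.muller_program_ventral,
            ):
                for p in self.ap_range:
                    m = s - self.gradient_gamma * abs(p - 0.5)
                    lo_d, hi_d = prog.domain
                    if m < lo_d - 1e-9 or m > hi_d + 1e-9:
                        raise ValueError(
                            f"stage {s}: maturity {m:g} outside program domain "
                            f"[{lo_d:g}, {hi_d:g}] (reduce gradient_gamma or "
                            "extend the program knots)"
                        )


def default_config(**overrides) -> GeneratorConfig:
    """Full study conditions: five somite stages, central plus dorsal/ventral
    Müller rows, mid-to-tips maturation gradient, staged intercalation and
    posterior-restricted proliferation."""
    return GeneratorConfig(**overrides)


def trunk_config(**overrides) -> GeneratorConfig:
    """Trunk-region (40-60% AP) central-cell dataset: 5 stages x 100 cells."""
    kw = dict(
        cells_per_stage=100,
        muller_per_stage=0,
        ap_range=(0.4, 0.6),
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


# ---------------------------------------------------------------------------
# Voxelisation of one cell
# ---------------------------------------------------------------------------


def _transverse_semiaxes(area_body: float, rho: float, exponent: float):
    """Semi-axes (ry, rz) of a superellipse with area ``area_body`` and
    DV:ML extent ratio ``rho`` (ry/rz)."""
    phi = superellipse_fill_factor(exponent)
    rz = math.sqrt(area_body / (4.0 * phi * rho))
    return rho * rz, rz


def _cell_half_extents(ry: float, rz: float, flare: float, roll_rad: float):
    """DV/ML half extents of a (possibly rolled) flared cross-section."""
    c, s = abs(math.cos(roll_rad)), abs(math.sin(roll_rad))
    return (
        (c * ry + s * rz) * (1.0 + flare),
        (s * ry + c * rz) * (1.0 + flare),
    )


def _voxelize_cell(
    center,
    l_ap: float,
    ry: float,
    rz: float,
    flare: float,
    flange_frac: float,
    exponent: float,
    roll_rad: float,
    h: float,
):
    """Voxelise one flanged superellipse prism.

    Returns (mask, index_origin).  The AP faces must already lie on voxel
    boundaries (``center[0] - l_ap/2`` a multiple of ``h``); AP ownership is
    half-open so abutting cells never collide.
    """
    cx, cy, cz = center
    left = cx - l_ap / 2.0
    i0 = int(round(left / h))
    nx = int(round(l_ap / h))
    ryh, rzh = _cell_half_extents(ry, rz, flare, roll_rad)
    j0 = int(math.floor((cy - ryh) / h - 0.5)) - 1
    j1 = int(math.ceil((cy + ryh) / h - 0.5)) + 2
    k0 = int(math.floor((cz - rzh) / h - 0.5)) - 1
    k1 = int(math.ceil((cz + rzh) / h - 0.5)) + 2

    xs = (np.arange(i0, i0 + nx) + 0.5) * h - cx
    ys = (np.arange(j0, j1) + 0.5) * h - cy
    zs = (np.arange(k0, k1) + 0.5) * h - cz

    c, s = math.cos(roll_rad), math.sin(roll_rad)
    uy = c * ys[:, None] + s * zs[None, :]
    uz = -s * ys[:, None] + c * zs[None, :]

    half = l_ap / 2.0
    in_flange = np.abs(xs) > (1.0 - flange_frac) * half
    scale = np.where(in_flange, 1.0 + flare, 1.0)

    p = exponent
    base = (np.abs(uy) / ry) ** p + (np.abs(uz) / rz) ** p
    mask = base[None, :, :] <= scale[:, None, None] ** p
    return mask, (i0, j0, k0)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def _solve_spacings(lengths: np.ndarray, beta: float, n_window: int = 10):
    """Centre-to-centre AP spacings so every ``n_window``-cell window has
    extent ``beta * n_window * mean(lengths)`` (least squares, regularised
    towards the uniform solution)."""
    l = np.asarray(lengths, float)
    n = len(l)
    if n < 2:
        return np.zeros(0)
    lbar = l.mean()
    if n < n_window:
        # too few cells for a full window: scale pairwise abutment instead
        return beta * (l[:-1] + l[1:]) / 2.0
    target = beta * n_window * lbar
    d0 = np.full(n - 1, (target - lbar) / (n_window - 1))
    n_w = n - n_window + 1
    rows, cols, vals, b = [], [], [], []
    for i in range(n_w):
        for j in range(i, i + n_window - 1):
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
        b.append(target - (l[i] + l[i + n_window - 1]) / 2.0)
    m = np.zeros((n_w, n - 1))
    m[rows, cols] = vals
    b = np.asarray(b)
    lam = 1e-3
    a = np.vstack([m, math.sqrt(lam) * np.eye(n - 1)])
    rhs = np.concatenate([b, math.sqrt(lam) * d0])
    sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return np.clip(sol, 0.2 * lbar, None)


def _assign_rows(lefts: np.ndarray, rights: np.ndarray) -> np.ndarray:
    """Greedy interval colouring: overlapping x-intervals go to distinct DV
    rows (abutting intervals may share a row)."""
    rows_last = []
    out = np.zeros(len(lefts), int)
    for i in range(len(lefts)):
        placed = False
        for r, last in enumerate(rows_last):
            if lefts[i] >= last - 1e-9:
                rows_last[r] = rights[i]
                out[i] = r
                placed = True
                break
        if not placed:
            rows_last.append(rights[i])
            out[i] = len(rows_last) - 1
    return out


_ROW_OFFSETS = [0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticNotochord:
    """Output bundle of :func:`generate_notochord`."""

    volume: np.ndarray
    voxel_size_um: float
    nucleus_table: pd.DataFrame
    annotations: pd.DataFrame
    ground_truth: pd.DataFrame
    config: GeneratorConfig


@dataclass
class _PlacedCell:
    cell_id: int
    stage: int
    cell_type: str
    maturity: float
    ap_norm: float
    center: tuple[float, float, float]
    l_ap: float
    ry: float
    rz: float
    flare: float
    flange_frac: float
    exponent: float
    roll: float
    volume: float
    area: float
    beta_target: float
    prolif_label: str
    nucleus: tuple[float, float, float]


def _snap(value: float, h: float) -> float:
    return round(value / h) * h


def _realise_row(
    cfg: GeneratorConfig,
    stage: int,
    program: ShapeProgram,
    n: int,
    cell_type: str,
    beta: float,
    rng: np.random.Generator,
):
    """Geometry draws + AP placement for one single-file row (pre-offset)."""
    h = cfg.voxel_size_um
    lo, hi = cfg.ap_range
    p_norm = lo + (np.arange(n) + 0.5) * (hi - lo) / n
    maturity = stage - cfg.gradient_gamma * np.abs(p_norm - 0.5)
    cells = []
    for i in range(n):
        prog = program(maturity[i])
        if cfg.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
            eps_l, eps_a, eps_r = np.exp(rng.normal(0.0, sigma, 3))
            roll = math.radians(rng.uniform(-cfg.max_roll_deg, cfg.max_roll_deg))
        else:
            eps_l = eps_a = eps_r = 1.0
            roll = 0.0
        l = max(_snap(prog["l_ap"] * eps_l, h), 2 * h)
        area = prog["area"] * eps_a
        rho = prog["dv_ml"] * eps_r
        flare = prog["flare"]
        area_body = area / (1.0 + flare) ** 2
        ry, rz = _transverse_semiaxes(area_body, rho, program.exponent)
        vol = program.volume_from(l, area, flare, voxel_size=h)
        cells.append(
            dict(
                ap_norm=p_norm[i], maturity=maturity[i], l_ap=l, area=area,
                ry=ry, rz=rz, flare=flare, roll=roll, volume=vol,
                cell_type=cell_type, beta=beta,
            )
        )
    lengths = np.array([c["l_ap"] for c in cells])
    spac = _solve_spacings(lengths, beta)
    x = np.empty(n)
    x[0] = lengths[0] / 2.0
    for i in range(n - 1):
        x[i + 1] = x[i] + spac[i]
    # snap left faces to voxel boundaries, preserving ordering
    for i in range(n):
        left = _snap(x[i] - lengths[i] / 2.0, h)
        x[i] = left + lengths[i] / 2.0
    return cells, x


def generate_notochord(config: GeneratorConfig) -> SyntheticNotochord:
    """Generate the labelled volume plus nucleus/annotation/ground-truth
    tables for all configured stages.

    Stages are laid out as parallel blocks along the ML (z) axis of a single
    label volume; within a block, cells run anterior-to-posterior along x.
    Raises if two cells would claim the same voxel (label collision).
    """
    config.validate()
    h = config.voxel_size_um
    rng = np.random.default_rng(config.seed)
    placed: list[_PlacedCell] = []
    z_cursor = 3 * h
    cell_id = 0

    for stage in config.stages:
        beta = config.beta_schedule[stage]
        frac = config.posterior_prolif_fraction.get(stage, 0.0)
        rows_spec = [("central", config.central_program, config.n_central(stage), beta)]
        n_mul = config.n_muller(stage)
        if n_mul > 0:
            rows_spec.append(("muller_dorsal", config.muller_program, n_mul, 1.0))
            rows_spec.append(
                ("muller_ventral", config.muller_program_ventral, n_mul, 1.0)
            )

        stage_cells: list[_PlacedCell] = []
        y_central_half = 0.0
        z_half_max = 0.0
        for cell_type, program, n, row_beta in rows_spec:
            cells, x = _realise_row(config, stage, program, n, cell_type, row_beta, rng)
            lefts = x - np.array([c["l_ap"] for c in cells]) / 2.0
            rights = x + np.array([c["l_ap"] for c in cells]) / 2.0
            dv_rows = _assign_rows(lefts, rights)
            half_ext = [
                _cell_half_extents(c["ry"], c["rz"], c["flare"], c["roll"])
                for c in cells
            ]
            ry_max = max(e[0] for e in half_ext)
            pitch = 2.05 * ry_max + 4 * h
            if cell_type == "central":
                n_rows = dv_rows.max() + 1
                y_central_half = (max(_ROW_OFFSETS[:n_rows]) + 0.5) * pitch + 2 * h
            for c, xi, row, (ryh, rzh) in zip(cells, x, dv_rows, half_ext):
                if cell_type == "central":
                    y = _ROW_OFFSETS[row] * pitch
                elif cell_type == "muller_dorsal":
                    y = y_central_half + ryh + 2 * h + _ROW_OFFSETS[row] * pitch
                else:
                    y = -(y_central_half + ryh + 2 * h + _ROW_OFFSETS[row] * pitch)
                z_half_max = max(z_half_max, rzh)
                ctype = c["cell_type"]
                prolif = "none"
                if c["ap_norm"] >= 1.0 - frac - 1e-12 and ctype == "central":
                    u = rng.uniform()
                    if u < 0.55:
                        prolif = "EdU"
                    elif u < 0.67:
                        prolif = "PhH3"
                    if frac < 1.0:
                        ctype = "posterior_progenitor"
                nuc_off = rng.normal(0.0, 0.4, 3)
                nuc_off = np.clip(
                    nuc_off,
                    [-c["l_ap"] / 4, -c["ry"] / 2, -c["rz"] / 2],
                    [c["l_ap"] / 4, c["ry"] / 2, c["rz"] / 2],
                )
                cell_id += 1
                stage_cells.append(
                    _PlacedCell(
                        cell_id=cell_id, stage=stage, cell_type=ctype,
                        maturity=c["maturity"], ap_norm=c["ap_norm"],
                        center=(xi, y, 0.0), l_ap=c["l_ap"], ry=c["ry"],
                        rz=c["rz"], flare=c["flare"],
                        flange_frac=program.flange_frac,
                        exponent=program.exponent, roll=c["roll"],
                        volume=c["volume"], area=c["area"],
                        beta_target=c["beta"], prolif_label=prolif,
                        nucleus=(
                            xi + nuc_off[0], y + nuc_off[1], 0.0 + nuc_off[2]
                        ),
                    )
                )
        # shift the stage block into the global frame
        y_min = min(
            pc.center[1] - _cell_half_extents(pc.ry, pc.rz, pc.flare, pc.roll)[0]
            for pc in stage_cells
        )
        z_off = z_cursor + z_half_max
        for pc in stage_cells:
            cx, cy, cz = pc.center
            nx, ny, nz = pc.nucleus
            dy = -y_min + 5 * h
            pc.center = (cx, cy + dy, cz + z_off)
            pc.nucleus = (nx, ny + dy, nz + z_off)
        z_cursor = z_off + z_half_max + 6 * h
        placed.extend(stage_cells)

    # ---- rasterise ----
    x_max = max(pc.center[0] + pc.l_ap / 2 for pc in placed)
    y_max = max(
        pc.center[1] + _cell_half_extents(pc.ry, pc.rz, pc.flare, pc.roll)[0]
        for pc in placed
    )
    z_max = z_cursor
    shape = (
        int(math.ceil(x_max / h)) + 8,
        int(math.ceil(y_max / h)) + 8,
        int(math.ceil(z_max / h)) + 8,
    )
    dtype = np.uint16 if len(placed) < 65535 else np.uint32
    volume = np.zeros(shape, dtype=dtype)
    for pc in placed:
        mask, (i0, j0, k0) = _voxelize_cell(
            pc.center, pc.l_ap, pc.ry, pc.rz, pc.flare, pc.flange_frac,
            pc.exponent, pc.roll, h,
        )
        sl = (
            slice(i0, i0 + mask.shape[0]),
            slice(j0, j0 + mask.shape[1]),
            slice(k0, k0 + mask.shape[2]),
        )
        if min(i0, j0, k0) < 0 or any(
            s.stop > dim for s, dim in zip(sl, shape)
        ):
            raise RuntimeError(f"cell {pc.cell_id} extends outside the volume")
        region = volume[sl]
        clash = region[mask]
        if np.any(clash):
            other = int(clash[clash > 0][0]) if np.any(clash > 0) else -1
            raise RuntimeError(
                f"label collision: cell {pc.cell_id} overlaps cell {other}"
            )
        region[mask] = pc.cell_id

    # ---- tables ----
    gt = pd.DataFrame(
        {
            "cell_id": [pc.cell_id for pc in placed],
            "stage": [pc.stage for pc in placed],
            "maturity": [pc.maturity for pc in placed],
            "cell_type": [pc.cell_type for pc in placed],
            "ap_position_norm": [pc.ap_norm for pc in placed],
            "l_ap_um": [pc.l_ap for pc in placed],
            "volume_um3": [pc.volume for pc in placed],
            "area_um2": [pc.area for pc in placed],
            "beta_target": [pc.beta_target for pc in placed],
            "prolif_label": [pc.prolif_label for pc in placed],
            "x_left_um": [pc.center[0] - pc.l_ap / 2 for pc in placed],
            "x_right_um": [pc.center[0] + pc.l_ap / 2 for pc in placed],
            "centroid_ap_um": [pc.center[0] for pc in placed],
            "centroid_dv_um": [pc.center[1] for pc in placed],
            "centroid_ml_um": [pc.center[2] for pc in placed],
        }
    )
    layer = gt["cell_type"].map(
        {
            "central": "central",
            "posterior_progenitor": "central",
            "muller_dorsal": "muller_dorsal",
            "muller_ventral": "muller_ventral",
        }
    )
    annotations = pd.DataFrame(
        {
            "cell_id": gt["cell_id"],
            "embryo": ["sim-s%d" % s for s in gt["stage"]],
            "stage": gt["stage"],
            "layer": layer,
            "ap_position_norm": gt["ap_position_norm"],
            "cell_type": gt["cell_type"],
        }
    )
    nucleus_table = pd.DataFrame(
        {
            "cell_id": [pc.cell_id for pc in placed],
            "nucleus_ap_um": [pc.nucleus[0] for pc in placed],
            "nucleus_dv_um": [pc.nucleus[1] for pc in placed],
            "nucleus_ml_um": [pc.nucleus[2] for pc in placed],
        }
    )
    return SyntheticNotochord(
        volume=volume,
        voxel_size_um=h,
        nucleus_table=nucleus_table,
        annotations=annotations,
        ground_truth=gt,
        config=config,
    )


# ---------------------------------------------------------------------------
# Fixture shapes with closed-form metrics
# ---------------------------------------------------------------------------


def _fixture_cuboid(vol, label, h, origin_idx, size_um):
    n = [int(round(s / h)) for s in size_um]
    sl = tuple(slice(o, o + m) for o, m in zip(origin_idx, n))
    vol[sl] = label


def _fixture_implicit(vol, label, h, center_um, fn, rmax):
    i0 = [max(int(math.floor((c - rmax) / h)) - 1, 0) for c in center_um]
    i1 = [
        min(int(math.ceil((c + rmax) / h)) + 1, dim)
        for c, dim in zip(center_um, vol.shape)
    ]
    ax = [(np.arange(a, b) + 0.5) * h - c for a, b, c in zip(i0, i1, center_um)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    mask = fn(xx, yy, zz)
    region = vol[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    region[mask] = label


def generate_fixture_shapes(voxel_size_um: float = 0.5):
    """Axis-aligned cuboid, sphere, tri-axial ellipsoids and a rotated cuboid
    at known sizes, with a table of closed-form expected metrics.

    Returns (label volume, expected-metric table).
    """
    h = voxel_size_um
    shape = (int(120 / h), int(64 / h), int(64 / h))
    vol = np.zeros(shape, np.uint16)
    rows = []

    # 1: cuboid 20 x 10 x 5 µm, grid aligned (exact)
    _fixture_cuboid(vol, 1, h, (int(4 / h), int(4 / h), int(4 / h)), (20, 10, 5))
    rows.append(
        dict(
            label=1, shape="cuboid", volume_um3=1000.0, l_ap_um=20.0,
            l_dv_um=10.0, l_ml_um=5.0, aspect_ap_dv=2.0, aspect_ap_ml=4.0,
            aspect_dv_ml=2.0, area_um2=50.0, cuboidness=1.0,
            orientation_ap=1.0, orientation_dv=0.0, orientation_ml=0.0,
            sphericity=float("nan"), tol_rel=0.0,
        )
    )
    # 2: sphere r = 10 µm
    r = 10.0
    c2 = (60.0, 20.0, 20.0)
    _fixture_implicit(
        vol, 2, h, c2, lambda x, y, z: x * x + y * y + z * z <= r * r, r + h
    )
    rows.append(
        dict(
            label=2, shape="sphere", volume_um3=4.0 / 3.0 * math.pi * r**3,
            l_ap_um=2 * r, l_dv_um=2 * r, l_ml_um=2 * r, aspect_ap_dv=1.0,
            aspect_ap_ml=1.0, aspect_dv_ml=1.0,
            area_um2=math.pi * r * r, cuboidness=math.pi / 6.0,
            orientation_ap=float("nan"), orientation_dv=float("nan"),
            orientation_ml=float("nan"), sphericity=1.0, tol_rel=0.02,
        )
    )
    # 3: ellipsoid a=10, b=5, c=2.5 aligned with AP
    a, b, c = 10.0, 5.0, 2.5
    c3 = (20.0, 44.0, 20.0)
    _fixture_implicit(
        vol, 3, h, c3,
        lambda x, y, z: (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0, a + h,
    )
    rows.append(
        dict(
            label=3, shape="ellipsoid", volume_um3=4.0 / 3.0 * math.pi * a * b * c,
            l_ap_um=2 * a, l_dv_um=2 * b, l_ml_um=2 * c, aspect_ap_dv=2.0,
            aspect_ap_ml=4.0, aspect_dv_ml=2.0, area_um2=math.pi * b * c,
            cuboidness=math.pi / 6.0, orientation_ap=1.0, orientation_dv=0.0,
            orientation_ml=0.0, sphericity=float("nan"), tol_rel=0.02,
        )
    )
    # 4: the same ellipsoid rotated 90 deg about ML (z): major axis now DV
    c4 = (50.0, 44.0, 20.0)
    _fixture_implicit(
        vol, 4, h, c4,
        lambda x, y, z: (y / a) ** 2 + (x / b) ** 2 + (z / c) ** 2 <= 1.0, a + h,
    )
    rows.append(
        dict(
            label=4, shape="ellipsoid_rot90", volume_um3=4.0 / 3.0 * math.pi * a * b * c,
            l_ap_um=2 * b, l_dv_um=2 * a, l_ml_um=2 * c, aspect_ap_dv=0.5,
            aspect_ap_ml=2.0, aspect_dv_ml=4.0, area_um2=math.pi * a * c,
            cuboidness=math.pi / 6.0, orientation_ap=0.0, orientation_dv=1.0,
            orientation_ml=0.0, sphericity=float("nan"), tol_rel=0.02,
        )
    )
    # 5: cuboid 20 x 10 x 5 rotated 45 deg in the AP-DV plane
    c5 = (90.0, 30.0, 40.0)
    s2 = math.sqrt(0.5)

    def rot45(x, y, z):
        u = s2 * x + s2 * y
        v = -s2 * x + s2 * y
        return (np.abs(u) <= 10.0) & (np.abs(v) <= 5.0) & (np.abs(z) <= 2.5)

    _fixture_implicit(vol, 5, h, c5, rot45, 25.0)
    rows.append(
        dict(
            label=5, shape="cuboid_rot45", volume_um3=1000.0,
            l_ap_um=15 * math.sqrt(2), l_dv_um=15 * math.sqrt(2), l_ml_um=5.0,
            aspect_ap_dv=1.0, aspect_ap_ml=3 * math.sqrt(2),
            aspect_dv_ml=3 * math.sqrt(2), area_um2=float("nan"),
            cuboidness=1.0, orientation_ap=s2, orientation_dv=s2,
            orientation_ml=0.0, sphericity=float("nan"), tol_rel=0.02,
        )
    )
    return vol, pd.DataFrame(rows)


def random_superellipsoid_cells(
    n: int = 50, voxel_size_um: float = 0.5, seed: int = 0
):
    """Random tri-axial superellipsoids for oracle cross-checks.

    Yields (mask, params) where params carries the analytic volume
    ``8 * rx * ry * rz * volume_factor(p)``.
    """
    rng = np.random.default_rng(seed)
    h = voxel_size_um
    out = []
    for _ in range(n):
        rx, ry, rz = rng.uniform(4.5, 10.0, 3)
        p = rng.uniform(1.5, 5.0)

        def fn(x, y, z, rx=rx, ry=ry, rz=rz, p=p):
            return (
                (np.abs(x) / rx) ** p
                + (np.abs(y) / ry) ** p
                + (np.abs(z) / rz) ** p
            ) <= 1.0

        rmax = max(rx, ry, rz) + h
        size = int(math.ceil(2 * rmax / h)) + 4
        vol = np.zeros((size, size, size), np.uint8)
        cc = (size * h / 2,) * 3
        _fixture_implicit(vol, 1, h, cc, fn, rmax)
        analytic = 8.0 * rx * ry * rz * superellipsoid_volume_factor(p)
        out.append(
            (vol.astype(bool), dict(rx=rx, ry=ry, rz=rz, p=p, volume_um3=analytic))
        )
    return out


def flare_sweep(
    flares=(0.0, 0.1, 0.2, 0.3, 0.4),
    voxel_size_um: float = 0.25,
    l_ap: float = 6.0,
    area: float = 120.0,
    rho: float = 1.2,
):
    """A flat central-type cell at fixed AP length and projection area, with
    increasing end-flange flare.  Used to verify that flaring strictly raises
    surface area and strictly lowers cuboidness (the bowtie signature)."""
    h = voxel_size_um
    prog = default_central_program()
    masks = []
    for f in flares:
        area_body = area / (1.0 + f) ** 2
        ry, rz = _transverse_semiaxes(area_body, rho, prog.exponent)
        rmax = max(ry, rz) * (1 + f)
        c = (
            _snap(l_ap, h) * 1.5,
            math.ceil(rmax + 2) * 1.0,
            math.ceil(rmax + 2) * 1.0,
        )
        mask, origin = _voxelize_cell(
            c, _snap(l_ap, h), ry, rz, f, prog.flange_frac, prog.exponent, 0.0, h
        )
        masks.append(mask)
    return list(flares), masks


# ---------------------------------------------------------------------------
# Synthetic proliferation point tables
# ---------------------------------------------------------------------------


def generate_proliferation_table(
    stages=(6, 8, 10, 12, 14),
    embryos_per_stage: int = 3,
    nuclei_per_embryo: int = 40,
    posterior_fraction: dict[int, float] | None = None,
    axis_length_um: dict[int, float] | None = None,
    phh3_fraction: float = 0.18,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic EdU/PhH3 nucleus-position table for proliferation landscapes.

    Labelled nuclei are uniform over the proliferative AP window of each
    stage: the full axis where ``posterior_fraction`` is 1 (broad early
    division) shrinking to a posterior tip domain as the axis elongates.
    Raw coordinates are in µm with per-embryo anterior/posterior references.
    """
    posterior_fraction = posterior_fraction or {
        6: 1.0, 8: 0.35, 10: 0.25, 12: 0.18, 14: 0.12
    }
    axis_length_um = axis_length_um or {
        s: 250.0 + 45.0 * (s - 6) for s in stages
    }
    rng = np.random.default_rng(seed)
    rows = []
    for stage in stages:
        frac = posterior_fraction[stage]
        length = axis_length_um[stage]
        for e in range(embryos_per_stage):
            x_ant = rng.uniform(0.0, 30.0)
            emb_len = length * rng.normal(1.0, 0.03)
            n = rng.poisson(nuclei_per_embryo)
            p = rng.uniform(1.0 - frac, 1.0, n)
            marker = np.where(rng.uniform(size=n) < phh3_fraction, "PhH3", "EdU")
            for pi, mk in zip(p, marker):
                rows.append(
                    dict(
                        embryo=f"s{stage}e{e}", stage=stage, marker=mk,
                        x_um=x_ant + pi * emb_len, anterior_um=x_ant,
                        posterior_um=x_ant + emb_len, axis_length_um=emb_len,
                    )
                )
    return pd.DataFrame(rows)
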