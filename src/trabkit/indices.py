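"""Complexity indices computed on a trabecular skeleton graph.

Five indices summarize the cancellous architecture:

* **node density** — kernel-density estimate of skeleton-node positions on
  a regular 3D grid, in nodes/cm³; a proxy for the spatial density of
  trabecular connections.
* **trabecular angle** — the 3D angle (degrees) between a homologous
  reference axis and the unitary resultant of all branch directions;
  captures the dominant load-bearing orientation.
* **connectivity** — mean number of branches meeting at non-terminal
  nodes.
* **tortuosity** — per-branch ratio of centerline arc length to the
  straight-line distance between its end nodes (1 = straight).
* **fractal dimension** — box-counting slope over nested cubic grids on
  the skeleton point cloud; a scale-spanning complexity measure in (0, 3].
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.spatial import cKDTree

from trabkit.skeleton import SkeletonGraph, scale_graph
from trabkit.stack_io import ReferenceAxis

__all__ = [
    "DensityField",
    "IndexReport",
    "node_density",
    "trabecular_angle",
    "connectivity",
    "tortuosity",
    "fractal_dimension",
    "make_report",
    "density_colormap_slices",
]

_AXIS_NAMES = ("x", "y", "z")


@dataclass
class DensityField:
    """Node density on a regular 3D grid.

    ``values[i, j, k]`` is the density (nodes per cm³ of the working
    frame) at the cell center; the grid tiles the node bounding box.
    """

    values: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    bandwidth: np.ndarray
    scale_length: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density values must be a 3D grid")
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        self.bandwidth = np.asarray(self.bandwidth, dtype=float)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> np.ndarray:
        return (self.hi - self.lo) / np.asarray(self.values.shape)

    def cell_centers(self, axis: int) -> np.ndarray:
        m = self.values.shape[axis]
        s = self.cell_size[axis]
        return self.lo[axis] + (np.arange(m) + 0.5) * s

    def integral(self) -> float:
        """Numerical integral of the field over the grid, in node counts.

        Densities are per cm³ while the grid geometry is in working units
        (mm unless scaled), so the cell volume is divided by 1000.
        """
        cell_volume = float(np.prod(self.cell_size)) / 1000.0
        return float(self.values.sum() * cell_volume)


def node_density(
    graph: SkeletonGraph,
    grid_dims: tuple[int, int, int] = (100, 100, 100),
    scale_length: float | None = None,
    bandwidth: np.ndarray | None = None,
    support_fraction: float = 0.01,
) -> tuple[DensityField, dict[str, float]]:
    """Kernel density of skeleton nodes on a regular grid, in nodes/cm³.

    A Gaussian product kernel with per-axis normal-reference (Silverman)
    bandwidths is evaluated at the centers of a ``grid_dims`` grid tiling
    the node bounding box, then renormalized so that its discrete integral
    equals the node count (a boundary correction: nodes live in a bounded
    region, so mass escaping the box is folded back by rescaling).
    Densities are nodes per cm³ of the working frame — physical mm, or the
    dimensionless frame after division by ``scale_length``.

    Returns the field and a summary with mean/max/SD taken over the
    support cells (density above ``support_fraction`` of the maximum, so
    empty corners of the bounding box do not dilute the mean).
    """
    pts = graph.nodes
    n = pts.shape[0]
    if n < 2:
        raise ValueError("node density needs at least 2 nodes")
    if scale_length is not None:
        if scale_length <= 0:
            raise ValueError("scale_length must be positive")
        pts = pts / scale_length
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    for a in range(3):
        if hi[a] - lo[a] <= 0:
            raise ValueError(
                f"degenerate node bounding box: zero extent along {_AXIS_NAMES[a]}"
            )
    if bandwidth is None:
        sigma = pts.std(axis=0, ddof=1)
        if (sigma <= 0).any():
            a = int(np.argmin(sigma))
            raise ValueError(f"degenerate bandwidth along {_AXIS_NAMES[a]}")
        # Silverman normal-reference rule for d = 3
        bandwidth = sigma * (4.0 / (5.0 * n)) ** (1.0 / 7.0)
    bandwidth = np.broadcast_to(np.asarray(bandwidth, dtype=float), (3,)).copy()
    if (bandwidth <= 0).any():
        raise ValueError("bandwidths must be positive")

    grid_dims = tuple(int(m) for m in grid_dims)
    kernels = []
    for a in range(3):
        m = grid_dims[a]
        s = (hi[a] - lo[a]) / m
        centers = lo[a] + (np.arange(m) + 0.5) * s
        u = (centers[:, None] - pts[None, :, a]) / bandwidth[a]
        kernels.append(np.exp(-0.5 * u**2) / (bandwidth[a] * np.sqrt(2 * np.pi)))
    kx, ky, kz = kernels
    # sum over nodes of the 3D product kernel, assembled via BLAS
    xy = (kx[:, None, :] * ky[None, :, :]).reshape(-1, n)
    values = (xy @ kz.T).reshape(grid_dims)  # nodes per unit^3, un-normalized

    cell_volume = float(np.prod((hi - lo) / np.asarray(grid_dims)))
    total = float(values.sum() * cell_volume)
    values *= n / total  # renormalize: discrete integral == node count
    values *= 1000.0  # per unit^3 -> per cm^3 (1 cm^3 = 1000 mm^3)

    fld = DensityField(values=values, lo=lo, hi=hi, bandwidth=bandwidth,
                       scale_length=scale_length)
    support = values > support_fraction * values.max()
    sup_vals = values[support]
    summary = {
        "mean": float(sup_vals.mean()),
        "max": float(values.max()),
        "sd": float(sup_vals.std(ddof=0)),
        "n_support_cells": int(support.sum()),
        "n_nodes": int(n),
        "bandwidth_x": float(bandwidth[0]),
        "bandwidth_y": float(bandwidth[1]),
        "bandwidth_z": float(bandwidth[2]),
    }
    return fld, summary


def _branch_directions(graph: SkeletonGraph) -> np.ndarray:
    dirs = []
    for br in graph.branches:
        v = graph.nodes[br.node_b] - graph.nodes[br.node_a]
        norm = np.linalg.norm(v)
        if norm > 0:
            dirs.append(v / norm)
    return np.asarray(dirs).reshape(-1, 3)


def _major_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def trabecular_angle(
    graph: SkeletonGraph, axis: ReferenceAxis | str = "major"
) -> dict[str, Any]:
    """Angle (degrees) between the reference axis and the resultant
    trabecular direction.

    Each branch direction (end node minus start node, normalized) is
    axial — a trabecula has no intrinsic verse — so every unit vector is
    flipped into the hemisphere of the reference axis before the vector
    sum. The angle is ``arccos(|r·â| / ‖r‖)``, in [0, 90]. Pass
    ``axis="major"`` to reference the principal axis of the node cloud.

    Also reports the percentage contribution of each coordinate-axis
    component of the unit resultant.
    """
    dirs = _branch_directions(graph)
    if dirs.shape[0] == 0:
        raise ValueError("no branch with distinct endpoints: angle undefined")
    if isinstance(axis, str):
        if axis != "major":
            raise ValueError(f"axis must be a ReferenceAxis or 'major', got {axis!r}")
        ax = _major_axis(graph.nodes)
        axis_source = "major"
    else:
        ax = axis.direction
        axis_source = "reference"
    flip = (dirs @ ax) < 0
    dirs = np.where(flip[:, None], -dirs, dirs)
    resultant = dirs.sum(axis=0)
    norm = np.linalg.norm(resultant)
    if norm < 1e-12:
        raise ValueError("indeterminate direction: trabecular directions cancel out")
    unit = resultant / norm
    cosang = np.clip(abs(float(unit @ ax)), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    contrib = np.abs(unit) / np.abs(unit).sum() * 100.0
    return {
        "angle_deg": angle,
        "resultant": unit,
        "contributions_pct": contrib,
        "n_directions": int(dirs.shape[0]),
        "axis_source": axis_source,
        "axis_direction": np.asarray(ax, dtype=float),
    }


def connectivity(graph: SkeletonGraph) -> dict[str, Any]:
    """Mean branches per node over non-terminal nodes (degree >= 2).

    Terminal nodes are excluded from the average; a self-loop contributes
    2 to its node's degree and is reported in ``n_self_loops``.
    """
    deg = graph.degrees()
    nonterminal = deg[deg >= 2]
    if nonterminal.size == 0:
        raise ValueError("no non-terminal nodes: connectivity undefined")
    return {
        "mean": float(nonterminal.mean()),
        "sd": float(nonterminal.std(ddof=0)),
        "degrees": deg,
        "n_nonterminal": int(nonterminal.size),
        "n_terminal": int((deg == 1).sum()),
        "n_self_loops": graph.n_self_loops,
    }


def tortuosity(graph: SkeletonGraph) -> dict[str, Any]:
    """Per-branch arc length over chord length; 1 is a straight branch.

    Branches whose end nodes coincide (self-loops: chord 0, tortuosity
    formally infinite) are excluded from the mean and counted in
    ``n_excluded``.
    """
    values = []
    n_excluded = 0
    for br in graph.branches:
        chord = br.chord_length
        if chord <= 0:
            n_excluded += 1
            continue
        values.append(br.arc_length / chord)
    if not values:
        raise ValueError("all branches excluded: tortuosity undefined")
    vals = np.asarray(values)
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0)),
        "values": vals,
        "n_included": int(vals.size),
        "n_excluded": int(n_excluded),
    }


def _skeleton_points(graph: SkeletonGraph) -> np.ndarray:
    if not graph.branches:
        return graph.nodes.copy()
    return np.vstack([br.polyline for br in graph.branches])


def fractal_dimension(
    graph: SkeletonGraph,
    n_scales: int | None = None,
    scale_length: float | None = None,
) -> dict[str, Any]:
    """Box-counting fractal dimension of the skeleton point cloud.

    Cubic cells anchored at the bounding-box minimum corner, with side
    halving from the long bounding-box side down to 4x the median
    nearest-neighbor spacing of the (deduplicated) points — below that,
    counts saturate and flatten the fit. The dimension is the ordinary
    least-squares slope of log N(s) against log(1/s); the per-scale table
    and R² are returned for diagnostics.
    """
    pts = _skeleton_points(graph)
    if scale_length is not None:
        if scale_length <= 0:
            raise ValueError("scale_length must be positive")
        pts = pts / scale_length
    pts = np.unique(np.round(pts, 12), axis=0)
    if pts.shape[0] < 2:
        raise ValueError("box counting needs at least 2 distinct points")
    if n_scales is not None and n_scales < 3:
        raise ValueError("n_scales must be >= 3")
    lo = pts.min(axis=0)
    extent = pts.max(axis=0) - lo
    long_side = float(extent.max())
    if long_side <= 0:
        raise ValueError("degenerate point set: zero extent on every axis")

    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    stop_scale = 4.0 * float(np.median(dists[:, 1]))

    scales = []
    s = long_side
    while s >= stop_scale and s > 0:
        scales.append(s)
        if n_scales is not None and len(scales) >= n_scales:
            break
        s /= 2.0
    if len(scales) < 3:
        raise ValueError(
            f"fewer than 3 usable scales between the bounding box ({long_side:.4g}) "
            f"and the saturation scale ({stop_scale:.4g})"
        )

    counts = []
    for s in scales:
        m = np.maximum(np.ceil(extent / s).astype(int), 1)  # cells per axis
        idx = np.floor((pts - lo) / s).astype(int)
        idx = np.minimum(idx, m - 1)  # final cell along each axis is closed
        counts.append(int(np.unique(idx, axis=0).shape[0]))

    x = np.log(1.0 / np.asarray(scales))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "fd": float(slope),
        "scales": np.asarray(scales),
        "counts": np.asarray(counts),
        "r2": r2,
        "stop_scale": stop_scale,
    }


@dataclass
class IndexReport:
    """Per-specimen summary of the five complexity indices.

    Indices that could not be computed are None, with the reason in
    ``missing``.
    """

    specimen: str = "specimen"
    mean_node_density: float | None = None
    max_node_density: float | None = None
    sd_node_density: float | None = None
    mean_node_density_unscaled: float | None = None
    trabecular_angle: float | None = None
    mean_tortuosity: float | None = None
    sd_tortuosity: float | None = None
    mean_connectivity: float | None = None
    sd_connectivity: float | None = None
    fractal_dimension: float | None = None
    n_nodes: int = 0
    n_branches: int = 0
    n_terminal_nodes: int = 0
    n_excluded_branches: int = 0
    scale_length: float | None = None
    axis_source: str | None = None
    missing: dict[str, str] = dc_field(default_factory=dict)

    _COLUMNS = (
        "specimen",
        "mean_node_density",
        "max_node_density",
        "sd_node_density",
        "trabecular_angle",
        "mean_tortuosity",
        "sd_tortuosity",
        "mean_connectivity",
        "sd_connectivity",
        "fractal_dimension",
        "n_nodes",
        "n_branches",
        "n_terminal_nodes",
        "n_excluded_branches",
        "scale_length",
        "axis_source",
    )

    def to_frame(self):
        import pandas as pd

        row = {c: getattr(self, c) for c in self._COLUMNS}
        row["missing"] = ";".join(f"{k}:{v}" for k, v in sorted(self.missing.items()))
        return pd.DataFrame([row])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def make_report(
    graph: SkeletonGraph,
    axis: ReferenceAxis | str = "major",
    scale_length: float | None = None,
    specimen: str = "specimen",
    grid_dims: tuple[int, int, int] = (100, 100, 100),
) -> tuple[IndexReport, DensityField | None]:
    """Compute all five indices and assemble a report row.

    Node density and fractal dimension are computed on the skeleton scaled
    by ``scale_length`` when one is given (size correction against a
    homologous measurement such as femoral-head height); the angle,
    connectivity and tortuosity are scale-invariant. Sub-indices that fail
    are reported as missing with the reason rather than aborting the run.
    """
    report = IndexReport(
        specimen=specimen,
        n_nodes=graph.n_nodes,
        n_branches=graph.n_branches,
        scale_length=scale_length,
    )
    deg = graph.degrees()
    report.n_terminal_nodes = int((deg == 1).sum())

    density_field: DensityField | None = None
    try:
        density_field, summ = node_density(graph, grid_dims=grid_dims,
                                           scale_length=scale_length)
        report.mean_node_density = summ["mean"]
        report.max_node_density = summ["max"]
        report.sd_node_density = summ["sd"]
        if scale_length is not None:
            _, summ_u = node_density(graph, grid_dims=grid_dims)
            report.mean_node_density_unscaled = summ_u["mean"]
        else:
            report.mean_node_density_unscaled = summ["mean"]
    except ValueError as exc:
        report.missing["node_density"] = str(exc)

    try:
        ang = trabecular_angle(graph, axis=axis)
        report.trabecular_angle = ang["angle_deg"]
        report.axis_source = ang["axis_source"]
    except ValueError as exc:
        report.missing["trabecular_angle"] = str(exc)

    try:
        conn = connectivity(graph)
        report.mean_connectivity = conn["mean"]
        report.sd_connectivity = conn["sd"]
    except ValueError as exc:
        report.missing["connectivity"] = str(exc)

    try:
        tort = tortuosity(graph)
        report.mean_tortuosity = tort["mean"]
        report.sd_tortuosity = tort["sd"]
        report.n_excluded_branches = tort["n_excluded"]
    except ValueError as exc:
        report.missing["tortuosity"] = str(exc)

    try:
        fd = fractal_dimension(graph, scale_length=scale_length)
        report.fractal_dimension = fd["fd"]
    except ValueError as exc:
        report.missing["fractal_dimension"] = str(exc)

    return report, density_field


_PLANE_AXIS = {"parasagittal": 0, "coronal": 1, "axial": 2}


def density_colormap_slices(
    field: DensityField,
    plane: str,
    position: float,
    path: str | Path,
    axis_labels: tuple[str, str] | None = None,
    cmap: str = "jet",
) -> Path:
    """Render one plane of the density grid as a blue-to-red color map.

    ``position`` is the fractional location of the slice along the plane
    normal (0 = first cell, 1 = last). Writes a PNG with a color bar.
    """
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}, got {plane!r}")
    if not (0.0 <= position <= 1.0):
        raise ValueError(f"position must be in [0, 1], got {position}")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axis = _PLANE_AXIS[plane]
    m = field.values.shape[axis]
    k = min(int(round(position * (m - 1))), m - 1)
    sl = np.take(field.values, k, axis=axis)
    rem = [a for a in range(3) if a != axis]

    fig, ax = plt.subplots(figsize=(5, 4.2))
    extent = (field.lo[rem[0]], field.hi[rem[0]], field.lo[rem[1]], field.hi[rem[1]])
    im = ax.imshow(sl.T, origin="lower", cmap=cmap, extent=extent, aspect="equal")
    labels = axis_labels or (_AXIS_NAMES[rem[0]], _AXIS_NAMES[rem[1]])
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.set_title(f"node density, {plane} slice at {position:.0%}")
    fig.colorbar(im, ax=ax, label="nodes/cm³")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
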