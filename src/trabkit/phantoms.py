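"""Synthetic bone phantoms with exact ground truth.

A phantom is a cortical-like shell (ellipsoid or cylinder) enclosing a
lattice of rods standing in for trabeculae. Because the rods are
rasterized from analytic centerlines, the generator also yields the exact
compartment masks and the designed skeleton graph, so segmentation,
skeletonization and every index can be validated without any scan data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from trabkit.morphology import BoneCompartments
from trabkit.skeleton import Branch, SkeletonGraph
from trabkit.stack_io import ImageStack

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "degrade", "dice_coefficient"]


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary arrays."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


@dataclass
class PhantomSpec:
    """Geometry of a synthetic shell + rod-lattice phantom (voxel units)."""

    # semi-axes leave > 12 voxels of margin to the volume border so the
    # iterated closings of the isolation protocol are not clipped
    dims: tuple[int, int, int] = (96, 96, 96)
    outer_shape: str = "cylinder"
    semi_axes: tuple[float, float, float] = (34.0, 34.0, 36.0)
    shell_thickness: float = 4.0
    lattice_type: str = "cubic_rods"
    lattice_spacing: float = 14.0
    rod_radius: float = 2.0
    # rods parallel to the wall keep this clearance from it: trabeculae
    # attach to the cortex transversally, they do not run along it
    wall_clearance: float = 4.0
    n_random_rods: int = 30
    rod_waviness_amplitude: float = 0.0
    rod_waviness_wavelength: float = 20.0
    noise: float = 0.0
    spacing_mm: tuple[float, float, float] = (0.03, 0.03, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_shape not in ("ellipsoid", "cylinder"):
            raise ValueError(f"unknown outer_shape {self.outer_shape!r}")
        if self.lattice_type not in ("cubic_rods", "random_rods", "none"):
            raise ValueError(f"unknown lattice_type {self.lattice_type!r}")
        if self.shell_thickness < 1:
            raise ValueError("shell_thickness must be >= 1 voxel")
        if self.lattice_type != "none" and self.lattice_spacing <= 2 * self.rod_radius:
            raise ValueError("lattice_spacing must exceed twice the rod radius")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise rate must be in [0, 1)")
        if self.rod_waviness_amplitude < 0 or self.rod_waviness_wavelength <= 0:
            raise ValueError("waviness amplitude must be >= 0 and wavelength > 0")


@dataclass
class PhantomTruth:
    """Exact masks, designed skeleton graph and blueprint statistics."""

    compartments: BoneCompartments
    graph: SkeletonGraph
    blueprint_stats: dict[str, Any] = field(default_factory=dict)


def _region_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solid outer mask, inner (medullary) mask and their center."""
    dims = spec.dims
    center = (np.asarray(dims, dtype=float) - 1.0) / 2.0
    x = np.arange(dims[0])[:, None, None] - center[0]
    y = np.arange(dims[1])[None, :, None] - center[1]
    z = np.arange(dims[2])[None, None, :] - center[2]
    a, b, c = spec.semi_axes
    t = spec.shell_thickness
    ai, bi, ci = a - t, b - t, c - t
    if min(ai, bi, ci) <= 0:
        raise ValueError("shell thickness leaves no interior")
    if spec.outer_shape == "ellipsoid":
        outer = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
        inner = (x / ai) ** 2 + (y / bi) ** 2 + (z / ci) ** 2 <= 1.0
    else:  # cylinder with axis along z
        radial_o = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        radial_i = (x / ai) ** 2 + (y / bi) ** 2 <= 1.0
        outer = radial_o & (np.abs(z) <= c)
        inner = radial_i & (np.abs(z) <= ci)
    return outer, inner, center


def _inner_halfspan(spec: PhantomSpec, axis: int, u: float, v: float) -> float | None:
    """Half-extent of the inner region along `axis` at transverse offsets
    (u, v) from the center; None when the transverse point is outside."""
    a, b, c = spec.semi_axes
    t = spec.shell_thickness
    semis = (a - t, b - t, c - t)
    others = [i for i in range(3) if i != axis]
    su, sv = semis[others[0]], semis[others[1]]
    q = (u / su) ** 2 + (v / sv) ** 2
    if spec.outer_shape == "cylinder":
        if axis == 2:
            return semis[2] if q <= 1.0 else None
        # horizontal rod in a cylinder: span limited by the radial wall
        # solve ((x)/sx)^2 + (w/sw)^2 = 1 where w is the in-plane offset
        radial_other = others[0] if others[0] != 2 else others[1]
        w = u if others[0] == radial_other else v
        # also require |z-offset| <= ci
        zoff = v if others[1] == 2 else (u if others[0] == 2 else None)
        if zoff is not None and abs(zoff) > semis[2]:
            return None
        sw = semis[radial_other]
        rem = 1.0 - (w / sw) ** 2
        if rem <= 0:
            return None
        return semis[axis] * float(np.sqrt(rem))
    # ellipsoid
    rem = 1.0 - q
    if rem <= 0:
        return None
    return semis[axis] * float(np.sqrt(rem))


def _lattice_positions(spec: PhantomSpec, axis: int, center: np.ndarray) -> np.ndarray:
    """Absolute lattice-plane coordinates along one axis.

    Anchored at the integer voxel nearest the volume center so rod
    centerlines sit on voxel rows (odd rasterized width keeps the
    thinning symmetric)."""
    a = spec.semi_axes[axis] - spec.shell_thickness
    kmax = int(
        np.floor((a - spec.rod_radius - spec.wall_clearance - 0.5) / spec.lattice_spacing)
    )
    anchor = float(np.round(center[axis]))
    return anchor + np.arange(-kmax, kmax + 1) * spec.lattice_spacing


def _axial_span(
    spec: PhantomSpec, axis: int, u_abs: float, v_abs: float, center: np.ndarray
) -> tuple[float, float] | None:
    """Absolute (tmin, tmax) of the inner region along ``axis`` for a rod
    at absolute transverse coordinates (u_abs, v_abs); None if outside."""
    others = [i for i in range(3) if i != axis]
    half = _inner_halfspan(spec, axis, u_abs - center[others[0]], v_abs - center[others[1]])
    if half is None:
        return None
    return (center[axis] - half, center[axis] + half)


def _wavy_offset(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    A = spec.rod_waviness_amplitude
    lam = spec.rod_waviness_wavelength
    return A * np.sin(2.0 * np.pi * t / lam)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Rasterize the phantom and build its exact ground truth.

    Rods are rasterized by distance to their analytic centerline (within
    each transverse slice), so the truth polylines are exact centerlines.
    Deterministic for a given spec (the seed drives random rods only).
    """
    outer, inner, center = _region_masks(spec)
    dims = spec.dims
    rods = np.zeros(dims, dtype=bool)
    r2 = spec.rod_radius**2

    coords = [np.arange(d, dtype=float) for d in dims]

    def paint_axial_rod(axis: int, u: float, v: float) -> None:
        """Rod whose centerline runs along `axis` at absolute transverse
        coordinates (u, v) (first coordinate gets the sinusoidal wobble)."""
        others = [i for i in range(3) if i != axis]
        t = coords[axis] - center[axis]
        cu = u + _wavy_offset(spec, t)
        cv = v
        du = coords[others[0]][:, None] - cu[None, :]  # (dim_u, dim_axis)
        dv = coords[others[1]] - cv  # (dim_v,), cv constant along the rod
        dist2 = du[:, None, :] ** 2 + (dv**2)[None, :, None]
        tube = dist2 <= r2  # axes ordered (u, v, axis)
        order = np.argsort(others + [axis])
        rods_axis = np.transpose(tube, axes=order)
        np.logical_or(rods, rods_axis, out=rods)

    rng = np.random.default_rng(spec.seed)
    graph_nodes: list[np.ndarray] = []
    graph_branches: list[tuple[int, int, np.ndarray]] = []
    blueprint: dict[str, Any] = {}

    if spec.lattice_type == "cubic_rods":
        positions = [_lattice_positions(spec, a, center) for a in range(3)]
        if any(len(p) == 0 for p in positions):
            raise ValueError("lattice does not fit inside the shell interior")
        # paint rods along each axis through every transverse lattice point
        for axis in range(3):
            others = [i for i in range(3) if i != axis]
            for u in positions[others[0]]:
                for v in positions[others[1]]:
                    if _axial_span(spec, axis, u, v, center) is not None:
                        paint_axial_rod(axis, u, v)
        _build_lattice_truth(spec, positions, center, graph_nodes, graph_branches, blueprint)
    elif spec.lattice_type == "random_rods":
        _paint_random_rods(spec, rng, center, rods, graph_nodes, graph_branches, blueprint)
    else:
        blueprint["junction_count"] = 0

    rods &= inner
    binary_vox = (outer & ~inner) | rods
    spacing = spec.spacing_mm

    def mk(vox: np.ndarray) -> ImageStack:
        return ImageStack(vox.astype(np.uint8), spacing=spacing, is_binary=True)

    binary = mk(binary_vox)
    compartments = BoneCompartments(
        binary=binary,
        mask=mk(outer),
        voids=mk(inner & ~rods),
        interior=mk(inner),
        cortical=mk(outer & ~inner),
        cancellous=mk(inner & rods),
    )

    if graph_nodes:
        nodes_mm = np.asarray(graph_nodes) * np.asarray(spacing)
        branches = [
            Branch(node_a=a, node_b=b, polyline=poly * np.asarray(spacing))
            for a, b, poly in graph_branches
        ]
        graph = SkeletonGraph(nodes=nodes_mm, branches=branches, provenance="computed")
    else:
        graph = SkeletonGraph(nodes=np.empty((0, 3)), branches=[])

    if graph.n_branches:
        torts = []
        for br in graph.branches:
            if br.chord_length > 0:
                torts.append(br.arc_length / br.chord_length)
        blueprint["designed_tortuosity_mean"] = float(np.mean(torts)) if torts else None
        deg = graph.degrees()
        nonterm = deg[deg >= 2]
        blueprint["designed_connectivity_mean"] = (
            float(nonterm.mean()) if nonterm.size else None
        )
    truth = PhantomTruth(compartments=compartments, graph=graph, blueprint_stats=blueprint)
    return binary, truth


def _sample_rod_polyline(
    spec: PhantomSpec, axis: int, u: float, v: float, t0: float, t1: float,
    center: np.ndarray, n: int = 64,
) -> np.ndarray:
    """Centerline polyline (absolute voxel coords) of an axial rod segment
    between absolute stations t0..t1, at absolute transverse (u, v)."""
    t = np.linspace(t0, t1, max(n, 2))
    others = [i for i in range(3) if i != axis]
    pts = np.empty((t.size, 3))
    pts[:, axis] = t
    pts[:, others[0]] = u + _wavy_offset(spec, t - center[axis])
    pts[:, others[1]] = v
    return pts


def _build_lattice_truth(
    spec: PhantomSpec,
    offs: list[np.ndarray],
    center: np.ndarray,
    nodes: list[np.ndarray],
    branches: list[tuple[int, int, np.ndarray]],
    blueprint: dict[str, Any],
) -> None:
    """Designed skeleton of the cubic rod lattice: junctions at lattice
    intersections, terminals where rods meet the inner wall."""
    node_index: dict[tuple[float, float, float], int] = {}

    def add_node(p: np.ndarray) -> int:
        key = tuple(np.round(p, 6))
        if key not in node_index:
            node_index[key] = len(nodes)
            nodes.append(np.asarray(p, dtype=float))
        return node_index[key]

    junction_keys = set()
    for px in offs[0]:
        for py in offs[1]:
            for pz in offs[2]:
                p = np.asarray([px, py, pz])
                n_rods_through = 0
                for a in range(3):
                    others = [i for i in range(3) if i != a]
                    span = _axial_span(spec, a, p[others[0]], p[others[1]], center)
                    if span is not None and span[0] < p[a] < span[1]:
                        n_rods_through += 1
                if n_rods_through >= 2:
                    junction_keys.add(tuple(np.round(p, 6)))
                    add_node(p)
    blueprint["junction_count"] = len(junction_keys)

    for axis in range(3):
        others = [i for i in range(3) if i != axis]
        for u in offs[others[0]]:
            for v in offs[others[1]]:
                span = _axial_span(spec, axis, u, v, center)
                if span is None:
                    continue
                # stations along the rod: wall, junctions on it, wall
                stations: list[tuple[float, tuple | None]] = [(span[0], None)]
                for t in offs[axis]:
                    p3 = np.empty(3)
                    p3[axis] = t
                    p3[others[0]] = u
                    p3[others[1]] = v
                    key = tuple(np.round(p3, 6))
                    if key in junction_keys and span[0] < t < span[1]:
                        stations.append((float(t), key))
                stations.append((span[1], None))
                stations = sorted(set(stations))
                for (t0, k0), (t1, k1) in zip(stations[:-1], stations[1:]):
                    poly = _sample_rod_polyline(spec, axis, u, v, t0, t1, center)
                    # junction stations snap to the designed node position
                    if k0 is not None:
                        poly[0] = np.asarray(k0)
                        a = node_index[k0]
                    else:
                        a = add_node(poly[0])
                    if k1 is not None:
                        poly[-1] = np.asarray(k1)
                        b = node_index[k1]
                    else:
                        b = add_node(poly[-1])
                    branches.append((a, b, poly))


def _paint_random_rods(
    spec: PhantomSpec,
    rng: np.random.Generator,
    center: np.ndarray,
    rods: np.ndarray,
    nodes: list[np.ndarray],
    branches: list[tuple[int, int, np.ndarray]],
    blueprint: dict[str, Any],
) -> None:
    """Random straight chords through the interior, painted voxel-exactly
    by distance to the segment."""
    semis = np.asarray(spec.semi_axes) - spec.shell_thickness
    coords = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in spec.dims], indexing="ij"),
        axis=-1,
    )
    n_painted = 0
    attempts = 0
    while n_painted < spec.n_random_rods and attempts < spec.n_random_rods * 20:
        attempts += 1
        p = center + (rng.random(3) - 0.5) * semis  # interior point
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        # march to the inner wall in both directions
        ts = np.linspace(-2 * semis.max(), 2 * semis.max(), 512)
        pts = p[None, :] + ts[:, None] * d[None, :]
        rel = (pts - center) / semis
        if spec.outer_shape == "cylinder":
            inside = (rel[:, 0] ** 2 + rel[:, 1] ** 2 <= 1.0) & (np.abs(rel[:, 2]) <= 1.0)
        else:
            inside = (rel**2).sum(axis=1) <= 1.0
        if not inside.any():
            continue
        seg = pts[inside]
        a, b = seg[0], seg[-1]
        if np.linalg.norm(b - a) < 4 * spec.rod_radius:
            continue
        # paint by distance to the segment
        ap = coords - a
        ab = b - a
        tproj = np.clip((ap @ ab) / (ab @ ab), 0.0, 1.0)
        nearest = a + tproj[..., None] * ab
        dist2 = ((coords - nearest) ** 2).sum(axis=-1)
        np.logical_or(rods, dist2 <= spec.rod_radius**2, out=rods)
        ia = len(nodes)
        nodes.append(a)
        ib = len(nodes)
        nodes.append(b)
        branches.append((ia, ib, np.linspace(a, b, 32)))
        n_painted += 1
    blueprint["junction_count"] = 0
    blueprint["n_rods"] = n_painted


def degrade(
    stack: ImageStack,
    noise_rate: float = 0.01,
    blur_sigma: float = 1.0,
    seed: int = 0,
) -> ImageStack:
    """Render a binary phantom as noisy grayscale, emulating acquisition.

    Foreground maps to 200, background to 10 (8-bit); salt-and-pepper
    noise flips a ``noise_rate`` fraction of voxels to 255 or 0, then a
    Gaussian blur of ``blur_sigma`` voxels stands in for the scanner PSF
    and reconstruction smoothing (which is what keeps isolated noise
    voxels from surviving a global threshold, as in real reconstructions).
    Deterministic for a given seed. No attempt is made at physical μCT
    artifacts (beam hardening, rings).
    """
    if not (0.0 <= noise_rate < 1.0):
        raise ValueError("noise_rate must be in [0, 1)")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    gray = np.where(stack.voxels.astype(bool), 200.0, 10.0)
    rng = np.random.default_rng(seed)
    if noise_rate > 0:
        flip = rng.random(gray.shape) < noise_rate
        salt = rng.random(gray.shape) < 0.5
        gray = np.where(flip & salt, 255.0, gray)
        gray = np.where(flip & ~salt, 0.0, gray)
    if blur_sigma > 0:
        gray = ndimage.gaussian_filter(gray, sigma=blur_sigma)
    out = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    return ImageStack(out, spacing=stack.spacing, origin=stack.origin, is_binary=False)
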