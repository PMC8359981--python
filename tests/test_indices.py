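import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trabkit import (
    Branch,
    ReferenceAxis,
    SkeletonGraph,
    connectivity,
    density_colormap_slices,
    fractal_dimension,
    make_report,
    node_density,
    scale_graph,
    tortuosity,
    trabecular_angle,
)

Z_AXIS = ReferenceAxis(start=np.zeros(3), end=np.array([0.0, 0, 1]))


def graph_from_segments(segments):
    """Graph with one straight 2-point branch per (start, end) pair."""
    nodes = []
    branches = []
    for a, b in segments:
        ia = len(nodes)
        nodes.append(np.asarray(a, float))
        ib = len(nodes)
        nodes.append(np.asarray(b, float))
        branches.append(Branch(ia, ib, np.asarray([a, b], float)))
    return SkeletonGraph(nodes=np.asarray(nodes), branches=branches)


# ------------------------------------------------------------ tortuosity

def test_tortuosity_straight_branch_exact():
    g = graph_from_segments([((0, 0, 0), (0, 0, 5))])
    assert tortuosity(g)["mean"] == 1.0


def test_tortuosity_excludes_self_loops():
    loop = Branch(0, 0, np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]]))
    g = SkeletonGraph(nodes=np.zeros((1, 3)), branches=[loop])
    with pytest.raises(ValueError, match="excluded"):
        tortuosity(g)
    # mixed case: the loop is excluded, the straight branch counted
    g2 = SkeletonGraph(
        nodes=np.array([[0.0, 0, 0], [2, 0, 0]]),
        branches=[loop, Branch(0, 1, np.array([[0.0, 0, 0], [2, 0, 0]]))],
    )
    out = tortuosity(g2)
    assert out["mean"] == 1.0
    assert out["n_excluded"] == 1 and out["n_included"] == 1


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), n_pts=st.integers(3, 40))
def test_tortuosity_at_least_one_property(seed, n_pts):
    """Arc length never undercuts the chord (triangle inequality)."""
    rng = np.random.default_rng(seed)
    poly = rng.normal(size=(n_pts, 3))
    while np.linalg.norm(poly[-1] - poly[0]) < 1e-6:
        poly[-1] += 0.1
    g = SkeletonGraph(nodes=np.asarray([poly[0], poly[-1]]),
                      branches=[Branch(0, 1, poly)])
    assert tortuosity(g)["mean"] >= 1.0 - 1e-12


# ------------------------------------------------------------ angle

def test_angle_parallel_and_oblique():
    g = graph_from_segments([((0, 0, 0), (0, 0, 3))])
    assert trabecular_angle(g, axis=Z_AXIS)["angle_deg"] == pytest.approx(0.0, abs=1e-12)
    g45 = graph_from_segments([((0, 0, 0), (0, 1, 1))])
    assert trabecular_angle(g45, axis=Z_AXIS)["angle_deg"] == pytest.approx(45.0, abs=1e-9)


def test_angle_is_verse_independent():
    # the same trabecula traversed in either direction gives the same angle
    up = graph_from_segments([((0, 0, 0), (0, 1, 1))])
    down = graph_from_segments([((0, 1, 1), (0, 0, 0))])
    a1 = trabecular_angle(up, axis=Z_AXIS)["angle_deg"]
    a2 = trabecular_angle(down, axis=Z_AXIS)["angle_deg"]
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_angle_symmetric_pair_cancels_to_axis():
    s, c = np.sin(np.radians(30)), np.cos(np.radians(30))
    g = graph_from_segments([((0, 0, 0), (0, s, c)), ((0, 0, 0), (0, -s, c))])
    assert trabecular_angle(g, axis=Z_AXIS)["angle_deg"] == pytest.approx(0.0, abs=1e-9)


def test_angle_major_axis_mode():
    g = graph_from_segments([((0, 0, 0), (0, 0, 3)), ((0, 0, 4), (0, 0, 9))])
    out = trabecular_angle(g, axis="major")
    assert out["axis_source"] == "major"
    # the principal axis comes from an SVD, so allow its numerical noise
    assert out["angle_deg"] == pytest.approx(0.0, abs=1e-4)
    with pytest.raises(ValueError, match="major"):
        trabecular_angle(g, axis="minor")


def test_angle_contributions_sum_to_100():
    g = graph_from_segments([((0, 0, 0), (1, 2, 3))])
    out = trabecular_angle(g, axis=Z_AXIS)
    assert out["contributions_pct"].sum() == pytest.approx(100.0)


def test_angle_indeterminate_cases():
    loop = SkeletonGraph(
        nodes=np.zeros((1, 3)),
        branches=[Branch(0, 0, np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 0]]))],
    )
    with pytest.raises(ValueError, match="distinct endpoints"):
        trabecular_angle(loop, axis=Z_AXIS)
    # two orthogonal in-plane branches: resultant lies in the plane normal
    # to the axis only if it cancels; engineered exact cancellation
    g = graph_from_segments([((0, 0, 0), (1, 0, 0)), ((0, 0, 0), (-1, 0, 0))])
    with pytest.raises(ValueError, match="cancel"):
        trabecular_angle(g, axis=Z_AXIS)


# ------------------------------------------------------------ connectivity

def test_connectivity_counts():
    # H-shape: two degree-3 junctions, four terminals
    nodes = np.array([
        [0.0, 0, 0], [0, 0, 2],           # junctions
        [-1, 0, -1], [1, 0, -1], [-1, 0, 3], [1, 0, 3],  # terminals
    ])
    mk = lambda a, b: Branch(a, b, np.asarray([nodes[a], nodes[b]]))
    g = SkeletonGraph(nodes=nodes, branches=[
        mk(0, 1), mk(0, 2), mk(0, 3), mk(1, 4), mk(1, 5)])
    out = connectivity(g)
    assert out["mean"] == pytest.approx(3.0)
    assert out["n_terminal"] == 4 and out["n_nonterminal"] == 2


def test_connectivity_undefined_for_single_branch():
    g = graph_from_segments([((0, 0, 0), (1, 0, 0))])
    with pytest.raises(ValueError, match="non-terminal"):
        connectivity(g)


# ------------------------------------------------------------ node density

def uniform_cloud_graph(n=500, seed=0, side=10.0):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3)) * side
    return SkeletonGraph(nodes=pts, branches=[])


def test_density_integral_equals_node_count():
    g = uniform_cloud_graph(n=300)
    field, summary = node_density(g, grid_dims=(40, 40, 40))
    assert field.integral() == pytest.approx(300, rel=1e-9)
    assert summary["n_nodes"] == 300


def test_density_deterministic():
    g = uniform_cloud_graph(n=200, seed=3)
    f1, _ = node_density(g, grid_dims=(30, 30, 30))
    f2, _ = node_density(g, grid_dims=(30, 30, 30))
    assert np.array_equal(f1.values, f2.values)


def test_density_bandwidth_override():
    g = uniform_cloud_graph(n=100)
    field, summary = node_density(g, bandwidth=np.array([0.5, 0.5, 0.5]),
                                  grid_dims=(25, 25, 25))
    assert summary["bandwidth_x"] == 0.5
    assert field.integral() == pytest.approx(100, rel=1e-9)
    with pytest.raises(ValueError, match="positive"):
        node_density(g, bandwidth=np.array([0.5, -1, 0.5]))


def test_density_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 2"):
        node_density(SkeletonGraph(nodes=np.zeros((1, 3)), branches=[]))
    flat = SkeletonGraph(nodes=np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),
                         branches=[])
    with pytest.raises(ValueError, match="zero extent"):
        node_density(flat)
    g = uniform_cloud_graph(10)
    with pytest.raises(ValueError, match="scale_length"):
        node_density(g, scale_length=-1.0)


def test_density_field_geometry():
    g = uniform_cloud_graph(n=50)
    field, _ = node_density(g, grid_dims=(10, 20, 30))
    assert field.grid_dims == (10, 20, 30)
    centers = field.cell_centers(1)
    assert centers.shape == (20,)
    assert centers[0] == pytest.approx(field.lo[1] + field.cell_size[1] / 2)


def test_density_colormap(tmp_path):
    g = uniform_cloud_graph(n=100)
    field, _ = node_density(g, grid_dims=(15, 15, 15))
    out = density_colormap_slices(field, "coronal", 0.5, tmp_path / "cor.png")
    assert out.exists() and out.stat().st_size > 0
    with pytest.raises(ValueError, match="plane"):
        density_colormap_slices(field, "oblique", 0.5, tmp_path / "x.png")
    with pytest.raises(ValueError, match="position"):
        density_colormap_slices(field, "axial", 1.5, tmp_path / "x.png")


# ------------------------------------------------------------ fractal dimension

def test_fd_errors():
    g = SkeletonGraph(nodes=np.zeros((1, 3)), branches=[])
    with pytest.raises(ValueError, match="at least 2 distinct"):
        fractal_dimension(g)
    line = SkeletonGraph(
        nodes=np.array([[0.0, 0, 0], [1, 0, 0]]),
        branches=[Branch(0, 1, np.linspace([0, 0, 0], [1, 0, 0], 200))],
    )
    with pytest.raises(ValueError, match="n_scales"):
        fractal_dimension(line, n_scales=2)


def test_fd_reports_diagnostics():
    line = SkeletonGraph(
        nodes=np.array([[0.0, 0, 0], [1, 0, 0]]),
        branches=[Branch(0, 1, np.linspace([0, 0, 0], [1, 0, 0], 512))],
    )
    out = fractal_dimension(line)
    assert len(out["scales"]) == len(out["counts"]) >= 3
    assert (np.diff(out["counts"]) >= 0).all()  # finer cells, more of them
    assert 0.9 <= out["r2"] <= 1.0


# ------------------------------------------------------------ scale behavior

def test_indices_under_scaling(pipeline_graph):
    """Dividing coordinates by a homologous length leaves the dimensionless
    indices unchanged and multiplies densities by its cube."""
    L = 2.5
    scaled = scale_graph(pipeline_graph, L)
    assert tortuosity(scaled)["mean"] == pytest.approx(
        tortuosity(pipeline_graph)["mean"], rel=1e-9)
    assert connectivity(scaled)["mean"] == connectivity(pipeline_graph)["mean"]
    a0 = trabecular_angle(pipeline_graph, axis="major")["angle_deg"]
    a1 = trabecular_angle(scaled, axis="major")["angle_deg"]
    assert a1 == pytest.approx(a0, abs=1e-9)
    _, s0 = node_density(pipeline_graph, grid_dims=(40, 40, 40))
    _, s1 = node_density(scaled, grid_dims=(40, 40, 40))
    assert s1["mean"] == pytest.approx(s0["mean"] * L**3, rel=1e-6)
    fd0 = fractal_dimension(pipeline_graph)["fd"]
    fd1 = fractal_dimension(scaled)["fd"]
    assert fd1 == pytest.approx(fd0, abs=1e-9)


# ------------------------------------------------------------ report

def test_make_report_full(pipeline_graph):
    report, field = make_report(pipeline_graph, specimen="ph")
    assert report.missing == {}
    assert field is not None
    assert report.n_nodes == pipeline_graph.n_nodes
    assert report.mean_tortuosity >= 1.0
    assert report.mean_connectivity >= 2.0
    assert 0 < report.fractal_dimension <= 3.0


def test_make_report_partial_graph():
    # a single straight branch: density/connectivity/FD undefined,
    # tortuosity and angle still computable
    g = graph_from_segments([((0, 0, 0), (0, 1, 1))])
    report, field = make_report(g)
    assert report.mean_tortuosity == pytest.approx(1.0)
    assert report.trabecular_angle is not None
    assert "connectivity" in report.missing
    assert "node_density" in report.missing
    assert report.mean_connectivity is None


def test_report_csv_round_trip(tmp_path, pipeline_graph):
    import pandas as pd

    report, _ = make_report(pipeline_graph, specimen="ph")
    path = tmp_path / "indices.csv"
    report.to_csv(path)
    df = pd.read_csv(path)
    assert df.shape[0] == 1
    assert df.loc[0, "specimen"] == "ph"
    assert df.loc[0, "n_nodes"] == report.n_nodes
    assert df.loc[0, "mean_connectivity"] == pytest.approx(
        report.mean_connectivity, rel=1e-4)
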