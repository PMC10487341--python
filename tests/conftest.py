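import numpy as np
import pytest

import microves as mv
from microves.skeleton import smooth_branch


def analyze_mask(mask: mv.BinaryMask) -> mv.VesselGraph:
    """Mask → skeleton → graph with spline-smoothed branches."""
    g = mv.build_graph(mv.skeletonize(mask))
    return mv.VesselGraph(g.nodes, [smooth_branch(b) for b in g.branches], g.spacing)


def voxelized_curve_branch(points_um: np.ndarray) -> mv.Branch:
    """Round an analytic centerline to the voxel grid, as thinning would yield."""
    vox = np.round(points_um).astype(int)
    keep = np.any(np.diff(vox, axis=0, prepend=vox[:1] - 1) != 0, axis=1)
    return smooth_branch(mv.Branch(1, 2, vox[keep].astype(float)))


@pytest.fixture(scope="session")
def straight_tube():
    """Circular tube, radius 8 μm, axis along x, on a 1 μm cubic grid."""
    spec = mv.PhantomSpec(
        box_size=(120, 60, 60), spacing=1.0,
        tubes=[mv.TubeSpec(mv.Line((10, 30, 30), (110, 30, 30)), a=8.0)],
    )
    img, mask, truth = mv.render(spec)
    return spec, img, mask, truth


@pytest.fixture(scope="session")
def y_mask():
    """Three tubes meeting at one point: 1 junction, 3 endpoints, 3 branches."""
    spec = mv.PhantomSpec(
        box_size=(100, 100, 40), spacing=1.0,
        tubes=[
            mv.TubeSpec(mv.Line((10, 50, 20), (50, 50, 20)), a=5.0),
            mv.TubeSpec(mv.Line((50, 50, 20), (90, 80, 20)), a=5.0),
            mv.TubeSpec(mv.Line((50, 50, 20), (90, 20, 20)), a=5.0),
        ],
    )
    _, mask, _ = mv.render(spec)
    return mask


@pytest.fixture(scope="session")
def h_mask():
    """Two junctions bridged by one interior branch: 5 branches total."""
    spec = mv.PhantomSpec(
        box_size=(120, 120, 40), spacing=1.0,
        tubes=[
            mv.TubeSpec(mv.Line((10, 10, 20), (40, 60, 20)), a=5.0),
            mv.TubeSpec(mv.Line((10, 110, 20), (40, 60, 20)), a=5.0),
            mv.TubeSpec(mv.Line((40, 60, 20), (80, 60, 20)), a=5.0),
            mv.TubeSpec(mv.Line((80, 60, 20), (110, 10, 20)), a=5.0),
            mv.TubeSpec(mv.Line((80, 60, 20), (110, 110, 20)), a=5.0),
        ],
    )
    _, mask, _ = mv.render(spec)
    return mask


def random_network_graph(rng: np.random.Generator, n_nodes: int = 8, extra_edges: int = 3):
    """Random connected vessel graph with plausible lengths/diameters."""
    nodes = {
        i: mv.Node(i, rng.uniform(0, 500, 3), "junction") for i in range(n_nodes)
    }
    edges = [(i, i + 1) for i in range(n_nodes - 1)]  # spanning path
    while len(edges) < n_nodes - 1 + extra_edges:
        a, b = rng.integers(0, n_nodes, 2)
        if a != b and (min(a, b), max(a, b)) not in [(min(e), max(e)) for e in edges]:
            edges.append((int(a), int(b)))
    branches = [
        mv.Branch(
            a, b, np.array([nodes[a].position, nodes[b].position]),
            metrics={"length": float(rng.uniform(50, 200)), "diameter": float(rng.uniform(10, 40))},
        )
        for a, b in edges
    ]
    return mv.VesselGraph(nodes, branches)


def dense_flow_oracle(graph: mv.VesselGraph, bc: dict[int, float], mu: float = 1e-3):
    """Independent dense solve of the full branch+node equation system.

    Unknowns are [Q_1..Q_nb, p_1..p_nn]; rows are the per-branch pressure-drop
    relations p_a − p_b = R·Q and per-node mass balances (replaced by p = P at
    boundary nodes).  Built entirely from first principles, without reusing the
    sparse solver's assembly.
    """
    ids = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(ids)}
    nb, nn = len(graph.branches), len(ids)
    A = np.zeros((nb + nn, nb + nn))
    rhs = np.zeros(nb + nn)
    for k, b in enumerate(graph.branches):
        R = 128 * mu * (b.metrics["length"] * 1e-6) / (np.pi * (b.metrics["diameter"] * 1e-6) ** 4)
        A[k, nb + idx[b.node_a]] = 1.0
        A[k, nb + idx[b.node_b]] = -1.0
        A[k, k] = -R
    for j, nid in enumerate(ids):
        row = nb + j
        if nid in bc:
            A[row, nb + j] = 1.0
            rhs[row] = bc[nid]
        else:
            for k, b in enumerate(graph.branches):
                if b.node_a == nid:
                    A[row, k] -= 1.0
                if b.node_b == nid:
                    A[row, k] += 1.0
    sol = np.linalg.solve(A, rhs)
    return sol[:nb], {nid: sol[nb + idx[nid]] for nid in ids}
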