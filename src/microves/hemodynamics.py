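"""Poiseuille-network flow, wall shear stress, and radius-uncertainty effects.

Each branch is a straight resistor with hydraulic resistance
R_i = 128 μ L_i / (π D_i⁴); imposing constant pressures on boundary nodes
and mass conservation Σ Q = 0 at interior nodes yields a sparse linear
system (equivalent to the full set of n_branch Poiseuille equations plus
n_node balances) solved for nodal pressures.  From the branch flows the
mean velocity v_i = Q_i / (π r_i²) and the wall shear stress τ_i = 4 μ v_i / r_i
follow under the same laminar, Newtonian, circular-section assumptions.

Because the measured vessel radius enters R as r⁴ and τ as 1/r, its
uncertainty dominates the error budget of both estimates; this module
propagates it analytically (first order) and by Monte-Carlo resampling.

Default dynamic viscosity is 1.0 mPa·s (aqueous culture medium at room
temperature); it is configurable everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .skeleton import VesselGraph

__all__ = [
    "FlowProblem",
    "FlowSolution",
    "hydraulic_resistance",
    "solve_flow",
    "wall_shear_stress",
    "uncertainty_analytic",
    "uncertainty_monte_carlo",
    "select_boundary_nodes",
    "export_3d1d_inputs",
    "poiseuille_velocity",
]

log = logging.getLogger(__name__)

UM = 1e-6  # μm → m


def hydraulic_resistance(length_um: float, diameter_um: float, mu: float = 1e-3) -> float:
    """Hydraulic resistance 128·μ·L/(π·D⁴) in Pa·s/m³ (inputs in μm, Pa·s)."""
    L = np.asarray(length_um, dtype=float)
    D = np.asarray(diameter_um, dtype=float)
    if np.any(L <= 0) or np.any(D <= 0) or mu <= 0:
        raise ValueError("length, diameter and viscosity must be positive")
    R = 128.0 * mu * (L * UM) / (np.pi * (D * UM) ** 4)
    return float(R) if R.ndim == 0 else R


def poiseuille_velocity(dp: float, radius_um: float, length_um: float, mu: float = 1e-3) -> float:
    """Mean velocity Δp·r²/(8·μ·L) of laminar tube flow, in μm/s."""
    r, L = radius_um * UM, length_um * UM
    return dp * r**2 / (8 * mu * L) / UM


@dataclass
class FlowProblem:
    """A vessel graph with per-branch geometry plus pressure boundary data.

    Branch lengths and diameters are taken from each branch's metrics
    (``length``/``diameter`` in μm, as written by morphometry) unless
    overridden.  Boundary conditions are (node id → pressure Pa); at least
    two nodes with two distinct pressures are required.
    """

    graph: VesselGraph
    boundary_pressures: dict[int, float]
    mu: float = 1e-3  # Pa·s

    def __post_init__(self) -> None:
        if len(self.boundary_pressures) < 2:
            raise ValueError("need at least two boundary nodes")
        if len(set(self.boundary_pressures.values())) < 2:
            raise ValueError("need at least two distinct boundary pressures")
        for b in self.graph.branches:
            if b.metrics.get("length", b.length) <= 0:
                raise ValueError("every branch needs a positive length")
            if b.metrics.get("diameter", 0) <= 0:
                raise ValueError("every branch needs a positive diameter (run morphometry first)")


@dataclass
class FlowSolution:
    """Per-branch flow/velocity/WSS and per-node pressure."""

    Q: np.ndarray  # m³/s, signed positive node_a → node_b
    pressures: dict[int, float]  # Pa
    v: np.ndarray  # μm/s, magnitude
    tau: np.ndarray  # Pa, magnitude
    R: np.ndarray  # Pa·s/m³
    mu: float

    def branch_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Q_m3_s": self.Q, "velocity_um_s": self.v, "wss_Pa": self.tau,
             "resistance_Pa_s_m3": self.R}
        )

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.pressures), "pressure_Pa": list(self.pressures.values())}
        )


def _components(node_ids: list[int], edges: list[tuple[int, int]]) -> list[set[int]]:
    adj: dict[int, set[int]] = {n: set() for n in node_ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[int] = set()
    comps = []
    for n in node_ids:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            m = stack.pop()
            if m in comp:
                continue
            comp.add(m)
            stack.extend(adj[m] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def solve_flow(problem: FlowProblem) -> FlowSolution:
    """Solve the network for nodal pressures and branch flows.

    Boundary pressures are honoured exactly; interior nodes satisfy mass
    conservation to solver tolerance.  Connected components without any
    boundary node (or with a single pressure level) carry zero flow and are
    reported with a warning.
    """
    graph, mu = problem.graph, problem.mu
    node_ids = sorted(graph.nodes)
    idx = {nid: i for i, nid in enumerate(node_ids)}
    nb = len(graph.branches)

    lengths = np.array([b.metrics.get("length", b.length) for b in graph.branches])
    diameters = np.array([b.metrics["diameter"] for b in graph.branches])
    R = hydraulic_resistance(lengths, diameters, mu)
    R = np.atleast_1d(R)
    G = 1.0 / R

    comps = _components(node_ids, [(b.node_a, b.node_b) for b in graph.branches])
    bset = set(problem.boundary_pressures)
    for comp in comps:
        pressures_here = {problem.boundary_pressures[n] for n in comp & bset}
        if len(pressures_here) == 0:
            log.warning("component of %d nodes has no boundary node: zero flow", len(comp))

    n = len(node_ids)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    is_bound = np.zeros(n, dtype=bool)
    for nid, p in problem.boundary_pressures.items():
        i = idx[nid]
        is_bound[i] = True
        rows.append(i), cols.append(i), vals.append(1.0)
        rhs[i] = p
    for k, b in enumerate(graph.branches):
        i, j = idx[b.node_a], idx[b.node_b]
        if i == j:
            continue
        for (a, c) in ((i, j), (j, i)):
            if is_bound[a]:
                continue
            rows.append(a), cols.append(a), vals.append(G[k])
            rows.append(a), cols.append(c), vals.append(-G[k])
    # isolated interior nodes (no incident branch) need a trivial equation
    deg = np.zeros(n)
    for b in graph.branches:
        deg[idx[b.node_a]] += 1
        deg[idx[b.node_b]] += 1
    for i in range(n):
        if not is_bound[i] and deg[i] == 0:
            rows.append(i), cols.append(i), vals.append(1.0)

    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    # components with no boundary node make the Laplacian block singular;
    # anchor them at zero pressure
    for comp in comps:
        if not (comp & bset):
            anchor = idx[min(comp)]
            A[anchor, :] = 0
            A[anchor, anchor] = 1.0
            rhs[anchor] = 0.0
    p = spsolve(A.tocsr(), rhs)

    Q = np.zeros(nb)
    for k, b in enumerate(graph.branches):
        i, j = idx[b.node_a], idx[b.node_b]
        if i == j:
            continue
        Q[k] = (p[i] - p[j]) * G[k]
    radius_m = diameters / 2.0 * UM
    v = np.abs(Q) / (np.pi * radius_m**2) / UM  # μm/s
    tau = 4 * mu * (v * UM) / radius_m
    pressures = {nid: float(p[idx[nid]]) for nid in node_ids}
    return FlowSolution(Q=Q, pressures=pressures, v=v, tau=tau, R=R, mu=mu)


def wall_shear_stress(solution: FlowSolution) -> np.ndarray:
    """Per-branch wall shear stress τ = 4·μ·v/r in Pa (as stored on solve)."""
    return solution.tau


def select_boundary_nodes(
    graph: VesselGraph,
    p_in: float,
    p_out: float,
    axis: int = 0,
    margin_um: float = 20.0,
    bounds: tuple[float, float] | None = None,
) -> dict[int, float]:
    """Assign side pressures to nodes near the two opposite faces of the box.

    Mimics a chip perfused through its two side channels: nodes within
    ``margin_um`` of the low face get ``p_in``, of the high face ``p_out``.
    Nodes exactly on the margin are included.
    """
    pos = np.array([n.position for n in graph.nodes.values()])
    ids = list(graph.nodes)
    if bounds is None:
        bounds = (float(pos[:, axis].min()), float(pos[:, axis].max()))
    lo, hi = bounds
    bc: dict[int, float] = {}
    for nid, p in zip(ids, pos):
        if p[axis] <= lo + margin_um:
            bc[nid] = p_in
        elif p[axis] >= hi - margin_um:
            bc[nid] = p_out
    return bc


def uncertainty_analytic(v: float, tau: float, r: float, dr: float) -> tuple[float, float]:
    """First-order radius-uncertainty propagation for a single vessel.

    At fixed pressure drop and length, v = Δp·r²/(8μl) and τ = Δp·r/(2l),
    so dv = 2·v·dr/r  (= Δp/(8μl)·2r·dr) and dτ = τ·dr/r (= Δp/(2l)·dr).
    Units follow the inputs (v in μm/s, τ in Pa, r and dr in μm).
    """
    if r <= 0 or dr < 0:
        raise ValueError("radius must be positive and dr non-negative")
    return 2.0 * v * dr / r, tau * dr / r


def uncertainty_monte_carlo(
    r_nominal_um: np.ndarray | float,
    dr_sd_um: float,
    n_draws: int,
    seed: int,
    length_um: float = 100.0,
    dp: float | None = None,
    mu: float = 1e-3,
    v_target_um_s: float = 500.0,
    problem: FlowProblem | None = None,
) -> dict:
    """Monte-Carlo propagation of radius uncertainty into velocity and WSS.

    Radii are drawn per-branch from Normal(r_nominal, dr_sd), truncated
    positive by redrawing (the redraw count is logged).  For a single vessel
    the closed forms v = Δp·r²/(8μl), τ = Δp·r/(2l) are evaluated
    vectorised; for a network ``problem`` each draw re-solves the flow
    system and per-draw medians across branches are accumulated.  ``dp``
    defaults to the pressure drop giving ``v_target_um_s`` at the nominal
    radius (first entry for networks).

    Returns a dict of sample arrays (``r``, ``v``, ``tau``) and summaries
    (mean/sd/median per quantity, τ in Pa).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    r_nom = np.atleast_1d(np.asarray(r_nominal_um, dtype=float))
    if dp is None:
        dp = 8 * mu * (length_um * UM) * (v_target_um_s * UM) / (r_nom[0] * UM) ** 2

    network = problem is not None and len(problem.graph.branches) > 1
    shape = (n_draws, len(r_nom))
    radii = rng.normal(r_nom, dr_sd_um, size=shape)
    redraws = 0
    bad = radii <= 0
    while bad.any():
        redraws += int(bad.sum())
        radii[bad] = rng.normal(np.broadcast_to(r_nom, shape)[bad], dr_sd_um)
        bad = radii <= 0
    if redraws:
        log.info("uncertainty_monte_carlo: %d nonpositive radii redrawn", redraws)

    if not network:
        r = radii[:, 0]
        v = dp * (r * UM) ** 2 / (8 * mu * length_um * UM) / UM  # μm/s
        tau = dp * (r * UM) / (2 * length_um * UM)  # Pa
        r_out, v_out, tau_out = r, v, tau
    else:
        graph = problem.graph
        meds_r, meds_v, meds_tau = [], [], []
        for d in range(n_draws):
            for k, b in enumerate(graph.branches):
                b.metrics["diameter"] = 2 * radii[d, k]
            sol = solve_flow(FlowProblem(graph, problem.boundary_pressures, mu=problem.mu))
            meds_r.append(np.median(radii[d]))
            meds_v.append(np.median(sol.v))
            meds_tau.append(np.median(sol.tau))
        for k, b in enumerate(graph.branches):  # restore nominal geometry
            b.metrics["diameter"] = 2 * r_nom[k]
        r_out, v_out, tau_out = map(np.asarray, (meds_r, meds_v, meds_tau))

    def _summ(x: np.ndarray) -> dict:
        return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "median": float(np.median(x))}

    return {
        "r": r_out, "v": v_out, "tau": tau_out,
        "summary": {"r_um": _summ(r_out), "v_um_s": _summ(v_out), "tau_Pa": _summ(tau_out)},
        "dp_Pa": float(dp),
        "redraws": redraws,
    }


def export_3d1d_inputs(
    graph: VesselGraph,
    path: str | Path,
    boundary_pressures: dict[int, float] | None = None,
) -> tuple[Path, Path]:
    """Write the plain-text node/segment tables used by 1D network solvers.

    ``<path>.nodes.txt``: ``id x_um y_um z_um pressure_Pa`` (pressure blank
    for interior nodes).  ``<path>.segments.txt``: ``node_a node_b
    radius_um length_um``.  Round-tripping restores topology, radii and
    lengths exactly.
    """
    path = Path(path)
    bp = boundary_pressures or {}
    nodes_path = path.with_suffix(".nodes.txt")
    seg_path = path.with_suffix(".segments.txt")
    with open(nodes_path, "w") as fh:
        fh.write("# id x_um y_um z_um pressure_Pa\n")
        for n in graph.nodes.values():
            p = f"{bp[n.id]:.17g}" if n.id in bp else ""
            fh.write(f"{n.id} {n.position[0]:.17g} {n.position[1]:.17g} {n.position[2]:.17g} {p}\n")
    with open(seg_path, "w") as fh:
        fh.write("# node_a node_b radius_um length_um\n")
        for b in graph.branches:
            r = b.metrics.get("radius_mean", b.metrics.get("diameter", 0.0) / 2.0)
            fh.write(f"{b.node_a} {b.node_b} {r:.17g} {b.metrics.get('length', b.length):.17g}\n")
    return nodes_path, seg_path


def read_3d1d_inputs(path: str | Path) -> tuple[dict, list[tuple[int, int, float, float]]]:
    """Read back the exchange tables written by :func:`export_3d1d_inputs`."""
    path = Path(path)
    nodes = {}
    for line in path.with_suffix(".nodes.txt").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        nid = int(parts[0])
        nodes[nid] = {
            "position": np.array([float(p) for p in parts[1:4]]),
            "pressure": float(parts[4]) if len(parts) > 4 else None,
        }
    segments = []
    for line in path.with_suffix(".segments.txt").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        a, b, r, L = line.split()
        segments.append((int(a), int(b), float(r), float(L)))
    return nodes, segments
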