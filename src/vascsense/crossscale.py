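"""Macro-meso-micro simulator: graph flow, tracer transport, tissue viability.

Macro: Poiseuille-type edge conductance g = d^4 / (l + eps); node pressures
from the weighted graph Laplacian with Dirichlet inlet/outlet conditions;
edge flows g * dp (Kirchhoff-conserving).

Meso: edge flows are splatted as tangential velocity contributions onto the
voxel grid and Gaussian-smoothed; a tracer bolus then evolves by an explicit
advection-diffusion-reaction update (donor-cell upwind advection, 5-point
diffusion stencil, zero-flux boundaries, CFL-guarded):

    dc/dt + div(u c) = D lap(c) - lambda c + S.

Perfusion endpoints are peak concentration (CBV proxy), time-to-peak, and
area under the curve (CBF proxy).

Micro: an energy-balance viability proxy per voxel,
dE/dt = alpha*Phi - beta*Gamma - gamma*E, with survival probability
P = logistic(slope * (E - theta)).  Defaults follow the fixed parameter set
(D=0.80 mm^2/s, lambda=0.012 /s, dt=0.10 s, T=60 s, alpha=1.10, beta=0.85,
gamma=0.06, theta=0.20, slope=8.0, eps=1e-6), chosen a priori and never
re-tuned inside tests.

Uncertainty propagation runs the whole cascade per reconstruction realization
and reports unbiased variances of the perfusion endpoints (meso) and of the
survival map (micro), the latter averaged over the at-risk territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .core import ImageVolume
from .graphs import VascularGraph, resample_polyline

__all__ = [
    "MesoParams",
    "MicroParams",
    "FlowSolution",
    "UncertaintyReport",
    "edge_conductance",
    "solve_graph_flow",
    "select_boundary_nodes",
    "graph_to_velocity_field",
    "simulate_transport",
    "perfusion_endpoints",
    "simulate_viability",
    "propagate_uncertainty",
    "define_risk_region",
    "TABLE_DEFAULTS",
]

# fixed simulator parameter set (single provenance source)
TABLE_DEFAULTS = {
    "conductance_eps": 1e-6,
    "macro_weights": (0.6, 0.25, 0.15),
    "diffusivity_mm2_s": 0.80,
    "decay_per_s": 0.012,
    "dt_s": 0.10,
    "horizon_s": 60.0,
    "alpha": 1.10,
    "beta": 0.85,
    "gamma": 0.06,
    "theta": 0.20,
    "logistic_slope": 8.0,
}


@dataclass(frozen=True)
class MesoParams:
    diffusivity: float = TABLE_DEFAULTS["diffusivity_mm2_s"]  # mm^2/s
    decay_rate: float = TABLE_DEFAULTS["decay_per_s"]         # 1/s
    dt: float = TABLE_DEFAULTS["dt_s"]                        # s
    horizon: float = TABLE_DEFAULTS["horizon_s"]              # s
    # tissue grid spacing; perfusion is a tissue-scale quantity, and the
    # fixed explicit step dt=0.10 s with D=0.80 mm^2/s is stable only for
    # h >= sqrt(2*dim*D*dt) ~ 0.57 mm in 2-D, so the transport grid is
    # coarser than the angiographic voxel grid
    spacing_mm: float = 1.0
    bolus_amplitude: float = 1.0
    bolus_duration_s: float = 5.0

    def __post_init__(self):
        if self.diffusivity < 0 or self.dt <= 0 or self.horizon <= 0:
            raise ValueError("D >= 0 and dt, T > 0 required")
        if self.decay_rate < 0:
            raise ValueError("decay must be >= 0")

    def check_stability(self, ndim: int, umax: float = 0.0):
        h = self.spacing_mm
        if self.diffusivity > 0:
            dt_max = h**2 / (2 * ndim * self.diffusivity)
            if self.dt > dt_max + 1e-12:
                raise ValueError(
                    f"explicit diffusion unstable: dt={self.dt} exceeds "
                    f"h^2/(2*dim*D)={dt_max:.4g} s"
                )
        if umax > 0:
            dt_adv = h / umax
            if self.dt > dt_adv:
                raise ValueError(
                    f"advection CFL violated: dt={self.dt} exceeds "
                    f"h/max|u|={dt_adv:.4g} s"
                )


@dataclass(frozen=True)
class MicroParams:
    alpha: float = TABLE_DEFAULTS["alpha"]
    beta: float = TABLE_DEFAULTS["beta"]
    gamma: float = TABLE_DEFAULTS["gamma"]
    theta: float = TABLE_DEFAULTS["theta"]
    logistic_slope: float = TABLE_DEFAULTS["logistic_slope"]
    demand_kappa: float = 1.0
    demand_max: float = 2.0

    def __post_init__(self):
        if self.gamma <= 0 or self.logistic_slope <= 0:
            raise ValueError("gamma and logistic slope must be positive")


@dataclass
class FlowSolution:
    pressures: dict
    flows: dict  # (u, v, key) -> signed flow along u -> v
    inlets: tuple
    outlets: tuple

    def node_imbalance(self, graph: VascularGraph) -> float:
        """Max net flow at internal nodes, relative check done by caller."""
        net = {n: 0.0 for n in graph.g.nodes}
        for (u, v, k), f in self.flows.items():
            net[u] -= f
            net[v] += f
        internal = [n for n in net
                    if n not in self.inlets and n not in self.outlets]
        if not internal:
            return 0.0
        return float(max(abs(net[n]) for n in internal))

    def total_inflow(self) -> float:
        total = 0.0
        for (u, v, k), f in self.flows.items():
            if u in self.inlets:
                total += max(f, 0.0)
            if v in self.inlets:
                total += max(-f, 0.0)
        return total


@dataclass
class UncertaintyReport:
    U_meso: dict           # endpoint name -> spatially averaged variance
    U_micro: np.ndarray    # voxelwise variance of P_survival
    U_micro_mean: float    # mean over the risk region
    risk_mask: np.ndarray
    K: int

    def to_dict(self):
        return {
            "U_meso": {k: float(v) for k, v in self.U_meso.items()},
            "U_micro_mean": float(self.U_micro_mean),
            "risk_voxels": int(self.risk_mask.sum()),
            "K": self.K,
        }


# ---------------------------------------------------------------------------
# macro: conductance and flow
# ---------------------------------------------------------------------------

def edge_conductance(diameter_mm: float, length_mm: float,
                     eps: float = TABLE_DEFAULTS["conductance_eps"]) -> float:
    """Poiseuille-type scaling g = d^4 / (l + eps), unit constant."""
    if diameter_mm < 0 or length_mm < 0:
        raise ValueError("diameter and length must be >= 0")
    return float(diameter_mm**4 / (length_mm + eps))


def annotate_conductances(g: VascularGraph,
                          eps: float = TABLE_DEFAULTS["conductance_eps"]):
    for *_, d in g.g.edges(data=True):
        d["conductance"] = edge_conductance(d["diameter_mm"], d["length_mm"], eps)
    return g


def select_boundary_nodes(g: VascularGraph, inlet_border: str = "left",
                          n_inlets: int = 1):
    """Degree-1 nodes nearest the declared inlet border are inlets; the
    remaining terminals are outlets.

    If the graph has fewer than two degree-1 nodes (every terminal absorbed
    into a loop), the lowest-degree nodes stand in, ordered by distance from
    the inlet border, so a perfused network always has a boundary condition.
    """
    if g.n_nodes < 2:
        raise ValueError("need at least two nodes for flow")
    terminals = [n for n in g.g.nodes if g.g.degree(n) == 1]
    if len(terminals) < 2:
        by_degree = sorted(g.g.nodes, key=lambda n: (g.g.degree(n), n))
        for n in by_degree:
            if n not in terminals:
                terminals.append(n)
            if len(terminals) >= max(2, n_inlets + 1):
                break
    axis, sign = {"left": (1, +1), "right": (1, -1),
                  "top": (0, +1), "bottom": (0, -1)}[inlet_border]
    pos = g.node_positions()
    order = sorted(terminals, key=lambda n: sign * pos[n][axis])
    inlets = tuple(order[:n_inlets])
    outlets = tuple(n for n in terminals if n not in inlets)
    return inlets, outlets


def solve_graph_flow(g: VascularGraph, inlets, outlets) -> FlowSolution:
    """Pressures from the conductance-weighted Laplacian; flows g_e * dp.

    Inlets are held at pressure 1, outlets at 0.
    """
    inlets, outlets = tuple(inlets), tuple(outlets)
    if not inlets or not outlets:
        raise ValueError("need at least one inlet and one outlet")
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g.g)):
        for n in comp:
            comp_of[n] = ci
    cin = {comp_of[n] for n in inlets}
    cout = {comp_of[n] for n in outlets}
    if not (cin & cout):
        raise ValueError(
            f"inlets (components {sorted(cin)}) and outlets (components "
            f"{sorted(cout)}) are not connected"
        )
    annotate_conductances(g)
    nodes = sorted(g.g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rowsL, colsL, vals = [], [], []
    diag = np.zeros(n)
    for u, v, k, d in g.g.edges(keys=True, data=True):
        ge = d["conductance"]
        if u == v:
            continue  # self loops carry no pressure drop
        i, j = idx[u], idx[v]
        rowsL += [i, j]
        colsL += [j, i]
        vals += [-ge, -ge]
        diag[i] += ge
        diag[j] += ge
    rowsL += list(range(n))
    colsL += list(range(n))
    vals += list(diag)
    L = csr_matrix((vals, (rowsL, colsL)), shape=(n, n))
    p = np.zeros(n)
    fixed = {idx[m]: 1.0 for m in inlets}
    fixed.update({idx[m]: 0.0 for m in outlets})
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    pf = np.zeros(n)
    for i, val in fixed.items():
        pf[i] = val
    if len(free):
        rhs = -L[free][:, sorted(fixed)] @ np.array(
            [fixed[i] for i in sorted(fixed)])
        sol = spsolve(L[free][:, free].tocsc(), rhs)
        p[free] = np.atleast_1d(sol)
    for i, val in fixed.items():
        p[i] = val
    pressures = {nodes[i]: float(p[i]) for i in range(n)}
    flows = {}
    for u, v, k, d in g.g.edges(keys=True, data=True):
        if u == v:
            flows[(u, v, k)] = 0.0
        else:
            flows[(u, v, k)] = d["conductance"] * (pressures[u] - pressures[v])
    return FlowSolution(pressures, flows, inlets, outlets)


# ---------------------------------------------------------------------------
# meso: velocity field and transport
# ---------------------------------------------------------------------------

def graph_to_velocity_field(flow: FlowSolution, graph: VascularGraph,
                            grid_shape, voxel_size_mm: float,
                            smoothing_sigma_mm: float = 1.0) -> np.ndarray:
    """Splat signed edge flows as tangential velocities onto the voxel grid.

    Returns an array of shape ``(ndim, *grid_shape)`` in mm/s-equivalent
    arbitrary units; linear in the flows.
    """
    if smoothing_sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    ndim = len(grid_shape)
    field_ = np.zeros((ndim,) + tuple(grid_shape))
    counts = np.zeros(grid_shape)
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        f = flow.flows.get((u, v, k), 0.0)
        if f == 0.0:
            continue
        poly = resample_polyline(d["polyline_mm"] / voxel_size_mm, 0.5)
        if len(poly) < 2:
            continue
        tang = np.gradient(poly, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = tang / np.maximum(norm, 1e-12)
        vox = np.clip(np.round(poly).astype(int), 0,
                      np.asarray(grid_shape) - 1)
        for p, t in zip(vox, tang):
            field_[(slice(None),) + tuple(p)] += f * t
            counts[tuple(p)] += 1.0
    nz = counts > 0
    for a in range(ndim):
        comp = field_[a]
        comp[nz] = comp[nz] / counts[nz]
        if smoothing_sigma_mm > 0:
            field_[a] = ndimage.gaussian_filter(
                comp, sigma=smoothing_sigma_mm / voxel_size_mm)
    return field_


def _upwind_flux_divergence(c, u, h):
    """Divergence of the donor-cell upwind flux with zero-flux boundaries."""
    ndim = c.ndim
    div = np.zeros_like(c)
    for ax in range(ndim):
        u_face = 0.5 * (u[ax] + np.roll(u[ax], -1, axis=ax))
        # flux through the face between cell i and i+1 along ax
        c_up = np.where(u_face > 0, c, np.roll(c, -1, axis=ax))
        flux = u_face * c_up
        # zero-flux outer boundaries: the face after the last cell is closed,
        # and rolling it to position 0 also closes the face before cell 0
        sl_last = [slice(None)] * ndim
        sl_last[ax] = slice(-1, None)
        flux[tuple(sl_last)] = 0.0
        div += (flux - np.roll(flux, 1, axis=ax)) / h
    return div


def _laplacian_zero_flux(c, h):
    lap = np.zeros_like(c)
    for ax in range(c.ndim):
        fwd = np.roll(c, -1, axis=ax)
        bwd = np.roll(c, 1, axis=ax)
        sl0 = [slice(None)] * c.ndim
        sl0[ax] = slice(0, 1)
        sln = [slice(None)] * c.ndim
        sln[ax] = slice(-1, None)
        fwd[tuple(sln)] = c[tuple(sln)]  # mirror at the boundary
        bwd[tuple(sl0)] = c[tuple(sl0)]
        lap += (fwd - 2 * c + bwd) / h**2
    return lap


def simulate_transport(u: np.ndarray, params: MesoParams,
                       c0: np.ndarray | None = None,
                       source_mask: np.ndarray | None = None,
                       output_every_s: float = 1.0):
    """Explicit advection-diffusion-reaction evolution of a tracer field.

    Returns ``(times, series)`` with ``series[t]`` the concentration field at
    ``times[t]``.  Raises on CFL violation, naming the admissible step.
    """
    u = np.asarray(u, dtype=float)
    grid_shape = u.shape[1:]
    ndim = len(grid_shape)
    umax = float(np.max(np.abs(u))) if u.size else 0.0
    params.check_stability(ndim, umax)
    h = params.spacing_mm
    c = np.zeros(grid_shape) if c0 is None else np.asarray(c0, float).copy()
    n_steps = int(round(params.horizon / params.dt))
    every = max(1, int(round(output_every_s / params.dt)))
    times = [0.0]
    series = [c.copy()]
    for step in range(1, n_steps + 1):
        t = step * params.dt
        rhs = -_upwind_flux_divergence(c, u, h)
        if params.diffusivity > 0:
            rhs += params.diffusivity * _laplacian_zero_flux(c, h)
        rhs -= params.decay_rate * c
        if source_mask is not None and t <= params.bolus_duration_s:
            rhs = rhs + params.bolus_amplitude * source_mask
        c = c + params.dt * rhs
        if step % every == 0 or step == n_steps:
            times.append(t)
            series.append(c.copy())
    return np.asarray(times), np.asarray(series)


def perfusion_endpoints(times: np.ndarray, series: np.ndarray):
    """(peak map, time-to-peak map, AUC map) from a concentration series."""
    series = np.asarray(series)
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two time points")
    peak = series.max(axis=0)
    ttp = times[np.argmax(series, axis=0)]
    auc = np.trapezoid(series, times, axis=0)
    return peak, ttp, auc


# ---------------------------------------------------------------------------
# micro: viability
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_viability(supply: np.ndarray, params: MicroParams,
                       T: float = 60.0, dt: float = 0.10,
                       demand: np.ndarray | float | None = None,
                       reference_supply: float | None = None,
                       output_every_s: float = 5.0):
    """Forward-Euler energy balance and logistic survival probability.

    ``demand`` defaults to the bounded perfusion-deficit form
    ``min(demand_max, 1 + kappa * relative deficit)`` against
    ``reference_supply`` (median positive supply when not given).
    """
    if dt >= 2.0 / params.gamma:
        raise ValueError(
            f"explicit viability update unstable: dt must be < "
            f"{2.0 / params.gamma:.4g} s"
        )
    phi = np.asarray(supply, dtype=float)
    if demand is None:
        if reference_supply is None:
            pos = phi[phi > 0]
            reference_supply = float(np.median(pos)) if pos.size else 1.0
        deficit = np.maximum(0.0, (reference_supply - phi)
                             / max(reference_supply, 1e-12))
        demand = np.minimum(params.demand_max,
                            1.0 + params.demand_kappa * deficit)
    gam = np.broadcast_to(np.asarray(demand, dtype=float), phi.shape)
    E = np.zeros_like(phi)
    n_steps = int(round(T / dt))
    every = max(1, int(round(output_every_s / dt)))
    times = [0.0]
    e_series = [E.copy()]
    for step in range(1, n_steps + 1):
        E = E + dt * (params.alpha * phi - params.beta * gam
                      - params.gamma * E)
        if step % every == 0 or step == n_steps:
            times.append(step * dt)
            e_series.append(E.copy())
    p_map = _logistic(params.logistic_slope * (E - params.theta))
    return np.asarray(times), np.asarray(e_series), p_map


# ---------------------------------------------------------------------------
# uncertainty propagation and risk region
# ---------------------------------------------------------------------------

def run_cascade(img: ImageVolume, topo_cfg, meso: MesoParams,
                micro: MicroParams, inlet_border: str = "left"):
    """Image -> graph -> flow -> transport -> endpoints -> viability."""
    from .topology import diagrams_from_image
    _, g = diagrams_from_image(img, topo_cfg)
    if g.n_edges == 0:
        raise ValueError("no vessels extracted; cascade undefined")
    inlets, outlets = select_boundary_nodes(g, inlet_border)
    flow = solve_graph_flow(g, inlets, outlets)
    # transport runs on the coarser tissue grid (meso.spacing_mm)
    h = meso.spacing_mm
    grid = tuple(int(np.ceil(n * img.voxel_size_mm / h)) for n in img.shape)
    u = graph_to_velocity_field(flow, g, grid, h)
    # cap velocities to respect the advective CFL at the fixed dt
    umax_admissible = 0.5 * h / meso.dt
    scale = float(np.max(np.abs(u)))
    if scale > umax_admissible:
        u = u * (umax_admissible / scale)
    src = np.zeros(grid)
    pos = g.node_positions()
    for n_in in inlets:
        c = np.clip(np.round(pos[n_in] / h).astype(int), 0,
                    np.asarray(grid) - 1)
        src[tuple(c)] = 1.0
    src = ndimage.gaussian_filter(src, sigma=2.0)
    top = src.max()
    if top > 0:
        src = src / top
    times, series = simulate_transport(u, meso, source_mask=src)
    peak, ttp, auc = perfusion_endpoints(times, series)
    denom = float(np.median(auc[auc > 0])) if (auc > 0).any() else 1.0
    supply = auc / max(denom, 1e-12)
    _, _, p_map = simulate_viability(supply, micro, T=meso.horizon,
                                     dt=meso.dt)
    return {"graph": g, "flow": flow, "velocity": u, "times": times,
            "series": series, "peak": peak, "ttp": ttp, "auc": auc,
            "p_survival": p_map}


def propagate_uncertainty(realizations, topo_cfg, meso: MesoParams,
                          micro: MicroParams,
                          risk_mask: np.ndarray | None = None,
                          reference_endpoints=None,
                          inlet_border: str = "left") -> UncertaintyReport:
    """Run the full cascade per realization; report endpoint variances.

    ``U_meso``: unbiased voxelwise variance of each perfusion endpoint,
    spatially averaged.  ``U_micro``: voxelwise variance of the survival map;
    its mean over the risk region is the compact micro summary.
    """
    members = list(realizations)
    K = len(members)
    if K < 2:
        raise ValueError("uncertainty propagation needs K >= 2 realizations")
    peaks, ttps, aucs, ps = [], [], [], []
    for m in members:
        res = run_cascade(m, topo_cfg, meso, micro, inlet_border)
        peaks.append(res["peak"])
        ttps.append(res["ttp"])
        aucs.append(res["auc"])
        ps.append(res["p_survival"])
    u_meso = {
        "peak": float(np.mean(np.var(np.stack(peaks), axis=0, ddof=1))),
        "time_to_peak": float(np.mean(np.var(np.stack(ttps), axis=0, ddof=1))),
        "auc": float(np.mean(np.var(np.stack(aucs), axis=0, ddof=1))),
    }
    u_micro = np.var(np.stack(ps), axis=0, ddof=1)
    if risk_mask is None and reference_endpoints is not None:
        mean_auc = np.mean(np.stack(aucs), axis=0)
        risk_mask = define_risk_region(reference_endpoints,
                                       {"auc": mean_auc})
    if risk_mask is None or not np.asarray(risk_mask, bool).any():
        raise ValueError("risk region is empty; cannot summarize micro "
                         "uncertainty")
    risk_mask = np.asarray(risk_mask, dtype=bool)
    return UncertaintyReport(
        U_meso=u_meso,
        U_micro=u_micro,
        U_micro_mean=float(u_micro[risk_mask].mean()),
        risk_mask=risk_mask,
        K=K,
    )


def define_risk_region(healthy_endpoints, lesioned_endpoints,
                       fraction: float = 0.6) -> np.ndarray:
    """At-risk territory: voxels whose lesioned AUC falls below ``fraction``
    times the healthy AUC at that voxel, within the perfused tissue domain.

    The voxelwise reference (rather than a global summary) makes the mask
    empty when nothing changed and monotone in ``fraction``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    h = np.asarray(healthy_endpoints["auc"], dtype=float)
    l = np.asarray(lesioned_endpoints["auc"], dtype=float)
    tissue = h > 1e-9 * max(h.max(), 1e-30)
    return tissue & (l < fraction * h)
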