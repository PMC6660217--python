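"""Passive compartmental model on a tree: steady state, transients, impedance.

The membrane of each compartment is an RC leak (conductance ``gpas * area``,
capacitance ``cm * area``, reversal ``Epas``); compartments are coupled by
axial conductances ``pi * dbar^2 / (4 * Ra * l)`` along the tree edges.  No
active conductances.

Unit system (self-consistent; conversions happen once in :func:`build_model`):
mV, ms, nA, uS, nF, um.  Then ``nA / uS = mV``, ``nF / uS = ms`` and
``1 / uS = MOhm``, so no further unit factors appear in the solvers.

Writing the membrane potential as ``u = V - Epas``, the system is

    C du/dt = -(G_m + L) u + I(t)

with ``C`` the diagonal capacitance matrix, ``G_m`` the diagonal leak and
``L`` the (weighted) graph Laplacian of axial conductances.  The steady
state solves ``(G_m + L) u = I`` exactly; transients use backward Euler by
default (Crank-Nicolson behind a flag) with time step ``dt = 0.025 ms``.
For current-only stimuli the stepping scheme is evaluated through an exact
modal decomposition of the symmetrized system (each mode is a first-order
IIR recursion run by ``scipy.signal.lfilter``), which is bit-compatible
with the time loop up to floating point and much faster on long stimuli;
voltage-clamp protocols use the explicit loop with pinned compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal
import scipy.sparse
import scipy.sparse.linalg

from .morphology import Morphology, edge_geometry

__all__ = [
    "PassiveParams",
    "CompartmentalModel",
    "Stimulus",
    "Trace",
    "TransferMatrix",
    "build_model",
    "steady_state",
    "simulate",
    "white_noise_current",
    "transfer_matrix",
    "input_resistance",
]

DEFAULT_DT = 0.025  # ms


@dataclass(frozen=True)
class PassiveParams:
    """Specific passive cable parameters.

    Ra : axial resistivity, Ohm*cm.
    cm : specific membrane capacitance, uF/cm^2.
    gpas : specific leak conductance, S/cm^2.
    Epas : leak reversal potential, mV.
    """

    Ra: float = 150.0
    cm: float = 1.0
    gpas: float = 2.64e-4
    Epas: float = -45.0

    def __post_init__(self):
        if not (self.Ra > 0 and self.cm > 0 and self.gpas > 0):
            raise ValueError("Ra, cm and gpas must all be positive")


@dataclass
class CompartmentalModel:
    """Discretized passive electrical network on a tree.

    One compartment per morphology node.  Arrays are aligned with
    ``comp_ids``; ``edges`` holds (parent_index, child_index) pairs into that
    ordering with axial conductance ``g_axial`` (uS) per edge.
    """

    comp_ids: np.ndarray          # node ids, shape (n,)
    regions: np.ndarray           # region name per compartment, shape (n,)
    areas: np.ndarray             # um^2, shape (n,)
    membrane_conductance: np.ndarray  # uS, shape (n,)
    membrane_capacitance: np.ndarray  # nF, shape (n,)
    edges: np.ndarray             # (n-1, 2) int indices
    g_axial: np.ndarray           # uS per edge
    Epas: float                   # mV

    _id_to_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._id_to_index = {int(i): k for k, i in enumerate(self.comp_ids)}
        if np.any(self.membrane_conductance <= 0):
            raise ValueError("membrane conductances must be positive")
        if np.any(self.membrane_capacitance <= 0):
            raise ValueError("membrane capacitances must be positive")
        if self.edges.size and np.any(self.g_axial <= 0):
            raise ValueError("axial conductances must be positive")

    @property
    def n(self) -> int:
        return len(self.comp_ids)

    def index(self, comp_id: int) -> int:
        try:
            return self._id_to_index[int(comp_id)]
        except KeyError:
            raise KeyError(f"unknown compartment id {comp_id}") from None

    def region_compartments(self, region: str) -> np.ndarray:
        return self.comp_ids[self.regions == region]

    def system_matrix(self) -> scipy.sparse.csc_matrix:
        """``G_m + L`` in uS (sparse, symmetric positive definite)."""
        n = self.n
        diag = self.membrane_conductance.copy()
        rows, cols, vals = [], [], []
        for (i, j), g in zip(self.edges, self.g_axial):
            diag[i] += g
            diag[j] += g
            rows += [i, j]
            cols += [j, i]
            vals += [-g, -g]
        rows += list(range(n))
        cols += list(range(n))
        vals += list(diag)
        return scipy.sparse.csc_matrix(
            (vals, (rows, cols)), shape=(n, n), dtype=float
        )

    def to_tables(self):
        """(compartment table, edge table) as pandas DataFrames for inspection."""
        import pandas as pd

        comp = pd.DataFrame(
            {
                "comp_id": self.comp_ids,
                "region": self.regions,
                "area_um2": self.areas,
                "g_membrane_uS": self.membrane_conductance,
                "c_membrane_nF": self.membrane_capacitance,
            }
        )
        edge = pd.DataFrame(
            {
                "parent_id": self.comp_ids[self.edges[:, 0]]
                if self.edges.size
                else np.array([], dtype=int),
                "child_id": self.comp_ids[self.edges[:, 1]]
                if self.edges.size
                else np.array([], dtype=int),
                "g_axial_uS": self.g_axial,
            }
        )
        return comp, edge


@dataclass(frozen=True)
class Stimulus:
    """One stimulus applied at a compartment.

    kind: ``current_step`` (amplitude nA), ``current_white_noise``
    (``noise_sd`` nA per sample, ``seed``), or ``voltage_clamp_step``
    (amplitude mV, ideal clamp).  ``onset``/``duration`` in ms.
    """

    site: int
    kind: str = "current_step"
    amplitude: float = 0.0
    onset: float = 0.0
    duration: float = 100.0
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in (
            "current_step",
            "current_white_noise",
            "voltage_clamp_step",
        ):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


@dataclass
class Trace:
    """Sampled voltages at monitored sites (and clamp current if clamped)."""

    time: np.ndarray             # ms, shape (T,)
    voltage: np.ndarray          # mV, shape (n_monitors, T)
    monitors: list               # compartment ids, aligned with rows
    clamp_current: np.ndarray | None = None  # nA, shape (T,)

    def site(self, comp_id: int) -> np.ndarray:
        return self.voltage[self.monitors.index(comp_id)]


@dataclass
class TransferMatrix:
    """Steady-state transfer resistances between sites, MOhm.

    ``R_transfer[i, j]`` is the voltage deflection at site i per unit
    current injected at site j; symmetric for a passive network
    (reciprocity), with input resistances on the diagonal.
    """

    sites: list
    R_transfer: np.ndarray


# -- construction ----------------------------------------------------------


def build_model(morphology: Morphology, params: PassiveParams) -> CompartmentalModel:
    """Discretize a morphology into a passive compartmental model.

    One compartment per node.  A compartment's membrane area is the sum of
    the half-areas of its incident edges (cylinder with mean endpoint
    diameter), so total capacitance and leak match the edge-sum section
    totals; an isolated single node falls back to sphere area ``4 pi r^2``.
    Axial conductance of edge (i, j): ``pi dbar^2 / (4 Ra l)`` converted to
    uS.  Zero-length edges must have been collapsed upstream.
    """
    n = len(morphology)
    if n == 0:
        raise ValueError("cannot build a model from an empty morphology")
    ids = np.array([node.id for node in morphology.nodes], dtype=int)
    regions = np.array([node.region for node in morphology.nodes], dtype=object)
    index = {int(i): k for k, i in enumerate(ids)}

    areas = np.zeros(n)
    edges = []
    g_ax = []
    for parent_id, child_id in morphology.edges():
        length, dbar = edge_geometry(morphology, child_id)
        if length <= 0:
            raise ValueError(
                f"zero-length edge ({parent_id}, {child_id}); collapse it first"
            )
        half_area = 0.5 * math.pi * dbar * length
        i, j = index[parent_id], index[child_id]
        areas[i] += half_area
        areas[j] += half_area
        edges.append((i, j))
        # um / (Ohm*cm) = 1e2 uS
        g_ax.append(math.pi * dbar**2 / (4.0 * params.Ra * length) * 1e2)

    if n == 1:
        areas[0] = 4.0 * math.pi * morphology.root.radius**2

    # uF/cm^2 * um^2 = 1e-5 nF ; S/cm^2 * um^2 = 1e-2 uS
    return CompartmentalModel(
        comp_ids=ids,
        regions=regions,
        areas=areas,
        membrane_conductance=params.gpas * areas * 1e-2,
        membrane_capacitance=params.cm * areas * 1e-5,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        g_axial=np.array(g_ax, dtype=float),
        Epas=params.Epas,
    )


# -- steady state ----------------------------------------------------------


def steady_state(model: CompartmentalModel, injected_currents: dict) -> dict:
    """Exact steady-state voltages (mV) under constant current injection.

    ``injected_currents`` maps compartment id -> nA.  With zero injection
    every compartment sits at ``Epas``.
    """
    rhs = np.zeros(model.n)
    for comp_id, current in injected_currents.items():
        rhs[model.index(comp_id)] += current
    A = model.system_matrix()
    if model.n > 3:
        u = scipy.sparse.linalg.spsolve(A, rhs)
    else:
        u = np.linalg.solve(A.toarray(), rhs)
    return {int(cid): model.Epas + u[k] for k, cid in enumerate(model.comp_ids)}


def input_resistance(model: CompartmentalModel, site: int) -> float:
    """Steady-state input resistance at ``site`` in MOhm (dV/dI)."""
    v = steady_state(model, {site: 1.0})
    return v[int(site)] - model.Epas


def transfer_matrix(model: CompartmentalModel, sites) -> TransferMatrix:
    """Steady-state transfer resistance matrix over ``sites`` (MOhm).

    Column j holds the voltage deflections per unit current injected at
    site j; by reciprocity of the passive network the matrix is symmetric.
    """
    sites = [int(s) for s in sites]
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate sites")
    A = model.system_matrix()
    lu = scipy.sparse.linalg.splu(A)
    R = np.empty((len(sites), len(sites)))
    for j, s in enumerate(sites):
        rhs = np.zeros(model.n)
        rhs[model.index(s)] = 1.0
        u = lu.solve(rhs)
        R[:, j] = [u[model.index(t)] for t in sites]
    return TransferMatrix(sites=sites, R_transfer=R)


# -- stimuli ---------------------------------------------------------------


def white_noise_current(seed: int, dt: float, sd: float, duration: float) -> np.ndarray:
    """I.i.d. Gaussian current samples (nA), one per time step, reproducible."""
    if not sd > 0:
        raise ValueError("sd must be positive")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, size=n)


def _current_matrix(model, stimuli, time, dt):
    """Injected current per compartment per time step, shape (n, T)."""
    I = np.zeros((model.n, len(time)))
    for stim in stimuli:
        k = model.index(stim.site)
        on = time >= stim.onset - 1e-12
        off = time <= stim.onset + stim.duration + 1e-12
        window = on & off
        if stim.kind == "current_step":
            I[k, window] += stim.amplitude
        elif stim.kind == "current_white_noise":
            samples = white_noise_current(
                stim.seed, dt, stim.noise_sd, stim.duration + dt
            )
            idx = np.flatnonzero(window)
            I[k, idx] += samples[: len(idx)]
    return I


# -- transient simulation --------------------------------------------------


def simulate(
    model: CompartmentalModel,
    stimuli,
    dt: float = DEFAULT_DT,
    t_end: float = None,
    monitors=None,
    method: str = "backward_euler",
) -> Trace:
    """Integrate the passive system from ``V = Epas`` and record monitors.

    Parameters
    ----------
    stimuli : list of Stimulus
    dt : time step, ms (default 0.025).
    t_end : end time, ms; defaults to the latest stimulus end.
    monitors : compartment ids to record (required, non-empty).
    method : ``backward_euler`` (default) or ``crank_nicolson``.

    Voltage clamp pins the clamped compartment to ``Epas + amplitude``
    during its window (ideal clamp); the clamp current needed to hold it
    there is reported on the trace.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not monitors:
        raise ValueError("monitors must be a non-empty list of compartment ids")
    if method not in ("backward_euler", "crank_nicolson"):
        raise ValueError(f"unknown method {method!r}")
    monitors = [int(m) for m in monitors]
    monitor_idx = [model.index(m) for m in monitors]
    stimuli = list(stimuli)
    if t_end is None:
        if not stimuli:
            raise ValueError("t_end required when there are no stimuli")
        t_end = max(s.onset + s.duration for s in stimuli)

    n_steps = int(round(t_end / dt))
    time = np.arange(n_steps + 1) * dt
    clamps = [s for s in stimuli if s.kind == "voltage_clamp_step"]
    currents = [s for s in stimuli if s.kind != "voltage_clamp_step"]
    I = _current_matrix(model, currents, time, dt)

    if not clamps:
        u = _simulate_modal(model, I, dt, method)
        voltage = model.Epas + u[monitor_idx]
        return Trace(time=time, voltage=voltage, monitors=monitors)

    u, clamp_current = _simulate_clamped(model, I, clamps, time, dt, method)
    voltage = model.Epas + u[monitor_idx]
    return Trace(
        time=time, voltage=voltage, monitors=monitors, clamp_current=clamp_current
    )


def _simulate_modal(model, I, dt, method):
    """Exact modal evaluation of the stepping scheme (no clamps).

    Symmetrize with ``w = C^{1/2} u``: ``dw/dt = -K w + C^{-1/2} I`` with
    ``K = C^{-1/2} (G_m + L) C^{-1/2}`` symmetric PSD.  Each eigenmode is a
    scalar recursion identical to the chosen implicit scheme, evaluated by
    ``lfilter``.
    """
    C = model.membrane_capacitance
    s = 1.0 / np.sqrt(C)
    K = model.system_matrix().toarray() * np.outer(s, s)
    lam, Q = scipy.linalg.eigh(K)
    # forcing in modal coordinates, per step: f = Q^T C^{-1/2} I
    F = Q.T @ (I * s[:, None])
    Z = np.zeros_like(F)  # z_0 = 0: initial condition u = 0 at t = 0
    if method == "backward_euler":
        for m in range(len(lam)):
            a1 = 1.0 / (1.0 + lam[m] * dt)
            # z_k = a1 z_{k-1} + dt*a1*f_k  (f at the new time)
            Z[m, 1:] = scipy.signal.lfilter([dt * a1], [1.0, -a1], F[m, 1:])
    else:  # crank_nicolson
        for m in range(len(lam)):
            den = 1.0 + lam[m] * dt / 2.0
            b = [dt / (2 * den), dt / (2 * den)]
            a = [1.0, -(1.0 - lam[m] * dt / 2.0) / den]
            # seed the delay state with the true forcing at t = 0
            Z[m, 1:], _ = scipy.signal.lfilter(b, a, F[m, 1:], zi=[b[1] * F[m, 0]])
    return (Q @ Z) * s[:, None]


def _simulate_clamped(model, I, clamps, time, dt, method):
    """Implicit time loop with pinned compartments during clamp windows."""
    n = model.n
    A = model.system_matrix().toarray()
    C = model.membrane_capacitance
    theta = 1.0 if method == "backward_euler" else 0.5

    u = np.zeros((n, len(time)))
    clamp_current = np.zeros(len(time))
    lhs_cache: dict = {}

    for step in range(1, len(time)):
        t = time[step]
        active = [
            c
            for c in clamps
            if c.onset - 1e-12 <= t <= c.onset + c.duration + 1e-12
        ]
        key = tuple(sorted((c.site, c.amplitude) for c in active))
        if key not in lhs_cache:
            lhs = np.diag(C) / dt + theta * A
            for c in active:
                k = model.index(c.site)
                lhs[k, :] = 0.0
                lhs[k, k] = 1.0
            lhs_cache[key] = scipy.linalg.lu_factor(lhs)
        lu = lhs_cache[key]

        rhs = (
            C / dt * u[:, step - 1]
            - (1.0 - theta) * (A @ u[:, step - 1])
            + theta * I[:, step]
            + (1.0 - theta) * I[:, step - 1]
        )
        for c in active:
            rhs[model.index(c.site)] = c.amplitude
        u[:, step] = scipy.linalg.lu_solve(lu, rhs)

        # clamp current: residual of the unmodified balance at the pinned node
        for c in active:
            k = model.index(c.site)
            residual = (
                C[k] / dt * (u[k, step] - u[k, step - 1])
                + theta * (A[k] @ u[:, step])
                + (1.0 - theta) * (A[k] @ u[:, step - 1])
                - theta * I[k, step]
                - (1.0 - theta) * I[k, step - 1]
            )
            clamp_current[step] += residual
    return u, clamp_current
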