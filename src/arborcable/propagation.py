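"""Virtual voltage-propagation experiments on a passive model.

Implements the region-to-region propagation protocol (random injection
sites, calibrated square-pulse amplitudes, windowed monitors), the
steady-state asymmetry identity that explains directional propagation bias
(the ratio of propagated proportions between two sites equals the inverse
ratio of their input resistances, by reciprocity), the virtual ablation
experiment (sever the neurite leading into the LH and compare odor-like
responses before/after), and a reduced three-compartment model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable_model import (
    CompartmentalModel,
    PassiveParams,
    Stimulus,
    Trace,
    build_model,
    input_resistance,
    simulate,
    steady_state,
    transfer_matrix,
)
from .morphology import Morphology, sever

__all__ = [
    "InjectionExperiment",
    "MonitorWindows",
    "PropagationResult",
    "membrane_time_constant",
    "calibrate_amplitude",
    "make_monitor_windows",
    "run_injection_experiment",
    "asymmetry_identity",
    "ablation_experiment",
    "three_compartment_model",
]


@dataclass(frozen=True)
class InjectionExperiment:
    """Protocol: repeated random-site square-pulse injections in one region.

    Injection amplitudes are calibrated per site so the local peak
    deflection falls in ``target_local_deflection`` (mV).  ``pulse`` is the
    square-wave duration in ms; if None it defaults to 10x the membrane
    time constant so peak and steady state coincide.
    """

    source_region: str
    n_sites: int = 10
    n_repeats: int = 6
    target_local_deflection: tuple = (2.0, 20.0)
    pulse: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        lo, hi = self.target_local_deflection
        if not (0 < lo < hi):
            raise ValueError("target interval must be positive and ordered")


@dataclass
class MonitorWindows:
    """Named, disjoint groups of monitor compartments."""

    windows: dict  # name -> list of compartment ids

    def __post_init__(self):
        seen = set()
        for name, sites in self.windows.items():
            for s in sites:
                if s in seen:
                    raise ValueError(f"monitor windows overlap at compartment {s}")
                seen.add(s)

    def all_sites(self):
        return [s for sites in self.windows.values() for s in sites]


@dataclass
class PropagationResult:
    """Tidy per-(site, repeat, window) peaks and proportions plus summaries."""

    table: pd.DataFrame  # source_region, window, site, repeat, peak_mV, proportion
    source_region: str

    def summary(self) -> pd.DataFrame:
        """Mean and SD of the proportion per window, over sites and repeats."""
        return (
            self.table.groupby("window")["proportion"]
            .agg(["mean", "std"])
            .reset_index()
        )


def membrane_time_constant(model: CompartmentalModel) -> float:
    """Largest isolated-compartment membrane time constant, ms (cm/gpas)."""
    return float(
        np.max(model.membrane_capacitance / model.membrane_conductance)
    )


def calibrate_amplitude(
    model: CompartmentalModel,
    site: int,
    pulse_duration: float,
    target: tuple = (2.0, 20.0),
    dt: float = 0.1,
) -> float:
    """Bisection on injected current until the local peak lies in ``target``.

    Returns the amplitude in nA.  Deterministic; raises if the target
    interval is below the numerical floor.
    """
    lo_t, hi_t = target
    if not (0 < lo_t < hi_t):
        raise ValueError("target interval must be positive and ordered")

    def peak(amplitude: float) -> float:
        trace = simulate(
            model,
            [Stimulus(site=site, kind="current_step", amplitude=amplitude,
                      onset=0.0, duration=pulse_duration)],
            dt=dt,
            t_end=pulse_duration,
            monitors=[site],
        )
        return float(np.max(np.abs(trace.site(site) - model.Epas)))

    lo, hi = 1e-9, 1e-9
    while peak(hi) < lo_t:
        hi *= 10.0
        if hi > 1e6:
            raise ValueError("target deflection unreachable")
    if peak(hi) <= hi_t:
        return hi
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        p = peak(mid)
        if lo_t <= p <= hi_t:
            return mid
        if p < lo_t:
            lo = mid
        else:
            hi = mid
    raise ValueError("bisection failed to land in the target interval")


def make_monitor_windows(
    morphology: Morphology, seed: int = 0, n_al: int = 3, n_lh: int = 3
) -> MonitorWindows:
    """Standard windows: cell body (1 site), AL center (3), LH (3).

    The AL sites are drawn from the 20% of AL nodes nearest the AL centroid
    ("center of the AL"); LH sites are drawn uniformly from the LH nodes.
    """
    rng = np.random.default_rng(seed)
    soma = [morphology.root.id]

    al_ids = morphology.region_nodes("AL")
    lh_ids = morphology.region_nodes("LH")
    if not al_ids or not lh_ids:
        raise ValueError("morphology must contain AL and LH nodes")
    positions = np.array([morphology.node(i).position for i in al_ids])
    centroid = positions.mean(axis=0)
    dist = np.linalg.norm(positions - centroid, axis=1)
    n_central = max(n_al, int(math.ceil(0.2 * len(al_ids))))
    central = [al_ids[k] for k in np.argsort(dist)[:n_central]]
    al_pick = list(rng.choice(central, size=min(n_al, len(central)), replace=False))
    lh_pick = list(rng.choice(lh_ids, size=min(n_lh, len(lh_ids)), replace=False))
    return MonitorWindows(
        windows={"CB": soma, "AL": [int(x) for x in al_pick],
                 "LH": [int(x) for x in lh_pick]}
    )


def run_injection_experiment(
    model: CompartmentalModel,
    experiment: InjectionExperiment,
    monitors: MonitorWindows,
    dt: float = 0.1,
) -> PropagationResult:
    """Random-site calibrated injections; peak |dV| per window and proportions.

    For each repeat, ``n_sites`` source compartments are drawn uniformly
    from the source region's compartments (with replacement, with a
    warning, if the region is smaller than ``n_sites``).  Each injection is
    calibrated to the target deflection, simulated, and the peak absolute
    deflection of each window (mean over the window's sites) is expressed
    as a proportion of the peak at the source compartment.
    """
    region_comps = model.region_compartments(experiment.source_region)
    if len(region_comps) == 0:
        raise ValueError(f"region {experiment.source_region!r} has no compartments")
    replace = len(region_comps) < experiment.n_sites
    if replace:
        warnings.warn(
            f"region {experiment.source_region!r} has fewer compartments than "
            f"n_sites; sampling with replacement"
        )
    rng = np.random.default_rng(experiment.seed)
    pulse = experiment.pulse
    if pulse is None:
        pulse = 10.0 * membrane_time_constant(model)

    rows = []
    for repeat in range(experiment.n_repeats):
        sites = rng.choice(region_comps, size=experiment.n_sites, replace=replace)
        for site in sites:
            site = int(site)
            amp = calibrate_amplitude(
                model, site, pulse, experiment.target_local_deflection, dt=dt
            )
            monitor_ids = monitors.all_sites()
            all_monitors = monitor_ids + ([site] if site not in monitor_ids else [])
            trace = simulate(
                model,
                [Stimulus(site=site, kind="current_step", amplitude=amp,
                          onset=0.0, duration=pulse)],
                dt=dt,
                t_end=pulse,
                monitors=all_monitors,
            )
            dv = np.abs(trace.voltage - model.Epas)
            source_peak = float(np.max(dv[all_monitors.index(site)]))
            for name, window_sites in monitors.windows.items():
                peaks = [
                    float(np.max(dv[all_monitors.index(s)])) for s in window_sites
                ]
                window_peak = float(np.mean(peaks))
                rows.append(
                    {
                        "source_region": experiment.source_region,
                        "window": name,
                        "site": site,
                        "repeat": repeat,
                        "peak_mV": window_peak,
                        "proportion": window_peak / source_peak,
                    }
                )
    return PropagationResult(
        table=pd.DataFrame(rows), source_region=experiment.source_region
    )


def asymmetry_identity(model: CompartmentalModel, site_a: int, site_b: int):
    """Directional propagation bias versus the input-resistance ratio.

    At steady state the proportion propagated a->b is ``Z_ba / Z_aa`` and
    b->a is ``Z_ab / Z_bb``; since ``Z_ab = Z_ba`` (reciprocity), their
    ratio equals ``R_in(b) / R_in(a)`` exactly.  Returns
    ``(ratio_of_proportions, input_resistance_ratio)`` computed through the
    two independent routes (transfer matrix vs two direct steady-state
    solves) so the identity can be checked numerically.
    """
    if int(site_a) == int(site_b):
        raise ValueError("sites must be distinct")
    T = transfer_matrix(model, [site_a, site_b])
    R = T.R_transfer
    prop_ab = R[1, 0] / R[0, 0]
    prop_ba = R[0, 1] / R[1, 1]
    ratio_props = prop_ab / prop_ba
    ratio_rin = input_resistance(model, site_b) / input_resistance(model, site_a)
    return ratio_props, ratio_rin


def ablation_experiment(
    morphology: Morphology,
    params: PassiveParams,
    cut_edge: tuple,
    lh_excitation,
    al_inhibition,
    lh_monitors=None,
    dt: float = 0.1,
    t_end: float | None = None,
):
    """Peak LH depolarization before and after severing one edge.

    Before: the intact model is simulated with the LH excitatory stimuli
    and the AL hyperpolarizing stimuli together.  After: the morphology is
    severed at ``cut_edge``, the component containing the LH monitors is
    rebuilt, and only the stimuli whose target compartments survived are
    applied -- so an AL-isolating cut removes the AL inhibition while a
    contralateral (control) cut leaves it in place.  Returns
    ``(peak_before, peak_after)`` in mV, each the mean over the LH monitor
    sites of the peak signed depolarization relative to Epas.

    Raises if the cut splits the LH monitors across components.
    """
    if lh_monitors is None:
        lh_monitors = morphology.region_nodes("LH")
    if not lh_monitors:
        raise ValueError("no LH monitor sites")
    stimuli = list(lh_excitation) + list(al_inhibition)
    if t_end is None:
        t_end = max(s.onset + s.duration for s in stimuli)

    def peak_lh(model, stims):
        trace = simulate(model, stims, dt=dt, t_end=t_end, monitors=list(lh_monitors))
        return float(np.mean(np.max(trace.voltage - model.Epas, axis=1)))

    before = peak_lh(build_model(morphology, params), stimuli)

    proximal, distal = sever(morphology, cut_edge)
    prox_ids = {n.id for n in proximal.nodes}
    dist_ids = {n.id for n in distal.nodes}
    in_prox = [m for m in lh_monitors if m in prox_ids]
    in_dist = [m for m in lh_monitors if m in dist_ids]
    if in_prox and in_dist:
        raise ValueError("cut splits the LH monitor sites across components")
    part = proximal if in_prox else distal
    kept_ids = prox_ids if in_prox else dist_ids
    kept_stimuli = [s for s in stimuli if s.site in kept_ids]
    if not any(s.site in kept_ids for s in lh_excitation):
        raise ValueError("cut removed the LH excitation sites")

    after = peak_lh(build_model(part, params), kept_stimuli)
    return before, after


def three_compartment_model(
    R_soma: float,
    R_al: float,
    R_lh: float,
    g_couple_soma_al: float,
    g_couple_al_lh: float,
    cm: float = 0.01,
    Epas: float = -45.0,
) -> CompartmentalModel:
    """Reduced chain model soma -- AL -- LH.

    Membrane resistances in MOhm per compartment, couplings in uS, ``cm``
    in nF (scalar or per-compartment).  The 3x3 steady-state system is
    small enough to solve by hand, which makes this the reference object
    for the propagation-asymmetry identity: directional bias requires only
    unequal branch resistances.
    """
    for val in (R_soma, R_al, R_lh, g_couple_soma_al, g_couple_al_lh):
        if not val > 0:
            raise ValueError("all resistances and couplings must be positive")
    cap = np.broadcast_to(np.asarray(cm, dtype=float), (3,)).copy()
    return CompartmentalModel(
        comp_ids=np.array([1, 2, 3]),
        regions=np.array(["soma", "AL", "LH"], dtype=object),
        areas=np.ones(3),
        membrane_conductance=np.array([1.0 / R_soma, 1.0 / R_al, 1.0 / R_lh]),
        membrane_capacitance=cap,
        edges=np.array([[0, 1], [1, 2]]),
        g_axial=np.array([g_couple_soma_al, g_couple_al_lh]),
        Epas=Epas,
    )
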