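"""Synthetic data generators: morphologies, recordings, imaging volumes.

Everything the pipeline consumes can be generated here with known ground
truth, so planted-structure recovery and parameter recovery are testable
end to end without any external data.

The imaging generator emulates the study conditions of slow-indicator
volumetric odor imaging: 12 odors, 3-4 repeats each, 90 volumes per trial
at 6.5 volumes/s, odor on at 2 s for 1 s.  AL-like scenarios plant a single
shared non-negative spatial mode with odor-specific *negative* gains
(odor-invariant inhibition) and optionally one sign-flipped outlier odor
(ammonia-like weak excitation); LH-like scenarios plant odor-specific
non-negative excitatory modes with controllable group structure so some
odor pairs are similar.  The default image size is 64 x 64 (the full
256 x 256 of the recordings is available by config); trials differ by
noise only; ground-truth modes are returned for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cable_model import PassiveParams, Stimulus, build_model, simulate
from .fitting import Recording
from .imaging import TrialVolumeSeries, smooth
from .morphology import MorphNode, Morphology

__all__ = [
    "ImagingScenario",
    "EphysScenario",
    "default_protocols",
    "make_three_compartment",
    "make_ball_and_stick",
    "make_random_tree",
    "make_recording",
    "make_imaging",
    "make_paired_ablation",
]


# -- morphologies ------------------------------------------------------------


def make_three_compartment(
    r_soma: float = 3.0,
    r_al: float = 0.5,
    r_lh: float = 0.25,
    l_al: float = 100.0,
    l_lh: float = 100.0,
) -> Morphology:
    """Soma with one AL branch and one LH branch (three nodes).

    The minimal morphology reproducing directional propagation bias: only
    the difference between the two branch resistances matters.
    """
    for v in (r_soma, r_al, r_lh, l_al, l_lh):
        if not v > 0:
            raise ValueError("all dimensions must be positive")
    nodes = [
        MorphNode(1, -1, [0.0, 0.0, 0.0], r_soma, 1, "soma"),
        MorphNode(2, 1, [-l_al, 0.0, 0.0], r_al, 2, "AL"),
        MorphNode(3, 1, [l_lh, 0.0, 0.0], r_lh, 3, "LH"),
    ]
    return Morphology(nodes)


def make_ball_and_stick(
    soma_radius: float = 5.0,
    stick_length: float = 200.0,
    stick_radius: float = 0.5,
    n_nodes: int = 11,
    stick_region: str = "other",
) -> Morphology:
    """Soma plus a straight uniform cable of ``n_nodes - 1`` segments."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    nodes = [MorphNode(1, -1, [0.0, 0.0, 0.0], soma_radius, 1, "soma")]
    for k in range(1, n_nodes):
        x = stick_length * k / (n_nodes - 1)
        nodes.append(
            MorphNode(k + 1, k, [x, 0.0, 0.0], stick_radius, 5, stick_region)
        )
    return Morphology(nodes)


def make_random_tree(
    seed: int = 0,
    n_branchpoints: int = 4,
    region_fractions: dict | None = None,
    radius_range: tuple = (0.05, 0.5),
    total_length: float = 1000.0,
    segment_length: float = 20.0,
) -> Morphology:
    """Random branched tree with contiguous AL and LH subtrees.

    One subtree per requested region hangs off the soma with a total-length
    budget equal to its requested fraction (so realized fractions match the
    request up to the last-segment rounding); each subtree is a random
    binary tree with ``n_branchpoints`` split points, straight segments of
    ~``segment_length`` um in random directions, and radii tapering from
    ``radius_range[1]`` at the soma toward ``radius_range[0]`` at the tips.
    Reproducible under ``seed``.
    """
    if region_fractions is None:
        region_fractions = {"AL": 0.40, "LH": 0.30, "contralateral": 0.20,
                            "other": 0.10}
    if abs(sum(region_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("region fractions must sum to 1")
    rng = np.random.default_rng(seed)
    r_lo, r_hi = radius_range

    nodes = [MorphNode(1, -1, [0.0, 0.0, 0.0], max(r_hi, 1.0), 1, "soma")]
    next_id = [2]
    taper_span = 0.7 * total_length  # path distance over which radii taper

    def radius_at(dist, r_cap):
        # linear taper with path distance from the soma: smooth along runs
        return min(r_cap, r_hi + (r_lo - r_hi) * min(1.0, dist / taper_span))

    def chain(parent_id, origin, direction, length, dist, region, r_cap):
        """Straight chain of ~segment_length pieces consuming ``length`` um."""
        n_seg = max(1, int(round(length / segment_length)))
        pos, pid = origin.copy(), parent_id
        for k in range(n_seg):
            pos = pos + direction * (length / n_seg)
            dist += length / n_seg
            nid = next_id[0]
            next_id[0] += 1
            nodes.append(
                MorphNode(nid, pid, pos.copy(), radius_at(dist, r_cap), 5, region)
            )
            pid = nid
        return pid, pos, dist

    def grow(parent_id, origin, budget, n_bp, region, dist, r_cap=np.inf):
        """Random binary subtree consuming exactly ``budget`` um of length."""
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        if n_bp <= 0 or budget < 3 * segment_length:
            chain(parent_id, origin, direction, budget, dist, region, r_cap)
            return
        stem = budget * rng.uniform(0.15, 0.35)
        pid, pos, dist = chain(parent_id, origin, direction, stem, dist, region, r_cap)
        remaining = budget - stem
        split = rng.uniform(0.3, 0.7)
        left_bp = (n_bp - 1) // 2
        grow(pid, pos, remaining * split, left_bp, region, dist, r_cap)
        grow(pid, pos, remaining * (1 - split), n_bp - 1 - left_bp, region, dist, r_cap)

    for region, frac in region_fractions.items():
        if frac <= 0:
            continue
        budget = total_length * frac
        if region == "contralateral":
            # the contralateral arbor connects through a long commissural
            # neurite of EM-measured caliber (~0.04 um diameter), which makes
            # it electrotonically remote from the ipsilateral arbors
            stem_len = 0.5 * budget
            stem_r = min(r_lo, 0.02)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            n_seg = max(1, int(round(stem_len / segment_length)))
            pid, pos = 1, np.zeros(3)
            for k in range(n_seg):
                pos = pos + direction * (stem_len / n_seg)
                nid = next_id[0]
                next_id[0] += 1
                nodes.append(MorphNode(nid, pid, pos.copy(), stem_r, 5, region))
                pid = nid
            grow(pid, pos, budget - stem_len, n_branchpoints, region, stem_len,
                 r_cap=stem_r)
        else:
            grow(1, np.zeros(3), budget, n_branchpoints, region, 0.0)

    morph = Morphology(nodes)
    # fix the region label enum for nodes
    from .morphology import REGION_TO_LABEL

    for n in morph.nodes:
        n.structure_label = REGION_TO_LABEL[n.region]
    return morph


# -- electrophysiology -------------------------------------------------------


@dataclass
class EphysScenario:
    """Ground-truth somatic recording scenario.

    ``protocols`` is a list of :class:`~arborcable.cable_model.Stimulus`
    applied at the soma; ``noise_sd`` is the Gaussian noise SD added to the
    recorded somatic voltage, in mV.
    """

    morphology: Morphology
    params: PassiveParams
    protocols: list
    noise_sd: float = 0.0
    dt: float = 0.1
    tail: float = 20.0  # ms simulated past the stimulus end
    seed: int = 0

    def __post_init__(self):
        if not self.protocols:
            raise ValueError("protocols must be non-empty")


def default_protocols(
    soma_id: int, noise_seed: int = 7, noise_duration: float = 500.0
) -> list:
    """A current step plus a white-noise epoch, both at the soma.

    Amplitudes are sized to give somatic deflections of a few mV (the 2-20
    mV working range of the calibrated injections), which keeps the axial
    resistivity identifiable against realistic recording noise.
    """
    return [
        Stimulus(site=soma_id, kind="current_step", amplitude=-0.05,
                 onset=10.0, duration=200.0),
        Stimulus(site=soma_id, kind="current_white_noise", noise_sd=0.1,
                 onset=10.0, duration=noise_duration, seed=noise_seed),
    ]


def make_recording(scenario: EphysScenario) -> list:
    """Simulate the ground-truth model per protocol and add recording noise."""
    model = build_model(scenario.morphology, scenario.params)
    soma = scenario.morphology.root.id
    rng = np.random.default_rng(scenario.seed)
    recordings = []
    for stim in scenario.protocols:
        if stim.site != soma:
            raise ValueError("recording protocols must stimulate the soma")
        t_end = stim.onset + stim.duration + scenario.tail
        trace = simulate(
            model, [stim], dt=scenario.dt, t_end=t_end, monitors=[soma]
        )
        voltage = trace.site(soma).copy()
        if scenario.noise_sd > 0:
            voltage = voltage + rng.normal(0.0, scenario.noise_sd, size=len(voltage))
        recordings.append(
            Recording(
                stimulus=stim,
                time=trace.time,
                voltage=voltage,
                dt=scenario.dt,
                clamp_current=trace.clamp_current,
            )
        )
    return recordings


# -- imaging ------------------------------------------------------------------


@dataclass
class ImagingScenario:
    """Odor-response volumetric imaging scenario with planted structure."""

    n_odors: int = 12
    n_trials_per_odor: int = 3
    shape: tuple = (64, 64)
    n_z: int = 7
    n_volumes: int = 90
    volume_rate: float = 6.5
    odor_onset: float = 2.0
    odor_duration: float = 1.0
    mode_type: str = "shared_inhibitory"  # or "odor_specific_excitatory"
    outlier_odor: bool = True   # ammonia-like sign-flipped odor (AL-like mode)
    n_groups: int | None = None  # planted odor groups (LH-like mode)
    amplitude: float = 0.3      # peak |dF/F| scale
    noise_sd: float = 0.02      # per-voxel noise, dF/F units
    seed: int = 0

    def __post_init__(self):
        if self.mode_type not in ("shared_inhibitory", "odor_specific_excitatory"):
            raise ValueError(f"unknown mode_type {self.mode_type!r}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        if min(self.shape) <= 4 or self.n_volumes < 1 or self.n_z < 1:
            raise ValueError("shapes must be positive (and images > 4 px)")

    @property
    def odor_labels(self):
        labels = [f"odor_{k:02d}" for k in range(self.n_odors)]
        if self.mode_type == "shared_inhibitory" and self.outlier_odor:
            labels[-1] = "ammonia"
        return labels


def _blob_mode(rng, shape, n_blobs=4):
    """Smooth non-negative spatial mode, peak-normalized to 1."""
    Y, X = shape
    yy, xx = np.mgrid[0:Y, 0:X]
    mode = np.zeros(shape)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.2 * Y, 0.8 * Y), rng.uniform(0.2 * X, 0.8 * X)
        sy = rng.uniform(0.06, 0.15) * Y
        sx = rng.uniform(0.06, 0.15) * X
        mode += rng.uniform(0.5, 1.0) * np.exp(
            -((yy - cy) ** 2) / (2 * sy**2) - ((xx - cx) ** 2) / (2 * sx**2)
        )
    return mode / mode.max()


def _temporal_kernel(scenario: ImagingScenario) -> np.ndarray:
    """Alpha-function-like rise/decay, unit peak, zero before onset."""
    t = np.arange(scenario.n_volumes) / scenario.volume_rate
    tp = 1.0  # s to peak after onset, slow-indicator-like
    shifted = np.maximum(t - scenario.odor_onset, 0.0)
    kernel = (shifted / tp) * np.exp(1.0 - shifted / tp)
    return kernel


def _ground_truth(scenario: ImagingScenario, rng):
    """Planted modes (n_odors, Y, X), gains and group assignment."""
    n = scenario.n_odors
    gains = scenario.amplitude * rng.uniform(0.6, 1.4, size=n)
    if scenario.mode_type == "shared_inhibitory":
        shared = _blob_mode(rng, scenario.shape)
        signs = -np.ones(n)
        if scenario.outlier_odor:
            signs[-1] = 1.0  # ammonia-like excitation
            gains[-1] *= 0.5  # the excitation is weak
        modes = np.stack([shared] * n)
        groups = np.zeros(n, dtype=int)
        return modes, signs * gains, groups, shared
    # odor-specific excitatory
    n_groups = scenario.n_groups or n
    groups = np.arange(n) % n_groups
    group_modes = [_blob_mode(rng, scenario.shape) for _ in range(n_groups)]
    modes = []
    for k in range(n):
        jitter = 0.25 * _blob_mode(rng, scenario.shape) if n_groups < n else 0.0
        m = group_modes[groups[k]] + jitter
        modes.append(m / m.max())
    return np.stack(modes), gains, groups, None


def make_imaging(scenario: ImagingScenario):
    """Generate odor-response trials with planted spatial structure.

    Returns ``(trials, truth)`` where ``trials`` is a list of
    :class:`~arborcable.imaging.TrialVolumeSeries` (n_odors x
    n_trials_per_odor, noise differs per trial) and ``truth`` a dict with
    the planted ``modes`` (n_odors, Y, X), signed ``gains``, ``groups``,
    ``odor_labels`` and the textured baseline ``f0``.

    The signed dF/F of odor k at the response peak is ``gains[k] *
    modes[k]``; fluorescence is ``F0 * (1 + dff(t)) + F0 * noise`` with the
    temporal kernel applied, clipped at zero only if noise drives a voxel
    negative (warned, never silent).
    """
    rng = np.random.default_rng(scenario.seed)
    Y, X = scenario.shape
    f0 = 100.0 * (1.0 + 0.3 * smooth(rng.uniform(-1, 1, size=(Y, X)), 4, 1.0))
    f0 = np.maximum(f0, 10.0)
    z_gain = np.linspace(0.8, 1.2, scenario.n_z)
    kernel = _temporal_kernel(scenario)

    modes, gains, groups, shared = _ground_truth(scenario, rng)
    labels = scenario.odor_labels

    trials = []
    clipped = 0
    for k in range(scenario.n_odors):
        dff_true = gains[k] * modes[k]  # (Y, X) at peak
        for trial_idx in range(scenario.n_trials_per_odor):
            signal = 1.0 + kernel[:, None, None] * dff_true[None]
            data = (
                f0[None, None] * z_gain[None, :, None, None] * signal[:, None]
            )
            if scenario.noise_sd > 0:
                data = data + f0[None, None] * rng.normal(
                    0.0, scenario.noise_sd, size=data.shape
                )
            neg = data < 0
            if neg.any():
                clipped += int(neg.sum())
                data = np.maximum(data, 0.0)
            trials.append(
                TrialVolumeSeries(
                    data=data,
                    volume_rate=scenario.volume_rate,
                    baseline_s=scenario.odor_onset,
                    odor_onset=scenario.odor_onset,
                    odor_duration=scenario.odor_duration,
                    odor_label=labels[k],
                    trial_index=trial_idx,
                )
            )
    if clipped:
        warnings.warn(f"clipped {clipped} negative voxel value(s) to zero")
    truth = {
        "modes": modes,
        "gains": gains,
        "groups": groups,
        "odor_labels": labels,
        "shared_mode": shared,
        "f0": f0,
    }
    return trials, truth


def make_paired_ablation(scenario: ImagingScenario, gain_factor: float):
    """Before/after trial sets sharing ground truth, response scaled after.

    The after-trials regenerate the same planted modes with all gains
    multiplied by ``gain_factor`` (1.0 = control: no true change) and fresh
    noise.  Returns ``(before_trials, after_trials, truth)``.
    """
    if not gain_factor > 0:
        raise ValueError("gain_factor must be positive")
    before, truth = make_imaging(scenario)
    after_scenario = replace(scenario, seed=scenario.seed + 500_000)
    rng = np.random.default_rng(after_scenario.seed)
    # regenerate with identical structure: reuse truth, fresh noise
    Y, X = scenario.shape
    z_gain = np.linspace(0.8, 1.2, scenario.n_z)
    kernel = _temporal_kernel(scenario)
    f0 = truth["f0"]
    after = []
    for k in range(scenario.n_odors):
        dff_true = gain_factor * truth["gains"][k] * truth["modes"][k]
        for trial_idx in range(scenario.n_trials_per_odor):
            signal = 1.0 + kernel[:, None, None] * dff_true[None]
            data = f0[None, None] * z_gain[None, :, None, None] * signal[:, None]
            if scenario.noise_sd > 0:
                data = data + f0[None, None] * rng.normal(
                    0.0, scenario.noise_sd, size=data.shape
                )
            data = np.maximum(data, 0.0)
            after.append(
                TrialVolumeSeries(
                    data=data,
                    volume_rate=scenario.volume_rate,
                    baseline_s=scenario.odor_onset,
                    odor_onset=scenario.odor_onset,
                    odor_duration=scenario.odor_duration,
                    odor_label=truth["odor_labels"][k],
                    trial_index=trial_idx,
                )
            )
    return before, after, truth
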