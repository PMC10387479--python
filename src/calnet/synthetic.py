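"""Synthetic slice recordings with known (ground-truth) connectivity.

The generator emulates the structure of wide-field somatic calcium
recordings from acute cortical slices: several hundred neurons spread over
the full cortical depth, sampled at a few Hz for ~750 s, with a baseline
period, a brief excitatory stimulus, slow photobleaching and shot-like
noise.  Functional coupling is defined at the level the downstream analysis
infers it: a "connected" pair shares a common Poisson stream of calcium
transients (common drive), so their fluorescence co-fluctuates; everything
else about the two neurons is independent.

Every stochastic quantity flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so outputs are bit-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .core import CalciumRecording, CalnetError, StimulusProtocol

__all__ = [
    "GroundTruthNetwork",
    "DynamicsParams",
    "GroundTruth",
    "generate_network",
    "planted_network",
    "simulate_recording",
    "generate_roi_population",
    "SyntheticCell",
    "ROIPopulation",
]


@dataclass
class GroundTruthNetwork:
    """True coupling structure underlying a simulated recording."""

    depths: np.ndarray                      # (n,) normalized depth in [0, 1]
    adjacency: np.ndarray                   # (n, n) symmetric bool, hollow
    module_labels: np.ndarray               # (n,) depth-band index
    edge_params: dict[tuple[int, int], float]  # (i<j) -> shared-drive strength

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = self.depths.size
        if self.adjacency.shape != (n, n):
            raise CalnetError("adjacency must be n x n")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise CalnetError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise CalnetError("adjacency must have a zero diagonal")
        if np.any((self.depths < 0) | (self.depths > 1)):
            raise CalnetError("depths must lie in [0, 1]")
        for (i, j), s in self.edge_params.items():
            if not self.adjacency[i, j]:
                raise CalnetError(f"edge_params for non-edge ({i}, {j})")
            if s <= 0:
                raise CalnetError(f"edge strength must be > 0, got {s} for ({i}, {j})")

    @property
    def n_neurons(self) -> int:
        return self.depths.size

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.edge_params)


@dataclass(frozen=True)
class DynamicsParams:
    """Calcium-trace dynamics of the simulator.

    base_rate    transient rate per neuron (events/s) outside stimuli
    stim_gain    multiplicative rate gain inside the stimulus and KCl
                 intervals; scalar, or one value per neuron so responsiveness
                 can vary with depth
    shared_rate  event rate of each per-edge common-drive stream (events/s);
                 ``None`` means "same as base_rate"
    kernel_rise / kernel_decay
                 difference-of-exponentials transient kernel time constants
                 (s), normalized to unit peak
    amplitude_mode  'unimodal' or 'bimodal' per-neuron transient amplitude
                 distribution (fluorescence units); the bimodal mode mixes
                 two components at amp_mean/2 and 3*amp_mean/2
    bleach_slope linear photobleaching drift, fluorescence units per frame
    noise_sd     additive Gaussian noise SD, fluorescence units
    f0           baseline fluorescence level (> 0)
    """

    base_rate: float = 0.05
    stim_gain: float | np.ndarray = 6.0
    shared_rate: float | None = None
    kernel_rise: float = 0.3
    kernel_decay: float = 2.0
    amplitude_mode: str = "unimodal"
    amp_mean: float = 10.0
    amp_sd: float = 1.5
    event_jitter_sd: float = 0.25
    bleach_slope: float = -0.002
    noise_sd: float = 1.0
    f0: float = 100.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise CalnetError("f0 must be positive")
        if not (self.kernel_decay > self.kernel_rise > 0):
            raise CalnetError("require kernel_decay > kernel_rise > 0")
        if self.noise_sd < 0:
            raise CalnetError("noise_sd must be non-negative")
        if self.base_rate < 0:
            raise CalnetError("base_rate must be non-negative")
        if self.bleach_slope > 0:
            raise CalnetError("bleach_slope must be <= 0")
        if self.amplitude_mode not in ("unimodal", "bimodal"):
            raise CalnetError("amplitude_mode must be 'unimodal' or 'bimodal'")


@dataclass
class GroundTruth:
    """Everything a recovery test needs about how a recording was generated."""

    network: GroundTruthNetwork
    event_times: list[np.ndarray]                       # own transients per neuron
    shared_event_times: dict[tuple[int, int], np.ndarray]
    amplitudes: np.ndarray                              # per-neuron amplitude
    amplitude_component: np.ndarray                     # bimodal component index
    params: dict
    sub_seeds: dict[str, int]


def generate_network(
    n_neurons: int,
    n_layers: int,
    p_intra: float,
    p_inter: float,
    seed: int,
    edge_strength: float = 3.0,
) -> GroundTruthNetwork:
    """Layered stochastic block model over equal-width depth bands.

    Neurons are split as evenly as possible over ``n_layers`` equal-width
    bands of [0, 1]; depths are uniform within a band.  Edges are drawn
    independently with probability ``p_intra`` within a band and ``p_inter``
    across bands.  Each realized edge receives shared-drive strength
    ``edge_strength``.
    """
    if n_neurons < 2:
        raise CalnetError(f"need at least 2 neurons, got {n_neurons}")
    if n_layers < 1:
        raise CalnetError("n_layers must be >= 1")
    if not (0 <= p_inter <= p_intra <= 1):
        raise CalnetError(
            f"require 0 <= p_inter <= p_intra <= 1, got p_inter={p_inter}, p_intra={p_intra}"
        )
    if edge_strength <= 0:
        raise CalnetError("edge_strength must be > 0")
    rng = np.random.default_rng(seed)

    labels = np.repeat(np.arange(n_layers), np.diff(np.linspace(0, n_neurons, n_layers + 1).astype(int)))
    band_width = 1.0 / n_layers
    depths = (labels + rng.uniform(size=n_neurons)) * band_width

    same = labels[:, None] == labels[None, :]
    p = np.where(same, p_intra, p_inter)
    u = rng.uniform(size=(n_neurons, n_neurons))
    upper = np.triu(u < p, k=1)
    adjacency = upper | upper.T

    edge_params = {
        (int(i), int(j)): float(edge_strength) for i, j in zip(*np.nonzero(upper))
    }
    return GroundTruthNetwork(depths, adjacency, labels, edge_params)


def planted_network(
    n_neurons: int,
    n_edges: int,
    strength: float,
    seed: int,
    disjoint: bool = False,
) -> GroundTruthNetwork:
    """Network with exactly ``n_edges`` edges planted at random.

    Convenience constructor for recovery experiments where the exact edge
    count matters (a block model only fixes it in expectation).  With
    ``disjoint=True`` the planted edges form a matching (no shared
    endpoints), so each pair's common drive is undiluted by other edges —
    the clean setting for measuring edge-recovery sensitivity, since a
    neuron on several edges splits its co-fluctuation among partners.
    """
    if n_neurons < 2:
        raise CalnetError("need at least 2 neurons")
    max_edges = (n_neurons // 2) if disjoint else n_neurons * (n_neurons - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise CalnetError(f"n_edges must be in [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    depths = rng.uniform(size=n_neurons)
    adjacency = np.zeros((n_neurons, n_neurons), dtype=bool)
    edge_params: dict[tuple[int, int], float] = {}
    if disjoint:
        order = rng.permutation(n_neurons)
        edges = [tuple(sorted(order[2 * k : 2 * k + 2])) for k in range(n_edges)]
    else:
        pairs = [(i, j) for i in range(n_neurons) for j in range(i + 1, n_neurons)]
        edges = [pairs[k] for k in rng.choice(len(pairs), size=n_edges, replace=False)]
    for i, j in edges:
        adjacency[i, j] = adjacency[j, i] = True
        edge_params[(int(i), int(j))] = float(strength)
    return GroundTruthNetwork(depths, adjacency, np.zeros(n_neurons, dtype=int), edge_params)


def _rate_segments(protocol: StimulusProtocol) -> list[tuple[float, float, float]]:
    """(t0, t1, gain) segments of the piecewise-constant event-rate profile."""
    s0, s1 = protocol.stim_interval
    k0, k1 = protocol.kcl_interval
    T = protocol.total_duration
    segs = [
        (0.0, s0, 1.0),
        (s0, min(s1, T), None),  # gain filled by caller (may be per-neuron)
        (min(s1, T), k0, 1.0),
        (k0, min(k1, T), None),
        (min(k1, T), T, 1.0),
    ]
    return [(a, b, g) for a, b, g in segs if b > a]


def _poisson_times(
    rng: np.random.Generator,
    rate: float,
    segments: Sequence[tuple[float, float, float]],
    gain: float,
) -> np.ndarray:
    """Event times of a piecewise-homogeneous Poisson process."""
    out = []
    for t0, t1, g in segments:
        r = rate * (gain if g is None else g)
        if r <= 0:
            continue
        n = rng.poisson(r * (t1 - t0))
        if n:
            out.append(rng.uniform(t0, t1, size=n))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def _transient_kernel(dyn: DynamicsParams, fs: float) -> np.ndarray:
    t = np.arange(0.0, 8.0 * dyn.kernel_decay, 1.0 / fs)
    k = np.exp(-t / dyn.kernel_decay) - np.exp(-t / dyn.kernel_rise)
    peak = k.max()
    if peak <= 0:  # pragma: no cover - guarded by DynamicsParams invariants
        raise CalnetError("degenerate transient kernel")
    return k / peak


def _draw_amplitudes(
    rng: np.random.Generator, dyn: DynamicsParams, n: int
) -> tuple[np.ndarray, np.ndarray]:
    if dyn.amplitude_mode == "unimodal":
        comp = np.zeros(n, dtype=int)
        amps = rng.normal(dyn.amp_mean, dyn.amp_sd, size=n)
    else:
        comp = rng.integers(0, 2, size=n)
        means = np.where(comp == 0, 0.5 * dyn.amp_mean, 1.5 * dyn.amp_mean)
        amps = rng.normal(means, dyn.amp_sd)
    return np.clip(amps, 0.05 * dyn.amp_mean, None), comp


def simulate_recording(
    net: GroundTruthNetwork,
    protocol: StimulusProtocol,
    dyn: DynamicsParams,
    seed: int,
) -> tuple[CalciumRecording, GroundTruth]:
    """Simulate one slice recording on top of a ground-truth network.

    Each neuron fires its own Poisson transient train at ``base_rate``
    (multiplied by ``stim_gain`` inside the stimulus and KCl intervals);
    each true edge contributes a common Poisson stream whose transients are
    injected into both endpoints with amplitude scaled by the edge strength.
    Fluorescence is ``f0 + (impulses * kernel) + bleach_slope*frame + noise``.
    """
    n = net.n_neurons
    n_frames = protocol.n_frames
    fs = protocol.fs
    if n_frames < 2:
        raise CalnetError("protocol yields fewer than 2 frames")

    stim_gain = np.broadcast_to(np.asarray(dyn.stim_gain, dtype=float), (n,))
    if np.any(stim_gain < 0):
        raise CalnetError("stim_gain must be non-negative")

    ss = np.random.SeedSequence(seed)
    keys = ["amplitudes", "own_events", "shared_events", "jitter", "noise"]
    children = ss.spawn(len(keys))
    sub_seeds = {k: int(c.generate_state(1)[0]) for k, c in zip(keys, children)}
    rngs = {k: np.random.default_rng(c) for k, c in zip(keys, children)}

    segments = _rate_segments(protocol)
    amplitudes, comp = _draw_amplitudes(rngs["amplitudes"], dyn, n)

    own_events = [
        _poisson_times(rngs["own_events"], dyn.base_rate, segments, stim_gain[i])
        for i in range(n)
    ]
    shared_rate = dyn.base_rate if dyn.shared_rate is None else dyn.shared_rate
    shared_events: dict[tuple[int, int], np.ndarray] = {}
    for i, j in net.edges:
        gain = 0.5 * (stim_gain[i] + stim_gain[j])
        shared_events[(i, j)] = _poisson_times(
            rngs["shared_events"], shared_rate, segments, gain
        )

    jit = rngs["jitter"]

    def _jitter(k: int) -> np.ndarray:
        if dyn.event_jitter_sd <= 0:
            return np.ones(k)
        return jit.lognormal(0.0, dyn.event_jitter_sd, size=k)

    impulses = np.zeros((n, n_frames))
    for i, times in enumerate(own_events):
        if times.size:
            idx = np.minimum((times * fs).astype(int), n_frames - 1)
            np.add.at(impulses[i], idx, amplitudes[i] * _jitter(times.size))
    for (i, j), times in shared_events.items():
        if not times.size:
            continue
        idx = np.minimum((times * fs).astype(int), n_frames - 1)
        scale = net.edge_params[(i, j)] * _jitter(times.size)
        np.add.at(impulses[i], idx, amplitudes[i] * scale)
        np.add.at(impulses[j], idx, amplitudes[j] * scale)

    kernel = _transient_kernel(dyn, fs)
    signal = fftconvolve(impulses, kernel[None, :], mode="full", axes=1)[:, :n_frames]

    frames = np.arange(n_frames)
    fluor = dyn.f0 + signal + dyn.bleach_slope * frames[None, :]
    if dyn.noise_sd > 0:
        fluor = fluor + rngs["noise"].normal(0.0, dyn.noise_sd, size=fluor.shape)

    rec = CalciumRecording(
        fluorescence=fluor, fs=fs, depths=net.depths.copy(), protocol=protocol
    )
    params = asdict(dyn)
    params["stim_gain"] = np.asarray(dyn.stim_gain).tolist()
    gt = GroundTruth(
        network=net,
        event_times=own_events,
        shared_event_times=shared_events,
        amplitudes=amplitudes,
        amplitude_component=comp,
        params={"dynamics": params, "protocol": asdict(protocol), "seed": int(seed)},
        sub_seeds=sub_seeds,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Synthetic ROI populations for the morphometry module
# ---------------------------------------------------------------------------

#: Normalized-depth bands of the two morphometric comparison zones.
ZONES: dict[str, tuple[float, float]] = {"I": (0.7, 0.9), "II": (0.2, 0.5)}

#: Cortical thickness (um) used to place synthetic centroids in image space.
CORTEX_THICKNESS_UM = 1000.0


@dataclass
class SyntheticCell:
    """One synthetic soma outline with its generating parameters."""

    cell_id: str
    outline: np.ndarray          # (n_vertices, 2) in um, closed implicitly
    depth: float                 # normalized depth of the centroid
    true_area: float             # pi*a*b of the generating ellipse (um^2)
    true_roundness: float        # minor/major of the generating ellipse
    zone: str                    # 'I', 'II' or 'none'


@dataclass
class ROIPopulation:
    cells: list[SyntheticCell]
    #: straight boundary polylines in image coordinates (um): white matter at
    #: y=0, pial surface at y=CORTEX_THICKNESS_UM
    wm_line: np.ndarray
    pial_line: np.ndarray
    zone_effects: dict


def _zone_of(depth: float) -> str:
    for name, (lo, hi) in ZONES.items():
        if lo <= depth <= hi:
            return name
    return "none"


def generate_roi_population(
    n_cells: int,
    zone_effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    n_vertices: int = 24,
    mean_area: float = 120.0,
    log_area_sd: float = 0.2,
    mean_roundness: float = 0.7,
    roundness_sd: float = 0.12,
    field_width: float = 500.0,
) -> ROIPopulation:
    """Synthetic soma outlines with optional planted zone effects.

    Each cell is an ellipse outline (``n_vertices`` points exactly on the
    ellipse, random orientation) whose area is lognormal around
    ``mean_area`` um^2 and whose roundness (minor/major) is a clipped
    normal.  ``zone_effects`` maps zone name ('I' or 'II') to relative
    shifts, e.g. ``{"I": {"area": 0.15}}`` enlarges Zone-I somata by 15%;
    a ``"roundness"`` entry is an additive shift.  Generating area and
    roundness are recorded per cell as ground truth.
    """
    if n_cells < 1:
        raise CalnetError("n_cells must be >= 1")
    effects = {k: dict(v) for k, v in (zone_effects or {}).items()}
    for z in effects:
        if z not in ZONES:
            raise CalnetError(f"unknown zone {z!r}; known zones: {sorted(ZONES)}")
    rng = np.random.default_rng(seed)

    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    cells: list[SyntheticCell] = []
    for c in range(n_cells):
        depth = float(rng.uniform())
        zone = _zone_of(depth)
        area = float(rng.lognormal(np.log(mean_area), log_area_sd))
        roundness = float(np.clip(rng.normal(mean_roundness, roundness_sd), 0.2, 0.98))
        eff = effects.get(zone, {})
        area *= 1.0 + eff.get("area", 0.0)
        roundness = float(np.clip(roundness + eff.get("roundness", 0.0), 0.05, 1.0))

        a = np.sqrt(area / (np.pi * roundness))   # semi-major
        b = roundness * a                         # semi-minor
        phi = rng.uniform(0, np.pi)
        x = a * np.cos(theta)
        y = b * np.sin(theta)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        pts = np.column_stack([x, y]) @ rot.T
        centre = np.array(
            [rng.uniform(0, field_width), depth * CORTEX_THICKNESS_UM]
        )
        cells.append(
            SyntheticCell(
                cell_id=f"c{c:05d}",
                outline=pts + centre,
                depth=depth,
                true_area=area,
                true_roundness=roundness,
                zone=zone,
            )
        )

    wm_line = np.array([[-50.0, 0.0], [field_width + 50.0, 0.0]])
    pial_line = np.array(
        [[-50.0, CORTEX_THICKNESS_UM], [field_width + 50.0, CORTEX_THICKNESS_UM]]
    )
    return ROIPopulation(cells=cells, wm_line=wm_line, pial_line=pial_line, zone_effects=effects)
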