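"""Synthetic smFRET trajectory generation.

State paths are sampled with an exact (Gillespie-style) event algorithm from
the target's continuous-time Markov scheme and only then binned into camera
frames, so dwells comparable to the 0.1 s frame interval are represented
without discretization bias.  Photobleaching is a single exponential,
trace-terminating event drawn independently of the path (either fluorophore's
loss ends the FRET observable).

Each camera frame reports the occupancy-time-weighted average FRET of the
states visited during that frame; donor and acceptor counts then follow the
emission model (total intensity split by FRET, donor->acceptor leakage on the
background-free donor signal, additive channel backgrounds, Gaussian noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schemes import (
    STATE_INDEX,
    STATE_NAMES,
    EmissionModel,
    KineticScheme,
    TargetPreset,
    get_preset,
)

__all__ = [
    "StatePath",
    "IntensityTrace",
    "SimulatedDataset",
    "simulate_state_path",
    "emit_intensities",
    "generate_dataset",
]


@dataclass
class StatePath:
    """Piecewise-constant state trajectory of one molecule.

    ``states[i]`` occupies ``[t_start[i], t_end[i])``; segments are contiguous
    and cover ``[0, duration)``.  ``bleach_time`` is the (possibly infinite)
    time of the photobleach event.
    """

    states: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    bleach_time: float
    duration: float

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("empty state path")
        if np.any(self.t_end <= self.t_start):
            raise ValueError("segments must have positive duration")
        if not np.allclose(self.t_start[1:], self.t_end[:-1]):
            raise ValueError("segments must be contiguous")

    def dwell_durations(self, state: int | str) -> np.ndarray:
        """True (pre-binning) dwell durations of one state, excluding the
        first and last segments which are censored by the observation window."""
        idx = STATE_INDEX[state] if isinstance(state, str) else state
        mask = self.states == idx
        mask[0] = mask[-1] = False
        return (self.t_end - self.t_start)[mask]

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State index occupied at each time (vectorized)."""
        i = np.searchsorted(self.t_end, np.asarray(t), side="right")
        return self.states[np.clip(i, 0, len(self.states) - 1)]


@dataclass
class IntensityTrace:
    """Raw per-frame donor/acceptor counts for one molecule."""

    molecule_id: str
    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


@dataclass
class SimulatedDataset:
    """Traces plus the manifest (and, for tests, the ground-truth paths)."""

    traces: list[IntensityTrace]
    manifest: dict
    paths: list[StatePath] = field(default_factory=list)


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    seed=None,
    initial_state: int | str = "U",
    concentration: float | None = None,
) -> StatePath:
    """Sample one continuous-time Markov path and its photobleach time.

    ``initial_state`` may be a state name/index or ``"stationary"`` to draw
    the start from the scheme's stationary distribution (steady-state
    imaging); association experiments start in ``"U"``.
    """
    if not (np.isfinite(duration) and duration > 0):
        raise ValueError("duration must be positive")
    rng = _resolve_rng(seed)
    q = scheme.rate_matrix(concentration)

    bleach_time = (
        rng.exponential(1.0 / scheme.photobleach_rate)
        if scheme.photobleach_rate > 0
        else np.inf
    )

    if initial_state == "stationary":
        pi = scheme.stationary_distribution(concentration)
        state = int(rng.choice(3, p=pi))
    elif isinstance(initial_state, str):
        state = STATE_INDEX[initial_state]
    else:
        state = int(initial_state)

    states, starts, ends = [], [], []
    t = 0.0
    while t < duration:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            dwell = duration - t
            nxt = state
        else:
            dwell = rng.exponential(1.0 / exit_rate)
            p = q[state].copy()
            p[state] = 0.0
            nxt = int(rng.choice(3, p=p / p.sum()))
        t_end = min(t + dwell, duration)
        states.append(state)
        starts.append(t)
        ends.append(t_end)
        t = t + dwell
        state = nxt
    return StatePath(
        states=np.array(states, dtype=np.int8),
        t_start=np.array(starts),
        t_end=np.array(ends),
        bleach_time=float(bleach_time),
        duration=float(duration),
    )


def emit_intensities(
    path: StatePath,
    scheme: KineticScheme,
    emission: EmissionModel,
    n_frames: int,
    seed=None,
    molecule_id: str = "mol0",
) -> IntensityTrace:
    """Bin a state path into camera frames and add emission noise.

    Per frame the acceptor signal is ``total_intensity * fret_bar`` and the
    donor signal ``total_intensity * (1 - fret_bar)`` where ``fret_bar`` is
    the occupancy-time-weighted FRET over the live (pre-bleach) part of the
    frame; after the bleach both channels carry background and noise only.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    dt = emission.frame_interval
    if n_frames * dt > path.duration + 1e-9:
        raise ValueError("frame span exceeds the simulated path duration")
    rng = _resolve_rng(seed)
    fret_means = np.asarray(scheme.fret_means)

    live = np.zeros(n_frames)  # seconds of pre-bleach occupancy per frame
    fret_t = np.zeros(n_frames)  # time-integral of FRET per frame
    span = n_frames * dt
    for s, t0, t1 in zip(path.states, path.t_start, path.t_end):
        a = max(t0, 0.0)
        b = min(t1, span, path.bleach_time)
        if b <= a:
            continue
        i0 = int(a // dt)
        i1 = min(int(np.ceil(b / dt - 1e-12)), n_frames)
        edges = np.arange(i0, i1 + 1) * dt
        ov = np.minimum(edges[1:], b) - np.maximum(edges[:-1], a)
        live[i0:i1] += ov
        fret_t[i0:i1] += ov * fret_means[s]

    sig_acc = emission.total_intensity * fret_t / dt
    sig_don = emission.total_intensity * (live - fret_t) / dt
    donor = sig_don + emission.background_donor
    acceptor = (
        sig_acc
        + emission.leakage_fraction * sig_don
        + emission.background_acceptor
    )
    if emission.channel_noise_sd > 0:
        donor = donor + rng.normal(0.0, emission.channel_noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, emission.channel_noise_sd, n_frames)
    return IntensityTrace(
        molecule_id=molecule_id,
        time_s=np.arange(n_frames) * dt,
        donor=donor,
        acceptor=acceptor,
        frame_interval=dt,
    )


def generate_dataset(
    preset: TargetPreset | str,
    n_molecules: int,
    duration: float,
    seed: int,
    emission: EmissionModel | None = None,
    concentration: float | None = None,
    initial_state: int | str = "stationary",
    molecule_ids: list[str] | None = None,
    keep_paths: bool = True,
) -> SimulatedDataset:
    """Simulate a dataset of molecules for one target preset.

    The manifest records the preset name, concentration, frame interval, seed
    and the full ground-truth parameter block; the same seed reproduces the
    dataset byte-for-byte.
    """
    if isinstance(preset, str):
        preset = get_preset(preset, concentration)
    scheme = preset.scheme
    if concentration is not None:
        scheme = scheme.with_concentration(concentration)
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    emission = emission or EmissionModel()

    if molecule_ids is None:
        molecule_ids = [f"mol{i:05d}" for i in range(n_molecules)]
    if len(molecule_ids) != n_molecules:
        raise ValueError("molecule_ids length must equal n_molecules")
    if len(set(molecule_ids)) != n_molecules:
        raise ValueError("duplicate molecule ids")

    n_frames = int(round(duration / emission.frame_interval))
    children = np.random.SeedSequence(seed).spawn(n_molecules)
    traces, paths = [], []
    for mol_id, child in zip(molecule_ids, children):
        rng = np.random.default_rng(child)
        path = simulate_state_path(
            scheme, duration, rng, initial_state=initial_state
        )
        traces.append(
            emit_intensities(path, scheme, emission, n_frames, rng, mol_id)
        )
        if keep_paths:
            paths.append(path)

    try:
        tau_avg = scheme.mean_bound_lifetime()
    except ValueError:
        tau_avg = None
    manifest = {
        "preset": preset.name,
        "mismatch_interval": list(preset.mismatch_interval)
        if preset.mismatch_interval
        else None,
        "concentration_molar": scheme.concentration,
        "frame_interval_s": emission.frame_interval,
        "seed": int(seed),
        "n_molecules": n_molecules,
        "duration_s": float(duration),
        "initial_state": str(initial_state),
        "emission": {
            "total_intensity": emission.total_intensity,
            "channel_noise_sd": emission.channel_noise_sd,
            "background_donor": emission.background_donor,
            "background_acceptor": emission.background_acceptor,
            "leakage_fraction": emission.leakage_fraction,
        },
        "ground_truth": {
            "rate_constants": {
                f"{a}->{b}": {"value": rc.value, "per_molar": rc.per_molar}
                for (a, b), rc in scheme.rate_constants.items()
            },
            "fret_means": list(scheme.fret_means),
            "photobleach_rate_s": scheme.photobleach_rate,
            "tau_avg_bound_s": tau_avg,
            "tau_mid_s": scheme.mid_state_lifetime()
            if scheme.rate("S", "U") + scheme.rate("S", "H") > 0
            else None,
            "kon_M_s": scheme.total_association_rate_constant(),
        },
    }
    return SimulatedDataset(traces=traces, manifest=manifest, paths=paths)
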