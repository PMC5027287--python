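"""Standard end-to-end analysis recipes.

Each function simulates a dataset for one target preset and runs the
corresponding measurement exactly as the pipeline does: association kinetics
from unbound dwells, bound-state lifetimes from thresholded dwell survival
with photobleach correction, sampling-state lifetimes and FRET state means
from HMM idealization.  They are used by the reproduction script and the
test suite at different problem sizes.
"""

from __future__ import annotations

import numpy as np

from .correct import AnalysisConfig, build_histogram, correct_trace
from .dwells import (
    correct_photobleach_rate,
    estimate_photobleach_rate,
    extract_dwells,
    fit_survival,
)
from .idealize import aggregate_state_means, idealize_trajectories
from .simulate import generate_dataset

__all__ = [
    "simulate_and_correct",
    "association_rate_run",
    "bound_lifetime_run",
    "sampling_lifetime_run",
    "state_mean_run",
    "corrected_dissociation_run",
    "bound_fraction_profile",
]


def simulate_and_correct(
    preset: str,
    n_molecules: int,
    duration: float,
    seed: int,
    initial_state: str = "stationary",
    concentration: float | None = None,
):
    ds = generate_dataset(
        preset,
        n_molecules=n_molecules,
        duration=duration,
        seed=seed,
        concentration=concentration,
        initial_state=initial_state,
        keep_paths=False,
    )
    config = AnalysisConfig.from_manifest(ds.manifest)
    trajectories = [correct_trace(t, config) for t in ds.traces]
    return ds, config, trajectories


def association_rate_run(
    n_molecules: int = 300,
    duration: float = 120.0,
    seed: int = 0,
    preset: str = "cognate",
    concentration: float | None = None,
) -> float:
    """Bimolecular association constant (M^-1 s^-1) from an association
    experiment: molecules start unbound, unbound dwells are extracted from
    HMM-idealized trajectories, their single-exponential decay rate is
    photobleach-corrected and divided by the concentration."""
    ds, config, trajectories = simulate_and_correct(
        preset, n_molecules, duration, seed, initial_state="U", concentration=concentration
    )
    idealized = idealize_trajectories(trajectories)
    dwells = []
    for ideal in idealized:
        dwells.extend(extract_dwells(ideal, config))
    fit = fit_survival(
        dwells, dwell_class="unbound", model="single",
        frame_interval=config.frame_interval_s,
    )
    k_pb = estimate_photobleach_rate(trajectories)
    rate = correct_photobleach_rate(
        1.0 / fit.tau_avg_s, k_pb, concentration=ds.manifest["concentration_molar"]
    )
    return rate.k_on_M_s


def bound_lifetime_run(
    preset: str,
    n_molecules: int = 300,
    duration: float = 240.0,
    seed: int = 0,
    model: str = "double",
) -> float:
    """Amplitude-weighted bound-state lifetime (s): thresholded bound dwells
    (FRET > 0.2), maximum-likelihood survival fit with truncated dwells
    treated as complete, then k_actual = k_observed - k_photobleach."""
    _, config, trajectories = simulate_and_correct(preset, n_molecules, duration, seed)
    dwells = []
    for traj in trajectories:
        dwells.extend(extract_dwells(traj, config))
    fit = fit_survival(
        dwells, dwell_class="bound", model=model,
        frame_interval=config.frame_interval_s,
    )
    k_pb = estimate_photobleach_rate(trajectories)
    return correct_photobleach_rate(1.0 / fit.tau_avg_s, k_pb).tau_avg_s


def sampling_lifetime_run(
    n_molecules: int = 500,
    duration: float = 60.0,
    seed: int = 0,
    preset: str = "no_pam",
) -> float:
    """Mean sampling-state (mid-FRET) lifetime (s) from HMM idealization and
    a frame-discretized exponential fit of the mid-state dwells."""
    _, config, trajectories = simulate_and_correct(preset, n_molecules, duration, seed)
    idealized = idealize_trajectories(trajectories)
    dwells = []
    for ideal in idealized:
        dwells.extend(extract_dwells(ideal, config))
    fit = fit_survival(
        dwells, dwell_class="mid", model="single",
        frame_interval=config.frame_interval_s, binning="frame",
    )
    return fit.tau_avg_s


def state_mean_run(
    preset: str,
    state: int,
    n_molecules: int = 200,
    duration: float = 60.0,
    seed: int = 0,
) -> float:
    """Fitted FRET mean of one canonical state (0=zero, 1=mid, 2=high),
    aggregated over per-molecule free-mean HMM fits."""
    _, _, trajectories = simulate_and_correct(preset, n_molecules, duration, seed)
    idealized = idealize_trajectories(trajectories)
    means = aggregate_state_means(idealized)
    return float(means[state])


def corrected_dissociation_run(
    n_molecules: int = 300,
    duration: float = 600.0,
    seed: int = 0,
    preset: str = "cognate",
) -> float:
    """Photobleach-corrected dissociation rate (1/s) of a stably bound
    target whose observed lifetime is photobleaching-limited."""
    _, config, trajectories = simulate_and_correct(preset, n_molecules, duration, seed)
    dwells = []
    for traj in trajectories:
        dwells.extend(extract_dwells(traj, config))
    fit = fit_survival(
        dwells, dwell_class="bound", model="single",
        frame_interval=config.frame_interval_s,
    )
    k_pb = estimate_photobleach_rate(trajectories)
    return correct_photobleach_rate(1.0 / fit.tau_avg_s, k_pb).k_actual_s


def bound_fraction_profile(
    presets: list[str],
    n_molecules: int = 200,
    duration: float = 10.0,
    seed: int = 0,
) -> dict[str, float]:
    """Steady-state bound fraction (FRET > 0.75 in the pooled first frames)
    per target preset."""
    out = {}
    for i, name in enumerate(presets):
        _, config, trajectories = simulate_and_correct(
            name, n_molecules, duration, seed + i
        )
        out[name] = build_histogram(trajectories, config).bound_fraction
    return out
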