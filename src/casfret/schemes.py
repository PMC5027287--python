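"""Kinetic schemes for Cas9-RNA / DNA-target binding.

A :class:`KineticScheme` is a three-state continuous-time Markov chain over

* ``U`` -- unbound DNA (zero FRET),
* ``S`` -- the transient, sequence-nonspecific *sampling* mode (mid FRET,
  ~0.42), interpreted as PAM surveillance,
* ``H`` -- the RNA:DNA *heteroduplex* (R-loop) state (high FRET, ~0.92),

plus a single exponential photobleaching clock that truncates the observable
trajectory.  Rates out of ``U`` may be flagged as concentration-scaled
(second-order, per molar per second); all other rates are first order.

Per-target presets live in ``presets.json`` next to this module.  The preset
rate constants encode reported single-molecule kinetics for an SpCas9 guide
against a mismatch series of DNA targets (association constant ~6e6 M^-1 s^-1,
sampling-mode lifetime ~0.1 s, amplitude-weighted bound lifetimes of ~0.5 s /
~8 s / ~16 s for the 5-20 / 8-20 / 9-20 mismatch targets, photobleach-limited
stability for the cognate target); see docs/methods.md for the derivation of
each number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.linalg import expm

STATE_NAMES: tuple[str, str, str] = ("U", "S", "H")
STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Canonical FRET levels of the zero / mid / high states.
CANONICAL_FRET = (0.0, 0.42, 0.92)


@dataclass(frozen=True)
class RateConstant:
    """A single rate constant.

    ``per_molar`` marks second-order (concentration-scaled) entries; their
    effective first-order rate is ``value * concentration``.
    """

    value: float
    per_molar: bool = False


@dataclass
class KineticScheme:
    """Three-state CTMC with photobleaching for one DNA target.

    Parameters
    ----------
    rate_constants
        Mapping ``(from_state, to_state) -> RateConstant`` using the state
        names ``U``, ``S``, ``H``.  Missing pairs are rate 0.
    fret_means
        True FRET efficiency of each state, ordered (U, S, H).
    photobleach_rate
        Per-second rate of the trace-terminating photobleach event.
    concentration
        Cas9-RNA concentration (molar) used to scale ``per_molar`` entries.
    """

    rate_constants: dict[tuple[str, str], RateConstant]
    fret_means: tuple[float, float, float] = CANONICAL_FRET
    photobleach_rate: float = 0.0
    concentration: float = 20e-9

    def __post_init__(self) -> None:
        for (a, b), rc in self.rate_constants.items():
            if a not in STATE_INDEX or b not in STATE_INDEX or a == b:
                raise ValueError(f"invalid state pair {(a, b)!r}")
            if not np.isfinite(rc.value) or rc.value < 0:
                raise ValueError(f"rate {a}->{b} must be finite and >= 0")
        fm = np.asarray(self.fret_means, dtype=float)
        if fm.shape != (3,) or np.any(fm < 0) or np.any(fm > 1):
            raise ValueError("fret_means must be three values in [0, 1]")
        if fm[0] != 0.0:
            raise ValueError("the unbound state must have FRET mean 0")
        if not np.isfinite(self.photobleach_rate) or self.photobleach_rate < 0:
            raise ValueError("photobleach_rate must be finite and >= 0")
        if not (np.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError("concentration must be positive")

    # ------------------------------------------------------------------
    def rate(self, a: str, b: str, concentration: float | None = None) -> float:
        """Effective first-order rate (1/s) for the transition ``a -> b``."""
        conc = self.concentration if concentration is None else concentration
        rc = self.rate_constants.get((a, b))
        if rc is None:
            return 0.0
        return rc.value * conc if rc.per_molar else rc.value

    def rate_matrix(self, concentration: float | None = None) -> np.ndarray:
        """Generator matrix Q (rows = from-state, Q[i,i] = -sum of exits)."""
        q = np.zeros((3, 3))
        for a, i in STATE_INDEX.items():
            for b, j in STATE_INDEX.items():
                if i != j:
                    q[i, j] = self.rate(a, b, concentration)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def with_concentration(self, concentration: float) -> "KineticScheme":
        return replace(self, concentration=concentration)

    # ------------------------------------------------------------------
    # analytic summaries (used as ground truth in tests)
    def reachable_states(self, concentration: float | None = None) -> np.ndarray:
        """Boolean mask of states reachable from U."""
        q = self.rate_matrix(concentration)
        reach = np.zeros(3, dtype=bool)
        reach[0] = True
        for _ in range(3):
            for i in np.flatnonzero(reach):
                reach |= q[i] > 0
        return reach

    def stationary_distribution(self, concentration: float | None = None) -> np.ndarray:
        """Stationary distribution of the chain restricted to states reachable
        from U (unreachable states get probability 0)."""
        q = self.rate_matrix(concentration)
        reach = self.reachable_states(concentration)
        idx = np.flatnonzero(reach)
        qr = q[np.ix_(idx, idx)]
        n = len(idx)
        a = np.vstack([qr.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi_r, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.zeros(3)
        pi[idx] = np.clip(pi_r, 0, None)
        return pi / pi.sum()

    def occupancy(
        self,
        times: np.ndarray,
        p0: np.ndarray | str = "U",
        concentration: float | None = None,
    ) -> np.ndarray:
        """Master-equation state occupancies P(t) for the given start.

        ``p0`` may be a length-3 probability vector, a state name, or
        ``"stationary"``.
        """
        q = self.rate_matrix(concentration)
        if isinstance(p0, str):
            if p0 == "stationary":
                p0 = self.stationary_distribution(concentration)
            else:
                vec = np.zeros(3)
                vec[STATE_INDEX[p0]] = 1.0
                p0 = vec
        p0 = np.asarray(p0, dtype=float)
        return np.array([p0 @ expm(q * t) for t in np.atleast_1d(times)])

    def first_passage_probability(
        self, t: float, target: str = "H", concentration: float | None = None
    ) -> float:
        """P(the chain has visited ``target`` by time t | start in U)."""
        q = self.rate_matrix(concentration).copy()
        j = STATE_INDEX[target]
        q[j, :] = 0.0  # make the target absorbing
        p0 = np.zeros(3)
        p0[0] = 1.0
        return float((p0 @ expm(q * t))[j])

    def mean_bound_lifetime(self, concentration: float | None = None) -> float:
        """Mean duration of a bound (S or H) episode entered from U.

        Computed from the bound-subspace sub-generator: E[T] = alpha
        (-Q_BB)^-1 1 with the entry distribution alpha proportional to the
        U -> S / U -> H rates.
        """
        alpha, q_bb = self._bound_subspace(concentration)
        t_mean = np.linalg.solve(-q_bb, np.ones(len(alpha)))
        return float(alpha @ t_mean)

    def _bound_subspace(
        self, concentration: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Entry distribution and sub-generator over the bound states (S, H)
        actually reachable from U, for phase-type dwell calculations."""
        q = self.rate_matrix(concentration)
        entry = q[0, 1:]
        if entry.sum() <= 0:
            raise ValueError("scheme never leaves the unbound state")
        reach = entry > 0
        for _ in range(2):  # close under transitions within the bound subspace
            for i in np.flatnonzero(reach):
                reach |= q[1:, 1:][i] > 0
        idx = np.flatnonzero(reach)
        alpha = entry[idx] / entry.sum()
        return alpha, q[1:, 1:][np.ix_(idx, idx)]

    def bound_lifetime_components(
        self, concentration: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exponential-mixture representation (amplitudes, lifetimes) of the
        bound-dwell (phase-type) distribution.  Amplitudes sum to 1; for the
        presets used here both are non-negative."""
        alpha, q_bb = self._bound_subspace(concentration)
        n = len(alpha)
        if n == 1:
            return np.array([1.0]), np.array([-1.0 / q_bb[0, 0]])
        lam, v = np.linalg.eig(q_bb)
        # density f(t) = alpha expm(Q_BB t) (-Q_BB) 1 = sum_i c_i exp(lam_i t)
        w = np.linalg.solve(v, -q_bb @ np.ones(n))
        coef = (alpha @ v) * w  # coefficient of exp(lam_i t)
        taus = -1.0 / np.real(lam)
        amps = np.real(coef) * taus
        order = np.argsort(taus)
        return amps[order], taus[order]

    def total_association_rate_constant(self) -> float:
        """Sum of second-order U-exit rate constants (M^-1 s^-1)."""
        return sum(
            rc.value
            for (a, _), rc in self.rate_constants.items()
            if a == "U" and rc.per_molar
        )

    def mid_state_lifetime(self, concentration: float | None = None) -> float:
        """Mean dwell time in the sampling (mid-FRET) state, 1 / total exit rate."""
        q = self.rate_matrix(concentration)
        return float(-1.0 / q[1, 1])


@dataclass
class TargetPreset:
    """A named DNA target (cognate or ``x-y_mm`` mismatch series) with its
    kinetic scheme.  ``mismatch_interval`` gives the contiguous mismatched
    positions counted from the PAM-proximal end (position 1 next to PAM)."""

    name: str
    scheme: KineticScheme
    mismatch_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mismatch_interval is not None:
            x, y = self.mismatch_interval
            if not (1 <= x <= y <= 20):
                raise ValueError("mismatch interval must satisfy 1 <= x <= y <= 20")


@dataclass(frozen=True)
class EmissionModel:
    """Camera/emission parameters for synthetic two-channel traces."""

    total_intensity: float = 500.0
    channel_noise_sd: float = 30.0
    background_donor: float = 50.0
    background_acceptor: float = 50.0
    leakage_fraction: float = 0.07
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0.0 <= self.leakage_fraction <= 0.2):
            raise ValueError("leakage_fraction must be in [0, 0.2]")
        if self.channel_noise_sd < 0:
            raise ValueError("channel_noise_sd must be >= 0")


# ----------------------------------------------------------------------
def _load_preset_table() -> dict:
    with resources.files(__package__).joinpath("presets.json").open() as fh:
        return json.load(fh)


def load_presets(
    concentration: float | None = None,
) -> dict[str, TargetPreset]:
    """All built-in target presets, optionally re-scaled to a concentration."""
    table = _load_preset_table()
    presets = {}
    for name, entry in table["presets"].items():
        rates = {
            tuple(key.split("->")): RateConstant(spec["value"], spec.get("per_molar", False))
            for key, spec in entry["rates"].items()
        }
        scheme = KineticScheme(
            rate_constants=rates,
            fret_means=tuple(table["fret_means"]),
            photobleach_rate=table["photobleach_rate"],
            concentration=concentration or table["reference_concentration_molar"],
        )
        interval = entry.get("mismatch_interval")
        presets[name] = TargetPreset(
            name=name,
            scheme=scheme,
            mismatch_interval=tuple(interval) if interval else None,
        )
    return presets


def get_preset(name: str, concentration: float | None = None) -> TargetPreset:
    presets = load_presets(concentration)
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None
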