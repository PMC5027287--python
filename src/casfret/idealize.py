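"""Three-state HMM idealization of FRET trajectories.

Each molecule's corrected FRET trace is fitted with its own Gaussian-emission
hidden Markov model (three states: zero, mid, high), initialized at the
canonical FRET levels 0 / 0.42 / 0.92 and refined by expectation-maximization.
Viterbi decoding gives the idealized per-frame state path.

Because expectation-maximization on a single molecule can park two of the
three states on one emission cluster when a level is unvisited, fitted states
are mapped onto the canonical levels (band edges at 0.21 and 0.67, the
midpoints between neighbouring levels) and merged; canonical levels with no
occupancy are flagged degenerate rather than raising.

Camera time-averaging dilutes the frames adjacent to a transition (a frame
half-spent in a state shows half its FRET), which biases raw EM means of
short-dwell states low.  The reported ``state_means`` are therefore
re-estimated from transition-distal (dwell-interior) frames; the raw EM means
remain available as ``means_em_``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

# EM oscillations at tol=1e-6 trigger benign non-convergence warnings
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
from sklearn.base import BaseEstimator

from .correct import FretTrajectory
from .schemes import CANONICAL_FRET

__all__ = [
    "FretHmm",
    "IdealizedTrajectory",
    "TransitionDensity",
    "TransitionRates",
    "fit_hmm",
    "idealize_trajectories",
    "aggregate_state_means",
    "transition_density",
    "estimate_transition_rates",
]

#: Band edges mapping an arbitrary fitted mean onto the canonical levels.
_BAND_EDGES = (
    0.5 * (CANONICAL_FRET[0] + CANONICAL_FRET[1]),
    0.5 * (CANONICAL_FRET[1] + CANONICAL_FRET[2]),
)

ZERO, MID, HIGH = 0, 1, 2
STATE_LABELS = ("zero", "mid", "high")


def _canonical_level(mean: float) -> int:
    if mean < _BAND_EDGES[0]:
        return ZERO
    if mean < _BAND_EDGES[1]:
        return MID
    return HIGH


def _empirical_transmat(labels: np.ndarray, n_states: int = 3) -> np.ndarray:
    """Row-normalized transition counts; unobserved rows get the identity so
    every row sums to 1."""
    t = np.zeros((n_states, n_states))
    if labels.size > 1:
        np.add.at(t, (labels[:-1], labels[1:]), 1.0)
    rowsum = t.sum(axis=1)
    for i in range(n_states):
        if rowsum[i] > 0:
            t[i] /= rowsum[i]
        else:
            t[i, i] = 1.0
    return t


def _interior_means(
    fret: np.ndarray, labels: np.ndarray, n_states: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state mean/sd of FRET over dwell-interior frames (both neighbours
    in the same state); falls back to all frames of the state when a state has
    no interior frames."""
    means = np.full(n_states, np.nan)
    sds = np.full(n_states, np.nan)
    interior = np.zeros(len(labels), dtype=bool)
    if len(labels) >= 3:
        interior[1:-1] = (labels[1:-1] == labels[:-2]) & (labels[1:-1] == labels[2:])
    for s in range(n_states):
        sel = interior & (labels == s)
        if not sel.any():
            sel = labels == s
        if sel.any():
            means[s] = float(np.mean(fret[sel]))
            sds[s] = float(np.std(fret[sel]))
    return means, sds


class FretHmm(BaseEstimator):
    """Per-molecule Gaussian HMM idealizer for FRET traces.

    Parameters
    ----------
    init_means : tuple of float
        EM initialization for the three state means (canonical FRET levels).
    fix_means : bool
        Keep the state means pinned at ``init_means`` during EM.
    n_iter, tol : EM stopping rule (at most ``n_iter`` iterations, stop when
        the log-likelihood improves by less than ``tol``).

    Fitted attributes
    -----------------
    labels_ : canonical per-frame state indices (0=zero, 1=mid, 2=high).
    state_means_, state_sds_ : transition-distal estimates per canonical
        state (NaN for unoccupied states).
    means_em_ : raw EM means of the three fitted states (ascending).
    transmat_ : empirical transition-probability matrix over canonical states.
    occupancy_ : frame counts per canonical state.
    degenerate_ : boolean mask of canonical states with zero occupancy.
    log_likelihood_ : model log-likelihood of the fitted trace.
    """

    def __init__(
        self,
        init_means: tuple[float, float, float] = CANONICAL_FRET,
        fix_means: bool = False,
        anchor_weight: float = 10.0,
        n_iter: int = 500,
        tol: float = 1e-6,
        min_covar: float = 1e-4,
        random_state: int = 0,
    ):
        self.init_means = init_means
        self.fix_means = fix_means
        self.anchor_weight = anchor_weight
        self.n_iter = n_iter
        self.tol = tol
        self.min_covar = min_covar
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _nearest_level(self, fret: np.ndarray) -> np.ndarray:
        """Fallback hard classification by nearest initial mean."""
        d = np.abs(fret[:, None] - np.asarray(self.init_means)[None, :])
        return np.argmin(d, axis=1).astype(np.int8)

    def fit(self, fret: np.ndarray) -> "FretHmm":
        fret = np.asarray(fret, dtype=float).ravel()
        if fret.size < 20:
            raise ValueError("HMM idealization needs at least 20 valid frames")
        if not np.all(np.isfinite(fret)):
            raise ValueError("fret must be finite (drop invalid frames first)")
        x = fret.reshape(-1, 1)

        params = "stc" if self.fix_means else "stmc"
        model = GaussianHMM(
            n_components=3,
            covariance_type="diag",
            n_iter=self.n_iter,
            tol=self.tol,
            min_covar=self.min_covar,
            init_params="",
            params=params,
            random_state=self.random_state,
            # MAP anchor at the canonical levels: a state visited by the
            # molecule moves freely (the anchor acts like ``anchor_weight``
            # pseudo-frames), while a state with no data of its own stays at
            # its level instead of migrating onto another state's cluster.
            means_prior=np.asarray(self.init_means, dtype=float).reshape(-1, 1),
            means_weight=self.anchor_weight,
        )
        model.means_ = np.asarray(self.init_means, dtype=float).reshape(-1, 1)
        # start from a realistic per-state width; hmmlearn's default (the
        # global trace variance) makes the first E-step nearly uniform and
        # lets states migrate across clusters
        model.covars_ = np.full((3, 1), 0.01)
        # uniform start, sticky transitions (hmmlearn would otherwise draw
        # a random transition matrix, a poor starting point for dwell data)
        model.startprob_ = np.full(3, 1.0 / 3.0)
        model.transmat_ = np.full((3, 3), 0.05) + 0.85 * np.eye(3)
        raw_labels = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x)
                raw_labels = model.predict(x)
                self.log_likelihood_ = float(model.score(x))
        except Exception:  # degenerate trace: fall back to hard thresholds
            raw_labels = None
        if raw_labels is None:
            labels = self._nearest_level(fret)
            self.log_likelihood_ = np.nan
            self.means_em_ = np.full(3, np.nan)
        else:
            em_means = model.means_.ravel()
            # map each fitted state to its canonical level and merge
            mapping = np.array([_canonical_level(m) for m in em_means])
            labels = mapping[raw_labels].astype(np.int8)
            self.means_em_ = np.sort(em_means)
        self.model_ = model if raw_labels is not None else None

        self.labels_ = labels
        self.occupancy_ = np.bincount(labels, minlength=3)
        self.degenerate_ = self.occupancy_ == 0
        self.state_means_, self.state_sds_ = _interior_means(fret, labels)
        self.transmat_ = _empirical_transmat(labels)
        self.n_frames_ = int(fret.size)
        return self

    def predict(self, fret: np.ndarray) -> np.ndarray:
        """Canonical state labels for new FRET values using the fitted model."""
        fret = np.asarray(fret, dtype=float).ravel()
        if getattr(self, "model_", None) is None:
            return self._nearest_level(fret)
        raw = self.model_.predict(fret.reshape(-1, 1))
        mapping = np.array(
            [_canonical_level(m) for m in self.model_.means_.ravel()]
        )
        return mapping[raw].astype(np.int8)


@dataclass
class IdealizedTrajectory:
    """Viterbi-idealized state path of one molecule (canonical states)."""

    molecule_id: str
    states: np.ndarray
    state_means: np.ndarray
    state_sds: np.ndarray
    transition_matrix: np.ndarray
    log_likelihood: float
    occupancy: np.ndarray
    degenerate: np.ndarray
    fret: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.states)


def fit_hmm(
    trajectory: FretTrajectory | np.ndarray,
    init_means: tuple[float, float, float] = CANONICAL_FRET,
    fix_means: bool = False,
    **kwargs,
) -> IdealizedTrajectory:
    """Idealize one trajectory; accepts a FretTrajectory (valid pre-bleach
    frames are used) or a bare FRET array."""
    if isinstance(trajectory, FretTrajectory):
        fret = trajectory.valid_fret
        mol_id = trajectory.molecule_id
    else:
        fret = np.asarray(trajectory, dtype=float)
        mol_id = "trace"
    est = FretHmm(init_means=init_means, fix_means=fix_means, **kwargs).fit(fret)
    return IdealizedTrajectory(
        molecule_id=mol_id,
        states=est.labels_,
        state_means=est.state_means_,
        state_sds=est.state_sds_,
        transition_matrix=est.transmat_,
        log_likelihood=est.log_likelihood_,
        occupancy=est.occupancy_,
        degenerate=est.degenerate_,
        fret=fret,
    )


def idealize_trajectories(
    trajectories: list[FretTrajectory],
    min_frames: int = 20,
    **kwargs,
) -> list[IdealizedTrajectory]:
    """Idealize every trajectory with enough valid frames."""
    out = []
    for traj in trajectories:
        if traj.valid_fret.size >= min_frames:
            out.append(fit_hmm(traj, **kwargs))
    return out


def aggregate_state_means(idealized: list[IdealizedTrajectory]) -> np.ndarray:
    """Occupancy-weighted average of per-molecule state means (NaN when a
    state is occupied in no molecule)."""
    num = np.zeros(3)
    den = np.zeros(3)
    for ideal in idealized:
        for s in range(3):
            if np.isfinite(ideal.state_means[s]) and ideal.occupancy[s] > 0:
                num[s] += ideal.state_means[s] * ideal.occupancy[s]
                den[s] += ideal.occupancy[s]
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


@dataclass
class TransitionDensity:
    """2-D histogram over (FRET before, FRET after) for idealized transitions."""

    hist: np.ndarray
    bin_edges: np.ndarray
    n_transitions: int


def transition_density(
    idealized: list[IdealizedTrajectory],
    bin_width: float = 0.05,
    fret_range: tuple[float, float] = (-0.2, 1.2),
) -> TransitionDensity:
    """For every idealized state change, one point at (mean observed FRET of
    the preceding dwell, mean observed FRET of the following dwell)."""
    before, after = [], []
    for ideal in idealized:
        labels = ideal.states
        fret = ideal.fret
        if labels.size < 2:
            continue
        change = np.flatnonzero(labels[1:] != labels[:-1])  # dwell boundaries
        bounds = np.concatenate([[0], change + 1, [labels.size]])
        dwell_means = [
            float(np.mean(fret[bounds[i] : bounds[i + 1]]))
            for i in range(len(bounds) - 1)
        ]
        for i in range(len(dwell_means) - 1):
            before.append(dwell_means[i])
            after.append(dwell_means[i + 1])
    lo, hi = fret_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, _, _ = np.histogram2d(before, after, bins=(edges, edges))
    return TransitionDensity(
        hist=hist, bin_edges=edges, n_transitions=len(before)
    )


@dataclass
class TransitionRates:
    """State-to-state rates derived from per-molecule transition probabilities."""

    rates: np.ndarray  # 3x3, 1/s, 0 where unobserved
    mean_probabilities: np.ndarray  # geometric-mean per-frame probabilities
    observed: np.ndarray  # bool: pair seen in at least one molecule
    n_observed: np.ndarray  # number of molecules contributing per pair
    conversion: str
    frame_interval_s: float


def estimate_transition_rates(
    idealized: list[IdealizedTrajectory],
    frame_interval_s: float,
    conversion: str = "linear",
) -> TransitionRates:
    """Mean transition probabilities -> rates.

    The per-pair mean probability is the geometric mean (exponential of the
    mean log) of the per-molecule transition probabilities, over molecules in
    which the pair was observed; zero entries are excluded from the log-mean
    and reported via ``n_observed``.

    ``conversion="linear"`` multiplies by the sampling rate (the published
    convention: k = T_p / dt).  ``conversion="log"`` uses the exact
    discrete-observation inversion k = -ln(1 - T_p) / dt, which remains
    consistent when the rate is comparable to the sampling rate.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if conversion not in ("linear", "log"):
        raise ValueError("conversion must be 'linear' or 'log'")
    if not any(
        np.any(ideal.transition_matrix[~np.eye(3, dtype=bool)] > 0)
        for ideal in idealized
    ):
        raise ValueError("no off-diagonal transitions observed in any trajectory")

    logsum = np.zeros((3, 3))
    nobs = np.zeros((3, 3), dtype=int)
    for ideal in idealized:
        tp = ideal.transition_matrix
        mask = (tp > 0) & ~np.eye(3, dtype=bool)
        logsum[mask] += np.log(tp[mask])
        nobs[mask] += 1
    mean_p = np.zeros((3, 3))
    observed = nobs > 0
    mean_p[observed] = np.exp(logsum[observed] / nobs[observed])
    if conversion == "linear":
        rates = mean_p / frame_interval_s
    else:
        rates = -np.log1p(-np.clip(mean_p, 0.0, 1.0 - 1e-12)) / frame_interval_s
    rates[~observed] = 0.0
    return TransitionRates(
        rates=rates,
        mean_probabilities=mean_p,
        observed=observed,
        n_observed=nobs,
        conversion=conversion,
        frame_interval_s=frame_interval_s,
    )
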