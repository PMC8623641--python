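"""Epoch-based entropy (EpEn) of EEG signals via left-to-right HMMs.

The measure treats an EEG signal as a piecewise-stationary process: a
continuous left-to-right hidden Markov model (self-loop plus next-state
transitions only) with Gaussian-mixture emissions is fitted to the series,
the Viterbi path cuts it into quasi-stationary epochs, and the information
content of each epoch is computed from the state's emission density.  The
signal-level EpEn is the arithmetic mean of the per-epoch entropies, in
bits.  Channel coupling is quantified by fitting one joint HMM on the
stacked two-dimensional observation sequence of a channel pair: a high joint
EpEn indicates high information content conveyed by the coupling.

Two per-epoch entropy estimators are provided.  The default ``literal`` mode
sums ``-p log2 p`` of the state density over the epoch's samples.  The
``rate`` mode averages the negative log2-density per sample, an estimate of
the differential entropy rate of the epoch; it converges to
``0.5 log2(2 pi e sigma^2)`` for a Gaussian state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GMMHMM
from hmmlearn.base import ConvergenceMonitor
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

__all__ = [
    "HMMConfig",
    "TrainedHMM",
    "EpochSegmentation",
    "EpEnResult",
    "fit_left_right_hmm",
    "viterbi_segment",
    "epoch_entropy",
    "epen",
    "compute_epen",
    "epen_coupling",
]

_DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class HMMConfig:
    """Hyper-parameters of the left-to-right GMM-HMM.

    ``n_states`` (N) and ``n_mix`` (M) control the temporal and density
    resolution of the model; ``dim`` is 1 for single-channel entropy and 2
    for channel coupling.
    """

    n_states: int = 10
    n_mix: int = 3
    dim: int = 1
    covariance_kind: str = "full"  # or "diagonal"
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 1 or self.n_mix < 1:
            raise ValueError("n_states and n_mix must be >= 1")
        if self.dim not in (1, 2):
            raise ValueError("dim must be 1 (single channel) or 2 (coupling)")
        if self.covariance_kind not in ("full", "diagonal"):
            raise ValueError("covariance_kind must be 'full' or 'diagonal'")


@dataclass
class TrainedHMM:
    """Fitted left-to-right HMM with per-state GMM emission densities."""

    startprob: np.ndarray  # (N,)
    transmat: np.ndarray  # (N, N); support on diagonal and first superdiagonal
    weights: np.ndarray  # (N, M)
    means: np.ndarray  # (N, M, D)
    covars: np.ndarray  # (N, M, D, D)
    log_likelihoods: list = field(default_factory=list)
    config: HMMConfig | None = None

    @property
    def n_states(self) -> int:
        return self.startprob.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[2]

    def state_log_density(self, state: int, obs: np.ndarray) -> np.ndarray:
        """Natural-log GMM emission density of ``state`` at each row of obs."""
        X = np.atleast_2d(np.asarray(obs, dtype=float))
        if X.shape[1] != self.dim:
            X = X.reshape(-1, self.dim)
        comp = np.empty((X.shape[0], self.weights.shape[1]))
        for m in range(self.weights.shape[1]):
            comp[:, m] = multivariate_normal.logpdf(
                X, mean=self.means[state, m], cov=self.covars[state, m],
                allow_singular=False,
            )
        return logsumexp(comp + np.log(self.weights[state])[None, :], axis=1)

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedHMM":
        return cls(
            startprob=np.array(d["startprob"]),
            transmat=np.array(d["transmat"]),
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covars=np.array(d["covars"]),
        )


@dataclass
class EpochSegmentation:
    """Viterbi state path and the quasi-stationary epochs it induces."""

    state_path: np.ndarray  # (T,), non-decreasing
    epoch_bounds: list  # [(start, end)] half-open, partitioning [0, T)
    epoch_states: list  # state index per epoch

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_bounds)


@dataclass
class EpEnResult:
    epoch_entropies: np.ndarray  # bits, one per visited epoch
    epen: float  # bits; arithmetic mean of epoch_entropies
    n_epochs: int
    mode: str = "literal"
    config: HMMConfig | None = None


class _FullHistoryMonitor(ConvergenceMonitor):
    """Convergence monitor retaining every EM log-likelihood."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def _as_obs(obs, dim: int) -> np.ndarray:
    X = np.asarray(obs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != dim:
        raise ValueError(f"observation dimension {X.shape[1]} != config dim {dim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("observations contain NaN or Inf")
    return X


def _init_parameters(X: np.ndarray, cfg: HMMConfig):
    """Deterministic left-to-right initialization.

    States are seeded from a uniform time partition of the series; each
    state's M mixture components from M contiguous sub-blocks of its
    partition (block mean/covariance, equal weights).  This respects the
    temporal ordering the left-to-right structure encodes, is deterministic,
    and is equivariant under exchanging the coordinates of 2-D coupling
    observations.
    """
    T, D = X.shape
    N, M = cfg.n_states, cfg.n_mix
    reg = 1e-6 * max(float(np.var(X)), 1e-12)

    startprob = np.zeros(N)
    startprob[0] = 1.0
    transmat = np.zeros((N, N))
    hop = min(max(N / T, 1e-6), 0.5)  # expected dwell ~ T/N samples
    for i in range(N - 1):
        transmat[i, i] = 1.0 - hop
        transmat[i, i + 1] = hop
    transmat[N - 1, N - 1] = 1.0

    means = np.empty((N, M, D))
    covars = np.empty((N, M, D, D))
    state_edges = np.linspace(0, T, N + 1).astype(int)
    for i in range(N):
        seg = X[state_edges[i] : state_edges[i + 1]]
        sub = np.linspace(0, len(seg), M + 1).astype(int)
        for m in range(M):
            blk = seg[sub[m] : sub[m + 1]]
            if len(blk) == 0:
                blk = seg
            means[i, m] = blk.mean(axis=0)
            c = np.cov(blk.T, bias=True).reshape(D, D) if len(blk) > 1 else np.zeros((D, D))
            if cfg.covariance_kind == "diagonal":
                c = np.diag(np.diag(c))
            covars[i, m] = c + reg * np.eye(D)
    weights = np.full((N, M), 1.0 / M)
    return startprob, transmat, weights, means, covars


def fit_left_right_hmm(obs, cfg: HMMConfig) -> TrainedHMM:
    """Fit a left-to-right GMM-HMM by Baum-Welch (EM).

    The transition matrix is initialized with support only on each state's
    self-loop and immediate right neighbour; EM preserves these structural
    zeros, so the fitted model remains left-to-right.  Deterministic given
    ``cfg.seed`` (the seed only matters for hmmlearn internals; the
    initialization itself is seed-free).
    """
    X = _as_obs(obs, cfg.dim)
    T = X.shape[0]
    if T < 10 * cfg.n_states:
        raise ValueError(
            f"need >= {10 * cfg.n_states} samples for N={cfg.n_states} states, got {T}"
        )
    if np.any(X.var(axis=0) <= 0):
        raise ValueError("degenerate input: zero variance in at least one dimension")

    startprob, transmat, weights, means, covars = _init_parameters(X, cfg)
    cov_type = "full" if cfg.covariance_kind == "full" else "diag"
    model = GMMHMM(
        n_components=cfg.n_states,
        n_mix=cfg.n_mix,
        covariance_type=cov_type,
        n_iter=cfg.max_iter,
        tol=cfg.tol,
        init_params="",
        params="tmcw",  # startprob fixed at the left-to-right entry state
        random_state=cfg.seed,
    )
    model.startprob_ = startprob
    model.transmat_ = transmat
    model.weights_ = weights
    model.means_ = means
    if cov_type == "full":
        model.covars_ = covars
    else:
        model.covars_ = np.array([[np.diag(c) for c in row] for row in covars])
    model.monitor_ = _FullHistoryMonitor(model.tol, model.n_iter, model.verbose)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn degenerate-mixture chatter
        model.fit(X)
    history = list(model.monitor_.full_history)
    if len(history) >= cfg.max_iter and (
        len(history) < 2 or history[-1] - history[-2] > cfg.tol
    ):
        warnings.warn(
            f"EM did not converge within {cfg.max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    if cov_type == "full":
        fitted_covars = model.covars_
    else:
        fitted_covars = np.array(
            [[np.diag(v) for v in row] for row in model.covars_]
        )
    trained = TrainedHMM(
        startprob=model.startprob_.copy(),
        transmat=model.transmat_.copy(),
        weights=model.weights_.copy(),
        means=model.means_.copy(),
        covars=fitted_covars,
        log_likelihoods=history,
        config=cfg,
    )
    trained._model = model  # cached for Viterbi; not part of the contract
    return trained


def _hmmlearn_model(hmm: TrainedHMM) -> GMMHMM:
    model = getattr(hmm, "_model", None)
    if model is not None:
        return model
    N, M, D = hmm.means.shape
    model = GMMHMM(n_components=N, n_mix=M, covariance_type="full", init_params="")
    model.startprob_ = hmm.startprob
    model.transmat_ = hmm.transmat
    model.weights_ = hmm.weights
    model.means_ = hmm.means
    model.covars_ = hmm.covars
    hmm._model = model
    return model


def viterbi_segment(hmm: TrainedHMM, obs) -> EpochSegmentation:
    """Most probable state path and the epochs (contiguous runs) it defines.

    Left-to-right structure guarantees the path is non-decreasing and that
    at most N epochs are visited, each a contiguous sample range.
    """
    X = _as_obs(obs, hmm.dim)
    path = _hmmlearn_model(hmm).predict(X)
    if np.any(np.diff(path) < 0):  # cannot happen with left-to-right support
        raise AssertionError("Viterbi path is not non-decreasing")
    bounds, states = [], []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            bounds.append((start, t))
            states.append(int(path[start]))
            start = t
    return EpochSegmentation(state_path=path, epoch_bounds=bounds, epoch_states=states)


def epoch_entropy(
    hmm: TrainedHMM, seg: EpochSegmentation, obs, mode: str = "literal"
) -> np.ndarray:
    """Per-epoch entropy H* in bits from the state emission densities.

    ``literal`` (default): H*_i = -sum_{z in S_i} P_i(z) log2 P_i(z) with
    P_i the state-i GMM density evaluated at each sample of the epoch.
    ``rate``: mean of -log2 P_i(z) over the epoch's samples (per-sample
    entropy rate estimate).  Densities are floored at 1e-300 before the log.
    """
    if mode not in ("literal", "rate"):
        raise ValueError("mode must be 'literal' or 'rate'")
    X = _as_obs(obs, hmm.dim)
    if seg.epoch_bounds[0][0] != 0 or seg.epoch_bounds[-1][1] != X.shape[0]:
        raise ValueError("segmentation does not cover the observation sequence")
    out = []
    for (a, b), s in zip(seg.epoch_bounds, seg.epoch_states):
        assert b > a, "empty epoch cannot arise from a Viterbi partition"
        logp = hmm.state_log_density(s, X[a:b])
        p = np.maximum(np.exp(logp), _DENSITY_FLOOR)
        if mode == "literal":
            out.append(float(-np.sum(p * np.log2(p))))
        else:
            out.append(float(-np.mean(np.log2(p))))
    return np.asarray(out)


def epen(epoch_entropies) -> float:
    """EpEn of a signal: arithmetic mean of its per-epoch entropies (bits)."""
    h = np.asarray(epoch_entropies, dtype=float)
    if h.size == 0:
        raise ValueError("no epoch entropies to average")
    return float(np.mean(h))


def compute_epen(obs, cfg: HMMConfig, mode: str = "literal") -> EpEnResult:
    """Fit, segment, and average: the full EpEn computation for one series."""
    hmm = fit_left_right_hmm(obs, cfg)
    seg = viterbi_segment(hmm, obs)
    h = epoch_entropy(hmm, seg, obs, mode=mode)
    return EpEnResult(
        epoch_entropies=h, epen=epen(h), n_epochs=seg.n_epochs, mode=mode, config=cfg
    )


def epen_coupling(x, y, cfg: HMMConfig | None = None, mode: str = "literal") -> float:
    """Joint EpEn of a channel pair (bits).

    The two series are stacked into 2-D observations and one joint HMM is
    fitted; the single joint Viterbi path makes the quasi-stationary epochs
    shared between the channels by construction.  Higher values indicate
    higher information content conveyed by the coupling.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("channel series must have equal length")
    if cfg is None:
        cfg = HMMConfig(dim=2)
    elif cfg.dim != 2:
        raise ValueError("epen_coupling requires an HMMConfig with dim=2")
    return compute_epen(np.column_stack([x, y]), cfg, mode=mode).epen
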