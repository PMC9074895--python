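"""Gaussian hidden Markov models over per-cycle sequencing signal.

This module implements the probabilistic machinery used to segment read-2
log T-signal traces into an initiation segment, a poly(A) segment, and a
non-poly(A) segment (plus the transition states of the five-state variant).
States emit one real value per sequencing cycle from a state-specific
Gaussian; the transition matrix is left-to-right with structural zeros that
are preserved through unsupervised training.

All batch routines operate on a 2-D array of traces with a common length
(the simulator and sequencers produce fixed-length read 2); variable-length
inputs are handled by grouping traces of equal length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml
from scipy.special import logsumexp

__all__ = [
    "GHMMParams",
    "forward_loglik",
    "viterbi",
    "posterior_decode",
    "baum_welch",
    "sample_paths",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GHMMParams:
    """Parameters of a Gaussian-emission hidden Markov model.

    Attributes
    ----------
    startprob : (K,) initial-state probabilities, a simplex.
    transmat : (K, K) row-stochastic transition matrix.  Entries that are
        exactly zero are structural (disallowed moves) and remain zero
        through Baum-Welch training.
    means, variances : (K,) Gaussian emission parameters in log-T-signal
        units.
    state_names : optional labels; index of the poly(A) state is taken from
        ``polya_state``.
    polya_state : index of the state whose dwell length reports the
        poly(A)-tail length (1 for both the 3- and 5-state topologies).
    """

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    state_names: tuple = ()
    polya_state: int = 1

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.startprob.shape[0]

    def validate(self) -> None:
        k = self.startprob.shape[0]
        if self.transmat.shape != (k, k):
            raise ValueError("transition matrix shape does not match state count")
        if self.means.shape != (k,) or self.variances.shape != (k,):
            raise ValueError("emission parameter shapes do not match state count")
        if np.any(self.startprob < 0) or abs(self.startprob.sum() - 1.0) > 1e-9:
            raise ValueError("initial-state probabilities must form a simplex")
        if np.any(self.transmat < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")
        if not 0 <= self.polya_state < k:
            raise ValueError("polya_state out of range")

    def copy(self) -> "GHMMParams":
        return replace(
            self,
            startprob=self.startprob.copy(),
            transmat=self.transmat.copy(),
            means=self.means.copy(),
            variances=self.variances.copy(),
        )

    @property
    def structural_zeros(self) -> np.ndarray:
        """Boolean mask of disallowed transitions."""
        return self.transmat == 0.0

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "state_names": list(self.state_names),
            "polya_state": self.polya_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GHMMParams":
        return cls(
            startprob=np.array(d["startprob"], dtype=float),
            transmat=np.array(d["transmat"], dtype=float),
            means=np.array(d["means"], dtype=float),
            variances=np.array(d["variances"], dtype=float),
            state_names=tuple(d.get("state_names", ())),
            polya_state=int(d.get("polya_state", 1)),
        )

    @classmethod
    def default_three_state(cls) -> "GHMMParams":
        """Packaged initialization for the three-state splinted-ligation model."""
        return _load_default("three_state")

    @classmethod
    def default_five_state(cls) -> "GHMMParams":
        """Packaged initialization for the five-state variant."""
        return _load_default("five_state")


def _load_default(key: str) -> GHMMParams:
    text = resources.files("tailscape").joinpath("_defaults/ghmm_init.yaml").read_text()
    return GHMMParams.from_dict(yaml.safe_load(text)[key])


def _as_batch(traces) -> np.ndarray:
    x = np.asarray(traces, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("traces must be (n, length) with length >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite emission values in traces")
    return x


def _log_emission(x: np.ndarray, params: GHMMParams) -> np.ndarray:
    """Per-cycle Gaussian log density, shape (n, T, K)."""
    mu = params.means[None, None, :]
    var = params.variances[None, None, :]
    return -0.5 * ((x[:, :, None] - mu) ** 2 / var + np.log(var) + _LOG2PI)


def _log_clip(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def forward_loglik(traces, params: GHMMParams) -> np.ndarray:
    """Log-likelihood of each trace under the model (forward algorithm)."""
    x = _as_batch(traces)
    logb = _log_emission(x, params)
    log_a = _log_clip(params.transmat)
    la = _log_clip(params.startprob)[None, :] + logb[:, 0, :]
    for t in range(1, x.shape[1]):
        la = logsumexp(la[:, :, None] + log_a[None, :, :], axis=1) + logb[:, t, :]
    return logsumexp(la, axis=1)


def viterbi(traces, params: GHMMParams) -> np.ndarray:
    """Most probable state path per trace, shape (n, T)."""
    x = _as_batch(traces)
    n, t_len = x.shape
    k = params.n_states
    logb = _log_emission(x, params)
    log_a = _log_clip(params.transmat)
    delta = _log_clip(params.startprob)[None, :] + logb[:, 0, :]
    psi = np.zeros((n, t_len, k), dtype=np.int8)
    for t in range(1, t_len):
        cand = delta[:, :, None] + log_a[None, :, :]
        psi[:, t, :] = np.argmax(cand, axis=1)
        delta = np.max(cand, axis=1) + logb[:, t, :]
    paths = np.zeros((n, t_len), dtype=np.int8)
    paths[:, -1] = np.argmax(delta, axis=1)
    rows = np.arange(n)
    for t in range(t_len - 2, -1, -1):
        paths[:, t] = psi[rows, t + 1, paths[:, t + 1]]
    return paths


def posterior_decode(traces, params: GHMMParams) -> np.ndarray:
    """Per-cycle argmax of the posterior state marginals, shape (n, T)."""
    x = _as_batch(traces)
    la, lb, _ = _forward_backward(x, params)
    return np.argmax(la + lb, axis=2).astype(np.int8)


def _forward_backward(x: np.ndarray, params: GHMMParams):
    n, t_len = x.shape
    k = params.n_states
    logb = _log_emission(x, params)
    log_a = _log_clip(params.transmat)
    la = np.empty((n, t_len, k))
    la[:, 0, :] = _log_clip(params.startprob)[None, :] + logb[:, 0, :]
    for t in range(1, t_len):
        la[:, t, :] = (
            logsumexp(la[:, t - 1, :, None] + log_a[None, :, :], axis=1) + logb[:, t, :]
        )
    lb = np.empty((n, t_len, k))
    lb[:, -1, :] = 0.0
    for t in range(t_len - 2, -1, -1):
        lb[:, t, :] = logsumexp(
            log_a[None, :, :] + (logb[:, t + 1, :] + lb[:, t + 1, :])[:, None, :],
            axis=2,
        )
    return la, lb, logb


def baum_welch(
    traces,
    init: GHMMParams,
    max_iter: int = 100,
    tol: float = 1e-4,
    var_floor: float = 1e-6,
    chunk_size: int = 2000,
    update_startprob: bool = True,
):
    """Unsupervised maximum-likelihood training (EM / Baum-Welch).

    The per-iteration log-likelihood is non-decreasing; iteration stops when
    the mean per-trace improvement drops below ``tol`` or after ``max_iter``
    rounds.  Structural zeros of the transition matrix are preserved exactly:
    a disallowed move accrues zero expected counts, so its re-estimate is
    zero.  Emission variances are clamped at ``var_floor``.

    Returns ``(params, loglik_history)`` where ``loglik_history`` holds the
    total data log-likelihood evaluated at the start of each iteration.
    """
    x = _as_batch(traces)
    if x.shape[0] == 0:
        raise ValueError("empty training sample")
    params = init.copy()
    zeros = init.structural_zeros
    n = x.shape[0]
    history: list[float] = []
    for _ in range(max_iter):
        k = params.n_states
        start_counts = np.zeros(k)
        trans_counts = np.zeros((k, k))
        w = np.zeros(k)
        wx = np.zeros(k)
        wx2 = np.zeros(k)
        total_ll = 0.0
        log_a = _log_clip(params.transmat)
        for lo in range(0, n, chunk_size):
            xc = x[lo : lo + chunk_size]
            la, lb, logb = _forward_backward(xc, params)
            ll = logsumexp(la[:, -1, :], axis=1)
            total_ll += float(ll.sum())
            log_gamma = la + lb - ll[:, None, None]
            gamma = np.exp(log_gamma)
            start_counts += gamma[:, 0, :].sum(axis=0)
            # expected transition counts summed over traces and cycles
            log_xi = (
                la[:, :-1, :, None]
                + log_a[None, None, :, :]
                + (logb[:, 1:, :] + lb[:, 1:, :])[:, :, None, :]
                - ll[:, None, None, None]
            )
            trans_counts += np.exp(logsumexp(log_xi, axis=(0, 1)))
            w += gamma.sum(axis=(0, 1))
            wx += (gamma * xc[:, :, None]).sum(axis=(0, 1))
            wx2 += (gamma * (xc**2)[:, :, None]).sum(axis=(0, 1))
        history.append(total_ll)
        if len(history) > 1 and (history[-1] - history[-2]) / n < tol:
            break
        trans_counts[zeros] = 0.0
        row = trans_counts.sum(axis=1, keepdims=True)
        new_a = np.where(row > 0, trans_counts / np.where(row > 0, row, 1.0), params.transmat)
        new_mu = wx / np.maximum(w, 1e-300)
        new_var = np.maximum(wx2 / np.maximum(w, 1e-300) - new_mu**2, var_floor)
        new_pi = start_counts / start_counts.sum() if update_startprob else params.startprob
        params = replace(
            params,
            startprob=new_pi,
            transmat=new_a,
            means=new_mu,
            variances=new_var,
        )
    return params, history


def sample_paths(params: GHMMParams, n: int, length: int, rng: np.random.Generator):
    """Draw ``n`` state paths and emissions of ``length`` cycles.

    Returns ``(states, emissions)`` with shapes (n, length).  Used both by
    the trace simulator and by parameter-recovery tests.
    """
    if length < 1:
        raise ValueError("trace length must be >= 1")
    k = params.n_states
    states = np.empty((n, length), dtype=np.int8)
    cum_pi = np.cumsum(params.startprob)
    cum_a = np.cumsum(params.transmat, axis=1)
    states[:, 0] = np.searchsorted(cum_pi, rng.random(n))
    for t in range(1, length):
        u = rng.random(n)
        prev = states[:, t - 1]
        # row-wise inverse-CDF draw
        states[:, t] = (u[:, None] > cum_a[prev]).sum(axis=1)
    emissions = rng.normal(
        params.means[states], np.sqrt(params.variances[states])
    )
    return states, emissions
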