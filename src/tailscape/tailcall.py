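"""Poly(A)-tail length calling from per-cycle intensity traces.

The caller proceeds in three stages.  First, raw four-channel intensities
are converted into a per-cycle log T-signal: each channel is normalized by
its average read-1 intensity when reading that base, and the thymidine
channel is divided by the sum of the other three.  Cycles where all four
channels read zero (or the T signal is non-positive) are imputed from
neighboring cycles; traces with more than five such cycles are discarded.
Second, read-2 base calls route each tag: reads showing a run of >=10 T in
an 11-nt window within the first 30 nt go to the GHMM; reads failing the
screen but starting with >=4 contiguous T get a direct short-tail call
(tails < 10 nt are read directly); everything else is discarded.  Third,
the GHMM (trained unsupervised on a random sample of tags) decodes each
trace, and the number of cycles spent in the poly(A) state is the tail
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ghmm import GHMMParams, baum_welch, posterior_decode, viterbi

__all__ = [
    "compute_t_signal",
    "compute_t_signal_batch",
    "screen_for_ghmm",
    "call_short_tail",
    "train_ghmm",
    "decode_tail_lengths",
    "call_tails",
    "aggregate_gene_tails",
    "standards_report",
]

MAX_IMPUTED = 5
CHANNELS = ("A", "C", "G", "T")


def compute_t_signal(raw: np.ndarray, norms) -> np.ndarray | None:
    """Convert one (T, 4) intensity trace to a per-cycle log T-signal.

    ``raw`` columns are channels A, C, G, T; ``norms`` is a length-4 vector
    of positive per-channel read-1 reference intensities.  Returns a 1-D
    array of log T-signal values, or ``None`` when the trace has more than
    five zero-valued cycles and is discarded.
    """
    out = compute_t_signal_batch(np.asarray(raw, dtype=float)[None, :, :], norms)
    logts, keep = out
    return logts[0] if keep[0] else None


def compute_t_signal_batch(raw: np.ndarray, norms):
    """Vectorized T-signal computation for (n, T, 4) intensity stacks.

    Returns ``(logts, keep)`` where ``logts`` is (n, T) (rows of discarded
    traces are NaN) and ``keep`` is a boolean mask of retained traces.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != 4 or raw.shape[1] < 1:
        raise ValueError("raw intensities must have shape (n, cycles, 4)")
    norms = np.asarray(
        [norms[c] for c in CHANNELS] if isinstance(norms, dict) else norms, dtype=float
    )
    if norms.shape != (4,) or np.any(norms <= 0):
        raise ValueError("channel norms must be 4 positive values")
    scaled = raw / norms[None, None, :]
    other = scaled[:, :, 0] + scaled[:, :, 1] + scaled[:, :, 2]
    tchan = scaled[:, :, 3]
    all_zero = np.all(raw == 0.0, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsig = tchan / other
    bad = all_zero | ~np.isfinite(tsig) | (tsig <= 0)
    n_bad = bad.sum(axis=1)
    keep = n_bad <= MAX_IMPUTED
    logts = np.full(raw.shape[:2], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        logts[keep] = np.where(bad[keep], np.nan, np.log(np.where(bad[keep], 1.0, tsig[keep])))
    for i in np.nonzero(keep & (n_bad > 0))[0]:
        logts[i] = _impute(logts[i])
        if np.any(~np.isfinite(logts[i])):
            keep[i] = False
            logts[i] = np.nan
    return logts, keep


def _impute(values: np.ndarray) -> np.ndarray:
    """Fill NaN cycles with the mean of the 5 valid values on each side."""
    out = values.copy()
    valid_idx = np.nonzero(np.isfinite(values))[0]
    for i in np.nonzero(~np.isfinite(values))[0]:
        before = valid_idx[valid_idx < i][-5:]
        after = valid_idx[valid_idx > i][:5]
        neigh = np.concatenate([before, after])
        if neigh.size == 0:
            continue  # left NaN; caller discards
        out[i] = values[neigh].mean()
    return out


def screen_for_ghmm(read2_sequence: str, window: int = 11, min_t: int = 10, span: int = 30) -> bool:
    """True when read 2 shows the tail's T-stretch and should be GHMM-decoded.

    Scans 11-nt windows starting within the first 30 nt for >=10 T residues.
    Sequences shorter than ``span`` are scanned over their full length.
    """
    seq = read2_sequence.upper()
    last_start = min(span, len(seq) - window)
    for start in range(0, last_start + 1):
        if seq.count("T", start, start + window) >= min_t:
            return True
    return False


def call_short_tail(read2_sequence: str, min_run: int = 4) -> int | None:
    """Direct tail call for reads that begin with >=4 contiguous T residues.

    Returns the leading-T run length, or ``None`` (tag discarded) when the
    read starts with fewer than ``min_run`` T residues.  Only applied to
    reads that failed the GHMM screen, so calls are < 10 nt by construction.
    """
    seq = read2_sequence.upper()
    run = 0
    for base in seq:
        if base != "T":
            break
        run += 1
    return run if run >= min_run else None


def train_ghmm(
    traces: np.ndarray,
    init: GHMMParams | None = None,
    n_train: int = 10_000,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
):
    """Unsupervised Baum-Welch training on a random sample of tags.

    ``n_train`` tags are drawn uniformly without replacement (all tags are
    used when fewer are available).  Returns ``(params, loglik_history)``.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.shape[0] == 0:
        raise ValueError("no traces available for training")
    if init is None:
        init = GHMMParams.default_three_state()
    rng = np.random.default_rng(seed)
    if traces.shape[0] > n_train:
        idx = rng.choice(traces.shape[0], size=n_train, replace=False)
        traces = traces[idx]
    return baum_welch(traces, init, max_iter=max_iter, tol=tol)


def decode_tail_lengths(
    traces: np.ndarray,
    params: GHMMParams,
    method: str = "viterbi",
    chunk_size: int = 5000,
) -> np.ndarray:
    """Decode traces and count poly(A)-state cycles as the tail length."""
    traces = np.asarray(traces, dtype=float)
    decoder = {"viterbi": viterbi, "posterior": posterior_decode}[method]
    tails = np.empty(traces.shape[0], dtype=int)
    for lo in range(0, traces.shape[0], chunk_size):
        paths = decoder(traces[lo : lo + chunk_size], params)
        tails[lo : lo + chunk_size] = (paths == params.polya_state).sum(axis=1)
    return tails


@dataclass
class TailCallResult:
    """Per-tag tail calls plus the trained model that produced them."""

    calls: pd.DataFrame  # tag_id, gene, tail_length, route
    params: GHMMParams | None
    loglik_history: list


def call_tails(
    raw: np.ndarray,
    sequences,
    tag_ids,
    genes,
    norms,
    init: GHMMParams | None = None,
    n_train: int = 10_000,
    seed: int = 0,
    train: bool = True,
    method: str = "viterbi",
) -> TailCallResult:
    """Full calling pipeline: T signal, routing screens, training, decoding.

    ``raw`` is an (n, cycles, 4) intensity stack aligned with ``sequences``
    (read-2 base calls), ``tag_ids`` and ``genes``.  Tags whose trace is
    discarded during T-signal computation, or whose read 2 fails both the
    GHMM screen and the short-tail rule, are reported with route
    ``discarded`` and tail length -1.
    """
    tag_ids = np.asarray(tag_ids)
    genes = np.asarray(genes)
    sequences = list(sequences)
    logts, keep = compute_t_signal_batch(raw, norms)
    screened = np.array([screen_for_ghmm(s) for s in sequences])
    ghmm_mask = screened & keep
    route = np.full(len(sequences), "discarded", dtype=object)
    tails = np.full(len(sequences), -1, dtype=int)
    for i in np.nonzero(~screened)[0]:
        short = call_short_tail(sequences[i])
        if short is not None:
            route[i] = "direct"
            tails[i] = short
    params, history = (init, [])
    if ghmm_mask.any():
        if train:
            params, history = train_ghmm(
                logts[ghmm_mask], init=init, n_train=n_train, seed=seed
            )
        elif params is None:
            params = GHMMParams.default_three_state()
        tails[ghmm_mask] = decode_tail_lengths(logts[ghmm_mask], params, method=method)
        route[ghmm_mask] = "ghmm"
    calls = pd.DataFrame(
        {"tag_id": tag_ids, "gene": genes, "tail_length": tails, "route": route}
    )
    return TailCallResult(calls=calls, params=params, loglik_history=history)


def aggregate_gene_tails(calls: pd.DataFrame, min_tags: int = 50) -> pd.Series:
    """Mean tail length per gene, keeping genes with >= ``min_tags`` calls."""
    kept = calls[calls["route"] != "discarded"]
    counts = kept.groupby("gene")["tail_length"].count()
    means = kept.groupby("gene")["tail_length"].mean()
    return means[counts >= min_tags]


def standards_report(calls: pd.DataFrame, truth: dict) -> pd.DataFrame:
    """Recovery and accuracy table for spike-in tail-length standards.

    ``truth`` maps standard id -> (true length nt, input fraction).  Recovery
    ratio compares each standard's share of recovered standard tags with its
    input fraction; values near 1 indicate unbiased recovery, values below 1
    indicate depletion (as seen for long-tail standards).
    """
    unknown = set(calls["gene"]) - set(truth)
    if unknown:
        raise ValueError(f"unknown standard ids: {sorted(map(str, unknown))}")
    std_calls = calls
    total = len(std_calls)
    rows = []
    for std, (length, frac) in sorted(truth.items(), key=lambda kv: kv[1][0]):
        sub = std_calls[std_calls["gene"] == std]["tail_length"]
        recovered = len(sub) / total if total else np.nan
        rows.append(
            {
                "standard": std,
                "true_length": length,
                "input_fraction": frac,
                "recovered_fraction": recovered,
                "recovery_ratio": recovered / frac if total else np.nan,
                "n_tags": len(sub),
                "mean_called": sub.mean() if len(sub) else np.nan,
                "median_called": sub.median() if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)
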