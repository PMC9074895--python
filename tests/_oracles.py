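"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: path probabilities are
enumerated recursively, peak assignment is re-derived with a naive scan,
and rank correlations go through explicit ranking.  They are only feasible
at toy sizes, which is the point.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def _emission_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (math.log(2 * math.pi * var) + (x - mean) ** 2 / var)


def enumerate_paths(trace, startprob, transmat, means, variances):
    """All legal state paths with their log probabilities, by recursion.

    Returns a list of ``(path_tuple, logprob)``.  Only transitions with
    nonzero probability are followed, so left-to-right topologies stay
    cheap even for a dozen cycles.
    """
    k = len(startprob)
    t_len = len(trace)
    results = []

    def recurse(t, state, logp, path):
        logp = logp + _emission_logpdf(trace[t], means[state], variances[state])
        path = path + (state,)
        if t == t_len - 1:
            results.append((path, logp))
            return
        for nxt in range(k):
            if transmat[state][nxt] > 0:
                recurse(t + 1, nxt, logp + math.log(transmat[state][nxt]), path)

    for s in range(k):
        if startprob[s] > 0:
            recurse(0, s, math.log(startprob[s]), ())
    return results


def brute_force_loglik(trace, startprob, transmat, means, variances) -> float:
    paths = enumerate_paths(trace, startprob, transmat, means, variances)
    logps = np.array([lp for _, lp in paths])
    m = logps.max()
    return float(m + np.log(np.exp(logps - m).sum()))


def brute_force_viterbi(trace, startprob, transmat, means, variances):
    paths = enumerate_paths(trace, startprob, transmat, means, variances)
    best_path, _ = max(paths, key=lambda pl: pl[1])
    return np.array(best_path)


def naive_annotate(pileup: dict, halfwidth: int = 10, min_fraction: float = 0.10):
    """Reference greedy 3'-end assignment written the slow, obvious way."""
    remaining = {int(c): int(n) for c, n in pileup.items()}
    total = sum(remaining.values())
    out = []
    while remaining:
        best_coord, best_count = None, -1
        for coord in sorted(remaining):
            if remaining[coord] > best_count:
                best_coord, best_count = coord, remaining[coord]
        members = [c for c in list(remaining) if best_coord - halfwidth <= c <= best_coord + halfwidth]
        count = sum(remaining[c] for c in members)
        out.append((best_coord, count, count / total))
        for c in members:
            remaining.pop(c)
    return [(c, n, f) for c, n, f in out if f >= min_fraction]


def naive_t_window_screen(seq: str) -> bool:
    """Sliding-window >=10-of-11 T screen, re-derived character by character."""
    seq = seq.upper()
    for start in range(0, min(30, max(len(seq) - 11 + 1, 0))):
        window = seq[start : start + 11]
        if len(window) == 11 and sum(1 for b in window if b == "T") >= 10:
            return True
    return False


def rank_then_pearson(x, y) -> float:
    """Spearman via explicit ranking then a Pearson correlation."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def naive_seed_scan(sequence: str, seed_match_6mer: str) -> bool:
    """Exhaustive window scan for a 6-nt seed match."""
    sequence = sequence.upper().replace("U", "T")
    return any(
        sequence[i : i + 6] == seed_match_6mer for i in range(len(sequence) - 5)
    )
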