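"""Linear-chain CRF primitives in log space.

The CRF scores a label path y_1..y_n of a sentence with n tokens as

    s(y) = T[START, y_1] + sum_t e[t, y_t] + sum_t T[y_{t-1}, y_t] + T[y_n, STOP]

where ``e`` is the (n, L) emission matrix produced by the encoder and ``T``
an (L+2, L+2) transition matrix over the L labels plus virtual START/STOP
states (row/column L and L+1).  ``log_partition`` normalizes over all L^n
paths by the forward recursion; ``sequence_log_likelihood`` is the path
log-probability; per-sentence confidence is its per-word geometric mean,
exp(log-likelihood / n), so a 99.75% threshold lives in probability space.

Scalar functions operate on one sentence and are checked against brute-force
path enumeration in the test suite; the ``batch_*`` functions are the
vectorized forms used in training and decoding (padding positions masked).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

N_LABELS = 3  # B, I, O
START = N_LABELS
STOP = N_LABELS + 1

LABEL_TO_INDEX = {"B": 0, "I": 1, "O": 2}
INDEX_TO_LABEL = ("B", "I", "O")


def _check(emissions: np.ndarray, transitions: np.ndarray) -> None:
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (n, L) with n >= 1")
    L = emissions.shape[1]
    if transitions.shape != (L + 2, L + 2):
        raise ValueError(
            f"transitions must be ({L + 2}, {L + 2}), got {transitions.shape}"
        )


def log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all label paths of exp(path score), by the forward
    recursion in log space."""
    _check(emissions, transitions)
    n, L = emissions.shape
    alpha = transitions[START, :L] + emissions[0]
    for t in range(1, n):
        alpha = logsumexp(alpha[:, None] + transitions[:L, :L], axis=0) + emissions[t]
    return float(logsumexp(alpha + transitions[:L, STOP]))


def score_path(
    emissions: np.ndarray, transitions: np.ndarray, labels: np.ndarray
) -> float:
    """Unnormalized score of one label path (label indices)."""
    _check(emissions, transitions)
    labels = np.asarray(labels)
    n, L = emissions.shape
    if labels.shape != (n,):
        raise ValueError(f"labels must have shape ({n},)")
    if labels.min() < 0 or labels.max() >= L:
        raise ValueError("label index outside the label set")
    s = transitions[START, labels[0]] + transitions[labels[-1], STOP]
    s += emissions[np.arange(n), labels].sum()
    s += transitions[labels[:-1], labels[1:]].sum()
    return float(s)


def sequence_log_likelihood(
    emissions: np.ndarray, transitions: np.ndarray, labels: np.ndarray
) -> float:
    """Log-probability of ``labels`` under the CRF; always <= 0."""
    return score_path(emissions, transitions, labels) - log_partition(
        emissions, transitions
    )


def viterbi_decode(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[list[int], float]:
    """Maximum-score label path and its score.

    Ties are broken toward the lower label index both in the running max and
    in the backtrace (np.argmax returns the first maximizer), so decoding is
    deterministic.
    """
    _check(emissions, transitions)
    n, L = emissions.shape
    delta = transitions[START, :L] + emissions[0]
    back = np.zeros((n, L), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + transitions[:L, :L]  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(L)] + emissions[t]
    final = delta + transitions[:L, STOP]
    last = int(np.argmax(final))
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(final[last])


def sentence_confidence(
    emissions: np.ndarray, transitions: np.ndarray, labels: np.ndarray
) -> float:
    """Per-word geometric mean of the path probability, in (0, 1]."""
    n = emissions.shape[0]
    return float(np.exp(sequence_log_likelihood(emissions, transitions, labels) / n))


# ---------------------------------------------------------------------------
# Batched forms: emissions (B, T, L), mask (B, T) with padding at the tail.
# ---------------------------------------------------------------------------


def _logsumexp_ax1(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(x - m).sum(axis=1, keepdims=True)))[:, 0]


def batch_log_partition(
    emissions: np.ndarray, transitions: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Forward algorithm over a padded batch; returns (B,) logZ."""
    B, T, L = emissions.shape
    trans = transitions[:L, :L]
    alpha = transitions[START, :L][None, :] + emissions[:, 0, :]
    for t in range(1, T):
        new = (
            _logsumexp_ax1(alpha[:, :, None] + trans[None, :, :]).reshape(B, L)
            + emissions[:, t, :]
        )
        m = mask[:, t][:, None]
        alpha = np.where(m, new, alpha)
    return _logsumexp_ax1((alpha + transitions[:L, STOP][None, :])[:, :, None]).reshape(
        B
    )


def batch_score(
    emissions: np.ndarray,
    transitions: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Path scores of gold label index sequences over a padded batch."""
    B, T, L = emissions.shape
    lengths = mask.sum(axis=1)
    rows = np.arange(B)
    s = transitions[START, labels[:, 0]].astype(float)
    s += transitions[labels[rows, lengths - 1], STOP]
    emit = np.take_along_axis(emissions, labels[:, :, None], axis=2)[:, :, 0]
    s += (emit * mask).sum(axis=1)
    pair = transitions[labels[:, :-1], labels[:, 1:]]
    s += (pair * mask[:, 1:]).sum(axis=1)
    return s


def batch_nll_grad(
    emissions: np.ndarray,
    transitions: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Negative log-likelihoods and their gradients for a padded batch.

    Returns ``(nll, d_emissions, d_transitions)`` where nll has shape (B,),
    d_emissions the shape of ``emissions`` (gradient of sum of NLLs), and
    d_transitions the shape of ``transitions``.  Gradients are expected
    sufficient statistics minus observed ones (forward-backward).
    """
    B, T, L = emissions.shape
    trans = transitions[:L, :L]
    lengths = mask.sum(axis=1)
    rows = np.arange(B)

    # forward, storing alphas
    alphas = np.empty((B, T, L))
    alpha = transitions[START, :L][None, :] + emissions[:, 0, :]
    alphas[:, 0] = alpha
    for t in range(1, T):
        new = (
            _logsumexp_ax1(alpha[:, :, None] + trans[None, :, :]).reshape(B, L)
            + emissions[:, t, :]
        )
        alpha = np.where(mask[:, t][:, None], new, alpha)
        alphas[:, t] = alpha
    logZ = _logsumexp_ax1((alpha + transitions[:L, STOP][None, :])[:, :, None]).reshape(
        B
    )

    # backward: beta[b, t, j] = log-sum of path suffixes after emitting at t
    betas = np.empty((B, T, L))
    stop_col = transitions[:L, STOP][None, :]
    beta = np.broadcast_to(stop_col, (B, L)).copy()
    betas[:, T - 1] = beta
    for t in range(T - 2, -1, -1):
        nxt = emissions[:, t + 1, :] + beta  # (B, L)
        cand = _logsumexp_ax1(
            (trans[None, :, :] + nxt[:, None, :]).transpose(0, 2, 1)
        ).reshape(B, L)
        # if t is the last valid position, suffix is just the STOP transition
        beta = np.where(mask[:, t + 1][:, None], cand, stop_col)
        betas[:, t] = beta

    # unary marginals
    log_marg = alphas + betas - logZ[:, None, None]
    marg = np.exp(log_marg) * mask[:, :, None]

    d_emissions = marg.copy()
    one_hot = np.zeros_like(emissions)
    np.put_along_axis(one_hot, labels[:, :, None], 1.0, axis=2)
    d_emissions -= one_hot * mask[:, :, None]

    d_trans = np.zeros_like(transitions)
    # START -> j and i -> STOP expectations are unary marginals at the ends
    d_trans[START, :L] += marg[:, 0, :].sum(axis=0)
    last_marg = marg[rows, lengths - 1, :]
    d_trans[:L, STOP] += last_marg.sum(axis=0)
    # pairwise expectations at interior steps
    for t in range(1, T):
        active = mask[:, t]
        if not active.any():
            break
        lp = (
            alphas[:, t - 1, :, None]
            + trans[None, :, :]
            + emissions[:, t, None, :]
            + betas[:, t, None, :]
            - logZ[:, None, None]
        )
        pair = np.exp(lp) * active[:, None, None]
        d_trans[:L, :L] += pair.sum(axis=0)
    # observed statistics
    np.add.at(d_trans[START, :L], labels[:, 0], -1.0)
    np.add.at(d_trans[:L, STOP], labels[rows, lengths - 1], -1.0)
    pair_from = labels[:, :-1][mask[:, 1:]]
    pair_to = labels[:, 1:][mask[:, 1:]]
    np.subtract.at(d_trans, (pair_from, pair_to), 1.0)

    nll = logZ - batch_score(emissions, transitions, labels, mask)
    return nll, d_emissions, d_trans


def batch_viterbi(
    emissions: np.ndarray, transitions: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi decoding over a padded batch.

    Returns (paths, scores): paths (B, T) int64 with padding positions 0,
    scores (B,).  Tie-breaking as in :func:`viterbi_decode`.
    """
    B, T, L = emissions.shape
    trans = transitions[:L, :L]
    lengths = mask.sum(axis=1)
    delta = transitions[START, :L][None, :] + emissions[:, 0, :]
    deltas = np.empty((B, T, L))
    backs = np.zeros((B, T, L), dtype=np.int64)
    deltas[:, 0] = delta
    for t in range(1, T):
        cand = delta[:, :, None] + trans[None, :, :]  # (B, from, to)
        bk = np.argmax(cand, axis=1)
        new = np.take_along_axis(cand, bk[:, None, :], axis=1)[:, 0, :] + emissions[
            :, t, :
        ]
        m = mask[:, t][:, None]
        delta = np.where(m, new, delta)
        backs[:, t] = bk
        deltas[:, t] = delta

    paths = np.zeros((B, T), dtype=np.int64)
    scores = np.empty(B)
    for b in range(B):
        n = int(lengths[b])
        final = deltas[b, n - 1] + transitions[:L, STOP]
        last = int(np.argmax(final))
        scores[b] = final[last]
        paths[b, n - 1] = last
        for t in range(n - 1, 0, -1):
            paths[b, t - 1] = backs[b, t, paths[b, t]]
    return paths, scores
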