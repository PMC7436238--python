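"""Softmax and cross-entropy with analytic gradients."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch.

    Parameters
    ----------
    logits : (N, K) unnormalized scores
    targets : (N,) integer class indices

    Returns
    -------
    loss : float
    dlogits : (N, K) gradient of the mean loss w.r.t. the logits
    """
    N = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(N), targets] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(N), targets] -= 1.0
    dlogits /= N
    return float(loss), dlogits
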