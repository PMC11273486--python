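"""Losses for the two-stream objective.

The total objective is ``L_total = L_R + alpha * L_C`` where ``L_R`` is the
autoencoder reconstruction loss — the mean over the batch of the *summed*
squared error between each input window and its reconstruction — and ``L_C``
is the mean cross-entropy of the classifier's logits.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mse_reconstruction", "cross_entropy", "total_loss"]


def mse_reconstruction(
    X: np.ndarray, X_hat: np.ndarray, reduction: str = "sample_sum"
) -> tuple[float, np.ndarray]:
    """Reconstruction loss and its gradient with respect to ``X_hat``.

    ``reduction="sample_sum"`` is the definitional form
    ``L_R = (1/N) * sum_i ||X_i - X_hat_i||^2`` with the norm over every entry
    of the window (all channels and time points). ``"mean"`` divides further
    by the entries per window — the same minimizer, scaled so its gradient
    magnitudes suit the standard SGD learning-rate regime.
    """
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    if reduction == "sample_sum":
        denom = X.shape[0]
    elif reduction == "mean":
        denom = X.size
    else:
        raise ValueError("reduction must be 'sample_sum' or 'mean'")
    diff = X_hat - X
    loss = float(np.sum(diff * diff) / denom)
    grad = 2.0 * diff / denom
    return loss, grad


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient with respect to the logits."""
    N = logits.shape[0]
    if labels.shape[0] != N:
        raise ValueError("batch size mismatch between logits and labels")
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = float(-logp[np.arange(N), labels].mean())
    grad = np.exp(logp)
    grad[np.arange(N), labels] -= 1.0
    return loss, grad / N


def total_loss(L_R: float, L_C: float, alpha: float = 10.0) -> float:
    """Weighted two-stream objective ``L_R + alpha * L_C``."""
    if not (np.isfinite(L_R) and np.isfinite(L_C)):
        raise ValueError("losses must be finite")
    return float(L_R + alpha * L_C)
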