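"""Regression losses with analytic gradients.

All three losses reduce by the mean over every element of the
``(batch, targets)`` prediction array, so a joint SBP/DBP head contributes
both targets equally.  The residual convention is ``r = ref - pred``
(reference minus predicted); gradients are returned with respect to the
predictions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["huber_loss", "mse_loss", "mae_loss", "loss_and_grad"]


def huber_loss(pred, ref, delta: float = 1.0, return_grad: bool = False):
    """Huber loss: 0.5 r^2 for |r| <= delta, else delta |r| - 0.5 delta^2.

    Quadratic near zero like the MSE, linear in the tails like the MAE;
    continuous with continuous first derivative at |r| = delta.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref shapes differ")
    r = ref - pred
    a = np.abs(r)
    quad = a <= delta
    per = np.where(quad, 0.5 * r * r, delta * a - 0.5 * delta * delta)
    loss = float(per.mean())
    if not return_grad:
        return loss
    # d per / d pred = -r in the quadratic zone, -delta*sign(r) in the linear zone
    g = -np.clip(r, -delta, delta) / r.size
    return loss, g


def mse_loss(pred, ref, return_grad: bool = False):
    """Mean squared error."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != ref.shape:
        raise ValueError("pred and ref shapes differ")
    r = ref - pred
    loss = float(np.mean(r * r))
    if not return_grad:
        return loss
    return loss, -2.0 * r / r.size


def mae_loss(pred, ref, return_grad: bool = False):
    """Mean absolute error."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != ref.shape:
        raise ValueError("pred and ref shapes differ")
    r = ref - pred
    loss = float(np.mean(np.abs(r)))
    if not return_grad:
        return loss
    return loss, -np.sign(r) / r.size


_LOSSES = {"huber": huber_loss, "mse": mse_loss, "mae": mae_loss}


def loss_and_grad(name: str, pred, ref, delta: float = 1.0):
    """Dispatch by loss name; returns (scalar loss, gradient w.r.t. pred)."""
    if name == "huber":
        return huber_loss(pred, ref, delta=delta, return_grad=True)
    try:
        fn = _LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(_LOSSES)}") from None
    return fn(pred, ref, return_grad=True)
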