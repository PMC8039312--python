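"""Synaptic plasticity rules: Hebbian potentiation and the spatiotemporal rule.

Two update rules act on a weight matrix ``w`` (rows = output neurons,
columns = input neurons) given a binary input frame ``x``:

* Hebbian (HEBLR): every synapse from an active input onto an output neuron
  whose internal state reaches the firing threshold gains a fixed increment
  ``dw``.  Non-firing neurons change nothing; there is no decrement.

* Spatiotemporal (STLR): each active synapse is classified by a coincidence
  coefficient ``I_ij`` — a measure of how strongly the other coactive inputs
  onto neuron ``i`` cooperate with input ``j`` — against two thresholds
  (BCM-style): ``I >= theta1`` potentiates (+dw), ``theta2 < I < theta1``
  leaves the weight unchanged, ``I <= theta2`` depresses (-dw).  Firing of
  the output neuron plays no role, and weights may go negative (no clipping).

The coincidence coefficient comes in an exact product form,
``I_ij = w_ij x_j * sum_{m != j} w_im x_m``, and the large-network
approximation ``I_ij = w_ij x_j / s_i`` where ``s_i`` is the internal state.
For scale-free thresholding both the weight row and the input can be
projected onto the unit sphere, giving the normalized coefficient
``Ĩ_ij = w̃_ij * s̃_i`` that is linear in the normalized weight with slope
``s̃_i``.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np

__all__ = [
    "heblr_update",
    "stlr_coincidence",
    "stlr_update",
    "normalize_vectors",
    "normalized_state",
    "normalized_coincidence",
    "classify_regions",
]

CoincidenceForm = Literal["approximate", "exact"]


def _check_wx(w, x):
    w = np.asarray(w, dtype=float)
    x = np.asarray(x)
    if w.ndim != 2:
        raise ValueError(f"weight matrix must be 2-D, got shape {w.shape}")
    if x.ndim != 1 or x.shape[0] != w.shape[1]:
        raise ValueError(
            f"input frame shape {x.shape} does not match weight columns {w.shape[1]}"
        )
    return w, x.astype(float)


def heblr_update(w, x, dw: float, eta: float) -> np.ndarray:
    """One Hebbian step: ``w_ij += dw`` wherever ``s_i >= eta`` and ``x_j = 1``.

    Returns a new matrix; the input is not modified.  The update is
    element-wise non-decreasing (potentiation only).
    """
    w, x = _check_wx(w, x)
    s = w @ x
    fired = s >= eta
    out = w.copy()
    out[np.ix_(fired, x > 0)] += dw
    return out


def stlr_coincidence(w, x, form: CoincidenceForm = "approximate") -> np.ndarray:
    """Coincidence coefficient matrix ``I_ij`` for input frame ``x``.

    ``form="exact"`` uses the product form
    ``I_ij = w_ij x_j * (s_i - w_ij x_j)``; ``form="approximate"`` uses
    ``I_ij = w_ij x_j / s_i``.  Entries with ``x_j = 0`` are zero.  Rows with
    ``s_i = 0`` in the approximate form (no input drive) are defined as zero
    and trigger a warning — unreachable with positive weights and at least
    one active input, but the map must be total.
    """
    w, x = _check_wx(w, x)
    active = x > 0
    wx = w * x  # w_ij x_j
    s = wx.sum(axis=1)
    if form == "exact":
        return wx * (s[:, None] - wx)
    if form != "approximate":
        raise ValueError(f"form must be 'approximate' or 'exact', got {form!r}")
    out = np.zeros_like(w)
    drive = s != 0.0
    if active.any() and not drive.all():
        warnings.warn(
            "approximate coincidence: neuron(s) with zero input drive; "
            "their coefficients are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out[drive] = wx[drive] / s[drive, None]
    return out


def normalize_vectors(x, w_row):
    """Project one input frame and one weight row onto the unit sphere.

    Returns ``(x_tilde, w_tilde, s_tilde)`` with ``x_tilde = x/|x|``,
    ``w_tilde = w_row/|w_row|`` and ``s_tilde = w_tilde . x_tilde`` (the
    normalized internal state, in [-1, 1]).
    """
    x = np.asarray(x, dtype=float)
    w_row = np.asarray(w_row, dtype=float)
    nx = np.linalg.norm(x)
    nw = np.linalg.norm(w_row)
    if nx == 0.0 or nw == 0.0:
        raise ValueError("cannot normalize a zero-norm vector")
    x_t = x / nx
    w_t = w_row / nw
    return x_t, w_t, float(w_t @ x_t)


def normalized_state(w, x):
    """Matrix form of :func:`normalize_vectors`: all rows at once.

    Returns ``(x_tilde, w_tilde, s_tilde)`` where ``w_tilde`` has unit-norm
    rows and ``s_tilde`` is the vector of normalized internal states.
    """
    w, x = _check_wx(w, x)
    nx = np.linalg.norm(x)
    norms = np.linalg.norm(w, axis=1)
    if nx == 0.0 or (norms == 0.0).any():
        raise ValueError("cannot normalize a zero-norm vector")
    x_t = x / nx
    w_t = w / norms[:, None]
    return x_t, w_t, w_t @ x_t


def normalized_coincidence(w_tilde_row, s_tilde: float, x=None) -> np.ndarray:
    """Normalized coincidence ``Ĩ_ij = w̃_ij * s̃_i`` for one neuron.

    Linear in the normalized weight with slope ``s_tilde`` (a line through
    the origin).  If ``x`` is given, entries with ``x_j = 0`` are zeroed —
    learning only concerns active inputs.
    """
    w_tilde_row = np.asarray(w_tilde_row, dtype=float)
    out = w_tilde_row * float(s_tilde)
    if x is not None:
        out = np.where(np.asarray(x) > 0, out, 0.0)
    return out


def _coincidence_for_update(w, x, form: CoincidenceForm, normalized: bool) -> np.ndarray:
    if not normalized:
        return stlr_coincidence(w, x, form=form)
    _, w_t, s_t = normalized_state(w, x)
    return np.where(np.asarray(x) > 0, w_t * s_t[:, None], 0.0)


def stlr_update(
    w,
    x,
    dw: float,
    theta1: float,
    theta2: float,
    form: CoincidenceForm = "approximate",
    normalized: bool = True,
) -> np.ndarray:
    """One spatiotemporal-rule step.

    Active synapses (``x_j = 1``) are classified by the coincidence
    coefficient: ``I >= theta1`` → enhancement (+dw); ``theta1 > I > theta2``
    → invariance (no change); ``I <= theta2`` → attenuation (-dw).  Inactive
    synapses are untouched bit-for-bit.  With ``normalized=True`` the
    classification uses ``Ĩ_ij = w̃_ij s̃_i`` (scale-free thresholds);
    otherwise the raw coefficient in the requested ``form``.
    """
    if not theta1 > theta2:
        raise ValueError(f"theta1 ({theta1}) must be strictly greater than theta2 ({theta2})")
    w, x = _check_wx(w, x)
    active = x > 0
    if not active.any():  # no active synapse: nothing can change
        return w.copy()
    coincidence = _coincidence_for_update(w, x, form, normalized)
    out = w.copy()
    enhance = active[None, :] & (coincidence >= theta1)
    attenuate = active[None, :] & (coincidence <= theta2)
    out[enhance] += dw
    out[attenuate] -= dw
    return out


def classify_regions(s_tilde, theta1: float, theta2: float) -> np.ndarray:
    """Label neurons R1/R2/R3 by their normalized internal state.

    ``s̃ >= theta1`` → R1 (enhancement, invariance and attenuation all
    reachable); ``theta2 < s̃ < theta1`` → R2 (invariance and attenuation);
    ``s̃ <= theta2`` → R3 (attenuation only).  Boundaries are inclusive on
    the R1 and R3 sides.
    """
    if not theta1 > theta2:
        raise ValueError(f"theta1 ({theta1}) must be strictly greater than theta2 ({theta2})")
    s = np.asarray(s_tilde, dtype=float)
    labels = np.full(s.shape, "R2", dtype="<U2")
    labels[s >= theta1] = "R1"
    labels[s <= theta2] = "R3"
    return labels
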