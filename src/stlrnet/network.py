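"""Single-layer feed-forward threshold network and its plasticity estimators.

The network is a McCulloch–Pitts layer: internal state ``s_i = sum_j w_ij x_j``
and binary output ``y_i = 1`` iff ``s_i - eta >= 0`` (equality fires).  Two
scikit-learn-style estimators wrap the training loop: :class:`HebbianNetwork`
and :class:`STLRNetwork`.  ``fit`` takes a (t_len, n) stack of binary frames
presented in order — one plasticity update per frame, synchronous within a
step (all internal states computed from the pre-update weights).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .patterns import InputSequence
from .plasticity import (
    heblr_update,
    normalized_state,
    stlr_coincidence,
    stlr_update,
)

__all__ = ["init_weights", "internal_state", "fire", "HebbianNetwork", "STLRNetwork"]


def init_weights(n_outputs, n_inputs=None, low=0.0, high=1.0, random_state=None):
    """Initial synaptic weight matrix, i.i.d. uniform on ``[low, high)``.

    Feed-forward excitatory connections start nonnegative with the default
    range.  Deterministic given ``random_state``.
    """
    if n_inputs is None:
        n_inputs = n_outputs
    if not low < high:
        raise ValueError(f"invalid range: low={low} must be < high={high}")
    rng = check_random_state(random_state)
    return rng.uniform(low, high, size=(n_outputs, n_inputs))


def internal_state(w, x):
    """Membrane potential vector ``s_i = sum_j w_ij x_j``."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape[-1] != x.shape[0]:
        raise ValueError(f"dimension mismatch: weights {w.shape}, input {x.shape}")
    return w @ x


def fire(s, eta):
    """Binary outputs ``y_i = 1`` iff ``s_i >= eta`` (threshold equality fires)."""
    return (np.asarray(s, dtype=float) >= eta).astype(np.uint8)


def _coerce_frames(X) -> np.ndarray:
    if isinstance(X, InputSequence):
        X = X.frames
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"expected a (t_len, n) stack of frames, got shape {X.shape}")
    if X.size and not np.isin(X, (0, 1)).all():
        raise ValueError("input frames must be binary (0/1)")
    return X.astype(np.uint8)


class _PlasticNetwork(TransformerMixin, BaseEstimator):
    """Shared fit/predict machinery for the two plasticity estimators."""

    def __init__(
        self,
        n_outputs=None,
        dw=0.25,
        eta="auto",
        weight_low=0.0,
        weight_high=1.0,
        store_history=False,
        random_state=None,
    ):
        self.n_outputs = n_outputs
        self.dw = dw
        self.eta = eta
        self.weight_low = weight_low
        self.weight_high = weight_high
        self.store_history = store_history
        self.random_state = random_state

    # subclasses implement the per-frame update and threshold resolution
    def _resolve_thresholds(self, w, x0):  # pragma: no cover - overridden
        pass

    def _update(self, w, x):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y=None):
        """Train on an ordered stack of binary frames (one update per frame).

        Resolves data-scaled thresholds from the first frame (then frozen),
        initializes uniform weights, and applies the rule once per frame.
        """
        X = _coerce_frames(X)
        if self.dw <= 0:
            raise ValueError(f"dw must be positive, got {self.dw}")
        t_len, n = X.shape
        self.n_features_in_ = n
        n_out = n if self.n_outputs is None else int(self.n_outputs)
        w = init_weights(
            n_out, n, self.weight_low, self.weight_high, random_state=self.random_state
        )
        self.coef_init_ = w.copy()

        if t_len:
            s0 = internal_state(w, X[0])
            self.eta_ = float(np.median(s0)) if self.eta == "auto" else float(self.eta)
            self._resolve_thresholds(w, X[0])
        else:
            # degenerate no-training case: nothing to scale thresholds on
            self.eta_ = 0.0 if self.eta == "auto" else float(self.eta)
            self._resolve_thresholds(None, None)

        self.active_mask_ = np.zeros(n, dtype=bool)
        history = [w.copy()] if self.store_history else None
        for x in X:
            w = self._update(w, x)
            self.active_mask_ |= x > 0
            if history is not None:
                history.append(w.copy())
        self.coef_ = w
        self.n_steps_ = t_len
        self.frames_ = X
        if history is not None:
            self.coef_history_ = history
        return self

    def decision_function(self, X):
        """Internal states ``s = X W^T`` for each frame (rows) and neuron (cols)."""
        check_is_fitted(self, "coef_")
        X = _coerce_frames(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, estimator was fitted with {self.n_features_in_}"
            )
        return X.astype(float) @ self.coef_.T

    def predict(self, X):
        """Binary firing pattern for each frame under the frozen threshold."""
        return fire(self.decision_function(X), self.eta_)

    def transform(self, X):
        """Alias of :meth:`predict`, so the estimator composes in pipelines."""
        return self.predict(X)


class HebbianNetwork(_PlasticNetwork):
    """Hebbian (output-gated) plasticity on a single feed-forward layer.

    Every presentation potentiates by ``dw`` the synapses from active inputs
    onto neurons whose internal state reaches the firing threshold; nothing
    happens at non-firing neurons.  Trains toward pattern completion: similar
    input sequences recruit (and keep reinforcing) the same winner set.

    Parameters
    ----------
    dw : float, default 0.25
        Weight increment per potentiating event, on the scale of the initial
        uniform weights.
    eta : "auto" or float, default "auto"
        Firing threshold.  "auto" freezes it at the median internal state of
        the first frame, so about half the neurons fire initially.
    n_outputs : int or None
        Output-layer size; ``None`` means square (``n_outputs = n_inputs``).
    weight_low, weight_high : float
        Bounds of the uniform initial weight distribution.
    store_history : bool
        Keep a per-step weight snapshot list in ``coef_history_``.
    random_state : int, RandomState or None
        Controls the initial weights.

    Attributes
    ----------
    coef_ : (n_outputs, n_features) ndarray — trained weights.
    coef_init_ : ndarray — initial weights.
    eta_ : float — resolved firing threshold.
    active_mask_ : (n_features,) bool — inputs active at least once in training.
    """

    def _update(self, w, x):
        return heblr_update(w, x, dw=self.dw, eta=self.eta_)


class STLRNetwork(_PlasticNetwork):
    """Spatiotemporal-rule plasticity on a single feed-forward layer.

    Each active synapse is potentiated, left unchanged, or depressed by
    ``dw`` according to its coincidence coefficient against two BCM-style
    thresholds; output firing is irrelevant to learning and weights may go
    negative.  Trains toward pattern discrimination: small differences
    between input frames steer synapses into different branches.

    Parameters
    ----------
    dw : float, default 0.25
        Magnitude of potentiation and depression.
    theta1, theta2 : "auto" or float
        Upper (LTP) and lower (LTD) thresholds.  "auto" freezes them at the
        ``upper_quantile``/``lower_quantile`` quantiles of the coincidence
        coefficients over active synapses at the first frame.
    upper_quantile, lower_quantile : float, defaults 0.60 / 0.40
        Quantile levels used by the auto thresholds.  The defaults leave a
        narrow invariance band, so most active synapses are driven into the
        enhancement or attenuation branch.
    coincidence : {"approximate", "exact"}, default "approximate"
        Raw coefficient form (``w_ij x_j / s_i`` vs. the exact product).
    normalized : bool, default True
        Classify in the unit-sphere space ``Ĩ_ij = w̃_ij s̃_i`` (scale-free
        thresholds) rather than on the raw coefficient.
    eta : "auto" or float
        Output firing threshold (readout only, not used by learning).

    Attributes
    ----------
    coef_, coef_init_, eta_, active_mask_ : as in :class:`HebbianNetwork`.
    theta1_, theta2_ : float — resolved plasticity thresholds.
    """

    def __init__(
        self,
        n_outputs=None,
        dw=0.25,
        theta1="auto",
        theta2="auto",
        upper_quantile=0.60,
        lower_quantile=0.40,
        coincidence="approximate",
        normalized=True,
        eta="auto",
        weight_low=0.0,
        weight_high=1.0,
        store_history=False,
        random_state=None,
    ):
        super().__init__(
            n_outputs=n_outputs,
            dw=dw,
            eta=eta,
            weight_low=weight_low,
            weight_high=weight_high,
            store_history=store_history,
            random_state=random_state,
        )
        self.theta1 = theta1
        self.theta2 = theta2
        self.upper_quantile = upper_quantile
        self.lower_quantile = lower_quantile
        self.coincidence = coincidence
        self.normalized = normalized

    def coincidence_matrix(self, w, x):
        """Coincidence coefficients in the configured space (zero at x_j=0)."""
        if self.normalized:
            _, w_t, s_t = normalized_state(w, x)
            return np.where(np.asarray(x) > 0, w_t * s_t[:, None], 0.0)
        return stlr_coincidence(w, x, form=self.coincidence)

    def _resolve_thresholds(self, w, x0):
        if self.theta1 != "auto" and self.theta2 != "auto":
            self.theta1_, self.theta2_ = float(self.theta1), float(self.theta2)
        elif w is None or x0 is None or not (np.asarray(x0) > 0).any():
            # no frame to scale on: thresholds that never potentiate/depress
            self.theta1_, self.theta2_ = np.inf, -np.inf
        else:
            vals = self.coincidence_matrix(w, x0)[:, np.asarray(x0) > 0].ravel()
            self.theta1_ = (
                float(self.theta1)
                if self.theta1 != "auto"
                else float(np.quantile(vals, self.upper_quantile))
            )
            self.theta2_ = (
                float(self.theta2)
                if self.theta2 != "auto"
                else float(np.quantile(vals, self.lower_quantile))
            )
        if not self.theta1_ > self.theta2_:
            raise ValueError(
                f"resolved theta1 ({self.theta1_}) must exceed theta2 ({self.theta2_})"
            )

    def _update(self, w, x):
        return stlr_update(
            w,
            x,
            dw=self.dw,
            theta1=self.theta1_,
            theta2=self.theta2_,
            form=self.coincidence,
            normalized=self.normalized,
        )
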