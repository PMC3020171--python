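"""Recursive GLM coefficient estimation with a Kalman filter.

The state is the coefficient vector X(k) = [beta_1 ... beta_L]^T of one
channel's GLM, assumed to follow a random walk with zero drift (transition
matrix A = I, process noise covariance Q = q I).  The observation is the
scalar measurement y(k) = H(k) X(k) + v(k) with variance R = r.  Per step:

    predict:   X-  = X,            P-  = P + Q
    update:    E   = H P- H^T + r
               K   = P- H^T / E
               X   = X- + K (y - H X-)
               P   = (I - K H) P-   (then symmetrized)

Two running accumulators serve the downstream t-statistic: the Gram matrix
sum H^T H and the residual sum of squares.  The RSS uses the exact recursive
least-squares identity RSS(k) = RSS(k-1) + innovation^2 * r / E(k) (the
product of the pre- and post-update residuals), which in the q=0 limit equals
the batch residual sum of squares at the current coefficient estimate — the
quantity the sigma^2 estimator requires.

Everything is vectorized over channels: one :class:`KalmanState` carries all
channels' coefficient vectors and covariances, updated in parallel each step.
With ``q=0`` and a diffuse prior (``KalmanConfig.diffuse()``) the filter
degenerates to recursive ordinary least squares, the central correctness
oracle for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prewhiten import ARState, update_rho, whiten_pair

__all__ = ["KalmanConfig", "KalmanState", "init_state", "predict", "update",
           "step_all_channels"]


class KalmanConfigError(ValueError):
    pass


@dataclass(frozen=True)
class KalmanConfig:
    """Filter noise settings.

    Defaults follow the a-priori covariances quoted for this framework:
    process noise q = (0.01)^2 per coefficient per step and observation noise
    r = (0.5)^2, read as plain variances in the model's working units (uM for
    the data).  ``p0`` is the initial error-covariance diagonal; the state
    itself starts at zero.
    """

    q: float = 0.01**2
    r: float = 0.5**2
    p0: float = 1e4
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.q < 0:
            raise KalmanConfigError("q must be >= 0")
        if self.r <= 0:
            raise KalmanConfigError("r must be > 0")
        if self.p0 <= 0:
            raise KalmanConfigError("p0 must be > 0")

    @classmethod
    def diffuse(cls, r: float = 0.5**2) -> "KalmanConfig":
        """q=0 with a diffuse prior: the filter reduces to recursive OLS."""
        return cls(q=0.0, r=r, p0=1e8)


@dataclass
class KalmanState:
    """Per-channel filter state, vectorized over a leading channel axis.

    ``x_hat``: (C, L) coefficient estimates; ``p_cov``: (C, L, L) error
    covariances; ``gram``: (C, L, L) running sum of H^T H; ``rss``: (C,)
    running residual sum of squares; ``k``: number of processed samples.
    """

    x_hat: np.ndarray
    p_cov: np.ndarray
    gram: np.ndarray
    rss: np.ndarray
    k: int = 0

    @property
    def n_channels(self) -> int:
        return self.x_hat.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.x_hat.shape[1]


def init_state(
    n_regressors: int, cfg: KalmanConfig | None = None, n_channels: int = 1
) -> KalmanState:
    """Fresh state: x = x0 (default zeros), P = p0 I, empty accumulators."""
    cfg = cfg or KalmanConfig()
    if n_regressors < 1:
        raise KalmanConfigError("n_regressors must be >= 1")
    if cfg.x0 is None:
        x = np.zeros((n_channels, n_regressors))
    else:
        x0 = np.asarray(cfg.x0, dtype=float)
        if x0.shape != (n_regressors,):
            raise KalmanConfigError("x0 length must equal n_regressors")
        x = np.tile(x0, (n_channels, 1))
    p = np.tile(cfg.p0 * np.eye(n_regressors), (n_channels, 1, 1))
    return KalmanState(
        x_hat=x,
        p_cov=p,
        gram=np.zeros((n_channels, n_regressors, n_regressors)),
        rss=np.zeros(n_channels),
    )


def predict(state: KalmanState, cfg: KalmanConfig) -> KalmanState:
    """Time update: random-walk state (unchanged mean), P <- P + q I."""
    if cfg.q:
        idx = np.arange(state.n_regressors)
        state.p_cov[:, idx, idx] += cfg.q
    return state


def update(
    state: KalmanState,
    y_star: np.ndarray,
    row_star: np.ndarray,
    cfg: KalmanConfig,
) -> KalmanState:
    """Measurement update with a scalar observation per channel.

    ``y_star`` (C,) and ``row_star`` ((C, L) or (L,)) are the — possibly
    prewhitened — measurement and design row.  Accumulates the Gram matrix and
    the recursive RSS and increments the step counter.
    """
    y = np.atleast_1d(np.asarray(y_star, dtype=float))
    rows = np.asarray(row_star, dtype=float)
    if rows.ndim == 1:
        rows = np.broadcast_to(rows, (state.n_channels, rows.shape[0]))
    if rows.shape != state.x_hat.shape:
        raise ValueError(
            f"row shape {rows.shape} incompatible with state {state.x_hat.shape}"
        )
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(rows))):
        bad = np.argwhere(~np.isfinite(y)).ravel()
        raise ValueError(
            f"non-finite input at step {state.k}"
            + (f", channel index {bad[0]}" if bad.size else "")
        )
    p = state.p_cov
    ph = np.einsum("clm,cm->cl", p, rows)
    e_var = np.einsum("cl,cl->c", rows, ph) + cfg.r  # innovation variance E(k)
    innov = y - np.einsum("cl,cl->c", rows, state.x_hat)
    gain = ph / e_var[:, None]
    state.x_hat = state.x_hat + gain * innov[:, None]
    p = p - gain[:, :, None] * ph[:, None, :]
    state.p_cov = 0.5 * (p + p.transpose(0, 2, 1))
    state.gram += rows[:, :, None] * rows[:, None, :]
    # pre-update residual x post-update residual == innov^2 * r / E  (>= 0)
    state.rss += innov**2 * (cfg.r / e_var)
    state.k += 1
    return state


def step_all_channels(
    state: KalmanState,
    y_vec: np.ndarray,
    row: np.ndarray,
    ar: ARState | None,
    cfg: KalmanConfig,
) -> KalmanState:
    """One full online step across all channels sharing a design row.

    Applies prewhitening (when an AR state is supplied), then the predict and
    update steps, channel-independently, and finally refreshes the AR(1)
    coefficient estimate from the raw post-fit residuals.
    """
    y = np.atleast_1d(np.asarray(y_vec, dtype=float))
    if y.shape[0] != state.n_channels:
        raise ValueError(
            f"{y.shape[0]} measurements for {state.n_channels} channels"
        )
    if ar is not None:
        if ar.n_channels != state.n_channels:
            raise ValueError("AR state channel count mismatch")
        y_star, rows_star, ar = whiten_pair(ar, y, row)
    else:
        y_star, rows_star = y, row
    predict(state, cfg)
    update(state, y_star, rows_star, cfg)
    if ar is not None:
        raw_resid = y - np.einsum("l,cl->c", np.asarray(row, dtype=float),
                                  state.x_hat)
        update_rho(ar, raw_resid)
    return state
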