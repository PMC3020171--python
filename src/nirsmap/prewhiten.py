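"""AR(1) prewhitening of the regression error, estimated online.

Physiological noise leaves the GLM error serially correlated, which inflates
t-values.  Modelling the error as AR(1) with coefficient rho and differencing
both sides of the regression,

    y*(k) = y(k) - rho * y(k-1),    H*(k) = H(k) - rho * H(k-1),

restores (approximately) independent errors, assuming the coefficient vector
drifts slowly between consecutive steps.

rho is not observable directly; it is estimated online as the running lag-1
autocorrelation of the raw post-fit residuals, rho = sum e(k) e(k-1) / sum
e(k-1)^2, refreshed every sample and clipped to |rho| <= 0.99 to keep the
transform invertible.  The transform is the identity until ``burn_in`` samples
have been seen (the early residual stream is dominated by the estimator's own
transient), and always at the first sample, which has no predecessor.

All state is vectorized over channels: a single :class:`ARState` carries one
rho (and one lagged pair) per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ARConfig", "ARState", "init_ar_state", "update_rho", "whiten_pair"]

RHO_CLIP = 0.99


@dataclass(frozen=True)
class ARConfig:
    """Prewhitening settings.

    ``fixed_rho`` freezes the coefficient (e.g. a training-data value) instead
    of estimating it online; ``enabled=False`` makes the transform the
    identity throughout.
    """

    enabled: bool = True
    burn_in: int = 30
    fixed_rho: float | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.fixed_rho is not None and not (abs(self.fixed_rho) < 1):
            raise ValueError("|fixed_rho| must be < 1")


@dataclass
class ARState:
    """Per-channel AR(1) whitening state (arrays of shape (n_channels,))."""

    rho: np.ndarray
    num: np.ndarray          # running sum e(k) e(k-1)
    den: np.ndarray          # running sum e(k-1)^2
    prev_y: np.ndarray
    prev_row: np.ndarray     # (n_channels, L)
    prev_resid: np.ndarray
    n_seen: int = 0          # samples seen by whiten_pair
    n_resid: int = 0         # residuals seen by update_rho
    config: ARConfig = field(default_factory=ARConfig)

    @property
    def n_channels(self) -> int:
        return self.rho.shape[0]


def init_ar_state(
    n_channels: int, n_regressors: int, config: ARConfig | None = None
) -> ARState:
    cfg = config or ARConfig()
    rho0 = cfg.fixed_rho if cfg.fixed_rho is not None else 0.0
    return ARState(
        rho=np.full(n_channels, float(rho0)),
        num=np.zeros(n_channels),
        den=np.zeros(n_channels),
        prev_y=np.zeros(n_channels),
        prev_row=np.zeros((n_channels, n_regressors)),
        prev_resid=np.zeros(n_channels),
        config=cfg,
    )


def update_rho(state: ARState, residual: np.ndarray) -> ARState:
    """Fold the current raw regression residuals into the rho estimate.

    ``residual`` is y(k) - H(k) beta_hat(k) on the *untransformed* pair.  A
    degenerate (zero-variance) stream leaves rho unchanged.  With
    ``fixed_rho`` configured the estimate is never refreshed.
    """
    e = np.atleast_1d(np.asarray(residual, dtype=float))
    if (
        state.n_resid >= max(1, state.config.burn_in)
        and state.config.fixed_rho is None
    ):
        state.num += e * state.prev_resid
        state.den += state.prev_resid**2
        ok = state.den > 0
        state.rho[ok] = np.clip(state.num[ok] / state.den[ok], -RHO_CLIP, RHO_CLIP)
    state.prev_resid = e.copy()
    state.n_resid += 1
    return state


def whiten_pair(
    state: ARState, y: np.ndarray, row: np.ndarray
) -> tuple[np.ndarray, np.ndarray, ARState]:
    """Apply the AR(1) difference to a (measurement, design-row) pair.

    ``y`` has shape (n_channels,) (scalars are promoted); ``row`` is the
    shared design row of length L, or per-channel rows (n_channels, L).
    Returns the transformed pair and stores the raw pair for the next call.
    The first sample, and every sample during burn-in or with whitening
    disabled, passes through unchanged.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    row = np.asarray(row, dtype=float)
    if row.ndim == 1:
        rows = np.broadcast_to(row, (state.n_channels, row.shape[0]))
    else:
        rows = row
    if rows.shape != state.prev_row.shape:
        raise ValueError(
            f"design row shape {rows.shape} does not match state "
            f"{state.prev_row.shape}"
        )
    cfg = state.config
    active = cfg.enabled and state.n_seen > 0 and state.n_seen >= cfg.burn_in
    if active:
        y_star = y - state.rho * state.prev_y
        rows_star = rows - state.rho[:, None] * state.prev_row
    else:
        y_star = y.copy()
        rows_star = np.array(rows, copy=True)
    state.prev_y = y.copy()
    state.prev_row = np.array(rows, copy=True)
    state.n_seen += 1
    return y_star, rows_star, state
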