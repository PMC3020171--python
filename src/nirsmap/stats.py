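"""Running t-statistics, Bonferroni correction and the activation map.

At each step k the task coefficient of each channel is tested one-tailed
against zero.  With gram = sum_1^k H^T H and sigma2 = RSS / (k - L),

    t(k) = c^T beta_hat(k) / sqrt( sigma2 * c^T gram^{-1} c ),

compared against a t-distribution with k - L degrees of freedom.  A channel
becomes testable once dof >= 1 and its Gram matrix is invertible (with L = 5
regressors, the first testable step is k = 6).

Because the test repeats every step, the family-wise threshold is deflated
with the Bonferroni-type formula p_b = (1 - (1 - p_in)^j) / j, where j counts
the tests performed — either cumulatively over steps and channels (default,
conservative) or per step (channel count only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .kalman import KalmanState

__all__ = [
    "ContrastSpec",
    "TResult",
    "ActivationMap",
    "t_statistic",
    "bonferroni_threshold",
    "update_map",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Contrast vector selecting the coefficient combination under test.

    Default c = [1, 0, ..., 0]: the task coefficient, tested one-tailed for
    being greater than zero (a positive value indicates activation).
    """

    c: np.ndarray | None = None

    def vector(self, n_regressors: int) -> np.ndarray:
        if self.c is None:
            v = np.zeros(n_regressors)
            v[0] = 1.0
            return v
        v = np.asarray(self.c, dtype=float)
        if v.shape != (n_regressors,):
            raise ValueError(f"contrast length {v.shape} != L={n_regressors}")
        if not np.any(v):
            raise ValueError("contrast must have a nonzero entry")
        return v


@dataclass
class TResult:
    """Per-channel t-values with shared degrees of freedom.

    ``testable`` flags channels with dof >= 1 and an invertible Gram matrix;
    non-testable entries hold NaN rather than raising, so the streaming loop
    never stops on an early or degenerate step.
    """

    t: np.ndarray
    dof: int
    testable: np.ndarray


def t_statistic(state: KalmanState, contrast: ContrastSpec | None = None) -> TResult:
    """Running t-statistic for every channel at the filter's current step."""
    L = state.n_regressors
    c = (contrast or ContrastSpec()).vector(L)
    dof = state.k - L
    C = state.n_channels
    t = np.full(C, np.nan)
    testable = np.zeros(C, dtype=bool)
    if dof < 1:
        return TResult(t, dof, testable)
    rhs = np.broadcast_to(c[:, None], (C, L, 1))
    with np.errstate(all="ignore"):
        try:
            ginv_c = np.linalg.solve(state.gram, rhs)[:, :, 0]
        except np.linalg.LinAlgError:
            ginv_c = np.full((C, L), np.nan)
            for i in range(C):
                try:
                    ginv_c[i] = np.linalg.solve(state.gram[i], c)
                except np.linalg.LinAlgError:
                    pass
        sigma2 = state.rss / dof
        var = sigma2 * np.einsum("l,cl->c", c, ginv_c)
        num = np.einsum("l,cl->c", c, state.x_hat)
        t_all = num / np.sqrt(var)
    testable = np.isfinite(t_all)
    t[testable] = t_all[testable]
    return TResult(t, dof, testable)


def bonferroni_threshold(p_in: float, j: int) -> float:
    """Per-test threshold p_b = (1 - (1 - p_in)^j) / j for j tests.

    Identity at j=1 and strictly decreasing in j.  Evaluated via log1p/expm1
    so large j does not underflow.
    """
    if not (0.0 < p_in < 1.0):
        raise ValueError("p_in must lie in (0, 1)")
    if j < 1:
        raise ValueError("j must be >= 1")
    return -np.expm1(j * np.log1p(-p_in)) / j


@dataclass
class ActivationMap:
    """Per-channel activation bookkeeping at the current step.

    ``active`` is the Bonferroni-corrected call; first-crossing times are
    recorded once (in seconds) for both the uncorrected (p <= p_in) and
    corrected (p <= p_b) thresholds and never unset.
    """

    n_channels: int
    t_values: np.ndarray = field(init=False)
    dof: int = field(default=0, init=False)
    p_uncorrected: np.ndarray = field(init=False)
    p_threshold_corrected: float = field(default=np.nan, init=False)
    j: int = field(default=0, init=False)
    active: np.ndarray = field(init=False)
    first_active_time_uncorrected_s: np.ndarray = field(init=False)
    first_active_time_corrected_s: np.ndarray = field(init=False)
    n_testable_steps: int = field(default=0, init=False)
    tests_so_far: int = field(default=0, init=False)
    k: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        n = self.n_channels
        self.t_values = np.full(n, np.nan)
        self.p_uncorrected = np.full(n, np.nan)
        self.active = np.zeros(n, dtype=bool)
        self.first_active_time_uncorrected_s = np.full(n, np.nan)
        self.first_active_time_corrected_s = np.full(n, np.nan)

    def to_dataframe(self, channel_names=None) -> pd.DataFrame:
        names = channel_names or [f"ch{i + 1}" for i in range(self.n_channels)]
        return pd.DataFrame(
            {
                "channel": names,
                "t": self.t_values,
                "dof": self.dof,
                "p_uncorrected": self.p_uncorrected,
                "p_threshold_corrected": self.p_threshold_corrected,
                "active": self.active,
                "first_active_time_uncorrected_s":
                    self.first_active_time_uncorrected_s,
                "first_active_time_corrected_s":
                    self.first_active_time_corrected_s,
            }
        )


def update_map(
    amap: ActivationMap,
    tres: TResult,
    p_in: float,
    j_policy: str,
    k: int,
    sampling_rate_hz: float,
) -> ActivationMap:
    """Fold one step's t-values into the activation map.

    ``j_policy``: "cumulative" counts every test performed so far (channels x
    testable steps); "per_step" counts only the current step's channels.
    """
    if j_policy not in ("cumulative", "per_step"):
        raise ValueError(f"unknown j_policy {j_policy!r}")
    amap.k = k
    amap.t_values = tres.t.copy()
    amap.dof = tres.dof
    n_tests_now = int(tres.testable.sum())
    if n_tests_now == 0:
        return amap
    amap.n_testable_steps += 1
    amap.tests_so_far += n_tests_now
    j = amap.tests_so_far if j_policy == "cumulative" else n_tests_now
    amap.j = j
    amap.p_threshold_corrected = bonferroni_threshold(p_in, j)
    p = np.full(amap.n_channels, np.nan)
    p[tres.testable] = _stats.t.sf(tres.t[tres.testable], tres.dof)
    amap.p_uncorrected = p
    with np.errstate(invalid="ignore"):
        amap.active = p <= amap.p_threshold_corrected
    t_s = k / sampling_rate_hz
    new_unc = (p <= p_in) & np.isnan(amap.first_active_time_uncorrected_s)
    amap.first_active_time_uncorrected_s[new_unc] = t_s
    new_cor = amap.active & np.isnan(amap.first_active_time_corrected_s)
    amap.first_active_time_corrected_s[new_cor] = t_s
    return amap
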