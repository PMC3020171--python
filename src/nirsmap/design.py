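"""GLM design matrix for block-design NIRS experiments.

The regression model predicts each channel's dHbO series with L explanatory
variables: a task regressor (stimulus boxcar convolved with a double-gamma
hemodynamic response), a constant baseline, and a small set of discrete-cosine
(DCT) columns absorbing very-low-frequency drift.  With the default three DCT
columns the design has L = 5 regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ProtocolSpec",
    "FINGER_TAPPING_PROTOCOL",
    "HRFParams",
    "DesignMatrix",
    "stimulus_vector",
    "double_gamma_kernel",
    "dct_regressors",
    "build_design",
]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolSpec:
    """Block-design experimental protocol.

    A preparation (rest) period followed by ``n_sessions`` repetitions of a
    task block and a rest block, sampled at ``sampling_rate_hz``.
    """

    preparation_s: float
    n_sessions: int
    task_s: float
    rest_s: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if min(self.preparation_s, self.task_s, self.rest_s) < 0:
            raise ProtocolError("durations must be non-negative")
        if self.n_sessions < 1:
            raise ProtocolError("n_sessions must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ProtocolError("sampling_rate_hz must be positive")

    @property
    def total_duration_s(self) -> float:
        return self.preparation_s + self.n_sessions * (self.task_s + self.rest_s)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    def block_onsets_s(self) -> list[tuple[float, float]]:
        """(onset, offset) seconds of each task block."""
        out = []
        for s in range(self.n_sessions):
            onset = self.preparation_s + s * (self.task_s + self.rest_s)
            out.append((onset, onset + self.task_s))
        return out


#: The finger-tapping protocol used throughout the examples: 42 s preparation,
#: ten sessions of 21 s tapping + 30 s rest, sampled at 1.81 Hz (552 s total).
FINGER_TAPPING_PROTOCOL = ProtocolSpec(
    preparation_s=42.0,
    n_sessions=10,
    task_s=21.0,
    rest_s=30.0,
    sampling_rate_hz=1.81,
)


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic impulse response parameters (seconds).

    The kernel is a gamma-shaped positive lobe whose mode sits at
    ``peak_delay_s`` minus a gamma-shaped undershoot at ``undershoot_delay_s``
    scaled by ``1/undershoot_ratio``, truncated at ``kernel_length_s`` and
    normalized to peak amplitude 1.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion_s <= 0 or self.undershoot_dispersion_s <= 0:
            raise ValueError("dispersions must be positive")
        if self.kernel_length_s <= self.peak_delay_s:
            raise ValueError("kernel_length_s must exceed peak_delay_s")
        if self.undershoot_ratio <= 0:
            raise ValueError("undershoot_ratio must be positive")


@dataclass
class DesignMatrix:
    """Time-by-regressor matrix with named columns.

    Column order is ``[task, baseline, dct_1 ... dct_m]``.
    """

    matrix: np.ndarray
    regressor_names: list[str]
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.regressor_names):
            raise ValueError("name count must match column count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def row(self, k: int) -> np.ndarray:
        """Regressor row H(k) for the streaming loop (0-based k)."""
        if not (0 <= k < self.n_samples):
            raise IndexError(f"time step {k} out of range [0, {self.n_samples})")
        return self.matrix[k]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.regressor_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def stimulus_vector(protocol: ProtocolSpec) -> np.ndarray:
    """Binary stimulus vector: 1 during task blocks, 0 elsewhere.

    Block boundaries are floored to sample indices with half-open
    [onset, offset) coverage, so block lengths are deterministic.
    """
    n = protocol.n_samples
    if n == 0:
        raise ProtocolError("protocol spans zero samples")
    v = np.zeros(n)
    fs = protocol.sampling_rate_hz
    for onset_s, offset_s in protocol.block_onsets_s():
        i0 = int(np.floor(onset_s * fs))
        i1 = int(np.floor(offset_s * fs))
        v[i0 : min(i1, n)] = 1.0
    return v


def double_gamma_kernel(
    params: HRFParams | None = None, sampling_rate_hz: float = 1.81
) -> np.ndarray:
    """Sampled double-gamma impulse response, peak-normalized to 1.

    Gamma shapes are ``1 + delay/dispersion`` with scale ``dispersion`` so the
    positive lobe's mode is exactly ``peak_delay_s`` (and the undershoot's
    ``undershoot_delay_s``).  Support is [0, kernel_length_s).
    """
    p = params or HRFParams()
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    t = np.arange(0.0, p.kernel_length_s, 1.0 / sampling_rate_hz)
    peak = _stats.gamma.pdf(
        t, a=1.0 + p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s
    )
    under = _stats.gamma.pdf(
        t,
        a=1.0 + p.undershoot_delay_s / p.undershoot_dispersion_s,
        scale=p.undershoot_dispersion_s,
    )
    h = peak - under / p.undershoot_ratio
    return h / np.max(h)


def dct_regressors(
    n_samples: int,
    sampling_rate_hz: float,
    n_terms: int | None = None,
    cutoff_hz: float | None = None,
    min_terms: int = 0,
) -> np.ndarray:
    """Unit-normalized DCT-II high-pass columns c_r(k) = cos(pi r (2k+1) / 2N).

    The set size is either given directly (``n_terms``) or derived from a
    cut-off frequency: the number of DCT frequencies r/(2T) at or below
    ``cutoff_hz``, never below ``min_terms``.  Columns are mutually orthogonal
    and orthogonal to the constant.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if n_terms is None:
        if cutoff_hz is None:
            raise ValueError("specify n_terms or cutoff_hz")
        if cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        record_s = n_samples / sampling_rate_hz
        m = max(int(np.floor(2.0 * record_s * cutoff_hz)), min_terms)
        if m == 0:
            raise ValueError(
                "cut-off yields an empty DCT set; pass n_terms or min_terms "
                "explicitly"
            )
    else:
        m = int(n_terms)
        if m < 0:
            raise ValueError("n_terms must be non-negative")
    if m == 0:
        return np.empty((n_samples, 0))
    k = np.arange(n_samples)
    cols = np.stack(
        [np.cos(np.pi * r * (2 * k + 1) / (2 * n_samples)) for r in range(1, m + 1)],
        axis=1,
    )
    return cols / np.linalg.norm(cols, axis=0)


def build_design(
    protocol: ProtocolSpec,
    hrf: HRFParams | None = None,
    n_dct: int | None = 3,
    dct_cutoff_hz: float | None = None,
) -> DesignMatrix:
    """Assemble the design matrix [task, baseline, dct_1..dct_m].

    The task column is the stimulus vector causally convolved with the
    double-gamma kernel, truncated to the record length and peak-normalized to
    1 so its coefficient reads directly as the peak evoked response in uM.
    """
    n = protocol.n_samples
    stim = stimulus_vector(protocol)
    kernel = double_gamma_kernel(hrf, protocol.sampling_rate_hz)
    task = np.convolve(stim, kernel)[:n]
    peak = np.max(np.abs(task))
    if peak > 0:
        task = task / peak
    dct = dct_regressors(
        n, protocol.sampling_rate_hz, n_terms=n_dct, cutoff_hz=dct_cutoff_hz
    )
    matrix = np.column_stack([task, np.ones(n), dct])
    names = ["task", "baseline"] + [f"dct_{r}" for r in range(1, dct.shape[1] + 1)]
    return DesignMatrix(matrix, names, protocol.sampling_rate_hz)
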